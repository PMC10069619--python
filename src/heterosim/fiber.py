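"""Coarse-grained chromatin fiber: topology, folding, methylation bookkeeping.

The fiber is a simple path of nucleosome core beads (radius 5 nm), each
carrying one H3K9 tail-site particle (radius 1 nm) on a short tether.
One site per nucleosome keeps the per-nucleosome methylation state
(me0–me3) well defined.  The two central nucleosomes are permanently
tri-methylated: they stand in for the chemically induced HP1 recruitment
site that nucleates spreading, and demethylation attempts on them are
silently refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SystemConfig
from .engine import TetherSpec, minimum_image

__all__ = [
    "Nucleosome",
    "ChromatinFiber",
    "MethylationEvent",
    "build_fiber",
    "random_fold",
    "set_methylation",
    "replay_events",
    "occupancy_fractions",
]


@dataclass
class Nucleosome:
    index: int            # 0-based internal; reports are 1-based
    core_id: int
    site_id: int
    meth_state: int = 0   # 0..3
    permanent: bool = False


@dataclass
class MethylationEvent:
    step: int
    enzyme: str           # G9a / SUV39H / SETDB1 / KDM / manual
    nucleosome: int       # 0-based index
    from_state: int
    to_state: int
    accepted: bool = True


@dataclass
class ChromatinFiber:
    """Ordered nucleosome chain with per-nucleosome H3K9 methylation."""

    nucleosomes: list
    spacing_bp: float
    core_site_tether: TetherSpec
    linker_tether: TetherSpec
    event_log: list = field(default_factory=list)
    coordinates: np.ndarray | None = None  # (n_particles, 3), set by random_fold

    @property
    def n(self) -> int:
        return len(self.nucleosomes)

    def states(self) -> np.ndarray:
        return np.array([nuc.meth_state for nuc in self.nucleosomes], dtype=np.int8)

    def permanent_mask(self) -> np.ndarray:
        return np.array([nuc.permanent for nuc in self.nucleosomes], dtype=bool)

    def permanent_positions_1based(self) -> tuple:
        return tuple(i + 1 for i, nuc in enumerate(self.nucleosomes) if nuc.permanent)


def build_fiber(n: int, config: SystemConfig) -> ChromatinFiber:
    """Fiber of ``n`` nucleosomes; the two central ones permanently me3.

    Central pair at 1-based positions ⌊n/2⌋ and ⌊n/2⌋+1.  Particle ids:
    cores 0..n-1, sites n..2n-1.  Implied spacing fiber_span_bp/n (~196 bp
    for the default 20-kb / 102-nucleosome fiber) is kept as metadata.
    """
    if n < 2:
        raise ConfigError(f"a fiber needs at least 2 nucleosomes, got {n}")
    geo = config.geometry
    r_core = geo.radius_nm["core"]
    r_site = geo.radius_nm["h3k9"]
    core_site = TetherSpec(
        r_core + r_site, r_core + r_site + geo.core_site_slack_nm, geo.damping_k_per_nm
    )
    linker = TetherSpec(
        2 * r_core, 2 * r_core + geo.linker_slack_nm, geo.damping_k_per_nm
    )
    center_lo = n // 2 - 1  # 0-based ⌊n/2⌋ in 1-based numbering
    nucleosomes = []
    for i in range(n):
        permanent = i in (center_lo, center_lo + 1)
        nucleosomes.append(
            Nucleosome(
                index=i,
                core_id=i,
                site_id=n + i,
                meth_state=3 if permanent else 0,
                permanent=permanent,
            )
        )
    return ChromatinFiber(
        nucleosomes=nucleosomes,
        spacing_bp=config.fiber_span_bp / n,
        core_site_tether=core_site,
        linker_tether=linker,
    )


def _sample_tether_distance(spec: TetherSpec, rng: np.random.Generator) -> float:
    """Draw a pair distance ∝ r² on [min_len, free_len] (the free range of
    the equilibrium density r²·w(r), truncated at the free length)."""
    u = rng.random()
    lo3, hi3 = spec.min_len**3, spec.free_len**3
    return (lo3 + u * (hi3 - lo3)) ** (1.0 / 3.0)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_fold(
    fiber: ChromatinFiber,
    config: SystemConfig,
    rng: np.random.Generator,
    max_retries: int = 2000,
) -> np.ndarray:
    """Self-avoiding random placement of cores and tail sites.

    Cores are grown sequentially: each next core at a tether-respecting
    random distance and uniform direction from the previous, rejecting
    hard-core overlaps with everything already placed; each site is then
    attached the same way to its core.  Returns (2n, 3) coordinates
    (cores then sites) and stores them on the fiber.
    """
    geo = config.geometry
    box = float(config.box_edge_nm)
    n = fiber.n
    r_core = geo.radius_nm["core"]
    r_site = geo.radius_nm["h3k9"]
    radii = np.concatenate([np.full(n, r_core), np.full(n, r_site)])
    coords = np.empty((2 * n, 3))
    placed: list[int] = []

    def overlaps(pos: np.ndarray, my_radius: float, skip: set) -> bool:
        for j in placed:
            if j in skip:
                continue
            d = minimum_image(pos - coords[j], box)
            if d @ d < (my_radius + radii[j]) ** 2:
                return True
        return False

    coords[0] = rng.random(3) * box
    placed.append(0)
    for i in range(1, n):
        for attempt in range(max_retries):
            dist = _sample_tether_distance(fiber.linker_tether, rng)
            pos = (coords[i - 1] + dist * _random_unit(rng)) % box
            if not overlaps(pos, r_core, skip={i - 1}):
                coords[i] = pos
                break
        else:
            raise RuntimeError(
                f"random_fold: failed to place core {i} after {max_retries} "
                "retries (box too small for the fiber)"
            )
        placed.append(i)
    for i in range(n):
        sid = n + i
        for attempt in range(max_retries):
            dist = _sample_tether_distance(fiber.core_site_tether, rng)
            pos = (coords[i] + dist * _random_unit(rng)) % box
            if not overlaps(pos, r_site, skip={i}):
                coords[sid] = pos
                break
        else:
            raise RuntimeError(
                f"random_fold: failed to place H3K9 site {i} after "
                f"{max_retries} retries (box too small)"
            )
        placed.append(sid)
    fiber.coordinates = coords
    return coords


def set_methylation(
    fiber: ChromatinFiber,
    index: int,
    new_state: int,
    step: int = 0,
    enzyme: str = "manual",
) -> ChromatinFiber:
    """Apply one ±1 methylation event to nucleosome ``index`` (0-based).

    Demethylation of a permanent nucleosome is refused silently (logged as
    a rejected event, state unchanged) — permanence models the nucleation
    site.  A |Δstate| ≠ 1 transition is a precondition violation.
    """
    nuc = fiber.nucleosomes[index]
    old = nuc.meth_state
    if abs(new_state - old) != 1 or not 0 <= new_state <= 3:
        raise ValueError(
            f"methylation must change by ±1 within 0..3 (got {old}→{new_state})"
        )
    if nuc.permanent and new_state < 3:
        fiber.event_log.append(
            MethylationEvent(step, enzyme, index, old, old, accepted=False)
        )
        return fiber
    nuc.meth_state = new_state
    fiber.event_log.append(MethylationEvent(step, enzyme, index, old, new_state))
    return fiber


def replay_events(
    initial_states: np.ndarray,
    events,
) -> np.ndarray:
    """Reconstruct final per-nucleosome states from an event log.

    Accepts either :class:`MethylationEvent` objects or (nucleosome,
    from_state, to_state) rows; used to audit that the event log and the
    sampled methylation field agree exactly.
    """
    states = np.asarray(initial_states, dtype=np.int8).copy()
    for ev in events:
        if isinstance(ev, MethylationEvent):
            if not ev.accepted:
                continue
            nuc, from_state, to_state = ev.nucleosome, ev.from_state, ev.to_state
        else:
            nuc, from_state, to_state = int(ev[0]), int(ev[1]), int(ev[2])
        if states[nuc] != from_state:
            raise ValueError(
                f"event log inconsistent at nucleosome {nuc}: "
                f"state {states[nuc]} but event says {from_state}→{to_state}"
            )
        states[nuc] = to_state
    return states


def occupancy_fractions(states_matrix: np.ndarray) -> np.ndarray:
    """Fractions f_me0..f_me3 per time sample from a (samples, n) state
    matrix; rows always sum to one."""
    states = np.asarray(states_matrix)
    out = np.empty((states.shape[0], 4))
    for s in range(4):
        out[:, s] = (states == s).mean(axis=1)
    return out
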