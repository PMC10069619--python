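"""System assembly: configuration → particle arrays → Monte Carlo runs.

Particle layout: nucleosome cores ``0..n-1``, H3K9 sites ``n..2n-1``,
then protein beads in species order (HP1 as CD+CSD pairs, each HMT as
bind+cat pairs, KDM as single beads).  Molecule-level diffusivities are
converted to per-bead values (``D_bead = n_beads × D_species``) so that a
tethered chain's centre of mass diffuses at the calibrated species rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .binding import register_interactions, rules_to_arrays
from .config import ENZYMES, PROTEINS, RULE_IDS, SystemConfig
from .engine import VoxelGrid, minimum_image
from .fiber import ChromatinFiber, build_fiber, random_fold
from .reactions import pt_arrays

__all__ = ["System", "RunResult", "build_system", "KIND_NAMES", "ENZYME_NAMES"]

KIND_NAMES = (
    "nucleosome_core",
    "h3k9_site",
    "hp1_cd",
    "hp1_csd",
    "hmt_bind",
    "hmt_cat",
    "kdm",
)
ENZYME_NAMES = ("G9a", "SUV39H", "SETDB1", "KDM")

_KIND_RADIUS_KEY = {
    _kernel.CORE: "core",
    _kernel.H3K9: "h3k9",
    _kernel.CD: "hp1_bead",
    _kernel.CSD: "hp1_bead",
    _kernel.BIND: "hmt_bead",
    _kernel.CAT: "hmt_bead",
    _kernel.KDM: "kdm",
}


@dataclass
class RunResult:
    """Sampled output of one kernel run."""

    times_us: np.ndarray             # sample times, µs (absolute)
    meth: np.ndarray                 # (samples, n_nucleosomes) int8
    bond_counts: np.ndarray          # (samples, n_rules) int32
    events: pd.DataFrame             # step, enzyme, nucleosome, from_state, to_state
    lifetimes: dict                  # rule_id → residence-time statistics
    positions_nm: np.ndarray | None  # (samples, n_particles, 3) unwrapped
    seed: int
    n_steps: int


@dataclass
class System:
    """A fully assembled simulation state plus its static tables."""

    config: SystemConfig
    fiber: ChromatinFiber
    pos: np.ndarray
    upos: np.ndarray
    kind: np.ndarray
    enzyme: np.ndarray
    radius: np.ndarray
    sigma: np.ndarray
    sibling: np.ndarray
    mv_a: np.ndarray
    mv_b: np.ndarray
    mv_sig: np.ndarray
    mv_sigint: np.ndarray
    mv_imin: np.ndarray
    mv_ifree: np.ndarray
    nuc_of: np.ndarray
    site_of: np.ndarray
    t_indptr: np.ndarray
    t_partner: np.ndarray
    t_min: np.ndarray
    t_free: np.ndarray
    meth: np.ndarray
    perm: np.ndarray
    sl_partner: np.ndarray
    sl_rule: np.ndarray
    sl_formed: np.ndarray
    sl_back: np.ndarray
    cat_active: np.ndarray
    cat_reactivate: np.ndarray
    rule_pa: np.ndarray
    rule_pd: np.ndarray
    rule_capture2: np.ndarray
    pt_hmt: np.ndarray
    pt_kdm: np.ndarray
    species_slices: dict = field(default_factory=dict)
    step_count: int = 0

    @property
    def n_particles(self) -> int:
        return self.pos.shape[0]

    @property
    def n_nucleosomes(self) -> int:
        return self.meth.shape[0]

    @property
    def box_edge(self) -> float:
        return float(self.config.box_edge_nm)

    # ------------------------------------------------------------------
    def run(
        self,
        n_steps: int | None = None,
        seed: int = 0,
        report_interval: int | None = None,
        record_positions: bool | None = None,
        event_capacity: int = 2_000_000,
        lifetime_capacity: int = 500_000,
    ) -> RunResult:
        """Advance the system ``n_steps`` and collect samples.

        The kernel mutates the system state in place, so consecutive calls
        continue one trajectory (absolute step counts are preserved in the
        logs).
        """
        cfg = self.config
        n_steps = cfg.n_steps if n_steps is None else int(n_steps)
        report = cfg.report_interval if report_interval is None else int(report_interval)
        record = cfg.record_positions if record_positions is None else bool(record_positions)
        n_samples = n_steps // report
        n_nuc = self.n_nucleosomes
        N = self.n_particles

        samp_meth = np.zeros((max(1, n_samples), n_nuc), dtype=np.int8)
        samp_bonds = np.zeros((max(1, n_samples), _kernel.N_RULES), dtype=np.int32)
        samp_pos = (
            np.zeros((max(1, n_samples), N, 3)) if record else np.zeros((1, 1, 3))
        )
        ev_step = np.zeros(event_capacity, dtype=np.int64)
        ev_enzyme = np.zeros(event_capacity, dtype=np.int8)
        ev_nuc = np.zeros(event_capacity, dtype=np.int32)
        ev_from = np.zeros(event_capacity, dtype=np.int8)
        ev_to = np.zeros(event_capacity, dtype=np.int8)
        lt_rule = np.zeros(lifetime_capacity, dtype=np.int8)
        lt_dur = np.zeros(lifetime_capacity, dtype=np.int64)
        lt_n = np.zeros(_kernel.N_RULES, dtype=np.int64)
        lt_sum = np.zeros(_kernel.N_RULES, dtype=np.float64)
        cens_n = np.zeros(_kernel.N_RULES, dtype=np.int64)
        cens_sum = np.zeros(_kernel.N_RULES, dtype=np.float64)

        box = self.box_edge
        ncell = max(1, int(box / cfg.voxel_edge_nm))
        max_radius = float(self.radius.max())
        capt = np.sqrt(self.rule_capture2)
        assoc_range = np.zeros(_kernel.N_KINDS)
        # association is enumerated from the target side: H3K9 sites and CSDs
        assoc_range[_kernel.H3K9] = max(
            capt[_kernel.R_CD],
            capt[_kernel.R_KME_G9A : _kernel.R_KME_SETDB1 + 1].max(),
            capt[_kernel.R_CAT : _kernel.R_CAT + 3].max(),
            capt[_kernel.R_KDM],
        )
        assoc_range[_kernel.CSD] = max(
            capt[_kernel.R_CSD],
            capt[_kernel.R_BINDCSD : _kernel.R_BINDCSD + 3].max(),
        )
        if ncell >= 3:
            cell_edge = box / ncell
            needed = max(2.0 * max_radius, assoc_range.max())
            if cell_edge < needed:
                raise ValueError(
                    f"voxel edge {cell_edge:.3g} nm below the largest "
                    f"interaction distance {needed:.3g} nm"
                )

        ev_count, lt_count = _kernel.run_kernel(
            self.pos, self.upos, self.meth,
            self.sl_partner, self.sl_rule, self.sl_formed, self.sl_back,
            self.cat_active, self.cat_reactivate,
            self.kind, self.enzyme, self.radius, self.sibling,
            self.nuc_of, self.perm,
            self.mv_a, self.mv_b, self.mv_sig, self.mv_sigint,
            self.mv_imin, self.mv_ifree,
            self.t_indptr, self.t_partner, self.t_min, self.t_free,
            self.rule_pa, self.rule_pd, self.rule_capture2,
            self.pt_hmt, self.pt_kdm, assoc_range,
            box, ncell,
            cfg.geometry.damping_k_per_nm, cfg.geometry.bond_slack_nm,
            cfg.geometry.max_step_nm, max_radius,
            n_steps, report, self.step_count,
            int(cfg.cat_refractory_steps), int(seed) & 0x7FFFFFFF,
            samp_meth, samp_bonds, samp_pos, record,
            ev_step, ev_enzyme, ev_nuc, ev_from, ev_to,
            lt_rule, lt_dur, lt_n, lt_sum, cens_n, cens_sum,
        )

        dt = cfg.time_step_us
        times = (self.step_count + (np.arange(n_samples) + 1) * report) * dt
        events = pd.DataFrame(
            {
                "step": ev_step[:ev_count],
                "enzyme": [ENZYME_NAMES[e] for e in ev_enzyme[:ev_count]],
                "nucleosome": ev_nuc[:ev_count],
                "from_state": ev_from[:ev_count],
                "to_state": ev_to[:ev_count],
            }
        )
        lifetimes = {}
        for r, rid in enumerate(RULE_IDS):
            mask = lt_rule[:lt_count] == r
            lifetimes[rid] = {
                "completed_us": lt_dur[:lt_count][mask].astype(float) * dt,
                "n_completed": int(lt_n[r]),
                "sum_completed_us": float(lt_sum[r]) * dt,
                "n_censored": int(cens_n[r]),
                "sum_censored_us": float(cens_sum[r]) * dt,
            }
        self.step_count += n_steps
        # sync fiber bookkeeping with kernel state
        for q, nuc in enumerate(self.fiber.nucleosomes):
            nuc.meth_state = int(self.meth[q])
        return RunResult(
            times_us=times,
            meth=samp_meth[:n_samples],
            bond_counts=samp_bonds[:n_samples],
            events=events,
            lifetimes=lifetimes,
            positions_nm=samp_pos[:n_samples] if record else None,
            seed=int(seed),
            n_steps=n_steps,
        )

    def step(self, seed: int = 0) -> None:
        """Advance exactly one sweep (move/dissociate/associate/react)."""
        self.run(n_steps=1, report_interval=1, seed=seed, record_positions=False)

    # ------------------------------------------------------------------
    def validate_state(self, overlap_tol: float = 1e-9) -> None:
        """Hard consistency audit: particles in box, reciprocal bonds,
        no hard-core overlaps between non-linked particles."""
        box = self.box_edge
        if np.any(self.pos < 0) or np.any(self.pos >= box):
            raise AssertionError("particle outside box")
        for i in range(self.n_particles):
            for s in range(2):
                j = self.sl_partner[i, s]
                if j >= 0:
                    sb = self.sl_back[i, s]
                    if self.sl_partner[j, sb] != i:
                        raise AssertionError(f"orphan bond {i}↔{j}")
        linked = set()
        for i in range(self.n_particles):
            for e in range(self.t_indptr[i], self.t_indptr[i + 1]):
                linked.add((i, int(self.t_partner[e])))
            for s in range(2):
                j = self.sl_partner[i, s]
                if j >= 0:
                    linked.add((i, int(j)))
        pos = self.pos
        for i in range(self.n_particles):
            delta = minimum_image(pos - pos[i], box)
            d = np.sqrt((delta**2).sum(axis=1))
            rr = self.radius + self.radius[i]
            bad = np.where(d < rr - overlap_tol)[0]
            for j in bad:
                if j != i and (i, int(j)) not in linked:
                    raise AssertionError(
                        f"hard-core overlap between particles {i} and {j}"
                    )

    def bead_ids(self, species: str, bead: int = 0) -> np.ndarray:
        """Particle ids of one bead of every copy of a species
        (bead 0 = CD / bind / the single bead; bead 1 = CSD / cat)."""
        start, stop, nbeads = self.species_slices[species]
        return np.arange(start + bead, stop, nbeads, dtype=int)


# ---------------------------------------------------------------------------


def _place_proteins(
    system_arrays: dict,
    config: SystemConfig,
    rng: np.random.Generator,
    start: int,
    max_retries: int = 20_000,
) -> None:
    """Scatter protein beads uniformly at random, avoiding overlaps."""
    pos = system_arrays["pos"]
    radius = system_arrays["radius"]
    sibling = system_arrays["sibling"]
    box = float(config.box_edge_nm)
    grid = VoxelGrid(box, max(2.0 * radius.max(), 10.0))
    for i in range(start):
        grid.insert(i, pos[i])
    geo = config.geometry
    i = start
    N = pos.shape[0]
    while i < N:
        sib = sibling[i]
        for attempt in range(max_retries):
            cand = rng.random(3) * box
            if _clear(cand, radius[i], grid, pos, radius, box):
                break
        else:
            raise RuntimeError(f"could not place particle {i} (box too crowded)")
        pos[i] = cand
        grid.insert(i, cand)
        if sib == i + 1:  # second bead of a two-bead molecule
            mn = radius[i] + radius[i + 1]
            fr = geo.bindcat_free_len_nm
            for attempt in range(max_retries):
                u = rng.random()
                dist = (mn**3 + u * (fr**3 - mn**3)) ** (1 / 3)
                vec = rng.normal(size=3)
                vec /= np.linalg.norm(vec)
                cand2 = (cand + dist * vec) % box
                if _clear(cand2, radius[i + 1], grid, pos, radius, box, skip=i):
                    break
            else:
                raise RuntimeError(f"could not place bead {i + 1}")
            pos[i + 1] = cand2
            grid.insert(i + 1, cand2)
            i += 2
        else:
            i += 1


def _clear(cand, r_self, grid, pos, radius, box, skip=-1) -> bool:
    cutoff = r_self + radius.max()
    for j in grid.neighbor_query(cand, cutoff):
        if j == skip:
            continue
        d = minimum_image(pos[j] - cand, box)
        if d @ d < (r_self + radius[j]) ** 2:
            return False
    return True


def build_system(config: SystemConfig, rng: np.random.Generator | int = 0) -> System:
    """Build fiber + proteins, fold and scatter them, and freeze all tables."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = config.n_nucleosomes
    fiber = build_fiber(n, config)
    geo = config.geometry
    copies = config.effective_copies()

    # ---- particle attribute arrays -----------------------------------
    kinds: list[int] = [_kernel.CORE] * n + [_kernel.H3K9] * n
    enzymes: list[int] = [-1] * (2 * n)
    sibling: list[int] = [-1] * (2 * n)
    species_slices: dict = {}
    dt = config.time_step_us

    def add_molecule(kind_codes, enzyme_code):
        first = len(kinds)
        for kc in kind_codes:
            kinds.append(kc)
            enzymes.append(enzyme_code)
            sibling.append(-1)
        if len(kind_codes) == 2:
            sibling[first] = first + 1
            sibling[first + 1] = first

    for species in PROTEINS:
        start = len(kinds)
        if species == "HP1":
            beads, enzyme_code = (_kernel.CD, _kernel.CSD), -1
        elif species == "KDM":
            beads, enzyme_code = (_kernel.KDM,), _kernel.KDM_ENZ
        else:
            beads, enzyme_code = (_kernel.BIND, _kernel.CAT), ENZYMES.index(species)
        for _ in range(copies[species]):
            add_molecule(beads, enzyme_code)
        species_slices[species] = (start, len(kinds), len(beads))

    N = len(kinds)
    kind = np.array(kinds, dtype=np.int8)
    enzyme = np.array(enzymes, dtype=np.int8)
    sibling_arr = np.array(sibling, dtype=np.int32)
    radius = np.array([geo.radius_nm[_KIND_RADIUS_KEY[k]] for k in kinds])
    diff = config.diffusivity

    # ---- mobile units ------------------------------------------------
    # fiber beads and KDM move as single beads; HP1 and HMTs move as
    # two-bead molecules (COM move at the species diffusivity plus a
    # COM-preserving internal relaxation move at twice that rate, the
    # relative diffusivity of two free beads)
    mv_a: list[int] = []
    mv_b: list[int] = []
    mv_sig: list[float] = []
    mv_sigint: list[float] = []
    mv_imin: list[float] = []
    mv_ifree: list[float] = []
    sigma = np.zeros(N)  # per-bead species sigma, kept for reference ops

    def add_mover(a: int, b: int, d_species: float, imin: float = 0.0, ifree: float = 0.0):
        mv_a.append(a)
        mv_b.append(b)
        mv_sig.append(np.sqrt(2.0 * d_species * dt))
        mv_sigint.append(np.sqrt(4.0 * d_species * dt) if b >= 0 else 0.0)
        mv_imin.append(imin)
        mv_ifree.append(ifree)
        sigma[a] = np.sqrt(2.0 * d_species * dt)
        if b >= 0:
            sigma[b] = sigma[a]

    for q in range(n):
        add_mover(q, -1, diff["core"])
    for q in range(n):
        add_mover(n + q, -1, diff["h3k9"])
    for species in PROTEINS:
        start0, stop0, nbeads = species_slices[species]
        d_species = diff[species]
        if nbeads == 1:
            for a in range(start0, stop0):
                add_mover(a, -1, d_species)
        else:
            for a in range(start0, stop0, 2):
                add_mover(
                    a, a + 1, d_species,
                    imin=radius[a] + radius[a + 1],
                    ifree=geo.bindcat_free_len_nm,
                )

    nuc_of = np.full(N, -1, dtype=np.int32)
    nuc_of[n : 2 * n] = np.arange(n)
    site_of = np.arange(n, 2 * n, dtype=np.int32)

    # ---- permanent tethers (CSR over both directions) ----------------
    edges = []
    for q in range(n - 1):
        edges.append((q, q + 1, fiber.linker_tether.min_len, fiber.linker_tether.free_len))
    for q in range(n):
        edges.append((q, n + q, fiber.core_site_tether.min_len, fiber.core_site_tether.free_len))
    for species in PROTEINS:
        start, stop, nbeads = species_slices[species]
        if nbeads == 2 and stop > start:
            mn = radius[start] + radius[start + 1]
            fr = geo.bindcat_free_len_nm
            for a in range(start, stop, 2):
                edges.append((a, a + 1, mn, fr))
    counts = np.zeros(N + 1, dtype=np.int32)
    for a, b, _, _ in edges:
        counts[a + 1] += 1
        counts[b + 1] += 1
    t_indptr = np.cumsum(counts).astype(np.int32)
    fill = t_indptr[:-1].copy()
    n_dir = 2 * len(edges)
    t_partner = np.zeros(n_dir, dtype=np.int32)
    t_min = np.zeros(n_dir)
    t_free = np.zeros(n_dir)
    for a, b, mn, fr in edges:
        t_partner[fill[a]] = b
        t_min[fill[a]] = mn
        t_free[fill[a]] = fr
        fill[a] += 1
        t_partner[fill[b]] = a
        t_min[fill[b]] = mn
        t_free[fill[b]] = fr
        fill[b] += 1

    # ---- coordinates -------------------------------------------------
    pos = np.zeros((N, 3))
    pos[: 2 * n] = random_fold(fiber, config, rng)
    arrays = {"pos": pos, "radius": radius, "sibling": sibling_arr}
    _place_proteins(arrays, config, rng, start=2 * n)

    # unwrapped coordinates: continuous within every tethered unit, so
    # intramolecular separations read off the unwrapped frame are physical
    box = float(config.box_edge_nm)
    upos = pos.copy()
    for q in range(1, n):
        upos[q] = upos[q - 1] + minimum_image(pos[q] - pos[q - 1], box)
    for q in range(n):
        upos[n + q] = upos[q] + minimum_image(pos[n + q] - pos[q], box)
    for species in PROTEINS:
        start0, stop0, nbeads = species_slices[species]
        if nbeads == 2:
            for a in range(start0, stop0, 2):
                upos[a + 1] = upos[a] + minimum_image(pos[a + 1] - pos[a], box)

    rules = register_interactions(config)
    rule_arrays = rules_to_arrays(rules)
    pt_hmt, pt_kdm = pt_arrays(config)

    return System(
        config=config,
        fiber=fiber,
        pos=pos,
        upos=upos,
        kind=kind,
        enzyme=enzyme,
        radius=radius,
        sigma=sigma,
        mv_a=np.array(mv_a, dtype=np.int32),
        mv_b=np.array(mv_b, dtype=np.int32),
        mv_sig=np.array(mv_sig),
        mv_sigint=np.array(mv_sigint),
        mv_imin=np.array(mv_imin),
        mv_ifree=np.array(mv_ifree),
        sibling=sibling_arr,
        nuc_of=nuc_of,
        site_of=site_of,
        t_indptr=t_indptr,
        t_partner=t_partner,
        t_min=t_min,
        t_free=t_free,
        meth=fiber.states().copy(),
        perm=fiber.permanent_mask().copy(),
        sl_partner=np.full((N, 2), -1, dtype=np.int32),
        sl_rule=np.full((N, 2), -1, dtype=np.int8),
        sl_formed=np.zeros((N, 2), dtype=np.int64),
        sl_back=np.zeros((N, 2), dtype=np.int8),
        cat_active=np.ones(N, dtype=np.bool_),
        cat_reactivate=np.zeros(N, dtype=np.int64),
        rule_pa=rule_arrays["pa"],
        rule_pd=rule_arrays["pd"],
        rule_capture2=rule_arrays["capture2"],
        pt_hmt=pt_hmt,
        pt_kdm=pt_kdm,
        species_slices=species_slices,
    )
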