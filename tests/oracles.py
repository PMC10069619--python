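"""Independent oracles for the test suite.

Everything here is deliberately written from first principles — naive
enumeration, rejection sampling, closed forms, and a textbook Gillespie
SSA — and never calls into the package's production code paths it is
used to check.
"""

from __future__ import annotations

import numpy as np


def brute_force_neighbors(
    positions: dict,
    query: np.ndarray,
    cutoff: float,
    box: float,
) -> list:
    """All-pairs neighbor search with minimum-image distances (closed ball)."""
    out = []
    q = np.asarray(query, dtype=float)
    for pid, p in positions.items():
        d = np.asarray(p, dtype=float) - q
        d -= box * np.round(d / box)
        if float(d @ d) <= cutoff * cutoff:
            out.append(pid)
    return sorted(out)


def chain_growth_fold(
    n: int,
    bead_radius: float,
    min_len: float,
    free_len: float,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Self-avoiding tethered chain by rejection sampling.

    Each next bead is drawn uniformly from the ball of radius ``free_len``
    around the previous bead, rejecting draws below ``min_len`` or
    overlapping any placed bead — i.e. the distance density on
    [min_len, free_len] is ∝ r², matching a tether-respecting uniform
    placement.  Returns (n, 3) coordinates in open space.
    """
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(max_tries):
            v = rng.uniform(-free_len, free_len, 3)
            r = np.linalg.norm(v)
            if r > free_len or r < min_len:
                continue
            cand = coords[i - 1] + v
            ok = True
            for j in range(i - 1):
                if np.linalg.norm(cand - coords[j]) < 2 * bead_radius:
                    ok = False
                    break
            if ok:
                coords[i] = cand
                break
        else:
            raise RuntimeError("chain growth failed")
    return coords


def tether_distance_moments(min_len: float, free_len: float, k: float) -> float:
    """Mean pair distance of the stationary density ∝ r²·w(r) by direct
    1D numerical integration (w = 1 on [min, free], exp(-k·Δd) beyond)."""
    hi = free_len + 12.0 / k
    r = np.linspace(min_len, hi, 20_000)
    w = np.where(r <= free_len, 1.0, np.exp(-k * (r - free_len)))
    dens = r * r * w
    return float(np.trapezoid(r * dens, r) / np.trapezoid(dens, r))


def two_state_bound_fraction(n_sites: int, n_binders: int, pa: float, pd: float, q: float) -> float:
    """Stationary bound fraction of one binder against ``n_sites`` sites
    from the per-step two-state chain: P(bind) = n_sites·q·pa per free
    step, P(release) = pd per bound step (single-binder approximation)."""
    if n_binders != 1:
        raise ValueError("closed form given for a single binder")
    on = n_sites * q * pa
    return on / (on + pd)


def gillespie_kdm_sites(
    n_sites: int,
    init_state: int,
    n_kdm: int,
    kon_per_step: float,
    koff_per_step: float,
    pt_per_step: float,
    t_grid_steps: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """SSA for the demethylase subsystem: ``n_sites`` independent sites
    sharing a pool of ``n_kdm`` erasers.

    Site state = (methylation m, bound flag).  Rates per unit step:
    binding of a free eraser to a free site with m ≥ 1: n_free·kon;
    unbinding: koff; demethylation while bound and m ≥ 1: pt.  Returns
    the mean methylation state over sites at each requested time.
    """
    m = np.full(n_sites, init_state, dtype=int)
    bound = np.full(n_sites, -1, dtype=int)  # -1 free, else occupied
    t = 0.0
    out = np.zeros((len(t_grid_steps), ))
    gi = 0
    while gi < len(t_grid_steps):
        n_free_kdm = n_kdm - int((bound >= 0).sum())
        rates = []
        moves = []
        for s in range(n_sites):
            if bound[s] < 0 and m[s] >= 1:
                rates.append(n_free_kdm * kon_per_step)
                moves.append(("bind", s))
            if bound[s] >= 0:
                rates.append(koff_per_step)
                moves.append(("unbind", s))
                if m[s] >= 1:
                    rates.append(pt_per_step)
                    moves.append(("react", s))
        total = float(np.sum(rates))
        if total == 0.0:
            while gi < len(t_grid_steps):
                out[gi] = m.mean()
                gi += 1
            break
        dt = rng.exponential(1.0 / total)
        t_new = t + dt
        while gi < len(t_grid_steps) and t_grid_steps[gi] < t_new:
            out[gi] = m.mean()
            gi += 1
        t = t_new
        pick = rng.choice(len(rates), p=np.asarray(rates) / total)
        what, s = moves[pick]
        if what == "bind":
            bound[s] = 1
        elif what == "unbind":
            bound[s] = -1
        else:
            m[s] -= 1
    return out
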