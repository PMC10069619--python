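"""Validation assays: controlled miniature experiments that measure the
model's emergent kinetic quantities back from trajectories.

Each assay builds a purpose-reduced system (one or two species, binding
or transport isolated) exactly as a bench calibration experiment would,
runs it, and feeds the samples to the estimators in
:mod:`heterosim.calibration`:

* :func:`free_hp1_diffusion` — protein-only box, no binding; MSD fit of
  the HP1 diffusion coefficient.
* :func:`hp1_residence_koff` — HP1 on a tri-methylated fiber, binding
  only; censored-MLE exponential off-rate from bond residence times.
* :func:`chromatin_binding_kd` — one enzyme species (plus optionally
  HP1) against a uniformly methylated fiber with catalysis switched off;
  apparent dissociation constant from time-averaged free/bound counts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .binding import rule_index
from .calibration import (
    DiffusionEstimate,
    KdEstimate,
    KoffEstimate,
    estimate_diffusion,
    estimate_kd,
    estimate_koff,
)
from .config import PROTEINS, RULE_IDS, KineticsConfig, SystemConfig
from .system import System, build_system

__all__ = [
    "free_hp1_diffusion",
    "hp1_residence_koff",
    "chromatin_binding_kd",
    "knockdown_plateau",
    "relative_plateau_decrease",
]


def _no_binding_kinetics() -> KineticsConfig:
    return KineticsConfig(
        mode="raw",
        pa={r: 0.0 for r in RULE_IDS},
        pd={r: 1e-6 for r in RULE_IDS},
    )


def _copies(**kwargs) -> dict:
    copies = {name: 0 for name in PROTEINS}
    copies.update(kwargs)
    return copies


def _build(config: SystemConfig, seed: int) -> tuple[System, int]:
    ss = np.random.SeedSequence([int(seed)])
    init_ss, kernel_ss = ss.spawn(2)
    system = build_system(config, rng=np.random.default_rng(init_ss))
    return system, int(kernel_ss.generate_state(1)[0] & 0x7FFFFFFF)


def free_hp1_diffusion(
    seed: int = 0,
    n_hp1: int = 24,
    n_steps: int = 100_000,
    sample_every: int = 10,
    lag_range_steps: tuple = (10, 1000),
) -> DiffusionEstimate:
    """Diffusion coefficient of free HP1 from a protein-only box.

    No binding rules are enabled; the fiber is reduced to the minimal
    two-nucleosome stub.  The ensemble MSD of the HP1 beads is fitted as
    MSD(τ) = 6·D·τ + c over lags spanning ``lag_range_steps``; the
    intercept absorbs the intramolecular (CD–CSD tether) relaxation so
    the slope reports the molecule's transport coefficient.
    """
    config = SystemConfig(
        n_nucleosomes=2,
        fiber_span_bp=392.0,
        protein_copies=_copies(HP1=n_hp1),
        kinetics=_no_binding_kinetics(),
        n_steps=int(n_steps),
        report_interval=int(sample_every),
        record_positions=True,
    )
    system, kseed = _build(config, seed)
    result = system.run(seed=kseed)
    beads = np.concatenate([system.bead_ids("HP1", 0), system.bead_ids("HP1", 1)])
    lags_steps = np.unique(
        np.round(
            np.logspace(
                np.log10(lag_range_steps[0]), np.log10(lag_range_steps[1]), 12
            )
        ).astype(int)
    )
    lags = np.unique(np.maximum(1, lags_steps // sample_every))
    return estimate_diffusion(
        result.positions_nm[:, beads, :],
        sample_interval_us=sample_every * config.time_step_us,
        lags=lags,
        rng=np.random.default_rng(seed + 1),
    )


def hp1_residence_koff(
    seed: int = 0,
    n_nucleosomes: int = 24,
    n_hp1: int = 48,
    concentration_uM: float = 40.0,
    n_steps: int = 1_500_000,
    min_events: int = 20,
) -> KoffEstimate:
    """Emergent HP1 off-rate from chromodomain–H3K9me residence times.

    A fully tri-methylated short fiber with HP1 only and no enzymes; the
    chromodomain bond lifetimes (completed, plus right-censored bonds
    still alive at the end) give the maximum-likelihood exponential rate.
    The HP1 concentration is raised above the study value to collect
    enough binding events — residence times depend only on pd.
    """
    config = SystemConfig(
        n_nucleosomes=n_nucleosomes,
        fiber_span_bp=196.0 * n_nucleosomes,
        protein_copies=_copies(HP1=n_hp1),
        concentration_uM=concentration_uM,
        n_steps=int(n_steps),
        report_interval=max(1, int(n_steps) // 200),
    )
    system, kseed = _build(config, seed)
    system.meth[:] = 3  # pre-methylated substrate
    result = system.run(seed=kseed)
    rec = result.lifetimes["CD-H3K9"]
    completed = rec["completed_us"]
    # reconstruct censored set from aggregates (individual censored spans
    # are not logged): total censored time split over censored bonds
    n_cens = rec["n_censored"]
    censored = (
        np.full(n_cens, rec["sum_censored_us"] / n_cens) if n_cens else np.empty(0)
    )
    return estimate_koff(completed, censored, min_events=min_events)


def chromatin_binding_kd(
    species: str,
    seed: int = 0,
    n_nucleosomes: int = 24,
    copies: int = 24,
    with_hp1: bool = False,
    meth_state: int | None = None,
    n_steps: int = 1_000_000,
) -> KdEstimate:
    """Apparent enzyme–chromatin dissociation constant at equilibrium.

    The fiber is set uniformly to ``meth_state`` (default: the highest
    state at which the species' substrate rule is eligible), catalysis is
    switched off (pt = 0) so the binding equilibrium is stationary, and
    Kd = [free enzyme][free eligible sites]/[complex] is averaged over
    the post-burn-in samples.
    """
    if species == "KDM":
        rule = "KDM-H3K9"
        default_state = 3
    elif species in ("G9a", "SUV39H", "SETDB1"):
        rule = f"CAT-H3K9:{species}"
        default_state = 2
    else:
        raise ValueError(f"unknown species {species!r}")
    state = default_state if meth_state is None else int(meth_state)
    kw = {species: copies}
    if with_hp1:
        kw["HP1"] = copies
    config = SystemConfig(
        n_nucleosomes=n_nucleosomes,
        fiber_span_bp=196.0 * n_nucleosomes,
        protein_copies=_copies(**kw),
        pt_scale=0.0,
        n_steps=int(n_steps),
        report_interval=max(1, int(n_steps) // 500),
    )
    system, kseed = _build(config, seed)
    system.meth[~system.perm] = state
    result = system.run(seed=kseed)
    r = rule_index(rule)
    complexes = result.bond_counts[:, r].astype(float)
    if species == "KDM":
        eligible = int((system.meth >= 1).sum())
    else:
        eligible = int((system.meth <= 2).sum())
    free_enzyme = copies - complexes
    free_sites = eligible - complexes
    return estimate_kd(
        free_enzyme, free_sites, complexes, config.box_volume_nm3()
    )


def knockdown_plateau(
    knockdown: dict | None = None,
    seed: int = 0,
    n_replicas: int = 10,
    n_nucleosomes: int = 24,
    copies: int = 12,
    pt_scale: float = 100.0,
    n_steps: int = 500_000,
    concentration_uM: float = 10.0,
) -> np.ndarray:
    """Stationary me3 level of the desk-scale knockdown proxy, per replica.

    The proxy is a 24-nucleosome fiber with every transform probability
    multiplied by 100 (ratios preserved) and reduced copy numbers at the
    study concentrations.  Each replica starts from a *fully methylated*
    fiber and relaxes down to the stationary level — the same equilibrium
    the nucleated system climbs to, reached without the stochastic
    ignition waiting time of uphill runs.  The plateau is the
    final-quartile mean of the fiber-averaged me3 fraction.

    Returns an array of ``n_replicas`` plateau estimates.
    """
    from .config import SystemConfig  # local import keeps module init light
    from .experiments import plateau_level, replica_seed

    config = SystemConfig(
        n_nucleosomes=n_nucleosomes,
        fiber_span_bp=196.0 * n_nucleosomes,
        protein_copies={name: copies for name in PROTEINS},
        knockdown=knockdown or {},
        concentration_uM=concentration_uM,
        pt_scale=pt_scale,
        n_steps=int(n_steps),
        report_interval=max(1, int(n_steps) // 200),
    )
    plateaus = np.empty(n_replicas)
    for rep in range(n_replicas):
        system, kseed = _build(config, replica_seed(seed, rep))
        system.meth[:] = 3
        result = system.run(seed=kseed)
        me3 = (result.meth == 3).mean(axis=1)
        plateaus[rep] = plateau_level(me3)
    return plateaus


def relative_plateau_decrease(
    plateau_wt: np.ndarray, plateau_kd: np.ndarray
) -> float:
    """100 × (plateau_WT − plateau_KD) / plateau_WT, replica-averaged."""
    wt = float(np.mean(plateau_wt))
    kd = float(np.mean(plateau_kd))
    return 100.0 * (wt - kd) / wt
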