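"""Replica/scenario orchestration, observables, and artifact I/O.

The observables mirror the standard read-outs of the knockdown study:

* ensemble-averaged H3K9me3 time charts (mean over nucleosomes and
  replicas, with replica dispersion) and their plateau — the "maximum
  methylation level", operationalized as the mean over the final quartile
  of samples;
* per-nucleosome me3 probability densities in time windows (the
  heat-strip view of spreading along the fiber);
* a centrifugal-spread statistic: the rank correlation between a
  nucleosome's distance from the fiber centre and its first-passage time
  to me3 (nucleosomes never reaching me3 are censored at the run length).

Trajectories are persisted as HDF5 with a full provenance header
(schema version, config YAML, seed); summaries and event logs export as
flat delimited tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .config import RULE_IDS, ScenarioSet, SystemConfig
from .system import ENZYME_NAMES, RunResult, System, build_system

__all__ = [
    "ReplicaTrajectory",
    "EnsembleSummary",
    "run_replica",
    "run_scenarios",
    "summarize_replicas",
    "me3_timecourse",
    "me3_site_profile",
    "centrifugal_index",
    "plateau_level",
    "first_passage_steps",
    "replica_seed",
    "write_trajectory",
    "read_trajectory",
    "write_summary_table",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def config_hash(config: SystemConfig) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def replica_seed(master_seed: int, replica_index: int) -> int:
    """Per-replica seed derived solely from (master seed, replica index)."""
    ss = np.random.SeedSequence([int(master_seed), int(replica_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ReplicaTrajectory:
    """One replica's sampled trajectory plus provenance."""

    config_hash: str
    seed: int
    times_us: np.ndarray
    meth: np.ndarray              # (samples, n_nucleosomes)
    bond_counts: np.ndarray       # (samples, n_rules)
    events: pd.DataFrame
    lifetimes: dict
    n_steps: int
    permanent: np.ndarray
    config_yaml: str = ""

    @property
    def n_nucleosomes(self) -> int:
        return self.meth.shape[1]


def run_replica(
    config: SystemConfig,
    seed: int,
    record_positions: bool | None = None,
) -> ReplicaTrajectory:
    """Build, fold, scatter and advance one replica; deterministic in
    (config, seed).  The seed drives both the random initial configuration
    and the trajectory stream."""
    ss = np.random.SeedSequence([int(seed)])
    init_ss, kernel_ss = ss.spawn(2)
    system = build_system(config, rng=np.random.default_rng(init_ss))
    kernel_seed = int(kernel_ss.generate_state(1)[0] & 0x7FFFFFFF)
    result = system.run(seed=kernel_seed, record_positions=record_positions)
    return ReplicaTrajectory(
        config_hash=config_hash(config),
        seed=int(seed),
        times_us=result.times_us,
        meth=result.meth,
        bond_counts=result.bond_counts,
        events=result.events,
        lifetimes=result.lifetimes,
        n_steps=result.n_steps,
        permanent=system.perm.copy(),
        config_yaml=yaml.safe_dump(config.to_dict(), sort_keys=True),
    )


# ---------------------------------------------------------------------------
# Ensemble summaries
# ---------------------------------------------------------------------------


def plateau_level(series: np.ndarray) -> float:
    """Plateau ("maximum methylation level"): mean over the final quartile."""
    x = np.asarray(series, dtype=float)
    return float(x[3 * len(x) // 4 :].mean())


def _region_slice(n: int, region: str) -> slice:
    if region == "half":
        lo = n // 4
        return slice(lo, lo + n // 2)
    return slice(0, n)


@dataclass
class EnsembleSummary:
    """Replica-averaged methylation statistics for one scenario."""

    label: str
    n_replicas: int
    times_us: np.ndarray
    frac_mean: dict               # state → (samples,) mean fiber fraction
    frac_std: dict                # state → (samples,) replica std
    site_me3: np.ndarray          # (samples, n) replica-averaged me3 indicator
    plateau_me3: float
    plateau_me3_per_replica: np.ndarray
    first_passage: np.ndarray     # (replicas, n) steps to me3, censored at run length
    n_steps: int
    permanent: np.ndarray
    seeds: list = field(default_factory=list)
    config_hash: str = ""
    averaging_region: str = "full"

    @property
    def n_nucleosomes(self) -> int:
        return self.site_me3.shape[1]


def first_passage_steps(traj: ReplicaTrajectory) -> np.ndarray:
    """Per-nucleosome first-passage time (steps) to me3 from the event log;
    nucleosomes that never reach me3 are censored at the run length.
    Permanently methylated nucleosomes are first-passage 0."""
    n = traj.n_nucleosomes
    fpt = np.full(n, float(traj.n_steps))
    fpt[traj.permanent] = 0.0
    ev = traj.events
    arrivals = ev[ev["to_state"] == 3]
    if len(arrivals):
        first = arrivals.groupby("nucleosome")["step"].min()
        for nuc, step in first.items():
            if not traj.permanent[nuc]:
                fpt[nuc] = min(fpt[nuc], float(step))
    return fpt


def summarize_replicas(
    label: str,
    replicas: list,
    averaging_region: str = "full",
) -> EnsembleSummary:
    """Collapse replica trajectories into an ensemble summary.

    Statistics are invariant under replica reordering (means/stds over the
    replica axis)."""
    if not replicas:
        raise ValueError("no replicas to summarize")
    n = replicas[0].n_nucleosomes
    region = _region_slice(n, averaging_region)
    times = replicas[0].times_us
    frac_mean, frac_std = {}, {}
    for state in (1, 2, 3):
        per_rep = np.stack(
            [(r.meth[:, region] == state).mean(axis=1) for r in replicas]
        )  # (replicas, samples)
        frac_mean[state] = per_rep.mean(axis=0)
        frac_std[state] = per_rep.std(axis=0, ddof=1) if len(replicas) > 1 else np.zeros_like(per_rep[0])
    site_me3 = np.stack([(r.meth == 3) for r in replicas]).mean(axis=0)
    per_rep_me3 = np.stack([(r.meth[:, region] == 3).mean(axis=1) for r in replicas])
    plateaus = np.array([plateau_level(row) for row in per_rep_me3])
    fpt = np.stack([first_passage_steps(r) for r in replicas])
    return EnsembleSummary(
        label=label,
        n_replicas=len(replicas),
        times_us=times,
        frac_mean=frac_mean,
        frac_std=frac_std,
        site_me3=site_me3,
        plateau_me3=float(plateaus.mean()),
        plateau_me3_per_replica=plateaus,
        first_passage=fpt,
        n_steps=replicas[0].n_steps,
        permanent=replicas[0].permanent,
        seeds=[r.seed for r in replicas],
        config_hash=replicas[0].config_hash,
        averaging_region=averaging_region,
    )


def run_scenarios(
    scenarios: ScenarioSet,
    master_seed: int = 0,
    labels: list | None = None,
    progress: bool = False,
) -> list:
    """Run every requested scenario (serially; replicas are independent and
    their seeds depend only on (master seed, replica index), so any
    scheduler would produce identical summaries).  A failed replica is
    recorded and skipped rather than aborting the scenario."""
    summaries = []
    for label in labels if labels is not None else scenarios.labels():
        config = scenarios.config_for(label)
        replicas, failures = [], []
        for rep in range(scenarios.n_replicas):
            seed = replica_seed(master_seed, rep)
            try:
                replicas.append(run_replica(config, seed))
            except Exception as exc:  # noqa: BLE001 - per-replica isolation
                failures.append((rep, repr(exc)))
            if progress:
                print(f"  {label}: replica {rep + 1}/{scenarios.n_replicas}", flush=True)
        summary = summarize_replicas(label, replicas, config.averaging_region)
        if failures:
            summary.seeds.append({"failures": failures})
        summaries.append(summary)
    return summaries


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


def me3_timecourse(summaries: list) -> pd.DataFrame:
    """Tidy time-chart table: one row per (scenario, time); columns are the
    fiber-averaged me1/me2/me3 means, the replica std of me3, and the
    scenario plateau."""
    rows = []
    for s in summaries:
        for i, t in enumerate(s.times_us):
            rows.append(
                {
                    "scenario": s.label,
                    "time_us": float(t),
                    "time_steps": int(round(t)),
                    "me1": float(s.frac_mean[1][i]),
                    "me2": float(s.frac_mean[2][i]),
                    "me3": float(s.frac_mean[3][i]),
                    "me3_std": float(s.frac_std[3][i]),
                    "plateau_me3": s.plateau_me3,
                    "n_replicas": s.n_replicas,
                }
            )
    return pd.DataFrame(rows)


def me3_site_profile(
    summary: EnsembleSummary,
    time_windows: list,
) -> pd.DataFrame:
    """Per-nucleosome me3 probability density, ensemble-/time-averaged over
    each (start_us, end_us) window.  Nucleosome positions are reported
    1-based."""
    rows = []
    times = summary.times_us
    for w, (lo, hi) in enumerate(time_windows):
        mask = (times >= lo) & (times <= hi)
        if not mask.any():
            raise ValueError(f"time window ({lo}, {hi}) contains no samples")
        dens = summary.site_me3[mask].mean(axis=0)
        for q in range(summary.n_nucleosomes):
            rows.append(
                {
                    "scenario": summary.label,
                    "window": w,
                    "window_start_us": lo,
                    "window_end_us": hi,
                    "nucleosome": q + 1,
                    "me3_density": float(dens[q]),
                }
            )
    return pd.DataFrame(rows)


def centrifugal_index(summary: EnsembleSummary) -> tuple:
    """Spearman rank correlation between distance-from-centre and
    first-passage time to me3, pooled over replicas (permanent nucleosomes
    excluded).  Positive values indicate centrifugal spread — methylation
    arriving later at nucleosomes further from the nucleation centre.

    Returns (statistic, p_value)."""
    n = summary.n_nucleosomes
    centre = (n - 1) / 2.0
    dist = np.abs(np.arange(n) - centre)
    keep = ~summary.permanent
    fpt = summary.first_passage[:, keep]
    if np.all(fpt == fpt.flat[0]):
        raise ValueError("no me3 arrivals: centrifugal index undefined")
    d = np.tile(dist[keep], summary.first_passage.shape[0])
    rho, p = stats.spearmanr(d, fpt.ravel())
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_ENZ_CODE = {name: i for i, name in enumerate(ENZYME_NAMES)}


def write_trajectory(path: str | Path, traj: ReplicaTrajectory) -> None:
    """Persist one replica to HDF5 with a provenance header."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config_hash"] = traj.config_hash
        f.attrs["config_yaml"] = traj.config_yaml
        f.attrs["seed"] = traj.seed
        f.attrs["n_steps"] = traj.n_steps
        f.create_dataset("times_us", data=traj.times_us)
        f.create_dataset("meth", data=traj.meth, compression="gzip")
        f.create_dataset("bond_counts", data=traj.bond_counts, compression="gzip")
        f.create_dataset("permanent", data=traj.permanent)
        ev = f.create_group("events")
        ev.create_dataset("step", data=traj.events["step"].to_numpy(np.int64))
        ev.create_dataset(
            "enzyme",
            data=np.array([_ENZ_CODE[e] for e in traj.events["enzyme"]], dtype=np.int8),
        )
        ev.create_dataset("nucleosome", data=traj.events["nucleosome"].to_numpy(np.int32))
        ev.create_dataset("from_state", data=traj.events["from_state"].to_numpy(np.int8))
        ev.create_dataset("to_state", data=traj.events["to_state"].to_numpy(np.int8))
        lt = f.create_group("lifetimes")
        for rid in RULE_IDS:
            g = lt.create_group(rid.replace("/", "_"))
            rec = traj.lifetimes[rid]
            g.create_dataset("completed_us", data=rec["completed_us"])
            for key in ("n_completed", "sum_completed_us", "n_censored", "sum_censored_us"):
                g.attrs[key] = rec[key]


def read_trajectory(path: str | Path) -> ReplicaTrajectory:
    """Load a trajectory, refusing silently-incompatible files."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"{path}: schema_version {version} incompatible with "
                f"reader version {SCHEMA_VERSION}"
            )
        events = pd.DataFrame(
            {
                "step": f["events/step"][()],
                "enzyme": [ENZYME_NAMES[c] for c in f["events/enzyme"][()]],
                "nucleosome": f["events/nucleosome"][()],
                "from_state": f["events/from_state"][()],
                "to_state": f["events/to_state"][()],
            }
        )
        lifetimes = {}
        for rid in RULE_IDS:
            g = f["lifetimes"][rid.replace("/", "_")]
            lifetimes[rid] = {
                "completed_us": g["completed_us"][()],
                **{k: g.attrs[k] for k in (
                    "n_completed", "sum_completed_us", "n_censored", "sum_censored_us"
                )},
            }
        return ReplicaTrajectory(
            config_hash=str(f.attrs["config_hash"]),
            seed=int(f.attrs["seed"]),
            times_us=f["times_us"][()],
            meth=f["meth"][()],
            bond_counts=f["bond_counts"][()],
            events=events,
            lifetimes=lifetimes,
            n_steps=int(f.attrs["n_steps"]),
            permanent=f["permanent"][()].astype(bool),
            config_yaml=str(f.attrs["config_yaml"]),
        )


def write_summary_table(summaries: list, path: str | Path) -> None:
    """Flat delimited export: one row per (scenario, time, statistic)."""
    df = me3_timecourse(summaries)
    long = df.melt(
        id_vars=["scenario", "time_us", "time_steps"],
        value_vars=["me1", "me2", "me3", "me3_std", "plateau_me3"],
        var_name="statistic",
        value_name="value",
    )
    long.to_csv(path, index=False)
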