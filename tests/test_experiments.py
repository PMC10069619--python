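"""Orchestration and observables: replicas, summaries, profiles, persistence."""

import numpy as np
import pandas as pd
import pytest

from heterosim.config import PROTEINS, ScenarioSet, SystemConfig, miniature_config
from heterosim.experiments import (
    EnsembleSummary,
    centrifugal_index,
    config_hash,
    first_passage_steps,
    me3_site_profile,
    me3_timecourse,
    plateau_level,
    read_trajectory,
    replica_seed,
    run_replica,
    run_scenarios,
    summarize_replicas,
    write_summary_table,
    write_trajectory,
)


@pytest.fixture(scope="module")
def trio(mini_config):
    """Three replicas of the miniature system."""
    return [run_replica(mini_config, replica_seed(7, i)) for i in range(3)]


class TestRunReplica:
    def test_determinism_bit_identical(self, mini_config):
        a = run_replica(mini_config, seed=42)
        b = run_replica(mini_config, seed=42)
        assert np.array_equal(a.meth, b.meth)
        assert np.array_equal(a.bond_counts, b.bond_counts)
        assert a.events.equals(b.events)

    def test_distinct_seeds_distinct_trajectories(self, mini_config):
        a = run_replica(mini_config, seed=1)
        b = run_replica(mini_config, seed=2)
        assert not np.array_equal(a.meth, b.meth)

    def test_no_proteins_keeps_nucleation_baseline(self):
        cfg = SystemConfig(
            n_nucleosomes=12, fiber_span_bp=12 * 196.0, box_edge_nm=120.0,
            protein_copies={p: 0 for p in PROTEINS},
            n_steps=5_000, report_interval=100,
        )
        traj = run_replica(cfg, seed=3)
        # me3 stays exactly 2/12 forever: no writers, no erasers
        assert np.all((traj.meth == 3).mean(axis=1) == pytest.approx(2 / 12))
        assert len(traj.events) == 0

    def test_config_hash_tracks_content(self, mini_config):
        assert config_hash(mini_config) != config_hash(
            mini_config.replace(seed=mini_config.seed + 1)
        )


class TestSummaries:
    def test_replica_reordering_invariance(self, trio):
        a = summarize_replicas("x", trio)
        b = summarize_replicas("x", [trio[2], trio[0], trio[1]])
        assert a.plateau_me3 == pytest.approx(b.plateau_me3)
        for state in (1, 2, 3):
            assert np.allclose(a.frac_mean[state], b.frac_mean[state])
        assert np.allclose(np.sort(a.plateau_me3_per_replica),
                           np.sort(b.plateau_me3_per_replica))

    def test_single_replica_summary_is_its_own_statistics(self, trio):
        s = summarize_replicas("one", trio[:1])
        own = (trio[0].meth == 3).mean(axis=1)
        assert np.allclose(s.frac_mean[3], own)
        assert s.plateau_me3 == pytest.approx(plateau_level(own))

    def test_plateau_is_final_quartile_mean(self):
        series = np.concatenate([np.zeros(75), np.ones(25)])
        assert plateau_level(series) == pytest.approx(1.0)

    def test_timecourse_table_shape_and_occupancy(self, trio):
        df = me3_timecourse([summarize_replicas("x", trio)])
        assert set(df.columns) >= {"scenario", "time_us", "me1", "me2", "me3"}
        assert len(df) == len(trio[0].times_us)
        total = df[["me1", "me2", "me3"]].sum(axis=1)
        assert np.all(total <= 1.0 + 1e-9)

    def test_first_passage_censoring(self, trio):
        fpt = first_passage_steps(trio[0])
        assert fpt.shape == (trio[0].n_nucleosomes,)
        assert np.all(fpt[trio[0].permanent] == 0)
        assert np.all(fpt <= trio[0].n_steps)


class TestSiteProfile:
    def test_nucleation_sites_have_unit_density(self, trio):
        s = summarize_replicas("x", trio)
        t_end = float(s.times_us[-1])
        df = me3_site_profile(s, [(0.0, t_end / 2), (t_end / 2, t_end)])
        perm_positions = np.where(s.permanent)[0] + 1
        for pos in perm_positions:
            dens = df[df["nucleosome"] == pos]["me3_density"].to_numpy()
            assert dens == pytest.approx(1.0)

    def test_pt_zero_control_has_no_off_center_density(self):
        cfg = miniature_config(n_nucleosomes=8, copies=6, pt_scale=0.0,
                               n_steps=10_000, report_interval=200)
        s = summarize_replicas("ctl", [run_replica(cfg, seed=5)])
        df = me3_site_profile(s, [(0.0, float(s.times_us[-1]))])
        off = df[~df["nucleosome"].isin(np.where(s.permanent)[0] + 1)]
        assert np.all(off["me3_density"] == 0.0)

    def test_empty_window_rejected(self, trio):
        s = summarize_replicas("x", trio)
        with pytest.raises(ValueError, match="window"):
            me3_site_profile(s, [(1e12, 2e12)])


def _fake_summary(fpt_matrix, n_steps=1000):
    n = fpt_matrix.shape[1]
    perm = np.zeros(n, dtype=bool)
    perm[n // 2 - 1 : n // 2 + 1] = True
    return EnsembleSummary(
        label="fake", n_replicas=fpt_matrix.shape[0],
        times_us=np.arange(10.0), frac_mean={}, frac_std={},
        site_me3=np.zeros((10, n)), plateau_me3=0.0,
        plateau_me3_per_replica=np.zeros(fpt_matrix.shape[0]),
        first_passage=fpt_matrix, n_steps=n_steps, permanent=perm,
    )


class TestCentrifugalIndex:
    def test_perfectly_ordered_arrival_gives_one(self):
        n = 20
        centre = (n - 1) / 2
        fpt = np.abs(np.arange(n) - centre)[None, :] * 100.0
        rho, _ = centrifugal_index(_fake_summary(fpt))
        assert rho == pytest.approx(1.0)

    def test_uniform_random_arrival_is_null(self):
        rng = np.random.default_rng(0)
        fpt = rng.random((30, 20)) * 1000
        rho, p = centrifugal_index(_fake_summary(fpt))
        assert abs(rho) < 0.1

    def test_no_arrivals_is_an_error(self):
        fpt = np.full((3, 20), 1000.0)
        fpt[:, 9:11] = 0.0  # permanent only
        summary = _fake_summary(fpt)
        summary.first_passage = np.full((3, 20), 7.0)  # constant everywhere
        with pytest.raises(ValueError, match="centrifugal"):
            centrifugal_index(summary)


class TestScenarioRuns:
    def test_subset_run_counts_and_labels(self, mini_config):
        cfg = mini_config.replace(n_steps=8_000, report_interval=400)
        sset = ScenarioSet(
            base=cfg,
            variants=[("WT", None, 1.0), ("SETDB1_50", "SETDB1", 0.5)],
            n_replicas=2,
        )
        summaries = run_scenarios(sset, master_seed=3)
        assert [s.label for s in summaries] == ["WT", "SETDB1_50"]
        assert all(s.n_replicas == 2 for s in summaries)

    def test_replica_seed_depends_only_on_master_and_index(self):
        assert replica_seed(5, 3) == replica_seed(5, 3)
        assert replica_seed(5, 3) != replica_seed(5, 4)
        assert replica_seed(6, 3) != replica_seed(5, 3)
        assert 0 <= replica_seed(5, 3) < 2**31


class TestPersistence:
    def test_trajectory_round_trip(self, trio, tmp_path):
        path = tmp_path / "replica.h5"
        write_trajectory(path, trio[0])
        back = read_trajectory(path)
        assert np.array_equal(back.meth, trio[0].meth)
        assert np.array_equal(back.bond_counts, trio[0].bond_counts)
        assert back.events.equals(trio[0].events)
        assert back.seed == trio[0].seed
        assert back.config_hash == trio[0].config_hash
        rec_a = back.lifetimes["CD-H3K9"]
        rec_b = trio[0].lifetimes["CD-H3K9"]
        assert rec_a["n_completed"] == rec_b["n_completed"]

    def test_incompatible_schema_refused(self, trio, tmp_path):
        import h5py

        path = tmp_path / "replica.h5"
        write_trajectory(path, trio[0])
        with h5py.File(path, "r+") as f:
            f.attrs["schema_version"] = 9999
        with pytest.raises(ValueError, match="schema_version"):
            read_trajectory(path)

    def test_summary_table_is_tidy_csv(self, trio, tmp_path):
        path = tmp_path / "summary.csv"
        write_summary_table([summarize_replicas("x", trio)], path)
        df = pd.read_csv(path)
        assert set(df.columns) == {"scenario", "time_us", "time_steps",
                                   "statistic", "value"}
        # one row per (scenario, time, statistic)
        assert not df.duplicated(["scenario", "time_us", "statistic"]).any()
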