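"""Spatial engine: tethers, move proposals, neighbor search, transport."""

import math

import numpy as np
import pytest
from scipy import integrate

from heterosim import build_system
from heterosim.calibration import estimate_diffusion
from heterosim.config import RULE_IDS, KineticsConfig, SystemConfig
from heterosim.engine import (
    ParticleState,
    TetherSpec,
    VoxelGrid,
    minimum_image,
    propose_move,
    tether_acceptance,
)

from oracles import brute_force_neighbors, tether_distance_moments


def _no_binding():
    return KineticsConfig(
        mode="raw", pa={r: 0.0 for r in RULE_IDS}, pd={r: 1e-6 for r in RULE_IDS}
    )


@pytest.fixture(scope="module")
def hp1_box():
    """24 free HP1 molecules, no binding, positions sampled every 10 steps."""
    cfg = SystemConfig(
        n_nucleosomes=2,
        fiber_span_bp=392.0,
        protein_copies={"HP1": 24, "G9a": 0, "SUV39H": 0, "SETDB1": 0, "KDM": 0},
        kinetics=_no_binding(),
        n_steps=150_000,
        report_interval=10,
        record_positions=True,
    )
    system = build_system(cfg, rng=5)
    result = system.run(seed=17)
    return cfg, system, result


class TestTetherAcceptance:
    SPEC = TetherSpec(min_len=3.0, free_len=4.0, damping_k=0.3)

    @pytest.mark.parametrize(
        "dist,expected",
        [
            (3.5, 1.0),                    # inside the free range
            (4.0, 1.0),                    # boundary of the free range
            (5.0, math.exp(-0.3)),         # one nm beyond: exp(-0.3) ≈ 0.7408
            (2.9, 0.0),                    # below hard contact
            (3.0, 1.0),                    # exactly at contact
        ],
    )
    def test_damping_law(self, dist, expected):
        assert tether_acceptance(dist, self.SPEC) == pytest.approx(expected)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TetherSpec(min_len=4.0, free_len=4.0)
        with pytest.raises(ValueError):
            TetherSpec(min_len=3.0, free_len=4.0, damping_k=-1.0)


class TestProposeMove:
    def _particle(self, d):
        return ParticleState(id=0, kind="hp1", position=np.zeros(3),
                             radius=1.5, diffusivity=d)

    def test_per_axis_rms_matches_sqrt_2Ddt(self):
        rng = np.random.default_rng(0)
        p = self._particle(0.550)
        draws = np.array([propose_move(p, 1.0, rng) for _ in range(20_000)])
        # √(2·0.550·1) ≈ 1.0488 nm per axis
        assert draws.std(axis=0) == pytest.approx([1.0488] * 3, rel=0.03)
        assert np.linalg.norm(draws.mean(axis=0)) < 0.02  # no drift

    def test_zero_diffusivity_is_immobile(self):
        rng = np.random.default_rng(0)
        assert np.all(propose_move(self._particle(0.0), 1.0, rng) == 0.0)

    def test_resolution_cap(self):
        rng = np.random.default_rng(1)
        p = self._particle(5.0)  # exaggerated mobility
        norms = [np.linalg.norm(propose_move(p, 1.0, rng, max_step=6.0))
                 for _ in range(2000)]
        assert max(norms) <= 6.0


class TestVoxelGrid:
    def test_empty_box(self):
        grid = VoxelGrid(box_edge=100.0, edge=10.0)
        assert grid.neighbor_query(np.array([50.0, 50.0, 50.0]), 5.0) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        box = 60.0
        grid = VoxelGrid(box_edge=box, edge=10.0)
        positions = {}
        for pid in range(50):
            pos = rng.random(3) * box
            positions[pid] = pos
            grid.insert(pid, pos)
        for _ in range(20):
            q = rng.random(3) * box
            assert grid.neighbor_query(q, 5.0) == brute_force_neighbors(
                positions, q, 5.0, box
            )

    def test_closed_ball_boundary(self):
        grid = VoxelGrid(box_edge=100.0, edge=10.0)
        grid.insert(0, np.array([10.0, 10.0, 10.0]))
        grid.insert(1, np.array([15.0, 10.0, 10.0]))
        # particle exactly at the cutoff distance is included
        assert grid.neighbor_query(np.array([10.0, 10.0, 10.0]), 5.0) == [0, 1]

    def test_cutoff_beyond_voxel_edge_rejected(self):
        grid = VoxelGrid(box_edge=100.0, edge=10.0)
        with pytest.raises(ValueError, match="voxel"):
            grid.neighbor_query(np.zeros(3), 11.0)

    def test_small_box_degrades_to_exhaustive(self):
        grid = VoxelGrid(box_edge=15.0, edge=10.0)  # ncell = 1
        grid.insert(0, np.array([1.0, 1.0, 1.0]))
        grid.insert(1, np.array([14.0, 14.0, 14.0]))  # 1.7 nm via wrap
        assert grid.neighbor_query(np.array([0.0, 0.0, 0.0]), 4.0) == [0, 1]

    def test_minimum_image(self):
        d = minimum_image(np.array([9.0, -9.0, 1.0]), 10.0)
        assert d == pytest.approx([-1.0, 1.0, 1.0])


class TestTransport:
    def test_free_diffusion_recovery(self, hp1_box):
        cfg, system, result = hp1_box
        beads = np.concatenate(
            [system.bead_ids("HP1", 0), system.bead_ids("HP1", 1)]
        )
        est = estimate_diffusion(
            result.positions_nm[:, beads, :],
            sample_interval_us=10.0,
            lags=[1, 2, 5, 10, 20, 50, 100],
            rng=np.random.default_rng(0),
        )
        assert est.d_um2_s == pytest.approx(0.550, rel=0.05)

    def test_no_drift(self, hp1_box):
        cfg, system, result = hp1_box
        disp = result.positions_nm[-1] - result.positions_nm[0]
        # ensemble-mean displacement ~ 0 versus per-particle dispersion
        mean_disp = np.linalg.norm(disp.mean(axis=0))
        rms_disp = np.sqrt((disp**2).sum(axis=1)).mean()
        assert mean_disp < 0.35 * rms_disp

    def test_particle_count_conserved_and_in_box(self, hp1_box):
        cfg, system, result = hp1_box
        assert system.n_particles == 2 * 2 + 2 * 24
        system.validate_state()  # raises on escape, orphan bond, or overlap

    def test_bind_cat_distance_density(self, hp1_box):
        """Tethered-pair distances follow the random-polymer density ∝ r²·w(r)."""
        cfg, system, result = hp1_box
        cd = system.bead_ids("HP1", 0)
        csd = system.bead_ids("HP1", 1)
        delta = result.positions_nm[:, cd, :] - result.positions_nm[:, csd, :]
        dist = np.sqrt((delta**2).sum(axis=-1))
        expected_mean = tether_distance_moments(3.0, 4.0, 0.3)
        assert dist.min() >= 3.0 - 1e-9          # never below hard contact
        # initial placement truncates at the free length; let the damping
        # tail fill in before comparing with the stationary density
        burn = 2 * dist.shape[0] // 3
        assert dist[burn:].mean() == pytest.approx(expected_mean, rel=0.05)

    def test_reproducibility_bit_identical(self):
        cfg = SystemConfig(
            n_nucleosomes=4,
            fiber_span_bp=784.0,
            protein_copies={"HP1": 6, "G9a": 2, "SUV39H": 2, "SETDB1": 2, "KDM": 2},
            n_steps=5_000,
            report_interval=100,
            record_positions=True,
        )
        runs = []
        for _ in range(2):
            system = build_system(cfg, rng=123)
            runs.append(system.run(seed=77))
        assert np.array_equal(runs[0].positions_nm, runs[1].positions_nm)
        assert np.array_equal(runs[0].meth, runs[1].meth)
        assert np.array_equal(runs[0].bond_counts, runs[1].bond_counts)


def test_tether_mean_oracle_consistency():
    """The 1D-integration oracle itself: the free-range-only density
    ∝ r² on [3, 4] has mean 3.54; adding the exponential tail pushes the
    mean above the free length region's."""
    r = np.linspace(3, 4, 10_000)
    base = float(np.trapezoid(r * r**2, r) / np.trapezoid(r**2, r))
    with_tail = tether_distance_moments(3.0, 4.0, 0.3)
    assert base == pytest.approx(3.547, abs=0.01)
    assert with_tail > base
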