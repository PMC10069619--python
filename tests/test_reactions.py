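"""Catalysis: pt tables, the three-condition rule, activity cycling,
and the ideal-mixing mode against a Gillespie oracle."""

import numpy as np
import pytest

from heterosim import build_system
from heterosim.config import (
    ConfigError,
    KineticsConfig,
    RULE_IDS,
    SystemConfig,
    miniature_config,
)
from heterosim.fiber import build_fiber, set_methylation
from heterosim.reactions import (
    CatState,
    ReactionRule,
    attempt_demethylation,
    attempt_methylation,
    build_pt_table,
    update_cat_activity,
)
from heterosim.wellmixed import WellMixedSystem

from oracles import gillespie_kdm_sites


class TestPtTable:
    def test_primary_activities_carry_the_largest_pt(self):
        rules = build_pt_table(SystemConfig())
        best = {}
        for r in rules:
            if r.enzyme != "KDM":
                if r.enzyme not in best or r.pt > best[r.enzyme][1]:
                    best[r.enzyme] = (r.substrate_state, r.pt)
        assert best["G9a"][0] == 0       # mono-methylation
        assert best["SETDB1"][0] == 1    # di-methylation
        assert best["SUV39H"][0] == 2    # tri-methylation

    def test_secondary_strictly_below_primary(self):
        rules = build_pt_table(SystemConfig())
        primary = {"G9a": 0, "SETDB1": 1, "SUV39H": 2}
        by_enzyme = {}
        for r in rules:
            by_enzyme.setdefault(r.enzyme, {})[r.substrate_state] = r.pt
        for enzyme, p in primary.items():
            for state, pt in by_enzyme[enzyme].items():
                if state != p:
                    assert pt < by_enzyme[enzyme][p]

    def test_kdm_rules_step_down_from_1_to_3(self):
        rules = [r for r in build_pt_table(SystemConfig()) if r.enzyme == "KDM"]
        assert sorted(r.substrate_state for r in rules) == [1, 2, 3]
        assert all(r.product_state == r.substrate_state - 1 for r in rules)

    def test_pt_scale_applies_uniformly(self):
        base = build_pt_table(SystemConfig())
        scaled = build_pt_table(SystemConfig(pt_scale=100.0))
        for b, s in zip(base, scaled):
            assert s.pt == pytest.approx(100.0 * b.pt)

    def test_all_zero_controls_allowed_but_inversions_rejected(self):
        build_pt_table(SystemConfig(pt_scale=0.0))  # pt = 0 everywhere is fine
        bad = SystemConfig()
        bad.kinetics.pt["SETDB1"] = [1e-5, 1e-6, 1e-6]  # primary not largest
        with pytest.raises(ConfigError, match="SETDB1"):
            build_pt_table(bad)

    def test_rule_validation(self):
        with pytest.raises(ConfigError):
            ReactionRule("G9a", 1, 3, 0.1)    # |Δ| ≠ 1
        with pytest.raises(ConfigError):
            ReactionRule("KDM", 0, -1, 0.1)   # below me0
        with pytest.raises(ConfigError):
            ReactionRule("G9a", 0, 1, 1.5)    # pt outside [0,1]


class TestThreeConditionRule:
    def _fiber(self):
        return build_fiber(8, SystemConfig(n_nucleosomes=8, fiber_span_bp=8 * 196.0))

    def test_fires_only_when_anchored_active_and_lucky(self):
        fiber = self._fiber()
        rng = np.random.default_rng(0)
        cat = CatState(active=True, anchored=True)
        fired = attempt_methylation(cat, fiber, 0, "G9a", None, rng, pt=1.0)
        assert fired
        assert fiber.nucleosomes[0].meth_state == 1
        assert not cat.active  # inactivated after the event

    def test_unanchored_cat_never_fires(self):
        fiber = self._fiber()
        rng = np.random.default_rng(0)
        cat = CatState(active=True, anchored=False)
        for _ in range(100):
            assert not attempt_methylation(cat, fiber, 0, "G9a", None, rng, pt=1.0)
        assert fiber.nucleosomes[0].meth_state == 0

    def test_me3_substrate_excluded(self):
        fiber = self._fiber()
        set_methylation(fiber, 0, 1)
        set_methylation(fiber, 0, 2)
        set_methylation(fiber, 0, 3)
        cat = CatState(active=True, anchored=True)
        rng = np.random.default_rng(0)
        assert not attempt_methylation(cat, fiber, 0, "SUV39H", None, rng, pt=1.0)

    def test_inactive_cat_blocked_until_dissociation(self):
        fiber = self._fiber()
        rng = np.random.default_rng(0)
        cat = CatState(active=True, anchored=True)
        attempt_methylation(cat, fiber, 0, "G9a", None, rng, pt=1.0)
        assert not attempt_methylation(cat, fiber, 0, "G9a", None, rng, pt=1.0)
        update_cat_activity(cat, substrate_bound=True, bind_anchored=True)
        assert not cat.active  # still bound → still refractory
        update_cat_activity(cat, substrate_bound=False, bind_anchored=True)
        assert cat.active      # dissociation-gated reset

    def test_fixed_timer_mode(self):
        cat = CatState(active=False, reactivate_at=50)
        update_cat_activity(cat, substrate_bound=True, bind_anchored=True,
                            step=49, refractory_steps=10)
        assert not cat.active
        update_cat_activity(cat, substrate_bound=True, bind_anchored=True,
                            step=50, refractory_steps=10)
        assert cat.active

    def test_demethylation_two_conditions_and_permanence(self):
        fiber = self._fiber()
        set_methylation(fiber, 0, 1)
        rng = np.random.default_rng(0)
        assert attempt_demethylation(fiber, 0, np.array([1.0, 1.0, 1.0]), rng)
        assert fiber.nucleosomes[0].meth_state == 0
        # permanent nucleation site never loses me3
        perm = next(i for i, nuc in enumerate(fiber.nucleosomes) if nuc.permanent)
        assert not attempt_demethylation(fiber, perm, np.array([1.0, 1.0, 1.0]), rng)
        assert fiber.nucleosomes[perm].meth_state == 3


class TestKernelGating:
    def test_no_anchoring_no_methylation(self):
        """Without HP1 and without methylated substrates for the Kme
        modules, HMT anchors have nothing to hold on to — no methylation
        can ever fire (condition i)."""
        cfg = miniature_config(
            n_nucleosomes=8, copies=8, binding_boost=10.0, pt_scale=1000.0,
            n_steps=60_000,
            protein_copies={"HP1": 0, "G9a": 8, "SUV39H": 8, "SETDB1": 8, "KDM": 0},
        )
        system = build_system(cfg, rng=3)
        # remove the nucleation pair: a fully unmethylated fiber
        system.meth[:] = 0
        system.perm[:] = False
        result = system.run(seed=4)
        assert len(result.events) == 0
        assert np.all(result.meth == 0)

    def test_pt_zero_keeps_field_at_nucleation(self):
        cfg = miniature_config(n_nucleosomes=8, copies=8, pt_scale=0.0,
                               n_steps=30_000)
        system = build_system(cfg, rng=5)
        result = system.run(seed=6)
        assert len(result.events) == 0
        assert np.all((result.meth == 3).sum(axis=1) == 2)  # nucleation only

    def test_stepwise_only_event_log(self, mini_replica):
        ev = mini_replica.events
        assert len(ev) > 0
        assert np.all(np.abs(ev["to_state"] - ev["from_state"]) == 1)

    def test_absorbing_me3_without_demethylase(self):
        """With no eraser present and nucleation active, every nucleosome
        eventually reaches the absorbing me3 state."""
        cfg = miniature_config(
            n_nucleosomes=6, copies=10, binding_boost=10.0, pt_scale=2000.0,
            n_steps=400_000,
            protein_copies={"HP1": 10, "G9a": 10, "SUV39H": 10, "SETDB1": 10, "KDM": 0},
        )
        system = build_system(cfg, rng=7)
        result = system.run(seed=8)
        assert np.all(result.meth[-1] == 3)


class TestWellMixedGillespie:
    def test_demethylation_cascade_matches_ssa(self):
        """Ideal-mixing trajectories of the eraser subsystem agree with an
        independent Gillespie simulation of the same CTMC rates."""
        kin = KineticsConfig(
            mode="raw",
            pa={r: (0.05 if r == "KDM-H3K9" else 0.0) for r in RULE_IDS},
            pd={r: 1e-3 for r in RULE_IDS},
        )
        cfg = SystemConfig(
            n_nucleosomes=4, fiber_span_bp=784.0, box_edge_nm=60.0,
            protein_copies={"HP1": 0, "G9a": 0, "SUV39H": 0, "SETDB1": 0, "KDM": 5},
            kinetics=kin, n_steps=30_000,
        )
        cfg.kinetics.pt["KDM"] = [5e-3, 5e-3, 5e-3]
        n_reps = 40
        t_grid = np.array([5_000, 10_000, 20_000, 30_000])
        wm_mean = np.zeros((n_reps, len(t_grid)))
        for rep in range(n_reps):
            wm = WellMixedSystem(cfg)
            wm.meth[:] = 3  # fully methylated start; two sites erodible
            res = wm.run(30_000, rng=np.random.default_rng(100 + rep),
                         report_interval=5_000)
            idx = [list((res.times_us // cfg.time_step_us).astype(int)).index(t)
                   for t in t_grid]
            free_sites = ~wm.perm
            wm_mean[rep] = res.meth[idx][:, free_sites].mean(axis=1)
        q = wm.q[RULE_IDS.index("KDM-H3K9")]
        rng = np.random.default_rng(999)
        ssa = np.array([
            gillespie_kdm_sites(
                n_sites=2, init_state=3, n_kdm=5,
                kon_per_step=0.05 * q, koff_per_step=1e-3, pt_per_step=5e-3,
                t_grid_steps=t_grid.astype(float), rng=rng,
            )
            for _ in range(200)
        ])
        wm_avg = wm_mean.mean(axis=0)
        ssa_avg = ssa.mean(axis=0)
        se = np.sqrt(wm_mean.var(axis=0) / n_reps + ssa.var(axis=0) / 200)
        assert np.all(np.abs(wm_avg - ssa_avg) < 3.5 * se + 0.02)

    def test_wellmixed_binding_equilibrium_analytic(self):
        """Ideal-mixing bound fraction matches the per-step chain exactly
        (no spatial corrections by construction)."""
        kin = KineticsConfig(
            mode="raw",
            pa={r: (0.05 if r == "KDM-H3K9" else 0.0) for r in RULE_IDS},
            pd={r: 2e-3 for r in RULE_IDS},
        )
        cfg = SystemConfig(
            n_nucleosomes=4, fiber_span_bp=784.0, box_edge_nm=60.0,
            protein_copies={"HP1": 0, "G9a": 0, "SUV39H": 0, "SETDB1": 0, "KDM": 1},
            kinetics=kin, pt_scale=0.0, n_steps=150_000,
        )
        wm = WellMixedSystem(cfg)
        wm.meth[:] = 3
        res = wm.run(150_000, rng=np.random.default_rng(11), report_interval=50)
        q = wm.q[RULE_IDS.index("KDM-H3K9")]
        on = 4 * q * 0.05
        expected = on / (on + 2e-3)
        measured = (res.bond_counts[:, RULE_IDS.index("KDM-H3K9")] > 0).mean()
        assert measured == pytest.approx(expected, rel=0.2)
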