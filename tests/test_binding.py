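"""Binding rules: table structure, eligibility, residence times, equilibria."""

import numpy as np
import pytest
from scipy import stats

from heterosim import build_system
from heterosim.binding import (
    RULE_ELIGIBLE_STATES,
    attempt_association,
    attempt_dissociation,
    register_interactions,
    rule_index,
    _SiteView,
)
from heterosim.config import RULE_IDS, KineticsConfig, SystemConfig, miniature_config

from oracles import two_state_bound_fraction


@pytest.fixture(scope="module")
def rules():
    return register_interactions(SystemConfig())


class TestRuleTable:
    def test_all_rule_families_present(self, rules):
        assert set(rules) == set(RULE_IDS)
        families = {rid.split(":")[0] for rid in rules}
        assert families == {
            "CD-H3K9", "CSD-CSD", "BIND-CSD", "KME-H3K9", "CAT-H3K9", "KDM-H3K9",
        }

    def test_suv39h_has_no_kme_module(self, rules):
        assert "KME-H3K9:SUV39H" not in rules
        assert "KME-H3K9:G9a" in rules and "KME-H3K9:SETDB1" in rules

    def test_probabilities_in_range(self, rules):
        for rule in rules.values():
            assert 0.0 <= rule.pa <= 1.0
            assert 0.0 < rule.pd <= 1.0

    def test_capture_radius_is_contact_plus_tolerance(self, rules):
        for rule in rules.values():
            assert rule.capture_radius == pytest.approx(rule.contact_radius + 0.5)

    def test_knockdown_leaves_rules_unchanged(self):
        base = register_interactions(SystemConfig())
        kd = register_interactions(SystemConfig(knockdown={"SETDB1": 0.5}))
        for rid in RULE_IDS:
            assert base[rid] == kd[rid]

    def test_eligibility_states(self):
        assert RULE_ELIGIBLE_STATES["CD-H3K9"] == (2, 3)          # reads me2/me3
        assert RULE_ELIGIBLE_STATES["KDM-H3K9"] == (1, 2, 3)      # erases me1+
        assert RULE_ELIGIBLE_STATES["CAT-H3K9:SUV39H"] == (0, 1, 2)


class TestReferenceOperations:
    def test_cd_ignores_unmethylated_site(self, rules):
        rng = np.random.default_rng(0)
        cd = _SiteView(particle_id=1)
        site = _SiteView(particle_id=2, meth_state=0)
        rule = rules["CD-H3K9"]
        assert attempt_association(cd, site, rule, rng, distance=2.6) is None

    def test_cd_binds_me3_when_draw_below_pa(self, rules):
        class AlwaysLow:
            def random(self):
                return 0.0

        cd = _SiteView(particle_id=1)
        site = _SiteView(particle_id=2, meth_state=3)
        bond = attempt_association(cd, site, rules["CD-H3K9"], AlwaysLow(), distance=2.6)
        assert bond is not None
        assert cd.free_valence == 0 and site.free_valence == 0

    def test_pa_zero_never_binds(self, rules):
        rng = np.random.default_rng(0)
        rule = rules["CD-H3K9"]
        zero = type(rule)(
            rule_id=rule.rule_id, kinds=rule.kinds, pa=0.0, pd=rule.pd,
            capture_radius=rule.capture_radius, contact_radius=rule.contact_radius,
            eligible_states=rule.eligible_states,
        )
        site = _SiteView(particle_id=2, meth_state=3)
        assert all(
            attempt_association(_SiteView(particle_id=1), site, zero, rng, distance=2.6)
            is None
            for _ in range(1000)
        )

    def test_out_of_range_pair_never_attempts(self, rules):
        class Boom:
            def random(self):
                raise AssertionError("attempted despite distance")

        site = _SiteView(particle_id=2, meth_state=3)
        assert attempt_association(
            _SiteView(particle_id=1), site, rules["CD-H3K9"], Boom(), distance=3.5
        ) is None

    def test_dissociation_pd_one_breaks_every_step(self, rules):
        from heterosim.binding import Bond

        class AlwaysLow:
            def random(self):
                return 0.0

        rule = rules["CD-H3K9"]
        one = type(rule)(
            rule_id=rule.rule_id, kinds=rule.kinds, pa=rule.pa, pd=1.0,
            capture_radius=rule.capture_radius, contact_radius=rule.contact_radius,
            eligible_states=rule.eligible_states,
        )
        bond = Bond(id=1, rule_id="CD-H3K9", partners=(1, 2), formed_at=0)
        assert attempt_dissociation(bond, one, AlwaysLow())


@pytest.fixture(scope="module")
def residence_run():
    """HP1 on a methylated miniature fiber with boosted dissociation."""
    cfg = miniature_config(
        n_nucleosomes=12, copies=12, binding_boost=50.0, pt_scale=0.0,
        n_steps=300_000, report_interval=1000,
        protein_copies={"HP1": 16, "G9a": 0, "SUV39H": 0, "SETDB1": 0, "KDM": 0},
    )
    system = build_system(cfg, rng=21)
    system.meth[:] = 3
    result = system.run(seed=22)
    return cfg, system, result


class TestResidenceTimes:
    def test_lifetimes_geometric_with_mean_one_over_pd(self, residence_run):
        cfg, system, result = residence_run
        rec = result.lifetimes["CD-H3K9"]
        pd = system.rule_pd[rule_index("CD-H3K9")]
        assert rec["n_completed"] >= 150
        # censored-MLE mean: total observed time / completions
        total = rec["sum_completed_us"] + rec["sum_censored_us"]
        mean_steps = total / cfg.time_step_us / rec["n_completed"]
        assert mean_steps == pytest.approx(1.0 / pd, rel=0.15)

    def test_lifetime_distribution_exponential(self, residence_run):
        cfg, system, result = residence_run
        durations = result.lifetimes["CD-H3K9"]["completed_us"]
        pd = system.rule_pd[rule_index("CD-H3K9")]
        # geometric(pd) ≈ exponential with scale 1/pd at small pd
        ks = stats.kstest(durations, "expon", args=(0.0, 1.0 / pd))
        assert ks.pvalue > 0.01

    def test_valence_never_exceeded(self, residence_run):
        cfg, system, result = residence_run
        system.validate_state()
        # sites have one reader slot: bound CD count can never exceed sites
        assert result.bond_counts[:, rule_index("CD-H3K9")].max() <= 12


class TestTwoParticleEquilibrium:
    def test_bound_fraction_matches_per_step_markov_chain(self):
        """Spatial equilibrium against the analytic two-state chain with
        ideal-gas encounter statistics (tiny box, exhaustive search path).

        pa is kept small so the chain's uniform-shell assumption holds (a
        strong association sink would deplete the contact shell), and the
        core bead is shrunk so it does not shadow the site's capture
        shell — the analytic chain knows nothing about excluded volume."""
        pa, pd = 0.05, 1e-3  # ~100 binding cycles per run for tight statistics
        kin = KineticsConfig(
            mode="raw",
            pa={r: (pa if r == "CD-H3K9" else 0.0) for r in RULE_IDS},
            pd={r: pd for r in RULE_IDS},
        )
        from heterosim.config import GeometryConfig

        geo = GeometryConfig()
        geo.radius_nm = dict(geo.radius_nm, core=0.6)
        geo.core_site_slack_nm = 6.0
        cfg = SystemConfig(
            n_nucleosomes=2, fiber_span_bp=392.0, box_edge_nm=40.0,
            protein_copies={"HP1": 1, "G9a": 0, "SUV39H": 0, "SETDB1": 0, "KDM": 0},
            kinetics=kin, geometry=geo, n_steps=1_200_000, report_interval=200,
        )
        system = build_system(cfg, rng=31)  # both nucleosomes are permanent me3
        result = system.run(seed=32)
        shell = 4.0 / 3.0 * np.pi * (3.0**3 - 2.5**3)  # capture shell, nm³
        q = shell / 40.0**3
        expected = two_state_bound_fraction(2, 1, pa, pd, q)
        measured = (result.bond_counts[:, rule_index("CD-H3K9")] > 0).mean()
        assert measured == pytest.approx(expected, rel=0.25)

    def test_emergent_kd_stable_across_box_sizes(self):
        """Kd from counts is a property of the rule, not the box (±30%).

        Both enzyme and site concentrations are held fixed while the box
        volume more than doubles."""
        from heterosim.assays import chromatin_binding_kd

        small = chromatin_binding_kd("KDM", seed=5, copies=12,
                                     n_nucleosomes=12, n_steps=400_000)
        large = chromatin_binding_kd("KDM", seed=6, copies=28,
                                     n_nucleosomes=28, n_steps=400_000)
        assert small.kd_uM == pytest.approx(large.kd_uM, rel=0.3)
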