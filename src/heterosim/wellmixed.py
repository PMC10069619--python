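"""Ideal-mixing mode: the reaction scheme with diffusion made instantaneous.

Positions are dropped entirely; every (binder, target) pair is "in
contact" in any step with the ideal-gas probability

    q(rule) = V_shell(rule) / V_box,

where V_shell is the capture-shell volume between hard contact and the
capture radius (the same contact statistics the spatial engine's
excluded volume produces),

so an eligible free pair associates with probability ``pa·q`` per step,
bonds dissociate with ``pd``, and the catalytic rules fire under exactly
the same conditions as in the spatial engine (anchoring, activity,
eligibility, permanence).  In the small-probability limit this is a
continuous-time Markov chain with on-rate ``n_free·pa·q/Δt``, off-rate
``pd/Δt`` and catalytic rate ``pt/Δt`` — which is what the independent
Gillespie oracle in the test suite simulates.

The mode serves two purposes: it isolates the stochastic chemistry from
the transport model for validation, and it provides analytic expected
values for binding equilibria (bound fraction ``pa·q·n / (pa·q·n + pd)``
for a single site against ``n`` free binders).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import rules_to_arrays, register_interactions
from .config import ENZYMES, RULE_IDS, SystemConfig
from .reactions import pt_arrays

__all__ = ["WellMixedSystem", "WellMixedResult"]

_RULE_INDEX = {rid: i for i, rid in enumerate(RULE_IDS)}


@dataclass
class WellMixedResult:
    times_us: np.ndarray
    meth: np.ndarray          # (samples, n_nucleosomes)
    bond_counts: np.ndarray   # (samples, n_rules)
    events: list              # (step, enzyme, nucleosome, from, to)


@dataclass
class _HP1:
    cd_site: int = -1     # nucleosome index the CD is bound to
    csd_dimer: int = -1   # partner HP1 index
    csd_hmt: int = -1     # global HMT index docked on the CSD


@dataclass
class _HMT:
    enzyme: int = 0
    bind_target: tuple = ("free", -1)   # ("free",-1) | ("csd", hp1) | ("site", nuc)
    cat_site: int = -1
    cat_active: bool = True


class WellMixedSystem:
    """Spatial engine's chemistry on a zero-dimensional stage."""

    def __init__(self, config: SystemConfig):
        self.config = config
        self.n = config.n_nucleosomes
        resolved = config.resolve_kinetics()
        rules = register_interactions(config)
        arr = rules_to_arrays(rules)
        self.pa = arr["pa"]
        self.pd = arr["pd"]
        volume = config.box_volume_nm3()
        # contact probability per pair: the capture shell between hard
        # contact and the capture radius (matching the spatial engine,
        # where excluded volume forbids r below the sum of radii)
        self.q = np.array(
            [
                (4.0 / 3.0)
                * np.pi
                * (rules[rid].capture_radius ** 3 - rules[rid].contact_radius ** 3)
                / volume
                for rid in RULE_IDS
            ]
        )
        self.pt_hmt, self.pt_kdm = pt_arrays(config)
        copies = config.effective_copies()
        self.meth = np.zeros(self.n, dtype=np.int8)
        center = self.n // 2 - 1
        self.perm = np.zeros(self.n, dtype=bool)
        self.perm[[center, center + 1]] = True
        self.meth[[center, center + 1]] = 3
        self.site_reader: np.ndarray = np.full(self.n, -1, dtype=int)  # binder token
        self.site_cat: np.ndarray = np.full(self.n, -1, dtype=int)     # HMT index
        self.hp1 = [_HP1() for _ in range(copies["HP1"])]
        self.hmts: list[_HMT] = []
        for e, name in enumerate(ENZYMES):
            for _ in range(copies[name]):
                self.hmts.append(_HMT(enzyme=e))
        self.kdm_site = np.full(copies["KDM"], -1, dtype=int)
        self.events: list = []
        self.step_count = 0

    # binder tokens for site_reader: HP1 cd → ("cd", i); Kme → ("kme", hmt);
    # KDM → ("kdm", k).  Encoded as ints: cd: i; kme: 10_000+hmt; kdm: 20_000+k.

    def _anchored(self, hmt: _HMT) -> bool:
        tag, idx = hmt.bind_target
        if tag == "site":
            return True
        if tag == "csd":
            return self.hp1[idx].cd_site >= 0
        return False

    def step(self, rng: np.random.Generator) -> None:
        pa, pd, q = self.pa, self.pd, self.q
        # ---- dissociation ----
        for i, h in enumerate(self.hp1):
            if h.cd_site >= 0 and rng.random() < pd[_RULE_INDEX["CD-H3K9"]]:
                self.site_reader[h.cd_site] = -1
                h.cd_site = -1
            if h.csd_dimer > i and rng.random() < pd[_RULE_INDEX["CSD-CSD"]]:
                self.hp1[h.csd_dimer].csd_dimer = -1
                h.csd_dimer = -1
        for gi, hmt in enumerate(self.hmts):
            tag, idx = hmt.bind_target
            if tag == "csd":
                r = _RULE_INDEX[f"BIND-CSD:{ENZYMES[hmt.enzyme]}"]
                if rng.random() < pd[r]:
                    self.hp1[idx].csd_hmt = -1
                    hmt.bind_target = ("free", -1)
            elif tag == "site":
                r = _RULE_INDEX[f"KME-H3K9:{ENZYMES[hmt.enzyme]}"]
                if rng.random() < pd[r]:
                    self.site_reader[idx] = -1
                    hmt.bind_target = ("free", -1)
            if hmt.cat_site >= 0:
                r = _RULE_INDEX[f"CAT-H3K9:{ENZYMES[hmt.enzyme]}"]
                if rng.random() < pd[r]:
                    self.site_cat[hmt.cat_site] = -1
                    hmt.cat_site = -1
                    hmt.cat_active = True
        for k in range(len(self.kdm_site)):
            if self.kdm_site[k] >= 0 and rng.random() < pd[_RULE_INDEX["KDM-H3K9"]]:
                self.site_reader[self.kdm_site[k]] = -1
                self.kdm_site[k] = -1

        # ---- association (every eligible free pair, Bernoulli pa·q) ----
        for nuc in rng.permutation(self.n):
            m = self.meth[nuc]
            if self.site_reader[nuc] < 0:
                r = _RULE_INDEX["CD-H3K9"]
                if m >= 2:
                    for i, h in enumerate(self.hp1):
                        if h.cd_site < 0 and rng.random() < pa[r] * q[r]:
                            h.cd_site = nuc
                            self.site_reader[nuc] = i
                            break
            if self.site_reader[nuc] < 0 and m >= 1:
                for gi, hmt in enumerate(self.hmts):
                    name = ENZYMES[hmt.enzyme]
                    if name == "SUV39H" or hmt.bind_target[0] != "free":
                        continue
                    r = _RULE_INDEX[f"KME-H3K9:{name}"]
                    if rng.random() < pa[r] * q[r]:
                        hmt.bind_target = ("site", nuc)
                        self.site_reader[nuc] = 10_000 + gi
                        break
            if self.site_reader[nuc] < 0 and m >= 1:
                r = _RULE_INDEX["KDM-H3K9"]
                for k in range(len(self.kdm_site)):
                    if self.kdm_site[k] < 0 and rng.random() < pa[r] * q[r]:
                        self.kdm_site[k] = nuc
                        self.site_reader[nuc] = 20_000 + k
                        break
            if self.site_cat[nuc] < 0 and m <= 2:
                for gi, hmt in enumerate(self.hmts):
                    if hmt.cat_site >= 0:
                        continue
                    r = _RULE_INDEX[f"CAT-H3K9:{ENZYMES[hmt.enzyme]}"]
                    if rng.random() < pa[r] * q[r]:
                        hmt.cat_site = nuc
                        self.site_cat[nuc] = gi
                        break
        for i in rng.permutation(len(self.hp1)):
            h = self.hp1[i]
            if h.csd_dimer < 0:
                r = _RULE_INDEX["CSD-CSD"]
                for j in range(len(self.hp1)):
                    if j != i and self.hp1[j].csd_dimer < 0:
                        if rng.random() < pa[r] * q[r]:
                            h.csd_dimer = j
                            self.hp1[j].csd_dimer = i
                            break
            if h.csd_hmt < 0:
                for gi, hmt in enumerate(self.hmts):
                    if hmt.bind_target[0] != "free":
                        continue
                    r = _RULE_INDEX[f"BIND-CSD:{ENZYMES[hmt.enzyme]}"]
                    if rng.random() < pa[r] * q[r]:
                        hmt.bind_target = ("csd", i)
                        h.csd_hmt = gi
                        break

        # ---- reactions ----
        t = self.step_count
        for gi, hmt in enumerate(self.hmts):
            nuc = hmt.cat_site
            if nuc < 0:
                continue
            m = self.meth[nuc]
            if m > 2 or not hmt.cat_active or not self._anchored(hmt):
                continue
            if rng.random() < self.pt_hmt[hmt.enzyme, m]:
                self.meth[nuc] = m + 1
                self.events.append((t, ENZYMES[hmt.enzyme], nuc, m, m + 1))
                hmt.cat_active = False
        for k in range(len(self.kdm_site)):
            nuc = self.kdm_site[k]
            if nuc < 0:
                continue
            m = self.meth[nuc]
            if m < 1 or self.perm[nuc]:
                continue
            if rng.random() < self.pt_kdm[m - 1]:
                self.meth[nuc] = m - 1
                self.events.append((t, "KDM", nuc, m, m - 1))
        self.step_count += 1

    def bond_counts(self) -> np.ndarray:
        counts = np.zeros(len(RULE_IDS), dtype=int)
        for i, h in enumerate(self.hp1):
            if h.cd_site >= 0:
                counts[_RULE_INDEX["CD-H3K9"]] += 1
            if h.csd_dimer > i:
                counts[_RULE_INDEX["CSD-CSD"]] += 1
        for hmt in self.hmts:
            tag, _ = hmt.bind_target
            name = ENZYMES[hmt.enzyme]
            if tag == "csd":
                counts[_RULE_INDEX[f"BIND-CSD:{name}"]] += 1
            elif tag == "site":
                counts[_RULE_INDEX[f"KME-H3K9:{name}"]] += 1
            if hmt.cat_site >= 0:
                counts[_RULE_INDEX[f"CAT-H3K9:{name}"]] += 1
        counts[_RULE_INDEX["KDM-H3K9"]] += int((self.kdm_site >= 0).sum())
        return counts

    def run(
        self,
        n_steps: int,
        rng: np.random.Generator | int = 0,
        report_interval: int = 100,
    ) -> WellMixedResult:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        n_samples = n_steps // report_interval
        meth = np.zeros((n_samples, self.n), dtype=np.int8)
        bonds = np.zeros((n_samples, len(RULE_IDS)), dtype=int)
        si = 0
        for s in range(n_steps):
            self.step(rng)
            if (s + 1) % report_interval == 0:
                meth[si] = self.meth
                bonds[si] = self.bond_counts()
                si += 1
        times = (np.arange(n_samples) + 1.0) * report_interval * self.config.time_step_us
        return WellMixedResult(times, meth, bonds, list(self.events))
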