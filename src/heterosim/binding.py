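"""Stochastic association/dissociation rules between particle sites.

Six rule families constitute the interaction model:

1. ``CD-H3K9``     — HP1 chromodomain reads di-/tri-methylated H3K9.
2. ``CSD-CSD``     — HP1 chromoshadow domains dimerize (nucleosome bridging).
3. ``BIND-CSD:*``  — each HMT's anchor (*bind*) docks on an HP1 chromoshadow.
4. ``KME-H3K9:*``  — G9a and SETDB1 (not SUV39H) bind methylated H3K9
                     directly through their Kme-reader modules.
5. ``CAT-H3K9:*``  — an HMT's catalytic (*cat*) domain engages a substrate
                     H3K9 in a state below me3.
6. ``KDM-H3K9``    — the demethylase binds methylated H3K9.

Every rule carries per-step probabilities (pa, pd): while an eligible free
pair sits within the capture radius an association fires with pa per step;
an existing bond dissociates with pd per step, making residence times
geometric with mean 1/pd steps.  Eligibility (methylation state, free
valence) is checked at bond creation only; a bond survives a state change
of its H3K9 partner until it stochastically dissociates.

Valence model: the H3K9 site has one *reader* slot (shared by HP1-CD,
Kme modules and KDM) and one *catalytic* slot (HMT cat); the HP1
chromoshadow has one dimerization slot and one HMT-recruitment slot; all
other sites are monovalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ENZYMES, RULE_IDS, RULE_KINDS, ConfigError, SystemConfig

__all__ = [
    "InteractionRule",
    "Bond",
    "register_interactions",
    "attempt_association",
    "attempt_dissociation",
    "rule_index",
]

#: Methylation states at which each rule's H3K9 side is eligible (at bond
#: creation); None for rules not involving an H3K9 site.
RULE_ELIGIBLE_STATES = {
    "CD-H3K9": (2, 3),
    "CSD-CSD": None,
    "BIND-CSD:G9a": None,
    "BIND-CSD:SUV39H": None,
    "BIND-CSD:SETDB1": None,
    "KME-H3K9:G9a": (1, 2, 3),
    "KME-H3K9:SETDB1": (1, 2, 3),
    "CAT-H3K9:G9a": (0, 1, 2),
    "CAT-H3K9:SUV39H": (0, 1, 2),
    "CAT-H3K9:SETDB1": (0, 1, 2),
    "KDM-H3K9": (1, 2, 3),
}

#: Slot used on the H3K9 side: "reader" or "cat".
RULE_H3K9_SLOT = {
    "CD-H3K9": "reader",
    "KME-H3K9:G9a": "reader",
    "KME-H3K9:SETDB1": "reader",
    "CAT-H3K9:G9a": "cat",
    "CAT-H3K9:SUV39H": "cat",
    "CAT-H3K9:SETDB1": "cat",
    "KDM-H3K9": "reader",
}


def rule_index(rule_id: str) -> int:
    """Stable integer index of a rule (kernel table order)."""
    return RULE_IDS.index(rule_id)


@dataclass(frozen=True)
class InteractionRule:
    """One binding pair with its per-step probabilities and geometry."""

    rule_id: str
    kinds: tuple
    pa: float
    pd: float
    capture_radius: float
    contact_radius: float
    eligible_states: tuple | None
    enzyme: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pa <= 1.0 and 0.0 <= self.pd <= 1.0):
            raise ConfigError(f"{self.rule_id}: pa/pd must lie in [0, 1]")
        if self.capture_radius < self.contact_radius:
            raise ConfigError(
                f"{self.rule_id}: capture radius below the sum of radii"
            )


@dataclass
class Bond:
    """A formed bond between two particle sites."""

    id: int
    rule_id: str
    partners: tuple          # (particle id, particle id)
    formed_at: int
    slots: tuple = ("", "")  # slot labels on each side


def register_interactions(config: SystemConfig) -> dict:
    """Instantiate the full rule table for a configuration.

    The table is identical across knockdown variants — knockdowns change
    copy numbers only.  SUV39H carries no Kme-module rule.
    """
    resolved = config.resolve_kinetics()
    rules = {}
    for rule_id in RULE_IDS:
        enzyme = rule_id.split(":", 1)[1] if ":" in rule_id else None
        if enzyme is not None and enzyme not in ENZYMES:
            raise ConfigError(f"rule {rule_id}: unknown enzyme {enzyme}")
        rules[rule_id] = InteractionRule(
            rule_id=rule_id,
            kinds=RULE_KINDS[rule_id],
            pa=resolved.pa[rule_id],
            pd=resolved.pd[rule_id],
            capture_radius=config.geometry.capture_radius(rule_id),
            contact_radius=config.geometry.contact_radius(rule_id),
            eligible_states=RULE_ELIGIBLE_STATES[rule_id],
            enzyme=enzyme,
        )
    return rules


@dataclass
class _SiteView:
    """Minimal view of a bindable site for the reference operations."""

    particle_id: int
    free_valence: int = 1
    meth_state: int | None = None


def attempt_association(
    a: _SiteView | "object",
    b: _SiteView | "object",
    rule: InteractionRule,
    rng: np.random.Generator,
    distance: float | None = None,
    step: int = 0,
    _counter: list = [0],
) -> Bond | None:
    """Reference association attempt (the kernel mirrors this logic).

    Preconditions — pair within capture radius, free valence on both
    sides, H3K9 state eligibility — are enforced here; the bond forms
    with probability ``rule.pa``.
    """
    if distance is not None and distance > rule.capture_radius:
        return None
    for site in (a, b):
        if getattr(site, "free_valence", 1) < 1:
            return None
        state = getattr(site, "meth_state", None)
        if state is not None and rule.eligible_states is not None:
            if state not in rule.eligible_states:
                return None
    if rng.random() >= rule.pa:
        return None
    _counter[0] += 1
    bond = Bond(
        id=_counter[0],
        rule_id=rule.rule_id,
        partners=(a.particle_id, b.particle_id),
        formed_at=step,
    )
    for site in (a, b):
        if hasattr(site, "free_valence"):
            site.free_valence -= 1
    return bond


def attempt_dissociation(
    bond: Bond,
    rule: InteractionRule,
    rng: np.random.Generator,
) -> bool:
    """Per-step Bernoulli dissociation; True when the bond breaks."""
    return bool(rng.random() < rule.pd)


def rules_to_arrays(rules: dict) -> dict:
    """Flatten the rule table into kernel-ready arrays (index = rule order)."""
    n = len(RULE_IDS)
    pa = np.zeros(n)
    pd = np.zeros(n)
    capture2 = np.zeros(n)
    for rid, rule in rules.items():
        i = rule_index(rid)
        pa[i] = rule.pa
        pd[i] = rule.pd
        capture2[i] = rule.capture_radius**2
    return {"pa": pa, "pd": pd, "capture2": capture2}
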