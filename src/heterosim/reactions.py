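"""Conditional catalysis: stepwise H3K9 methylation and demethylation.

An HMT is a tethered two-bead chain (*bind* anchor + *cat* SET domain).
A methylation event fires only when three conditions concur:

(i)   the *bind* bead is anchored to chromatin — either docked on the
      chromoshadow domain of an HP1 whose chromodomain is simultaneously
      bound to an H3K9 site, or (G9a/SETDB1) directly bound to a
      methylated H3K9 through its Kme module;
(ii)  the *cat* bead is bound to a substrate H3K9 in state me0/me1/me2;
(iii) the cat's stochastic draw falls below pt(enzyme, state).

The substrate then steps up one state and the cat bead turns *inactive*
(modelling co-factor exchange / conformational recovery); it re-activates
when its substrate bond dissociates (or, optionally, after a fixed
refractory time).  The one-bead demethylase needs only conditions (ii)
(state me1–me3, non-permanent site) and (iii).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ENZYMES, ConfigError, SystemConfig
from .fiber import ChromatinFiber, set_methylation

__all__ = [
    "ReactionRule",
    "CatState",
    "build_pt_table",
    "attempt_methylation",
    "attempt_demethylation",
    "update_cat_activity",
    "pt_arrays",
]


@dataclass(frozen=True)
class ReactionRule:
    """One catalytic transform: enzyme × substrate state → product state."""

    enzyme: str
    substrate_state: int
    product_state: int
    pt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pt <= 1.0:
            raise ConfigError(f"pt={self.pt} outside [0, 1]")
        step = self.product_state - self.substrate_state
        if self.enzyme == "KDM":
            if step != -1 or not 1 <= self.substrate_state <= 3:
                raise ConfigError("KDM rules step −1 from states 1..3")
        else:
            if step != 1 or not 0 <= self.substrate_state <= 2:
                raise ConfigError("HMT rules step +1 from states 0..2")


@dataclass
class CatState:
    """Activity bookkeeping of one catalytic bead."""

    active: bool = True
    anchored: bool = False
    reactivate_at: int = 0  # used only in fixed-timer mode


def build_pt_table(config: SystemConfig) -> list:
    """Full reaction-rule list from the config's pt tables (pt_scale applied).

    Validates the primary-activity structure: the largest entry of each
    HMT row sits at its primary activity (G9a → me0→me1, SETDB1 → me1→me2,
    SUV39H → me2→me3) and every secondary entry is strictly smaller.
    """
    resolved = config.resolve_kinetics()
    primary = {"G9a": 0, "SETDB1": 1, "SUV39H": 2}
    rules = []
    for enzyme in ENZYMES:
        row = resolved.pt[enzyme]
        if len(row) != 3:
            raise ConfigError(f"pt[{enzyme}] must have 3 entries (me0..me2)")
        p = primary[enzyme]
        for state, pt in enumerate(row):
            if state != p and pt >= row[p] and row[p] > 0:
                raise ConfigError(
                    f"pt[{enzyme}]: secondary entry me{state}→me{state + 1} "
                    f"({pt:g}) must be below the primary ({row[p]:g})"
                )
            if row[p] == 0 and pt > 0:
                raise ConfigError(
                    f"pt[{enzyme}]: secondary activity without a primary one"
                )
            rules.append(ReactionRule(enzyme, state, state + 1, pt))
    kdm_row = resolved.pt["KDM"]
    if len(kdm_row) != 3:
        raise ConfigError("pt[KDM] must have 3 entries (me1..me3)")
    for i, pt in enumerate(kdm_row):
        rules.append(ReactionRule("KDM", i + 1, i, pt))
    return rules


def pt_arrays(config: SystemConfig) -> tuple:
    """(pt_hmt[3 enzymes, 3 states], pt_kdm[3 states me1..me3]) arrays."""
    resolved = config.resolve_kinetics()
    pt_hmt = np.array([resolved.pt[e] for e in ENZYMES], dtype=float)
    pt_kdm = np.array(resolved.pt["KDM"], dtype=float)
    return pt_hmt, pt_kdm


def attempt_methylation(
    cat: CatState,
    fiber: ChromatinFiber,
    nucleosome_index: int,
    enzyme: str,
    pt_table: dict | None,
    rng: np.random.Generator,
    step: int = 0,
    pt: float | None = None,
) -> bool:
    """Reference methylation attempt on a cat-bound site (kernel mirror).

    Returns True when the event fired; failed conditions are silent
    non-events.  The caller supplies either a ``pt`` value or a
    ``pt_table[(enzyme, state)]`` mapping.
    """
    state = fiber.nucleosomes[nucleosome_index].meth_state
    if state > 2:
        return False
    if not (cat.anchored and cat.active):
        return False
    if pt is None:
        pt = pt_table[(enzyme, state)]
    if rng.random() >= pt:
        return False
    set_methylation(fiber, nucleosome_index, state + 1, step=step, enzyme=enzyme)
    cat.active = False
    return True


def attempt_demethylation(
    fiber: ChromatinFiber,
    nucleosome_index: int,
    pt_kdm: np.ndarray,
    rng: np.random.Generator,
    step: int = 0,
) -> bool:
    """Reference demethylation attempt by a site-bound KDM."""
    nuc = fiber.nucleosomes[nucleosome_index]
    state = nuc.meth_state
    if state < 1 or nuc.permanent:
        return False
    if rng.random() >= pt_kdm[state - 1]:
        return False
    set_methylation(fiber, nucleosome_index, state - 1, step=step, enzyme="KDM")
    return True


def update_cat_activity(
    cat: CatState,
    substrate_bound: bool,
    bind_anchored: bool,
    step: int = 0,
    refractory_steps: int = 0,
) -> CatState:
    """Refresh a cat bead's anchored/active flags.

    Dissociation-gated mode (default): an inactive cat re-activates as
    soon as its substrate bond is gone, which is exactly what prevents an
    immediate second transform on the same engagement.  Fixed-timer mode:
    re-activation at ``reactivate_at`` regardless of the bond.
    """
    cat.anchored = bind_anchored
    if not cat.active:
        if refractory_steps > 0:
            if step >= cat.reactivate_at:
                cat.active = True
        elif not substrate_bound:
            cat.active = True
    return cat
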