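"""Declarative system configuration: composition, geometry, kinetics, run controls.

A :class:`SystemConfig` fully describes one simulated system — a
coarse-grained chromatin fiber plus diffusing HP1, three H3K9
methyltransferases (G9a, SUV39H, SETDB1) and a generic demethylase (KDM)
in a periodic cubic box.  Configurations are read and written as YAML with
a ``schema_version`` key; kinetics may be given either as raw per-step
probability tables or as experimental anchors (KD, koff) that are
converted at load time (the resolved config records which path was used).

Units: lengths nm, times µs, concentrations µM, rates s⁻¹.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .calibration import pa_for_target_kd
from .constants import micromolar_to_molar, molar_to_per_nm3

SCHEMA_VERSION = 1

#: HMT enzymes, in the fixed internal order used by kernel tables.
ENZYMES = ("G9a", "SUV39H", "SETDB1")
#: All diffusing protein species.
PROTEINS = ("HP1",) + ENZYMES + ("KDM",)

#: Binding-rule identifiers (rule families 1–6 of the interaction model).
RULE_IDS = (
    "CD-H3K9",          # HP1 chromodomain ↔ H3K9me2/3
    "CSD-CSD",          # HP1 chromoshadow dimerization
    "BIND-CSD:G9a",     # HMT anchor ↔ HP1 chromoshadow
    "BIND-CSD:SUV39H",
    "BIND-CSD:SETDB1",
    "KME-H3K9:G9a",     # Kme-reader module ↔ H3K9me1/2/3 (G9a, SETDB1 only)
    "KME-H3K9:SETDB1",
    "CAT-H3K9:G9a",     # catalytic domain ↔ H3K9me0/1/2 (substrate engagement)
    "CAT-H3K9:SUV39H",
    "CAT-H3K9:SETDB1",
    "KDM-H3K9",         # demethylase ↔ H3K9me1/2/3
)

#: Particle kinds participating in each rule (for radii / capture distance).
RULE_KINDS = {
    "CD-H3K9": ("hp1_bead", "h3k9"),
    "CSD-CSD": ("hp1_bead", "hp1_bead"),
    "BIND-CSD:G9a": ("hmt_bead", "hp1_bead"),
    "BIND-CSD:SUV39H": ("hmt_bead", "hp1_bead"),
    "BIND-CSD:SETDB1": ("hmt_bead", "hp1_bead"),
    "KME-H3K9:G9a": ("hmt_bead", "h3k9"),
    "KME-H3K9:SETDB1": ("hmt_bead", "h3k9"),
    "CAT-H3K9:G9a": ("hmt_bead", "h3k9"),
    "CAT-H3K9:SUV39H": ("hmt_bead", "h3k9"),
    "CAT-H3K9:SETDB1": ("hmt_bead", "h3k9"),
    "KDM-H3K9": ("kdm", "h3k9"),
}


class ConfigError(ValueError):
    """Invalid or inconsistent configuration (message names the field)."""


@dataclass
class GeometryConfig:
    """Particle radii and tether parameters (nm)."""

    radius_nm: dict = field(
        default_factory=lambda: {
            "core": 5.0,      # nucleosome core bead
            "h3k9": 1.0,      # H3K9 tail site
            "hp1_bead": 1.5,  # HP1 CD and CSD beads
            "hmt_bead": 1.5,  # HMT bind and cat beads (R_bind = R_cat = 1.5)
            "kdm": 1.5,       # one-particle demethylase
        }
    )
    #: absolute free length of the bind–cat / CD–CSD intramolecular tether
    #: (the disordered-linker standard distance D_std)
    bindcat_free_len_nm: float = 4.0
    #: exponential damping multiplier k in exp(-k·Δd) beyond the free length
    damping_k_per_nm: float = 0.3
    #: free slack beyond hard contact for the core–site tether
    core_site_slack_nm: float = 3.0
    #: free slack beyond hard contact for the core–core linker tether
    linker_slack_nm: float = 6.0
    #: free slack beyond hard contact for dynamically formed bonds
    bond_slack_nm: float = 1.5
    #: capture radius = sum of radii + this tolerance
    capture_tolerance_nm: float = 0.5
    #: hard cap on a single proposed displacement (resolution bound)
    max_step_nm: float = 6.0

    def capture_radius(self, rule_id: str) -> float:
        ka, kb = RULE_KINDS[rule_id]
        return self.radius_nm[ka] + self.radius_nm[kb] + self.capture_tolerance_nm

    def contact_radius(self, rule_id: str) -> float:
        ka, kb = RULE_KINDS[rule_id]
        return self.radius_nm[ka] + self.radius_nm[kb]


#: Default species diffusivities, nm²/µs (≡ µm²/s).  HP1 is the measured
#: anchor; the enzymes are scaled from it by M^(-1/3) (Stokes) using their
#: molecular masses; fiber beads are slow (tethered chain).
DEFAULT_DIFFUSIVITY = {
    "HP1": 0.550,
    "G9a": 0.31,
    "SUV39H": 0.44,
    "SETDB1": 0.31,
    "KDM": 0.32,
    "core": 0.01,
    "h3k9": 0.2,
}

#: Default binding anchors per rule: target KD (µM) and koff (s⁻¹).
#: Reconstructions from the printed calibration anchors: the HP1
#: chromodomain off-rate is the measured ~4 s⁻¹; HMT–CSD, Kme-module,
#: enzyme–substrate and KDM–substrate affinities are all on the order of
#: 10 µM; CSD dimerization is tighter.  Off-rates without a printed
#: value are set faster than the chromodomain's (transient recruitment
#: and substrate engagement), which keeps bond populations equilibrating
#: well below the methylation timescale.
DEFAULT_ANCHORS = {
    "CD-H3K9": {"kd_uM": 10.0, "koff_s": 4.0},
    "CSD-CSD": {"kd_uM": 2.0, "koff_s": 40.0},
    "BIND-CSD:G9a": {"kd_uM": 10.0, "koff_s": 40.0},
    "BIND-CSD:SUV39H": {"kd_uM": 10.0, "koff_s": 40.0},
    "BIND-CSD:SETDB1": {"kd_uM": 10.0, "koff_s": 40.0},
    "KME-H3K9:G9a": {"kd_uM": 10.0, "koff_s": 40.0},
    "KME-H3K9:SETDB1": {"kd_uM": 10.0, "koff_s": 40.0},
    "CAT-H3K9:G9a": {"kd_uM": 10.0, "koff_s": 100.0},
    "CAT-H3K9:SUV39H": {"kd_uM": 10.0, "koff_s": 100.0},
    "CAT-H3K9:SETDB1": {"kd_uM": 10.0, "koff_s": 100.0},
    "KDM-H3K9": {"kd_uM": 10.0, "koff_s": 40.0},
}

#: Default transform probabilities per step (reconstructions; exposed in
#: config).  HMT rows are indexed by substrate state me0/me1/me2; the
#: primary activity of each enzyme carries the largest entry
#: (G9a → mono, SETDB1 → di, SUV39H → tri); secondary activities are 50×
#: reduced, reflecting the strong state-specificity of the three writers.
#: KDM is indexed by substrate state me1/me2/me3.  The overall scale is
#: set so that (i) firing per substrate engagement stays well below
#: saturation (pt ≪ pd of the engagement bond) — preserving enzyme
#: specificity — and (ii) whole-system turnover per enzyme lands in the
#: 10–10² s range; the eraser strength puts the wild-type stationary me3
#: level high but below saturation, so knockdowns register as a level
#: decrease.
DEFAULT_PT = {
    "G9a": [1.0e-5, 2.0e-7, 2.0e-7],
    "SUV39H": [2.0e-7, 2.0e-7, 1.0e-5],
    "SETDB1": [2.0e-7, 1.0e-5, 2.0e-7],
    "KDM": [2.5e-7, 2.5e-7, 2.5e-7],
}


@dataclass
class KineticsConfig:
    """Binding and reaction kinetics, either as anchors or raw tables.

    ``mode`` selects the calibration path recorded in the resolved config:

    * ``"anchors"`` — ``anchors[rule] = {kd_uM, koff_s}``; per-step
      probabilities are derived at load time (pd = koff·Δt, pa by the
      contact-volume calibration).
    * ``"raw"`` — ``pa[rule]``, ``pd[rule]`` given directly.
    """

    mode: str = "anchors"
    anchors: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_ANCHORS))
    pa: dict = field(default_factory=dict)
    pd: dict = field(default_factory=dict)
    pt: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_PT))


@dataclass
class ResolvedKinetics:
    """Per-step probability tables actually handed to the engine."""

    pa: dict
    pd: dict
    pt: dict
    calibration_path: str


@dataclass
class SystemConfig:
    """Full declarative description of one simulated system."""

    schema_version: int = SCHEMA_VERSION
    n_nucleosomes: int = 102
    fiber_span_bp: float = 20_000.0
    protein_copies: dict = field(
        default_factory=lambda: {name: 102 for name in PROTEINS}
    )
    knockdown: dict = field(default_factory=dict)
    concentration_uM: float = 10.0
    time_step_us: float = 1.0
    box_edge_nm: float | None = None
    voxel_edge_nm: float | None = None
    n_steps: int = 200_000
    report_interval: int = 1_000
    seed: int = 0
    diffusivity: dict = field(default_factory=lambda: dict(DEFAULT_DIFFUSIVITY))
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    #: multiply every pt by this factor (scaled-down proxy runs use 100)
    pt_scale: float = 1.0
    #: 0 → catalytic reactivation is dissociation-gated; >0 → fixed timer
    cat_refractory_steps: int = 0
    #: average the me3 time chart over the "full" fiber or the central "half"
    averaging_region: str = "full"
    #: record unwrapped protein-bead positions every report interval
    record_positions: bool = False

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()
        if self.box_edge_nm is None:
            self.box_edge_nm = derive_box_size(
                max(1, self.protein_copies.get("HP1", 1)), self.concentration_uM
            )
        if self.voxel_edge_nm is None:
            radii = self.geometry.radius_nm
            largest_pair = 2.0 * max(radii.values())
            max_capture = max(self.geometry.capture_radius(r) for r in RULE_IDS)
            self.voxel_edge_nm = max(
                largest_pair, max_capture, self.geometry.max_step_nm
            ) + 0.5
        if self.box_edge_nm < 2.0 * max(self.geometry.radius_nm.values()):
            raise ConfigError(
                f"box_edge_nm={self.box_edge_nm:g} smaller than twice the "
                "largest particle radius"
            )

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"schema_version={self.schema_version} not supported "
                f"(expected {SCHEMA_VERSION})"
            )
        if self.n_nucleosomes < 2:
            raise ConfigError(f"n_nucleosomes={self.n_nucleosomes} must be ≥ 2")
        for name, copies in self.protein_copies.items():
            if name not in PROTEINS:
                raise ConfigError(f"protein_copies: unknown protein {name!r}")
            if copies < 0:
                raise ConfigError(f"protein_copies[{name}]={copies} must be ≥ 0")
        for name, frac in self.knockdown.items():
            if name not in PROTEINS:
                raise ConfigError(f"knockdown: unknown enzyme {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"knockdown[{name}]={frac} outside [0, 1]")
        if not self.time_step_us > 0:
            raise ConfigError(f"time_step_us={self.time_step_us} must be > 0")
        if not self.concentration_uM > 0:
            raise ConfigError(f"concentration_uM={self.concentration_uM} must be > 0")
        if self.n_steps < 1 or self.report_interval < 1:
            raise ConfigError("n_steps and report_interval must be ≥ 1")
        if self.averaging_region not in ("full", "half"):
            raise ConfigError(
                f"averaging_region={self.averaging_region!r} must be 'full' or 'half'"
            )
        if self.kinetics.mode not in ("anchors", "raw"):
            raise ConfigError(f"kinetics.mode={self.kinetics.mode!r} unknown")

    # ------------------------------------------------------------------
    def copies_effective(self, name: str) -> int:
        """Copy count after knockdown; round-half-even keeps it unbiased."""
        copies = self.protein_copies.get(name, 0)
        frac = self.knockdown.get(name, 1.0)
        return int(np.round(copies * frac))

    def effective_copies(self) -> dict:
        return {name: self.copies_effective(name) for name in PROTEINS}

    def box_volume_nm3(self) -> float:
        return float(self.box_edge_nm) ** 3

    def resolve_kinetics(self) -> ResolvedKinetics:
        """Produce the per-step probability tables for the engine."""
        kin = self.kinetics
        pt = {
            name: [min(1.0, p * self.pt_scale) for p in kin.pt[name]]
            for name in kin.pt
        }
        for name in list(DEFAULT_PT):
            if name not in pt:
                raise ConfigError(f"kinetics.pt missing entries for {name}")
        if kin.mode == "raw":
            for rule in RULE_IDS:
                if rule not in kin.pa or rule not in kin.pd:
                    raise ConfigError(f"kinetics: missing raw pa/pd for rule {rule}")
            pa = {r: float(kin.pa[r]) for r in RULE_IDS}
            pd = {r: float(kin.pd[r]) for r in RULE_IDS}
            for r in RULE_IDS:
                if not (0 <= pa[r] <= 1 and 0 <= pd[r] <= 1):
                    raise ConfigError(f"kinetics: pa/pd for {r} outside [0, 1]")
            return ResolvedKinetics(pa, pd, pt, "raw")
        pa, pd = {}, {}
        for rule in RULE_IDS:
            if rule not in kin.anchors:
                raise ConfigError(f"kinetics: missing anchors for rule {rule}")
            anch = kin.anchors[rule]
            try:
                kd_uM, koff_s = float(anch["kd_uM"]), float(anch["koff_s"])
            except (KeyError, TypeError) as exc:
                raise ConfigError(f"kinetics.anchors[{rule}] needs kd_uM and koff_s") from exc
            pd[rule] = koff_s * self.time_step_us / 1e6
            if pd[rule] > 1:
                raise ConfigError(
                    f"kinetics.anchors[{rule}]: koff {koff_s} s⁻¹ gives pd > 1"
                )
            pa[rule] = pa_for_target_kd(
                pd[rule],
                micromolar_to_molar(kd_uM),
                self.geometry.contact_radius(rule),
                self.geometry.capture_radius(rule),
            )
        return ResolvedKinetics(pa, pd, pt, "anchors")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SystemConfig":
        data = copy.deepcopy(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "geometry" in data and isinstance(data["geometry"], dict):
            data["geometry"] = GeometryConfig(**data["geometry"])
        if "kinetics" in data and isinstance(data["kinetics"], dict):
            data["kinetics"] = KineticsConfig(**data["kinetics"])
        return cls(**data)

    def replace(self, **changes) -> "SystemConfig":
        d = self.to_dict()
        # force re-derivation of dependent fields when their inputs change
        if ("protein_copies" in changes or "concentration_uM" in changes) \
                and "box_edge_nm" not in changes:
            d["box_edge_nm"] = None
        d.update(changes)
        return SystemConfig.from_dict(d)


# ---------------------------------------------------------------------------


def derive_box_size(copy_count: int, concentration_uM: float) -> float:
    """Cubic box edge (nm) holding ``copy_count`` molecules at a concentration.

    Solves copy_count / (N_A · L³) = c; e.g. 102 copies at 10 µM → ≈257 nm.
    """
    if copy_count <= 0:
        raise ConfigError(f"copy_count={copy_count} must be > 0")
    if concentration_uM <= 0:
        raise ConfigError(f"concentration_uM={concentration_uM} must be > 0")
    density = molar_to_per_nm3(micromolar_to_molar(concentration_uM))
    return float((copy_count / density) ** (1.0 / 3.0))


def load_config(path: str | Path) -> SystemConfig:
    """Load and validate a YAML system configuration."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse failure: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return SystemConfig.from_dict(data)


def save_config(config: SystemConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Scenario suite
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSet:
    """The seven-system suite: wild type plus each HMT at 75% and 50%."""

    base: SystemConfig
    variants: list = field(default_factory=list)  # (label, enzyme|None, fraction)
    n_replicas: int = 25

    def __post_init__(self) -> None:
        labels = [v[0] for v in self.variants]
        if len(labels) != len(set(labels)):
            raise ConfigError("scenario labels must be unique")
        if not any(v[1] is None for v in self.variants):
            raise ConfigError("the wild-type variant must be present")

    def labels(self) -> list:
        return [v[0] for v in self.variants]

    def config_for(self, label: str) -> SystemConfig:
        for lab, enzyme, fraction in self.variants:
            if lab == label:
                if enzyme is None:
                    return self.base.replace()
                kd = dict(self.base.knockdown)
                kd[enzyme] = fraction
                return self.base.replace(knockdown=kd)
        raise ConfigError(f"unknown scenario label {label!r}")


def make_scenarios(base: SystemConfig, n_replicas: int = 25) -> ScenarioSet:
    """WT plus {G9a, SUV39H, SETDB1} × {75%, 50%} — seven systems."""
    variants = [("WT", None, 1.0)]
    for enzyme in ENZYMES:
        for fraction in (0.75, 0.50):
            variants.append((f"{enzyme}_{int(fraction * 100)}", enzyme, fraction))
    return ScenarioSet(base=base, variants=variants, n_replicas=n_replicas)


# ---------------------------------------------------------------------------
# Miniature fixtures
# ---------------------------------------------------------------------------


def miniature_config(
    n_nucleosomes: int = 8,
    copies: int = 8,
    binding_boost: float = 10.0,
    pt_scale: float = 1000.0,
    n_steps: int = 50_000,
    report_interval: int = 250,
    seed: int = 0,
    **overrides,
) -> SystemConfig:
    """Small, kinetically boosted system for tests.

    ``binding_boost`` multiplies every koff (and therefore, through the
    affinity-preserving calibration, every pa) so that binding equilibrates
    in ~10⁴ steps instead of ~10⁶; affinities (KD) are unchanged.
    """
    anchors = copy.deepcopy(DEFAULT_ANCHORS)
    for rule in anchors:
        anchors[rule]["koff_s"] *= binding_boost
    kin = KineticsConfig(mode="anchors", anchors=anchors)
    cfg = dict(
        n_nucleosomes=n_nucleosomes,
        fiber_span_bp=n_nucleosomes * 196.0,
        protein_copies={name: copies for name in PROTEINS},
        kinetics=kin,
        pt_scale=pt_scale,
        n_steps=n_steps,
        report_interval=report_interval,
        seed=seed,
    )
    cfg.update(overrides)
    return SystemConfig(**cfg)
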