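"""Kinetic calibration: experimental constants → per-step probabilities, and back.

Forward direction
-----------------
Binding processes in the engine are parameterized by per-step probabilities:
``pd`` (dissociation, drawn every step a bond exists) and ``pa``
(association, drawn every step an eligible pair sits within the capture
radius).  ``pd`` maps directly onto an off-rate, ``koff = pd / Δt``.  Two
routes to ``pa`` are provided:

* :func:`pa_from_kinetics` — the well-mixed relation
  ``pa = pd · [F] · kon / koff``, with ``[F]`` the free-partner
  concentration.  This treats the association process as an unconditional
  per-step Bernoulli chain and is appropriate for the ideal-mixing mode.
* :func:`pa_for_target_kd` — the contact-gated relation
  ``pa = pd / (KD · N_A · V_capture)``.  In the spatial engine an
  association attempt only fires while the pair is inside the capture
  shell; balancing the association flux ``pa · ⟨contact pairs⟩`` against
  the dissociation flux ``pd · n_bonds`` for an ideal dilute solution
  gives an emergent dissociation constant ``KD = pd / (pa · N_A · V_cap)``.
  Default engine probabilities are derived through this route so that
  dissociation constants measured back from trajectories recover the
  experimental anchors.

Reverse direction
-----------------
:func:`estimate_diffusion`, :func:`estimate_koff` and :func:`estimate_kd`
recover D, koff and KD from simulated trajectories for validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import (
    LITRE_PER_NM3,
    N_AVOGADRO,
    US_PER_S,
    molar_to_micromolar,
    per_nm3_to_molar,
)

__all__ = [
    "KineticAnchors",
    "CalibrationError",
    "pa_from_kinetics",
    "pa_for_target_kd",
    "capture_volume_nm3",
    "emergent_kd_molar",
    "estimate_diffusion",
    "estimate_koff",
    "estimate_kd",
    "equilibration_index",
    "DiffusionEstimate",
    "KoffEstimate",
    "KdEstimate",
]


class CalibrationError(ValueError):
    """Raised for missing or dimensionally inconsistent kinetic anchors."""


@dataclass(frozen=True)
class KineticAnchors:
    """Experimental kinetic constants for one binding process, in SI-molar units.

    Parameters
    ----------
    kon_per_M_s:
        Association rate constant, M⁻¹ s⁻¹ (1 mM⁻¹s⁻¹ = 1000 M⁻¹s⁻¹).
    koff_s:
        Dissociation rate constant, s⁻¹.
    free_conc_M:
        Free binding-partner concentration [F], M.
    kd_M:
        Optional dissociation constant; must agree with ``koff/kon`` within
        ``rtol`` when both are supplied (a deliberately strict dimensional
        consistency check — passing values in the wrong units trips it).
    """

    kon_per_M_s: float
    koff_s: float
    free_conc_M: float
    kd_M: float | None = None
    turnover_s: float | None = None
    rtol: float = 0.25

    def __post_init__(self) -> None:
        for name in ("kon_per_M_s", "koff_s", "free_conc_M"):
            value = getattr(self, name)
            if not value > 0:
                raise CalibrationError(f"{name} must be positive, got {value!r}")
        if self.kd_M is not None:
            implied = self.koff_s / self.kon_per_M_s
            if not math.isclose(self.kd_M, implied, rel_tol=self.rtol):
                raise CalibrationError(
                    f"kd_M={self.kd_M:g} M inconsistent with koff/kon="
                    f"{implied:g} M; check units (kon must be M⁻¹s⁻¹)"
                )

    @classmethod
    def from_common_units(
        cls,
        kon_per_mM_s: float,
        koff_s: float,
        free_conc_uM: float,
        kd_uM: float | None = None,
        **kwargs,
    ) -> "KineticAnchors":
        """Build anchors from the units the literature typically prints."""
        return cls(
            kon_per_M_s=kon_per_mM_s * 1e3,
            koff_s=koff_s,
            free_conc_M=free_conc_uM * 1e-6,
            kd_M=None if kd_uM is None else kd_uM * 1e-6,
            **kwargs,
        )


def pa_from_kinetics(pd: float, anchors: KineticAnchors) -> float:
    """Well-mixed per-step association probability, ``pa = pd·[F]·kon/koff``.

    Clamped to [0, 1]; a clamp emits a warning since it breaks the
    calibration relation.
    """
    if pd < 0 or pd > 1:
        raise CalibrationError(f"pd must lie in [0, 1], got {pd!r}")
    if pd == 0:
        return 0.0
    pa = pd * anchors.free_conc_M * anchors.kon_per_M_s / anchors.koff_s
    if pa > 1.0:
        warnings.warn(
            f"pa={pa:g} clamped to 1; calibration relation no longer exact",
            RuntimeWarning,
            stacklevel=2,
        )
        pa = 1.0
    return pa


def capture_volume_nm3(r_contact_nm: float, r_capture_nm: float) -> float:
    """Volume of the capture shell between hard contact and the capture radius."""
    if r_capture_nm <= r_contact_nm:
        raise CalibrationError(
            f"capture radius {r_capture_nm} must exceed contact radius {r_contact_nm}"
        )
    return 4.0 / 3.0 * math.pi * (r_capture_nm**3 - r_contact_nm**3)


def pa_for_target_kd(
    pd: float,
    kd_M: float,
    r_contact_nm: float,
    r_capture_nm: float,
) -> float:
    """Contact-gated per-step association probability realizing a target KD.

    Inverts ``KD = pd / (pa · N_A · V_cap)`` for ``pa``; clamps to 1 with a
    warning when the requested affinity is unreachable at the given pd.
    """
    if not kd_M > 0:
        raise CalibrationError(f"kd_M must be positive, got {kd_M!r}")
    if pd < 0 or pd > 1:
        raise CalibrationError(f"pd must lie in [0, 1], got {pd!r}")
    v_cap = capture_volume_nm3(r_contact_nm, r_capture_nm)
    pa = pd / (kd_M * N_AVOGADRO * v_cap * LITRE_PER_NM3)
    if pa > 1.0:
        warnings.warn(
            f"pa={pa:g} clamped to 1; target KD {kd_M:g} M unreachable at pd={pd:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        pa = 1.0
    return pa


def emergent_kd_molar(pa: float, pd: float, r_contact_nm: float, r_capture_nm: float) -> float:
    """Analytic dissociation constant implied by (pa, pd) under contact gating."""
    if pa == 0:
        return math.inf
    v_cap = capture_volume_nm3(r_contact_nm, r_capture_nm)
    return pd / (pa * N_AVOGADRO * v_cap * LITRE_PER_NM3)


# ---------------------------------------------------------------------------
# Trajectory estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiffusionEstimate:
    d_nm2_us: float
    ci_low: float
    ci_high: float
    n_particles: int
    n_samples: int

    @property
    def d_um2_s(self) -> float:
        # nm²/µs and µm²/s are numerically identical.
        return self.d_nm2_us


def estimate_diffusion(
    positions_nm: np.ndarray,
    sample_interval_us: float,
    lags: np.ndarray | list[int] | None = None,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> DiffusionEstimate:
    """Fit MSD(τ) = 6·D·τ + c to unwrapped free-particle trajectories.

    Parameters
    ----------
    positions_nm:
        Array (n_samples, n_particles, 3) of *unwrapped* positions sampled
        at a fixed interval.  Only freely diffusing (unbound) particles
        should be included.
    sample_interval_us:
        Time between consecutive samples, µs.
    lags:
        Lag indices (in samples) at which the ensemble MSD is evaluated;
        defaults to ten log-spaced lags between 1 and n_samples//4.

    The additive intercept absorbs short-time intramolecular relaxation of
    tethered multi-bead molecules so the slope reports the centre-of-mass
    (species) diffusivity.
    """
    pos = np.asarray(positions_nm, dtype=float)
    if pos.ndim == 2:
        pos = pos[:, None, :]
    n_samples, n_particles = pos.shape[0], pos.shape[1]
    if n_samples < 8:
        raise ValueError("need at least 8 samples to fit a diffusion coefficient")
    if lags is None:
        lags = np.unique(
            np.round(np.logspace(0, np.log10(max(2, n_samples // 4)), 10)).astype(int)
        )
    lags = np.asarray(lags, dtype=int)
    lags = lags[(lags >= 1) & (lags < n_samples)]

    def msd_per_particle(p: np.ndarray) -> np.ndarray:
        # p: (n_samples, k, 3) -> (n_lags, k)
        out = np.empty((len(lags), p.shape[1]))
        for i, lag in enumerate(lags):
            disp = p[lag:] - p[:-lag]
            out[i] = np.mean(np.sum(disp * disp, axis=-1), axis=0)
        return out

    msd_pp = msd_per_particle(pos)
    tau = lags * sample_interval_us

    def fit(msd: np.ndarray) -> float:
        slope, _ = np.polyfit(tau, msd, 1)
        return slope / 6.0

    d_hat = fit(msd_pp.mean(axis=1))
    rng = np.random.default_rng(0) if rng is None else rng
    if n_particles > 1 and n_boot > 0:
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n_particles, n_particles)
            boots[b] = fit(msd_pp[:, idx].mean(axis=1))
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = d_hat
    return DiffusionEstimate(d_hat, lo, hi, n_particles, n_samples)


@dataclass(frozen=True)
class KoffEstimate:
    koff_s: float
    ci_low: float
    ci_high: float
    n_completed: int
    total_bound_time_s: float


def estimate_koff(
    completed_us: np.ndarray | list[float],
    censored_us: np.ndarray | list[float] = (),
    min_events: int = 20,
) -> KoffEstimate:
    """Maximum-likelihood exponential off-rate from bond residence times.

    Bonds still alive at trajectory end enter as right-censored
    observations: the MLE is (number of completed lifetimes) / (total
    observed bound time).  CI from the exact gamma relation.
    """
    completed = np.asarray(completed_us, dtype=float)
    censored = np.asarray(censored_us, dtype=float)
    n = completed.size
    if n < min_events:
        raise ValueError(f"need ≥{min_events} completed bond lifetimes, got {n}")
    total_us = completed.sum() + censored.sum()
    koff = n / (total_us / US_PER_S)
    lo = stats.chi2.ppf(0.025, 2 * n) / 2.0 / (total_us / US_PER_S)
    hi = stats.chi2.ppf(0.975, 2 * n) / 2.0 / (total_us / US_PER_S)
    return KoffEstimate(koff, lo, hi, n, total_us / US_PER_S)


def equilibration_index(series: np.ndarray, frac: float = 0.2, tol: float = 0.1) -> int:
    """Burn-in heuristic: first index from which the running mean stays within
    ``tol`` standard deviations of the final-half mean, but never less than
    ``frac`` of the series length."""
    x = np.asarray(series, dtype=float)
    n = x.size
    floor = int(frac * n)
    ref = x[n // 2 :].mean()
    scale = x[n // 2 :].std() + 1e-12
    window = max(1, n // 20)
    means = np.convolve(x, np.ones(window) / window, mode="valid")
    ok = np.abs(means - ref) <= tol * scale + 1e-12
    idx = int(np.argmax(ok)) if ok.any() else n // 2
    return max(floor, idx)


@dataclass(frozen=True)
class KdEstimate:
    kd_uM: float
    n_samples: int
    burn_in: int
    lower_bound_only: bool = False


def estimate_kd(
    n_free_a: np.ndarray,
    n_free_b: np.ndarray,
    n_complex: np.ndarray,
    box_volume_nm3: float,
    burn_in: int | None = None,
) -> KdEstimate:
    """Equilibrium dissociation constant from trajectory counts.

    ``Kd = [A_free][B_free]/[AB]`` with concentrations formed from
    time-averaged counts over the equilibrated segment and the box volume.
    If no complexes were observed the estimate is flagged as a lower bound
    (Kd = ∞).
    """
    a = np.asarray(n_free_a, dtype=float)
    b = np.asarray(n_free_b, dtype=float)
    ab = np.asarray(n_complex, dtype=float)
    if not (a.shape == b.shape == ab.shape):
        raise ValueError("count series must share a shape")
    if burn_in is None:
        burn_in = equilibration_index(ab)
    a, b, ab = a[burn_in:], b[burn_in:], ab[burn_in:]
    mean_ab = ab.mean()
    if mean_ab == 0:
        return KdEstimate(math.inf, a.size, burn_in, lower_bound_only=True)
    conc = lambda counts: per_nm3_to_molar(counts / box_volume_nm3)  # noqa: E731
    kd_M = conc(a.mean()) * conc(b.mean()) / conc(mean_ab)
    return KdEstimate(molar_to_micromolar(kd_M), a.size, burn_in)


def fit_exponential_rate(durations_us: np.ndarray) -> float:
    """Cross-check: exponential rate (s⁻¹) by direct MLE fit on completed
    durations only (no censoring); scipy expon fit with loc pinned at 0."""
    durations = np.asarray(durations_us, dtype=float)
    loc, scale = stats.expon.fit(durations, floc=0.0)
    return 1.0 / (scale / US_PER_S)
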