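"""Dose-matrix synergy analytics: Webb fractional-product combination index,
Loewe additivity excess, single-agent dose-response fitting and isobolograms.

Conventions
-----------
* Fraction affected ``fa = 1 - viability``; fraction unaffected ``fu = 1 - fa``.
* Webb CI = fu_combo / (fu_a * fu_b): CI < 1 synergy, CI < 0.3 strong synergy,
  CI > 1 antagonism.
* Loewe additivity predicts the combination effect fa* solving
  ``dose_a / D_A(fa*) + dose_b / D_B(fa*) = 1`` where ``D(fa)`` is the
  single-agent dose achieving fa; *Loewe excess* is observed minus predicted
  fa, positive where the combination beats dose additivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "DoseMatrix",
    "SynergyResult",
    "DoseResponseCurve",
    "fraction_affected",
    "webb_ci",
    "classify_ci",
    "fit_single_agent_curve",
    "loewe_prediction",
    "loewe_excess_matrix",
    "isobologram",
]

STRONG_SYNERGY_CI = 0.3
SYNERGY_CI = 1.0


@dataclass
class DoseMatrix:
    """A fraction-affected grid over two ascending dose ranges (each incl. 0)."""

    drug_a_name: str
    drug_b_name: str
    doses_a: np.ndarray  # uM, strictly increasing, doses_a[0] == 0
    doses_b: np.ndarray
    fraction_affected: np.ndarray  # (len(doses_a), len(doses_b)), in [0, 1]

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.fraction_affected = np.asarray(self.fraction_affected, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d.ndim != 1 or d.size < 2 or np.any(np.diff(d) <= 0):
                raise ValueError(f"{name} must be a strictly increasing 1-d grid")
            if d[0] != 0:
                raise ValueError(f"{name} must start at dose 0")
        if self.fraction_affected.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("fraction_affected shape does not match the dose grids")
        fa = self.fraction_affected
        finite = fa[np.isfinite(fa)]
        if finite.size and (finite.min() < -1e-6 or finite.max() > 1 + 1e-6):
            raise ValueError("fraction affected must lie in [0, 1]")

    def transposed(self) -> "DoseMatrix":
        return DoseMatrix(
            self.drug_b_name,
            self.drug_a_name,
            self.doses_b,
            self.doses_a,
            self.fraction_affected.T,
        )


@dataclass
class SynergyResult:
    ci: np.ndarray  # NaN on zero-dose row/column and undefined cells
    loewe_excess: np.ndarray
    labels: np.ndarray  # object array of category strings ('' where undefined)
    flags: dict = field(default_factory=dict)


def fraction_affected(viability_fraction):
    """fa = 1 - viability; values marginally outside [0, 1] are clamped with a warning."""
    v = np.asarray(viability_fraction, dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = (v < 0) | (v > 1)
    if np.any(out_of_range & np.isfinite(v)):
        warnings.warn("viability outside [0, 1]; clamping", stacklevel=2)
        v = np.clip(v, 0.0, 1.0)
    fa = 1.0 - v
    return float(fa) if np.isscalar(viability_fraction) else fa


def webb_ci(fu_a: float, fu_b: float, fu_combo: float) -> float:
    """Webb fractional-product combination index fu_combo / (fu_a * fu_b).

    Returns NaN (undefined-CI marker) when fu_a * fu_b == 0, i.e. when a
    single agent already achieves complete kill.
    """
    denom = fu_a * fu_b
    if denom <= 0 or not math.isfinite(denom):
        return math.nan
    return fu_combo / denom


def classify_ci(ci: float) -> str:
    """Category label for a combination index (thresholds 0.3 and 1 exact)."""
    if not math.isfinite(ci):
        return ""
    if ci < STRONG_SYNERGY_CI:
        return "strong synergy"
    if ci < SYNERGY_CI:
        return "synergy"
    if ci == SYNERGY_CI:
        return "additive"
    return "antagonistic"


# ---------------------------------------------------------------------------
# single-agent dose-response curves


def _hill(d, floor, ceiling, ec50, slope):
    d = np.asarray(d, dtype=float)
    # computed in log space: (ec50/d)^slope overflows for tiny doses
    with np.errstate(divide="ignore", over="ignore"):
        log_ratio = slope * (np.log(ec50) - np.log(np.where(d > 0, d, 1.0)))
        ratio = np.where(d > 0, np.exp(np.minimum(log_ratio, 700.0)), np.inf)
    return floor + (ceiling - floor) / (1.0 + ratio)


@dataclass
class DoseResponseCurve:
    """Variable-slope logistic (4PL) fa(d), or a monotone interpolant fallback.

    ``inverse(fa)`` returns the dose achieving a fraction affected, defined on
    the achieved effect range; outside it, NaN.
    """

    floor: float = 0.0
    ceiling: float = 1.0
    ec50: float = 1.0
    slope: float = 1.0
    interpolant: tuple[np.ndarray, np.ndarray] | None = None  # (doses, fa), monotone
    inactive: bool = False
    fallback: bool = False

    def __call__(self, dose):
        if self.interpolant is not None:
            d, fa = self.interpolant
            return np.interp(dose, d, fa)
        return _hill(dose, self.floor, self.ceiling, self.ec50, self.slope)

    @property
    def effect_range(self) -> tuple[float, float]:
        if self.interpolant is not None:
            fa = self.interpolant[1]
            return float(fa.min()), float(fa.max())
        return self.floor, self.ceiling

    def inverse(self, fa: float) -> float:
        """Dose achieving fraction affected ``fa`` (NaN outside the effect range)."""
        if self.inactive:
            return math.nan
        if self.interpolant is not None:
            d, f = self.interpolant
            if fa < f[0] or fa > f[-1]:
                return math.nan
            return float(np.interp(fa, f, d))
        if not (self.floor < fa < self.ceiling):
            return 0.0 if fa <= self.floor else math.nan
        frac = (fa - self.floor) / (self.ceiling - fa)
        return float(self.ec50 * frac ** (1.0 / self.slope))


def fit_single_agent_curve(
    doses: Sequence[float],
    fa_values: Sequence[float],
    *,
    monotone_tolerance: float = 0.05,
) -> DoseResponseCurve:
    """Fit a variable-slope logistic to single-agent (dose, fraction affected) data.

    Data non-monotone beyond ``monotone_tolerance`` fall back to an
    isotonic-regression interpolant (with a warning).  A curve whose total
    effect span is negligible is flagged ``inactive`` (inverse undefined).
    """
    d = np.asarray(doses, dtype=float)
    fa = np.asarray(fa_values, dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 dose levels to fit a dose-response curve")
    order = np.argsort(d)
    d, fa = d[order], fa[order]

    if fa.max() - fa.min() < 1e-6:
        return DoseResponseCurve(
            floor=float(fa.mean()), ceiling=float(fa.mean()), inactive=True
        )

    drops = np.diff(fa)
    if drops.min() < -monotone_tolerance:
        warnings.warn(
            "dose-response data non-monotone beyond tolerance; "
            "falling back to isotonic interpolation",
            stacklevel=2,
        )
        return _isotonic_curve(d, fa)

    pos = d[d > 0]
    mid_guess = float(np.sqrt(pos[0] * pos[-1])) if pos.size else 1.0
    p0 = [max(fa.min(), 0.0), min(fa.max(), 1.0), mid_guess, 1.0]
    bounds = ([0.0, 0.0, 1e-12, 0.05], [1.0, 1.0, 1e12, 20.0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _hill, d, fa, p0=p0, bounds=bounds, maxfev=20000,
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
    except RuntimeError:
        return _isotonic_curve(d, fa)
    floor, ceiling, ec50, slope = map(float, popt)
    if ceiling - floor < 1e-6:
        return DoseResponseCurve(floor=floor, ceiling=ceiling, inactive=True)
    return DoseResponseCurve(floor=floor, ceiling=ceiling, ec50=ec50, slope=slope)


def _isotonic_curve(d: np.ndarray, fa: np.ndarray) -> DoseResponseCurve:
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=True)
    fa_fit = iso.fit_transform(d, fa)
    return DoseResponseCurve(interpolant=(d, fa_fit), fallback=True)


# ---------------------------------------------------------------------------
# Loewe additivity


def loewe_prediction(
    dose_a: float,
    dose_b: float,
    curve_a: DoseResponseCurve,
    curve_b: DoseResponseCurve,
) -> tuple[float, bool]:
    """Loewe-additive predicted fraction affected for a dose pair.

    Solves ``dose_a/D_A(fa) + dose_b/D_B(fa) = 1`` by bracketed root finding
    over the jointly achievable effect range.  Returns ``(fa, saturated)``;
    ``saturated`` marks cells clamped at a range boundary because no interior
    solution exists (e.g. the combination exceeds both single-agent maxima).
    """
    if curve_a.inactive and curve_b.inactive:
        return 0.0, False
    if curve_a.inactive:
        return float(curve_b(dose_b)), False
    if curve_b.inactive:
        return float(curve_a(dose_a)), False
    if dose_a == 0 and dose_b == 0:
        return 0.0, False
    if dose_a == 0:
        return float(curve_b(dose_b)), False
    if dose_b == 0:
        return float(curve_a(dose_a)), False

    lo_a, hi_a = curve_a.effect_range
    lo_b, hi_b = curve_b.effect_range
    lo = max(lo_a, lo_b)
    hi = min(hi_a, hi_b)

    def g(fa: float) -> float:
        da = curve_a.inverse(fa)
        db = curve_b.inverse(fa)
        if not (math.isfinite(da) and math.isfinite(db)):
            return math.nan
        total = 0.0
        total += dose_a / da if da > 0 else math.inf
        total += dose_b / db if db > 0 else math.inf
        return total - 1.0

    eps = 1e-9 * max(hi - lo, 1.0)
    f_lo, f_hi = lo + eps, hi - eps
    if f_hi <= f_lo:
        return float(hi), True
    g_lo, g_hi = g(f_lo), g(f_hi)
    if not math.isfinite(g_lo) or not math.isfinite(g_hi):
        return float(hi), True
    if g_lo <= 0:  # even the weakest achievable effect over-covers: clamp low
        return float(lo), True
    if g_hi > 0:  # doses exceed what the achievable range can express: clamp high
        return float(hi), True
    fa_star = brentq(g, f_lo, f_hi, xtol=1e-12, rtol=1e-12)
    return float(fa_star), False


def loewe_excess_matrix(matrix: DoseMatrix) -> SynergyResult:
    """Observed-minus-predicted (Loewe) fraction affected over a dose matrix.

    Single-agent curves are fitted from the zero-dose row and column; the
    zero row/column have zero excess by construction.  Webb CI and category
    labels are attached for every nonzero dose pair.
    """
    fa = matrix.fraction_affected
    baseline = fa[0, 0]
    curve_a = fit_single_agent_curve(matrix.doses_a, fa[:, 0] - baseline)
    curve_b = fit_single_agent_curve(matrix.doses_b, fa[0, :] - baseline)

    na, nb = fa.shape
    predicted = np.zeros_like(fa)
    saturated = np.zeros(fa.shape, dtype=bool)
    for i in range(na):
        for j in range(nb):
            if i == 0 and j == 0:
                continue
            p, sat = loewe_prediction(
                matrix.doses_a[i], matrix.doses_b[j], curve_a, curve_b
            )
            predicted[i, j] = p + baseline
            saturated[i, j] = sat
    predicted[0, :] = fa[0, :]
    predicted[:, 0] = fa[:, 0]
    excess = fa - predicted

    ci = np.full_like(fa, np.nan)
    labels = np.full(fa.shape, "", dtype=object)
    for i in range(1, na):
        for j in range(1, nb):
            ci[i, j] = webb_ci(1.0 - fa[i, 0], 1.0 - fa[0, j], 1.0 - fa[i, j])
            labels[i, j] = classify_ci(ci[i, j])
    return SynergyResult(
        ci=ci,
        loewe_excess=excess,
        labels=labels,
        flags={
            "saturated": saturated,
            "curve_a_inactive": curve_a.inactive,
            "curve_b_inactive": curve_b.inactive,
            "curve_a_fallback": curve_a.fallback,
            "curve_b_fallback": curve_b.fallback,
        },
    )


def isobologram(matrix: DoseMatrix, effect_level: float = 0.5) -> dict:
    """Iso-effect contour of a dose matrix plus the Loewe additivity segment.

    For each row of the matrix (fixed dose of drug A) the dose of drug B
    reaching ``effect_level`` is linearly interpolated; the additivity line
    joins the two single-agent iso-effect doses.  Contour points below the
    line indicate synergy.  An unreached effect level yields an empty contour
    with a diagnostic; ``effect_level = 0`` degenerates to the origin.
    """
    fa = matrix.fraction_affected
    if effect_level == 0:
        return {
            "contour": [(0.0, 0.0)],
            "additivity_line": ((0.0, 0.0), (0.0, 0.0)),
            "degenerate": True,
            "message": "effect level 0 is reached at the origin",
        }
    if fa.max() < effect_level:
        return {
            "contour": [],
            "additivity_line": None,
            "degenerate": False,
            "message": f"effect level {effect_level} never reached (max fa {fa.max():.3f})",
        }

    def _cross(doses: np.ndarray, values: np.ndarray) -> float:
        for k in range(1, values.size):
            v0, v1 = values[k - 1], values[k]
            if (v0 < effect_level <= v1) or (v0 >= effect_level and k == 1 and v0 == effect_level):
                if v1 == v0:
                    return float(doses[k])
                t = (effect_level - v0) / (v1 - v0)
                return float(doses[k - 1] + t * (doses[k] - doses[k - 1]))
        return math.nan

    contour: list[tuple[float, float]] = []
    for i, da in enumerate(matrix.doses_a):
        db = _cross(matrix.doses_b, fa[i, :])
        if math.isfinite(db):
            contour.append((float(da), db))
    d_a50 = _cross(matrix.doses_a, fa[:, 0])
    d_b50 = _cross(matrix.doses_b, fa[0, :])
    line = None
    if math.isfinite(d_a50) and math.isfinite(d_b50):
        line = ((d_a50, 0.0), (0.0, d_b50))
    return {"contour": contour, "additivity_line": line, "degenerate": False, "message": ""}
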