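"""Quantitative-immunoblot calibration math, profile summary statistics,
clustering of protein profiles, correlation analysis and IC50 fitting.

Concentration calibration follows the quantitative western-blot scheme:
densitometric intensity is mapped to loaded protein mass through a per-protein
linear calibration curve built from recombinant standards; dividing the
per-cell mass by the molecular weight and a reference cell volume (HeLa,
3.1 pL) yields an absolute molar concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .momp_model import ProteinProfile
from .synergy import DoseResponseCurve, fit_single_agent_curve

__all__ = [
    "CalibrationCurve",
    "SurvivalRecord",
    "lysate_concentration",
    "concentration_from_mass",
    "pa_aa_ratio",
    "correlate",
    "cluster_profiles",
    "fit_ic50",
]

HELA_CELL_VOLUME_PL = 3.1

PROTEIN_FIELDS = ("bcl2", "mcl1", "bak", "bax", "bclxl")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear densitometric calibration: intensity = slope * mass_ng + intercept."""

    protein: str
    slope: float  # intensity per ng loaded
    intercept: float = 0.0
    molecular_weight_kda: float = 20.0
    reference_cell_volume_pl: float = HELA_CELL_VOLUME_PL

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"{self.protein}: calibration slope must be > 0")
        if not self.molecular_weight_kda > 0:
            raise ValueError(f"{self.protein}: molecular weight must be > 0")

    def mass_ng(self, intensity: float) -> float:
        return (intensity - self.intercept) / self.slope


@dataclass(frozen=True)
class SurvivalRecord:
    """Surviving (Annexin V-/PI-) fraction for one cell line and treatment."""

    cell_line: str
    treatment: str
    timepoint_h: float
    surviving_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.surviving_fraction <= 1:
            raise ValueError(
                f"{self.cell_line}/{self.treatment}: surviving fraction must be in [0, 1]"
            )


def concentration_from_mass(
    per_cell_mass_g: float,
    molecular_weight_kda: float,
    cell_volume_pl: float = HELA_CELL_VOLUME_PL,
) -> float:
    """Concentration in uM from per-cell protein mass (g), MW (kDa), volume (pL).

    conc = (mass / MW) / volume; 1 kDa = 1e3 g/mol, 1 pL = 1e-12 L.
    """
    if per_cell_mass_g < 0:
        raise ValueError("per-cell mass must be >= 0")
    mol = per_cell_mass_g / (molecular_weight_kda * 1e3)
    molar = mol / (cell_volume_pl * 1e-12)
    return molar * 1e6  # M -> uM


def lysate_concentration(
    intensity: float,
    curve: CalibrationCurve,
    cells_per_lane: float,
    *,
    calibrated_range_ng: tuple[float, float] | None = None,
) -> tuple[float, list[str]]:
    """Absolute cellular concentration (uM) from a lysate band intensity.

    The calibration curve converts intensity to loaded mass; dividing by the
    number of cells loaded per lane gives per-cell mass, converted to molar
    concentration via molecular weight and the reference cell volume.

    Returns ``(concentration_uM, flags)``; an intensity below the blank maps
    to 0 with a ``below_blank`` flag, one outside the calibrated range adds
    an ``extrapolated`` flag.
    """
    if not cells_per_lane > 0:
        raise ValueError("cells_per_lane must be > 0")
    flags: list[str] = []
    mass = curve.mass_ng(intensity)
    if mass < 0:
        flags.append("below_blank")
        return 0.0, flags
    if calibrated_range_ng is not None:
        lo, hi = calibrated_range_ng
        if not lo <= mass <= hi:
            flags.append("extrapolated")
            warnings.warn(
                f"{curve.protein}: loaded mass {mass:.3g} ng outside calibrated "
                f"range [{lo}, {hi}] ng",
                stacklevel=2,
            )
    per_cell_mass_g = mass * 1e-9 / cells_per_lane
    conc = concentration_from_mass(
        per_cell_mass_g, curve.molecular_weight_kda, curve.reference_cell_volume_pl
    )
    return conc, flags


def pa_aa_ratio(profile: ProteinProfile) -> float:
    """Pro-apoptotic to anti-apoptotic ratio: (BAK + BAX) / (BCL2 + MCL1 + BCL(X)L)."""
    denom = profile.anti_apoptotic_total
    if denom <= 0:
        raise ValueError(f"{profile.cell_line}: anti-apoptotic sum is zero; ratio undefined")
    return profile.pro_apoptotic_total / denom


def correlate(x: Sequence[float], y: Sequence[float], method: str = "spearman"):
    """Correlation coefficient, its square, and the two-sided p-value.

    ``method`` is ``spearman`` (rank-based, ties by average ranks) or
    ``pearson``.  R^2 is reported as the squared coefficient of the chosen
    method, for parity with figure-style reporting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    coef = float(res.statistic if hasattr(res, "statistic") else res[0])
    p = float(res.pvalue if hasattr(res, "pvalue") else res[1])
    return coef, coef**2, p


def cluster_profiles(
    profiles: Sequence[ProteinProfile],
    method: str = "complete",
    k: int = 3,
    *,
    standardize: bool = False,
    seed: int = 0,
    n_restarts: int = 20,
):
    """Group protein profiles by their five-protein concentration vectors.

    Euclidean distance on raw uM concentrations by default (the profiles are
    absolute quantities; ``standardize=True`` z-scores each protein first).
    ``method='complete'`` returns deterministic complete-linkage labels plus
    the merge tree; ``method='kmeans'`` runs seeded k-means with restarts and
    keeps the best inertia.

    Returns ``(labels, merge_tree)``; the tree is None for k-means.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError("k cannot exceed the number of profiles")
    X = np.array([[getattr(p, f) for f in PROTEIN_FIELDS] for p in profiles])
    if not np.all(np.isfinite(X)):
        raise ValueError("profile concentrations must be finite")
    if standardize:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    if method in ("complete", "complete-linkage"):
        Z = linkage(X, method="complete", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        return labels, Z
    if method in ("kmeans", "k-means"):
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        return labels, None
    raise ValueError(f"unknown clustering method {method!r}")


def fit_ic50(doses: Sequence[float], viability: Sequence[float]) -> dict:
    """IC50 (uM) from a variable-slope logistic fit of viability vs dose.

    Viability is converted to fraction affected and fitted with the shared
    four-parameter logistic.  Data with no transition in range yield an
    ``unbounded_fit`` diagnostic instead of a number.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 dose levels spanning the transition")
    fa = 1.0 - viability
    curve: DoseResponseCurve = fit_single_agent_curve(doses, fa)
    if curve.inactive or (curve.effect_range[1] - curve.effect_range[0]) < 0.2:
        return {
            "ic50_uM": math.nan,
            "curve": curve,
            "diagnostic": "unbounded_fit: no dose-response transition in range",
        }
    if curve.interpolant is not None:
        mid = 0.5 * (curve.effect_range[0] + curve.effect_range[1])
        return {"ic50_uM": curve.inverse(mid), "curve": curve, "diagnostic": "isotonic_fallback"}
    return {"ic50_uM": curve.ec50, "curve": curve, "diagnostic": ""}
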