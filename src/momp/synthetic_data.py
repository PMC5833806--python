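"""Seeded generators for synthetic study inputs.

Three generators mirror the statistical structure of the analysis inputs:

* :func:`sample_profiles` draws cell-line protein profiles log-uniformly
  within per-protein ranges spanning the observed panel (absolute BCL-2
  family concentrations cover more than three orders of magnitude, so
  log-uniform, not Gaussian, sampling).
* :func:`survival_from_eta` maps stress-dose scores to surviving fractions
  through a monotone logistic link in log eta plus truncated Gaussian noise
  (cells needing more stress to undergo MOMP survive treatment better).
* :func:`synth_dose_matrix` builds 6x6 fraction-affected dose matrices with
  known ground truth (Bliss-independent, Loewe-additive/sham, synergistic or
  antagonistic) from two Hill curves.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .momp_model import ProteinProfile
from .synergy import DoseMatrix, _hill

__all__ = ["SyntheticConfig", "sample_profiles", "survival_from_eta", "synth_dose_matrix"]

# per-protein (min, max) uM spanning the observed TNBC panel
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "bcl2": (0.061, 4.581),
    "mcl1": (0.001, 0.663),
    "bak": (0.842, 3.173),
    "bax": (0.484, 2.284),
    "bclxl": (0.317, 1.415),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for all synthetic generators.

    The survival link is ``s(eta) = s_min + (s_max - s_min) *
    logistic(slope * (ln eta - ln eta_mid))``; the slope default was
    calibrated once so that, at the default noise level, rank correlation
    between eta and survival is high but not saturated.
    """

    seed: int
    n_cell_lines: int = 8
    concentration_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    noise_sd: float = 0.05
    survival_floor: float = 0.05
    survival_ceiling: float = 0.95
    survival_slope: float = 1.0
    eta_mid: float | None = None  # None -> geometric mean of the supplied etas

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cell_lines < 0:
            raise ValueError("n_cell_lines must be >= 0")
        for prot, (lo, hi) in self.concentration_ranges.items():
            if not 0 < lo < hi:
                raise ValueError(f"{prot}: range must satisfy 0 < min < max")


def sample_profiles(config: SyntheticConfig) -> list[ProteinProfile]:
    """Log-uniform profile draws within the configured per-protein ranges."""
    rng = np.random.default_rng(config.seed)
    profiles = []
    for i in range(config.n_cell_lines):
        conc = {
            prot: float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
            for prot, (lo, hi) in config.concentration_ranges.items()
        }
        profiles.append(ProteinProfile(cell_line=f"SYN-{i + 1:02d}", **conc))
    return profiles


def survival_from_eta(etas: Sequence[float], config: SyntheticConfig) -> np.ndarray:
    """Surviving fractions from stress-dose scores via the monotone link + noise.

    Noise is Gaussian (sd ``config.noise_sd``) truncated by clipping to
    [0, 1].  With ``noise_sd = 0`` the map is strictly increasing in eta.
    """
    etas = np.asarray(etas, dtype=float)
    if not np.all(np.isfinite(etas)) or np.any(etas <= 0):
        raise ValueError("etas must be finite and > 0")
    rng = np.random.default_rng(config.seed)
    mid = config.eta_mid if config.eta_mid is not None else float(
        np.exp(np.mean(np.log(etas)))
    )
    z = config.survival_slope * (np.log(etas) - math.log(mid))
    link = config.survival_floor + (config.survival_ceiling - config.survival_floor) / (
        1.0 + np.exp(-z)
    )
    noisy = link + rng.normal(0.0, config.noise_sd, size=etas.shape) if config.noise_sd else link
    return np.clip(noisy, 0.0, 1.0)


def synth_dose_matrix(
    truth: str,
    curve_params: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    boost: float = 0.3,
    n_doses: int = 6,
) -> DoseMatrix:
    """A 6x6 fraction-affected dose matrix with known interaction ground truth.

    ``truth`` selects the combination rule applied to two Hill marginals:

    * ``bliss``          fu_combo = fu_a * fu_b (Bliss independence; Webb CI = 1)
    * ``loewe_additive`` sham combination of one drug against itself:
      fa(d_a + potency_ratio * d_b) (exact dose additivity; Loewe excess = 0)
    * ``synergistic``    Bliss with interior unaffected fraction shrunk by
      (1 - boost) (Webb CI = 1 - boost < 1)
    * ``antagonistic``   Bliss with fu inflated by (1 + boost), capped at 1

    ``curve_params`` keys: ``ec50_a``, ``ec50_b``, ``slope_a``, ``slope_b``,
    ``ceiling`` (shared).  Gaussian noise (sd ``noise_sd``) is added and the
    grid clipped to [0, 1]; zero-dose margins stay noise-free so marginal
    consistency holds exactly at zero noise.
    """
    params = {
        "ec50_a": 1.0,
        "ec50_b": 30.0,
        "slope_a": 1.5,
        "slope_b": 2.0,
        "ceiling": 1.0,
        **(curve_params or {}),
    }
    rng = np.random.default_rng(seed)
    doses_a = np.concatenate([[0.0], np.geomspace(params["ec50_a"] / 10, params["ec50_a"] * 10, n_doses - 1)])
    doses_b = np.concatenate([[0.0], np.geomspace(params["ec50_b"] / 10, params["ec50_b"] * 10, n_doses - 1)])

    fa_a = _hill(doses_a, 0.0, params["ceiling"], params["ec50_a"], params["slope_a"])
    fa_b = _hill(doses_b, 0.0, params["ceiling"], params["ec50_b"], params["slope_b"])
    A, B = np.meshgrid(fa_a, fa_b, indexing="ij")

    if truth == "bliss":
        fa = 1.0 - (1.0 - A) * (1.0 - B)
    elif truth == "loewe_additive":
        # sham: drug B is drug A at a fixed potency ratio; exact additivity
        ratio = params["ec50_a"] / params["ec50_b"]
        DA, DB = np.meshgrid(doses_a, doses_b, indexing="ij")
        fa = _hill(DA + ratio * DB, 0.0, params["ceiling"], params["ec50_a"], params["slope_a"])
    elif truth in ("synergistic", "antagonistic"):
        fu = (1.0 - A) * (1.0 - B)
        factor = (1.0 - boost) if truth == "synergistic" else (1.0 + boost)
        fu_adj = np.minimum(fu * factor, 1.0)
        fa = 1.0 - fu_adj
        fa[0, :] = 1.0 - (1.0 - B[0, :])  # margins stay single-agent
        fa[:, 0] = 1.0 - (1.0 - A[:, 0])
    else:
        raise ValueError(f"unknown truth model {truth!r}")

    if noise_sd:
        noise = rng.normal(0.0, noise_sd, size=fa.shape)
        noise[0, 0] = 0.0
        fa = np.clip(fa + noise, 0.0, 1.0)

    return DoseMatrix(
        drug_a_name=f"drugA({truth})",
        drug_b_name="drugB",
        doses_a=doses_a,
        doses_b=doses_b,
        fraction_affected=fa,
    )
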