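"""Stress-dose scoring of mitochondrial apoptosis sensitivity.

The model ingests absolute concentrations (uM) of the five measured BCL-2
family proteins (BCL2, MCL1, BAK, BAX, BCL(X)L), instantiates the interaction
network from a declarative model definition, drives it with a 12-h
step-function production of the BH3-only initiators (BIM, PUMA, NOXA at equal
rates), and detects MOMP as the designated pore read-out crossing a threshold.

The *stress dose* eta of a profile is the minimal total BH3-only protein
production over the 12-h window that triggers MOMP, located by bisection.
Higher eta means the cell needs more stress to commit to apoptosis, i.e. it is
more resistant.  Selective antagonists of BCL2/BCL(X)L/MCL1 are added as
competitive binders of their target with kinetics derived from the published
dissociation constant, at an effective concentration of
``bioavailability_factor x nominal dose`` (default 0.5, accounting for drug
degradation and active extrusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .modeldef import ModelDefinition, load_model_definition
from .reaction_engine import (
    NetworkValidationError,
    ProductionSchedule,
    ProductionStep,
    Reaction,
    ReactionNetwork,
    Species,
    Trajectory,
    simulate,
)

__all__ = [
    "ProteinProfile",
    "Antagonist",
    "MompConfig",
    "StressDose",
    "binding_rates_from_kd",
    "build_momp_network",
    "pore_timecourse",
    "compute_eta",
    "eta_dose_curve",
    "pore_synergy_grid",
]

ANTAGONIST_TARGETS = ("BCL2", "BCLXL", "MCL1")


@dataclass(frozen=True)
class ProteinProfile:
    """Absolute per-cell-line concentrations (uM) of the measured BCL-2 proteins."""

    cell_line: str
    bcl2: float
    mcl1: float
    bak: float
    bax: float
    bclxl: float

    def __post_init__(self) -> None:
        for name in ("bcl2", "mcl1", "bak", "bax", "bclxl"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.cell_line}: {name} must be finite and >= 0, got {v}"
                )

    @property
    def anti_apoptotic_total(self) -> float:
        return self.bcl2 + self.mcl1 + self.bclxl

    @property
    def pro_apoptotic_total(self) -> float:
        return self.bak + self.bax

    def scaled(self, anti: float = 1.0, pro: float = 1.0) -> "ProteinProfile":
        """Profile with anti-apoptotic and/or effector concentrations scaled."""
        return replace(
            self,
            bcl2=self.bcl2 * anti,
            mcl1=self.mcl1 * anti,
            bclxl=self.bclxl * anti,
            bak=self.bak * pro,
            bax=self.bax * pro,
        )


@dataclass(frozen=True)
class Antagonist:
    """A selective BCL-2 family inhibitor described by target and affinity."""

    name: str
    target: str  # BCL2 | BCLXL | MCL1
    kd: float  # dissociation constant, nM
    bioavailability_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.target not in ANTAGONIST_TARGETS:
            raise ValueError(
                f"antagonist {self.name}: target must be one of {ANTAGONIST_TARGETS}"
            )
        if not self.kd > 0:
            raise ValueError(f"antagonist {self.name}: kd must be > 0 nM")
        if not 0 < self.bioavailability_factor <= 1:
            raise ValueError(
                f"antagonist {self.name}: bioavailability factor must be in (0, 1]"
            )


@dataclass(frozen=True)
class MompConfig:
    """Tunables of the stress-dose computation.

    ``pore_threshold=None`` defers to the model-definition default.
    ``eta_upper_bound=None`` uses 10x the profile's total anti-apoptotic
    concentration (mass-action buffering cannot exceed that by a large
    factor), with a 1 uM floor for degenerate profiles.
    """

    production_duration: float = 12.0  # h
    post_production_horizon: float = 0.0  # h
    pore_threshold: float | None = None  # uM of pore read-out
    bisection_rel_tol: float = 1e-3
    max_bisection_iterations: int = 40
    eta_upper_bound: float | None = None  # uM total BH3-only production
    solver_rtol: float = 1e-6
    solver_atol: float = 1e-6
    n_points: int = 241

    def __post_init__(self) -> None:
        if self.production_duration <= 0:
            raise ValueError("production_duration must be > 0")
        if self.post_production_horizon < 0:
            raise ValueError("post_production_horizon must be >= 0")
        if self.bisection_rel_tol <= 0:
            raise ValueError("bisection_rel_tol must be > 0")


@dataclass(frozen=True)
class StressDose:
    """Result of the eta bisection for one profile.

    ``status`` is ``converged`` (bracket refined to tolerance),
    ``momp_at_zero`` (MOMP without any stress input; eta = 0, degenerate),
    ``degenerate_threshold`` (pore threshold <= 0; eta = 0), or
    ``resistant_beyond_bound`` (no MOMP even at the upper bound; eta is None,
    a marker rather than a number).  ``bracket`` is the final (lo, hi)
    enclosing the true threshold dose when converged.
    """

    cell_line: str
    eta: float | None  # uM total BH3-only production over the window
    production_rate: float | None  # uM/h summed across stress species
    momp_reached: bool
    bisection_iterations: int
    status: str
    bracket: tuple[float, float] | None = None

    @property
    def resistant(self) -> bool:
        return self.status == "resistant_beyond_bound"


def binding_rates_from_kd(kd_nm: float, reference_forward_rate: float) -> tuple[float, float]:
    """(k_forward, k_reverse) in uM/h units from a K_D given in nM.

    Detailed balance holds exactly: k_reverse / k_forward == K_D (in uM).
    """
    if not kd_nm > 0:
        raise ValueError(f"kd must be > 0 nM, got {kd_nm}")
    if not reference_forward_rate > 0:
        raise ValueError("reference_forward_rate must be > 0")
    kd_um = kd_nm * 1e-3
    return reference_forward_rate, kd_um * reference_forward_rate


def build_momp_network(
    profile: ProteinProfile,
    model_def: ModelDefinition | None = None,
    antagonist_doses: Mapping[Antagonist, float] | None = None,
) -> ReactionNetwork:
    """Instantiate the interaction network for one protein profile.

    Initial concentrations of the five measured proteins come from the
    profile; every other species keeps its model-definition default.  Each
    antagonist with nominal dose > 0 adds one drug species at
    ``bioavailability_factor x dose`` plus reversible binding against its
    target species only; the drug-target complex joins the target's
    conservation group.
    """
    md = model_def if model_def is not None else _default_model()
    overrides = {md.profile_species[f]: getattr(profile, f) for f in md.profile_species}
    network = md.network.with_initial(overrides)

    doses = dict(antagonist_doses or {})
    active = [(a, d) for a, d in doses.items() if d != 0]
    for a, d in active:
        if d < 0:
            raise NetworkValidationError(f"antagonist {a.name}: negative dose {d}")
        if a.target not in md.antagonist_targets:
            raise NetworkValidationError(
                f"antagonist {a.name} targets {a.target!r}, absent from the model definition"
            )
    if not active:
        return network

    species = list(network.species)
    reactions = list(network.reactions)
    groups = {g: dict(m) for g, m in network.conservation_groups.items()}
    for a, dose in active:
        target_sid = md.antagonist_targets[a.target]
        drug_sid = a.name.upper()
        complex_sid = f"{drug_sid}_{target_sid}"
        if any(s.id == drug_sid for s in species):
            raise NetworkValidationError(f"duplicate antagonist species {drug_sid!r}")
        kf, kr = binding_rates_from_kd(a.kd, md.reference_forward_rate)
        effective = a.bioavailability_factor * dose
        species.append(Species(drug_sid, f"{a.name} (free drug)", effective))
        species.append(Species(complex_sid, f"{a.name}:{target_sid} complex", 0.0))
        reactions.append(
            Reaction(
                reactants=((drug_sid, 1), (target_sid, 1)),
                products=((complex_sid, 1),),
                rate_constant=kf,
                kind="association",
                name=f"{drug_sid}+{target_sid}->{complex_sid}",
            )
        )
        reactions.append(
            Reaction(
                reactants=((complex_sid, 1),),
                products=((drug_sid, 1), (target_sid, 1)),
                rate_constant=kr,
                kind="dissociation",
                name=f"{complex_sid}->{drug_sid}+{target_sid}",
            )
        )
        for gname, members in groups.items():
            if members.get(target_sid) is not None and gname == f"{target_sid}_total":
                members[complex_sid] = members[target_sid]
        groups[f"{drug_sid}_total"] = {drug_sid: 1.0, complex_sid: 1.0}
    return ReactionNetwork(species, reactions, groups, name=network.name)


def pore_timecourse(trajectory: Trajectory, model_def: ModelDefinition | None = None) -> np.ndarray:
    """Pore read-out (weighted sum of the designated pore species) per time point."""
    md = model_def if model_def is not None else _default_model()
    if not md.pore_species:
        raise NetworkValidationError("model definition lacks a pore designation")
    idx = [trajectory.species_ids.index(sid) for sid in md.pore_species]
    w = np.array(list(md.pore_species.values()))
    return w @ trajectory.concentrations[idx]


def _default_model() -> ModelDefinition:
    global _DEFAULT_MODEL
    try:
        return _DEFAULT_MODEL
    except NameError:
        _DEFAULT_MODEL = load_model_definition()
        return _DEFAULT_MODEL


def _momp_indicator(
    network: ReactionNetwork,
    md: ModelDefinition,
    cfg: MompConfig,
    threshold: float,
    total_dose: float,
) -> bool:
    """Does total BH3-only production ``total_dose`` trigger MOMP within the horizon?"""
    horizon = cfg.production_duration + cfg.post_production_horizon
    if total_dose > 0:
        per_species = total_dose / cfg.production_duration / len(md.stress_species)
        schedule = ProductionSchedule(
            ProductionStep(sid, per_species, 0.0, cfg.production_duration)
            for sid in md.stress_species
        )
    else:
        schedule = ProductionSchedule()
    traj = simulate(
        network,
        horizon,
        schedule,
        n_points=cfg.n_points,
        rtol=cfg.solver_rtol,
        atol=cfg.solver_atol,
    )
    return bool(pore_timecourse(traj, md).max() >= threshold)


def compute_eta(
    profile: ProteinProfile,
    config: MompConfig | None = None,
    antagonist_doses: Mapping[Antagonist, float] | None = None,
    model_def: ModelDefinition | None = None,
) -> StressDose:
    """Minimal MOMP-triggering stress dose eta for one profile, by bisection.

    eta is the total BH3-only protein production over the production window
    (production_rate x production_duration, the rate split equally across the
    stress species).  The MOMP indicator is assumed monotone in dose; this is
    asserted at the bracket endpoints before refinement.
    """
    md = model_def if model_def is not None else _default_model()
    cfg = config or MompConfig()
    threshold = cfg.pore_threshold if cfg.pore_threshold is not None else md.pore_threshold
    if threshold <= 0:
        return StressDose(profile.cell_line, 0.0, 0.0, True, 0, "degenerate_threshold")

    network = build_momp_network(profile, md, antagonist_doses)
    if _momp_indicator(network, md, cfg, threshold, 0.0):
        return StressDose(profile.cell_line, 0.0, 0.0, True, 0, "momp_at_zero")

    upper = cfg.eta_upper_bound
    if upper is None:
        upper = max(10.0 * profile.anti_apoptotic_total, 1.0)
    if not _momp_indicator(network, md, cfg, threshold, upper):
        return StressDose(profile.cell_line, None, None, False, 0, "resistant_beyond_bound")

    lo, hi = 0.0, upper
    iterations = 0
    while hi - lo > cfg.bisection_rel_tol * hi and iterations < cfg.max_bisection_iterations:
        mid = 0.5 * (lo + hi)
        if _momp_indicator(network, md, cfg, threshold, mid):
            hi = mid
        else:
            lo = mid
        iterations += 1
    return StressDose(
        profile.cell_line,
        hi,
        hi / cfg.production_duration,
        True,
        iterations,
        "converged",
        bracket=(lo, hi),
    )


def eta_dose_curve(
    profile: ProteinProfile,
    antagonist: Antagonist,
    doses: Sequence[float],
    config: MompConfig | None = None,
    model_def: ModelDefinition | None = None,
) -> list[tuple[float, StressDose]]:
    """eta at each nominal antagonist dose (uM); dose 0 is the baseline score."""
    if any(d < 0 for d in doses):
        raise NetworkValidationError("antagonist doses must be >= 0")
    return [
        (float(d), compute_eta(profile, config, {antagonist: float(d)}, model_def))
        for d in doses
    ]


def pore_synergy_grid(
    profile: ProteinProfile,
    antagonist: Antagonist,
    antagonist_doses: Sequence[float],
    stress_doses: Sequence[float],
    config: MompConfig | None = None,
    model_def: ModelDefinition | None = None,
) -> dict:
    """Maximum pore read-out over an antagonist x stress dose grid, plus Webb CI.

    Entry ``pore[i, j]`` is the peak pore amount under antagonist dose i and
    total BH3-only dose j.  Effect fractions for the combination index are the
    pore amounts normalised by the grid maximum; CI is computed per interior
    cell via the synergy module (NaN where a marginal is inactive).
    """
    from . import synergy

    md = model_def if model_def is not None else _default_model()
    cfg = config or MompConfig()
    a_doses = np.asarray(antagonist_doses, dtype=float)
    s_doses = np.asarray(stress_doses, dtype=float)
    if a_doses.size == 0 or s_doses.size == 0:
        raise NetworkValidationError("dose grids must be non-empty")
    if a_doses[0] != 0 or s_doses[0] != 0:
        raise NetworkValidationError("dose grids must include 0 as the first entry")

    horizon = cfg.production_duration + cfg.post_production_horizon
    pore = np.zeros((a_doses.size, s_doses.size))
    for i, ad in enumerate(a_doses):
        network = build_momp_network(profile, md, {antagonist: float(ad)})
        for j, sd in enumerate(s_doses):
            if sd > 0:
                per = sd / cfg.production_duration / len(md.stress_species)
                schedule = ProductionSchedule(
                    ProductionStep(sid, per, 0.0, cfg.production_duration)
                    for sid in md.stress_species
                )
            else:
                schedule = ProductionSchedule()
            traj = simulate(
                network,
                horizon,
                schedule,
                n_points=cfg.n_points,
                rtol=cfg.solver_rtol,
                atol=cfg.solver_atol,
            )
            pore[i, j] = pore_timecourse(traj, md).max()

    ref = pore.max()
    fa = pore / ref if ref > 0 else np.zeros_like(pore)
    ci = np.full_like(fa, np.nan)
    for i in range(1, a_doses.size):
        for j in range(1, s_doses.size):
            ci[i, j] = synergy.webb_ci(1.0 - fa[i, 0], 1.0 - fa[0, j], 1.0 - fa[i, j])
    return {
        "antagonist_doses": a_doses,
        "stress_doses": s_doses,
        "pore": pore,
        "fraction_affected": fa,
        "ci": ci,
    }
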