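"""Deterministic mass-action reaction-network ODE engine.

Networks are plain data: :class:`Species`, :class:`Reaction` and
:class:`ReactionNetwork` describe a mass-action system (reaction order <= 2)
in micromolar/hour units.  :func:`simulate` compiles the network into a
vectorised right-hand side with an analytic Jacobian and integrates it with a
stiff-capable method; :func:`check_conservation` audits conservation groups
against a simulated trajectory.

Time-dependent inputs (e.g. a step-function production of stress proteins)
are expressed as a :class:`ProductionSchedule` rather than as network
reactions, so the structural reaction count of a model is independent of the
applied stress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ProductionStep",
    "ProductionSchedule",
    "Trajectory",
    "NetworkValidationError",
    "SimulationError",
    "simulate",
    "check_conservation",
]

REACTION_KINDS = ("association", "dissociation", "production", "degradation", "conversion")


class NetworkValidationError(ValueError):
    """A network, reaction or input referenced undeclared species or broke an invariant."""


class SimulationError(RuntimeError):
    """The ODE solver failed to converge; the message names the failing interval."""


@dataclass(frozen=True)
class Species:
    id: str
    display_name: str = ""
    initial_concentration: float = 0.0  # uM

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("species id must be non-empty")
        if not math.isfinite(self.initial_concentration) or self.initial_concentration < 0:
            raise NetworkValidationError(
                f"species {self.id!r}: initial concentration must be finite and >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants``/``products`` are tuples of ``(species_id, stoichiometry)``.
    The mass-action order (sum of reactant stoichiometries) must be <= 2.
    Production reactions have no reactants, degradation reactions no products.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float  # 1/h for order<=1, 1/(uM*h) for order 2; uM/h for order 0
    kind: str = "conversion"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple((s, int(n)) for s, n in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(n)) for s, n in self.products))
        if self.kind not in REACTION_KINDS:
            raise NetworkValidationError(f"unknown reaction kind {self.kind!r}")
        if not math.isfinite(self.rate_constant) or self.rate_constant < 0:
            raise NetworkValidationError(
                f"reaction {self.name or self.reactants}: rate constant must be >= 0"
            )
        if any(n <= 0 for _, n in self.reactants) or any(n <= 0 for _, n in self.products):
            raise NetworkValidationError("stoichiometries must be positive integers")
        if self.order > 2:
            raise NetworkValidationError(
                f"reaction {self.name or self.reactants}: mass-action order "
                f"{self.order} > 2 is not supported"
            )
        if self.kind == "production" and self.reactants:
            raise NetworkValidationError("production reactions must have empty reactants")
        if self.kind == "degradation" and self.products:
            raise NetworkValidationError("degradation reactions must have empty products")

    @property
    def order(self) -> int:
        return sum(n for _, n in self.reactants)


@dataclass(frozen=True)
class ProductionStep:
    """Constant-rate production of one species over a time window [start, stop)."""

    species_id: str
    rate: float  # uM/h
    start: float = 0.0  # h
    stop: float = math.inf  # h

    def __post_init__(self) -> None:
        if self.rate < 0 or not math.isfinite(self.rate):
            raise NetworkValidationError("production rate must be finite and >= 0")
        if self.stop <= self.start:
            raise NetworkValidationError("production window must have stop > start")


class ProductionSchedule:
    """A set of step-function production inputs applied during simulation."""

    def __init__(self, steps: Iterable[ProductionStep] = ()):  # noqa: D401
        self.steps = tuple(steps)

    def breakpoints(self, horizon: float) -> list[float]:
        pts = {0.0, horizon}
        for s in self.steps:
            for t in (s.start, s.stop):
                if 0.0 < t < horizon:
                    pts.add(t)
        return sorted(pts)

    def rates_at(self, t: float, index: Mapping[str, int], n: int) -> np.ndarray:
        r = np.zeros(n)
        for s in self.steps:
            if s.start <= t < s.stop:
                r[index[s.species_id]] += s.rate
        return r

    def validate(self, index: Mapping[str, int]) -> None:
        for s in self.steps:
            if s.species_id not in index:
                raise NetworkValidationError(
                    f"production schedule references unknown species {s.species_id!r}"
                )


class ReactionNetwork:
    """Validated species + reactions + (optionally weighted) conservation groups.

    ``conservation_groups`` maps a group name to ``{species_id: weight}``; the
    weighted sum of member concentrations is expected to be constant whenever
    no production/degradation reaction touches the group.  Groups are checked
    against the stoichiometry matrix at construction: a group whose weight
    vector is not in the left null space of the conservative reactions raises;
    a group coupled to production/degradation is recorded in
    ``open_groups`` (flagged, not an error).
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        conservation_groups: Mapping[str, Mapping[str, float]] | None = None,
        name: str = "",
    ):
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise NetworkValidationError(f"duplicate species ids: {sorted(dupes)}")
        self.index: dict[str, int] = {s.id: i for i, s in enumerate(self.species)}

        n, m = len(self.species), len(self.reactions)
        S = np.zeros((n, m))
        for j, rxn in enumerate(self.reactions):
            for sid, stoich in rxn.reactants:
                if sid not in self.index:
                    raise NetworkValidationError(
                        f"reaction {rxn.name or j} references unknown species {sid!r}"
                    )
                S[self.index[sid], j] -= stoich
            for sid, stoich in rxn.products:
                if sid not in self.index:
                    raise NetworkValidationError(
                        f"reaction {rxn.name or j} references unknown species {sid!r}"
                    )
                S[self.index[sid], j] += stoich
        self.stoichiometry = S

        self.conservation_groups: dict[str, dict[str, float]] = {
            g: dict(members) for g, members in (conservation_groups or {}).items()
        }
        self.open_groups: set[str] = set()
        self._verify_groups()

    # -- construction helpers -------------------------------------------------

    def _verify_groups(self) -> None:
        open_kinds = {"production", "degradation"}
        for gname, members in self.conservation_groups.items():
            w = np.zeros(len(self.species))
            for sid, weight in members.items():
                if sid not in self.index:
                    raise NetworkValidationError(
                        f"conservation group {gname!r} references unknown species {sid!r}"
                    )
                w[self.index[sid]] = weight
            drift = w @ self.stoichiometry  # per-reaction net change of the group total
            for j, rxn in enumerate(self.reactions):
                if abs(drift[j]) < 1e-12:
                    continue
                if rxn.kind in open_kinds:
                    self.open_groups.add(gname)
                else:
                    raise NetworkValidationError(
                        f"conservation group {gname!r} is not conserved by reaction "
                        f"{rxn.name or j} (kind {rxn.kind}, net change {drift[j]:+g})"
                    )

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def with_initial(self, overrides: Mapping[str, float]) -> "ReactionNetwork":
        """A copy of the network with some initial concentrations replaced."""
        for sid in overrides:
            if sid not in self.index:
                raise NetworkValidationError(f"unknown species {sid!r} in initial override")
        species = [
            Species(s.id, s.display_name, float(overrides.get(s.id, s.initial_concentration)))
            for s in self.species
        ]
        return ReactionNetwork(species, self.reactions, self.conservation_groups, self.name)

    # -- compiled kinetics ----------------------------------------------------

    def _compiled(self):
        if not hasattr(self, "_compile_cache"):
            m = len(self.reactions)
            k = np.array([r.rate_constant for r in self.reactions])
            # reactant index slots: -1 means "no factor" (treated as 1.0)
            i1 = np.full(m, -1, dtype=np.intp)
            i2 = np.full(m, -1, dtype=np.intp)
            for j, rxn in enumerate(self.reactions):
                flat: list[int] = []
                for sid, stoich in rxn.reactants:
                    flat.extend([self.index[sid]] * stoich)
                if len(flat) >= 1:
                    i1[j] = flat[0]
                if len(flat) == 2:
                    i2[j] = flat[1]
            self._compile_cache = (k, i1, i2)
        return self._compile_cache

    def rates(self, c: np.ndarray) -> np.ndarray:
        k, i1, i2 = self._compiled()
        cx = np.concatenate([c, [1.0]])  # slot -1 -> 1.0
        return k * cx[i1] * cx[i2]

    def jacobian(self, c: np.ndarray) -> np.ndarray:
        k, i1, i2 = self._compiled()
        m, n = len(self.reactions), len(self.species)
        cx = np.concatenate([c, [1.0]])
        D = np.zeros((m, n + 1))
        rows = np.arange(m)
        np.add.at(D, (rows, i1), k * cx[i2])
        np.add.at(D, (rows, i2), k * cx[i1])
        return self.stoichiometry @ D[:, :n]


@dataclass
class Trajectory:
    """Simulated concentration time courses on a fixed output grid."""

    times: np.ndarray  # h, strictly increasing
    concentrations: np.ndarray  # species x time, uM
    species_ids: list[str]
    solver_metadata: dict = field(default_factory=dict)

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.concentrations[self.species_ids.index(species_id)]

    def to_frame(self):
        """Tidy (time, species, concentration) DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, len(self.species_ids)),
                "species": np.tile(self.species_ids, len(self.times)),
                "concentration_uM": self.concentrations.T.ravel(),
            }
        )


def simulate(
    network: ReactionNetwork,
    horizon: float,
    inputs: ProductionSchedule | None = None,
    *,
    n_points: int = 241,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the mass-action ODEs of ``network`` from 0 to ``horizon`` hours.

    ``inputs`` adds step-function production terms; the integration is split at
    every step boundary so the solver never straddles a discontinuity.
    Concentrations more negative than the solver tolerance raise; small
    negative excursions within tolerance are clipped to zero.
    """
    if horizon <= 0:
        raise NetworkValidationError(f"horizon must be > 0, got {horizon}")
    inputs = inputs or ProductionSchedule()
    inputs.validate(network.index)

    n = len(network.species)
    t_eval = np.linspace(0.0, horizon, n_points)
    segments = inputs.breakpoints(horizon)

    y = network.initial_state.copy()
    times = t_eval
    conc = np.empty((n, len(t_eval)))
    conc[:, 0] = y
    nfev = njac = 0
    for t0, t1 in zip(segments[:-1], segments[1:]):
        prod = inputs.rates_at(0.5 * (t0 + t1), network.index, n)

        # no clamping: mass-action kinetics self-correct small negative
        # excursions (negative c yields a restoring derivative), and keeping
        # rhs/jacobian consistent is what lets the implicit solver converge
        def rhs(t: float, c: np.ndarray) -> np.ndarray:
            return network.stoichiometry @ network.rates(c) + prod

        def jac(t: float, c: np.ndarray) -> np.ndarray:
            return network.jacobian(c)

        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, jac=jac, dense_output=True, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(
                f"ODE solver ({method}) failed on interval [{t0:g}, {t1:g}] h: {sol.message}"
            )
        nfev += sol.nfev
        njac += getattr(sol, "njev", 0) or 0
        mask = (t_eval > t0) & (t_eval <= t1)
        if mask.any():
            conc[:, mask] = sol.sol(t_eval[mask])
        y = sol.y[:, -1].copy()

    min_c = float(conc.min()) if conc.size else 0.0
    tol_floor = -100 * atol
    if min_c < tol_floor:
        raise SimulationError(
            f"negative concentration {min_c:.3e} uM exceeds solver tolerance {tol_floor:.1e}"
        )
    conc = np.clip(conc, 0.0, None)

    return Trajectory(
        times=times,
        concentrations=conc,
        species_ids=[s.id for s in network.species],
        solver_metadata={
            "method": method,
            "rtol": rtol,
            "atol": atol,
            "nfev": nfev,
            "njev": njac,
            "min_concentration": min_c,
        },
    )


def check_conservation(trajectory: Trajectory, network: ReactionNetwork) -> dict[str, dict]:
    """Maximum relative drift of each conservation group along a trajectory.

    Returns ``{group: {"max_relative_drift": float, "conserved": bool}}``.
    Groups touched by production/degradation reactions are reported with
    ``conserved=False`` (flagged, never an error).
    """
    if not network.conservation_groups:
        raise NetworkValidationError("network declares no conservation groups")
    out: dict[str, dict] = {}
    for gname, members in network.conservation_groups.items():
        idx = [trajectory.species_ids.index(sid) for sid in members]
        w = np.array([members[sid] for sid in members])
        totals = w @ trajectory.concentrations[idx]
        ref = totals[0]
        drift = float(np.max(np.abs(totals - ref)) / ref) if ref > 0 else float(np.max(np.abs(totals - ref)))
        out[gname] = {
            "max_relative_drift": drift,
            "conserved": gname not in network.open_groups,
        }
    return out
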