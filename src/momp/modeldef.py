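"""Loading of declarative model-definition files.

A model definition is a YAML (or JSON) document listing the species,
mass-action reactions, conservation groups and scoring metadata of a BCL-2
interaction network.  Keeping the network as data means the reaction list and
rate constants can be revised without code changes.

Schema (top-level keys)::

    name, version, description     identification
    units                          {concentration: uM, time: h} (fixed)
    species                        [{id, name, initial_uM}]
    reactions                      [{name, kind, reactants: {id: stoich},
                                     products: {id: stoich}, k}]
    conservation_groups            {group: {id: weight}}
    profile_species                profile field -> species id (measured proteins)
    stress_species                 species produced by the genotoxic-stress input
    pore                           {species: {id: weight}, threshold_uM}
    reference_forward_rate         generic association rate, uM^-1 h^-1
    antagonist_targets             antagonist target name -> species id
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .reaction_engine import NetworkValidationError, Reaction, ReactionNetwork, Species

__all__ = ["ModelDefinition", "load_model_definition", "default_model_path"]

_REQUIRED_KEYS = ("species", "reactions", "profile_species", "stress_species", "pore")


@dataclass
class ModelDefinition:
    """A parsed model definition plus the network template built from it."""

    name: str
    version: str
    network: ReactionNetwork
    profile_species: dict[str, str]
    stress_species: list[str]
    pore_species: dict[str, float]
    pore_threshold: float
    reference_forward_rate: float
    antagonist_targets: dict[str, str]
    source: str = ""
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        idx = self.network.index
        for fieldname, sid in self.profile_species.items():
            if sid not in idx:
                raise NetworkValidationError(
                    f"profile field {fieldname!r} maps to unknown species {sid!r}"
                )
        for sid in self.stress_species:
            if sid not in idx:
                raise NetworkValidationError(f"stress species {sid!r} not in network")
        if not self.pore_species:
            raise NetworkValidationError(
                "model definition lacks a pore designation (pore.species)"
            )
        for sid in self.pore_species:
            if sid not in idx:
                raise NetworkValidationError(f"pore species {sid!r} not in network")
        for name, sid in self.antagonist_targets.items():
            if sid not in idx:
                raise NetworkValidationError(
                    f"antagonist target {name!r} maps to unknown species {sid!r}"
                )


def default_model_path() -> Path:
    """Path of the packaged BCL-2 network definition."""
    return Path(str(resources.files("momp.data") / "drmomp_network.yaml"))


def load_model_definition(path: str | Path | None = None) -> ModelDefinition:
    """Parse a model-definition YAML/JSON file into a :class:`ModelDefinition`.

    With ``path=None`` the packaged default network is loaded.
    """
    path = Path(path) if path is not None else default_model_path()
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise NetworkValidationError(f"model definition {path}: missing key {key!r}")

    species = [
        Species(s["id"], s.get("name", s["id"]), float(s.get("initial_uM", 0.0)))
        for s in doc["species"]
    ]
    reactions = [
        Reaction(
            reactants=tuple((sid, int(n)) for sid, n in (r.get("reactants") or {}).items()),
            products=tuple((sid, int(n)) for sid, n in (r.get("products") or {}).items()),
            rate_constant=float(r["k"]),
            kind=r.get("kind", "conversion"),
            name=r.get("name", ""),
        )
        for r in doc["reactions"]
    ]
    network = ReactionNetwork(
        species,
        reactions,
        conservation_groups=doc.get("conservation_groups") or {},
        name=doc.get("name", path.stem),
    )
    pore = doc["pore"]
    return ModelDefinition(
        name=doc.get("name", path.stem),
        version=str(doc.get("version", "")),
        network=network,
        profile_species={k: v for k, v in doc["profile_species"].items()},
        stress_species=list(doc["stress_species"]),
        pore_species={k: float(v) for k, v in pore["species"].items()},
        pore_threshold=float(pore.get("threshold_uM", 0.0)),
        reference_forward_rate=float(doc.get("reference_forward_rate", 360.0)),
        antagonist_targets={k: v for k, v in (doc.get("antagonist_targets") or {}).items()},
        source=str(path),
        raw=doc,
    )
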