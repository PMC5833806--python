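import textwrap

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from momp.cli_io import packaged_table1_path, read_profiles
from momp.modeldef import load_model_definition
from momp.momp_model import ProteinProfile

# Minimal MOMP-competent network: one anti-apoptotic buffer (AA), one
# effector (E) activated directly by the stress input, dimer = pore.
TOY_MODEL_YAML = textwrap.dedent(
    """
    name: toy
    version: "1"
    units: {concentration: uM, time: h}
    species:
      - {id: STRESS, name: stress input, initial_uM: 0.0}
      - {id: AA, name: anti-apoptotic buffer, initial_uM: 0.0}
      - {id: E, name: effector, initial_uM: 0.0}
      - {id: Ea, name: activated effector, initial_uM: 0.0}
      - {id: STRESS_AA, name: stress:AA complex, initial_uM: 0.0}
      - {id: Ea2, name: effector dimer (pore), initial_uM: 0.0}
    reactions:
      - {name: bind, kind: association, reactants: {STRESS: 1, AA: 1},
         products: {STRESS_AA: 1}, k: 360.0}
      - {name: unbind, kind: dissociation, reactants: {STRESS_AA: 1},
         products: {STRESS: 1, AA: 1}, k: 0.72}
      - {name: activate, kind: conversion, reactants: {STRESS: 1, E: 1},
         products: {STRESS: 1, Ea: 1}, k: 20.0}
      - {name: dimerize, kind: association, reactants: {Ea: 2},
         products: {Ea2: 1}, k: 360.0}
      - {name: undimerize, kind: dissociation, reactants: {Ea2: 1},
         products: {Ea: 2}, k: 0.36}
    conservation_groups:
      AA_total: {AA: 1, STRESS_AA: 1}
      E_total: {E: 1, Ea: 1, Ea2: 2}
    profile_species: {bcl2: AA, bax: E}
    stress_species: [STRESS]
    pore: {species: {Ea2: 1.0}, threshold_uM: 0.05}
    reference_forward_rate: 360.0
    antagonist_targets: {BCL2: AA}
    """
)


@pytest.fixture(scope="session")
def model_def():
    return load_model_definition()


@pytest.fixture(scope="session")
def table1_profiles():
    return read_profiles(packaged_table1_path())


@pytest.fixture(scope="session")
def hcc1143(table1_profiles):
    return next(p for p in table1_profiles if p.cell_line == "HCC1143")


@pytest.fixture(scope="session")
def toy_model(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toy_model.yaml"
    path.write_text(TOY_MODEL_YAML)
    return load_model_definition(path)


@pytest.fixture(scope="session")
def toy_profile():
    # 1 uM buffer, 1 uM effector; other proteins absent from the toy network
    return ProteinProfile("toy", bcl2=1.0, mcl1=0.0, bak=0.0, bax=1.0, bclxl=0.0)
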