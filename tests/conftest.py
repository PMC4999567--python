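import numpy as np
import pandas as pd
import pytest

from ontokdd.ontology import load_bundled_ontology
from ontokdd.preprocess import AnalysisTable, flatten
from ontokdd.synthetic_registry import RegistryConfig, generate_registry


@pytest.fixture(scope="session")
def ontology():
    return load_bundled_ontology()


@pytest.fixture(scope="session")
def location_hierarchy(ontology):
    return ontology.hierarchy("cerebral_locations")


@pytest.fixture()
def mini_records():
    """Hand-built mini registry: 6 patients carrying 8 aneurysms."""
    patients = pd.DataFrame(
        {
            "id": ["P1", "P2", "P3", "P4", "P5", "P6"],
            "Patient.Sex": ["female", "female", "male", "female", "male", "female"],
            "Patient.Age": [61.0, 48.5, 70.0, 55.0, 39.0, 66.0],
        }
    )
    aneurysms = pd.DataFrame(
        {
            "id": ["A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8"],
            "patient_id": ["P1", "P2", "P2", "P3", "P4", "P4", "P5", "P6"],
            "Aneurysm.Location": [
                "AComm",
                "MCA",
                "ICA",
                "BasilarTip",
                "AComm",
                "Pericallosal",
                "PComm",
                "MCA",
            ],
            "Aneurysm.Width": [6.1, 3.2, 4.8, 10.5, 7.7, 2.1, 5.0, 3.9],
            "Aneurysm.Ruptured": [True, False, True, True, False, False, True, False],
            "Aneurysm.Presentation": [
                "SAH",
                "Coincidental",
                "SAH",
                "SAH",
                "Follow-up",
                "Coincidental",
                "SAH",
                "Epilepsy",
            ],
        }
    )
    return {"Patient": patients, "Aneurysm": aneurysms}


@pytest.fixture()
def mini_table(ontology, mini_records):
    return flatten(ontology, mini_records, grain="Aneurysm")


@pytest.fixture(scope="session")
def small_registry():
    """A small but realistic registry draw shared by slower tests."""
    return generate_registry(RegistryConfig(n_patients=120, seed=42))


@pytest.fixture(scope="session")
def small_table(ontology, small_registry):
    return flatten(ontology, small_registry.records(), grain="Aneurysm")


def make_table(ontology, rows, numeric=(), hierarchical=(), categorical=()):
    """Construct an AnalysisTable from explicit column dicts (test helper)."""
    from ontokdd.ontology import AttributeSpec

    data = pd.DataFrame(rows)
    columns = {}
    hierarchies = {}
    for name in numeric:
        columns[name] = AttributeSpec(name=name, kind="numeric")
    for name, hier in hierarchical:
        columns[name] = AttributeSpec(name=name, kind="hierarchical", hierarchy=hier.name)
        hierarchies[hier.name] = hier
    for name, cats in categorical:
        columns[name] = AttributeSpec(name=name, kind="categorical", categories=tuple(cats))
    return AnalysisTable(grain="Rec", data=data, columns=columns, hierarchies=hierarchies)
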