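import pytest
from hypothesis import settings

from comorbnet.data_model import AssociationTable, DiseaseID, EntityKind, PatientRecords
from comorbnet.ontology_semantics import OntologyDAG

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def d(code: str) -> DiseaseID:
    """Shorthand for an ICD-9 disease id."""
    return DiseaseID.parse(code)


@pytest.fixture
def gene_table() -> AssociationTable:
    """Two diseases sharing one gene: profiles {a,b} and {a,c}."""
    t = AssociationTable()
    t.add(d("100"), "a", EntityKind.GENE)
    t.add(d("100"), "b", EntityKind.GENE)
    t.add(d("101"), "a", EntityKind.GENE)
    t.add(d("101"), "c", EntityKind.GENE)
    return t


@pytest.fixture
def cohort() -> PatientRecords:
    """100 patients; diseases 200/201 each prevalence 10, 5 co-occurrences."""
    r = PatientRecords()
    for m in range(100):
        r.register_patient(f"pt{m:03d}")
    for m in range(5):
        r.add(f"pt{m:03d}", d("200"))
        r.add(f"pt{m:03d}", d("201"))
    for m in range(5, 10):
        r.add(f"pt{m:03d}", d("200"))
    for m in range(10, 15):
        r.add(f"pt{m:03d}", d("201"))
    return r


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """a -> {p1, p2} -> r, all is_a with w = 0.8."""
    return OntologyDAG(
        terms={"a", "p1", "p2", "r"},
        parents={
            "a": {("p1", "is_a"), ("p2", "is_a")},
            "p1": {("r", "is_a")},
            "p2": {("r", "is_a")},
        },
    )


@pytest.fixture
def sibling_dag() -> OntologyDAG:
    """Two siblings a, b under one root, is_a edges with w = 0.8."""
    return OntologyDAG(
        terms={"a", "b", "root"},
        parents={"a": {("root", "is_a")}, "b": {("root", "is_a")}},
    )
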