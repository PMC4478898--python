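"""Deterministic synthetic inputs for every part of the toolkit.

No bundled databases: association tables, patient cohorts, ontology DAGs
and multiplex layers are generated from a :class:`FixtureSpec`, seeded,
and byte-stable across runs.  Planting is constructive — shared-entity
counts and pair co-occurrence counts are placed exactly, not sampled —
so scores computed on a fixture recover the planted targets exactly.

The built-in ``figure8_multiplex`` fixture mirrors the toolkit's worked
integration example: ten diseases (ICD-9 categories 155, 157, 199, 286,
287, 571, 572, 574, 576, 782) on three layers (gene, pathway, clinical),
with disease 572 sharing no pathway with the other nine.  Its edge
weights are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import AssociationTable, DiseaseID, EntityKind, PatientRecords
from .layer_builder import DiseaseLayer
from .multiplex import MultiplexNetwork
from .ontology_semantics import OntologyDAG

__all__ = [
    "FixtureSpec",
    "make_association_table",
    "make_patient_records",
    "make_toy_dag",
    "figure8_multiplex",
    "FIGURE8_CODES",
]

FIGURE8_CODES = ["155", "157", "199", "286", "287", "571", "572", "574", "576", "782"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    overlap_model
        Exact shared-entity count to plant for specific disease pairs,
        keyed by (index_i, index_j).
    comorbidity_model
        Target relative risks to plant for specific disease pairs; the
        co-occurrence count is the inversion C = round(RR · P_i · P_j / N).
    prevalence
        Per-disease prevalence fraction for the patient cohort.
    """

    seed: int = 0
    n_diseases: int = 10
    n_entities_per_kind: int = 50
    n_patients: int = 100
    profile_size: int = 5
    prevalence: float = 0.1
    overlap_model: dict[tuple[int, int], int] = field(default_factory=dict)
    comorbidity_model: tuple[tuple[tuple[int, int], float], ...] = ()
    dag_depth: int = 3
    dag_branching: int = 2

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_entities_per_kind, self.n_patients) < 1:
            raise ValueError("all fixture counts must be at least 1")
        if any(rr < 0 for _, rr in self.comorbidity_model):
            raise ValueError("target relative risks must be nonnegative")


def disease_ids(spec: FixtureSpec) -> list[DiseaseID]:
    """Synthetic ICD-9 category codes D00, D01, ... rendered as 100+i."""
    return [DiseaseID("icd9", f"{100 + i:03d}") for i in range(spec.n_diseases)]


def make_association_table(spec: FixtureSpec, kind: EntityKind) -> AssociationTable:
    """Bipartite table with exactly planted pairwise overlaps.

    Each planted pair (i, j) receives its own block of shared entities of
    the size the overlap model demands; every disease is then padded with
    private entities up to ``spec.profile_size``.  With an empty overlap
    model all profiles are disjoint.
    """
    ids = disease_ids(spec)
    table = AssociationTable()
    counter = 0

    def fresh(n: int) -> list[str]:
        nonlocal counter
        out = [f"{kind.value}_{counter + m:05d}" for m in range(n)]
        counter += n
        return out

    planted: dict[int, list[str]] = {i: [] for i in range(spec.n_diseases)}
    for (i, j), n_shared in sorted(spec.overlap_model.items()):
        if not (0 <= i < spec.n_diseases and 0 <= j < spec.n_diseases and i != j):
            raise ValueError(f"overlap_model pair ({i}, {j}) out of range")
        shared = fresh(n_shared)
        planted[i].extend(shared)
        planted[j].extend(shared)

    for i in range(spec.n_diseases):
        entities = list(planted[i])
        pad = max(spec.profile_size - len(entities), 0)
        entities.extend(fresh(pad))
        for e in entities:
            table.add(ids[i], e, kind)
    return table


def make_patient_records(spec: FixtureSpec) -> PatientRecords:
    """Patient cohort with exactly planted pair co-occurrence counts.

    Each disease gets prevalence count P = round(prevalence · N).  For
    every (pair, target RR) the co-occurrence count C = round(RR·P_i·P_j/N)
    is placed exactly by choosing C patients carrying both diseases and
    P − C carrying each alone; an infeasible target (C above a margin)
    raises.  Diseases outside the comorbidity model are assigned
    independently at the same prevalence.
    """
    rng = np.random.default_rng(spec.seed)
    ids = disease_ids(spec)
    n = spec.n_patients
    p_count = max(int(round(spec.prevalence * n)), 1)
    patients = [f"pt{m:05d}" for m in range(n)]
    records = PatientRecords()
    for pt in patients:
        records.register_patient(pt)

    in_model: set[int] = set()
    for (i, j), rr in spec.comorbidity_model:
        if i in in_model or j in in_model:
            raise ValueError("comorbidity_model pairs must not share diseases")
        in_model.update((i, j))
        c = int(round(rr * p_count * p_count / n))
        if c > p_count:
            raise ValueError(
                f"target RR {rr} infeasible: co-occurrence {c} exceeds margin {p_count}"
            )
        pool = rng.permutation(n)
        both = pool[:c]
        only_i = pool[c : p_count]
        only_j = pool[p_count : 2 * p_count - c]
        for m in both:
            records.add(patients[m], ids[i])
            records.add(patients[m], ids[j])
        for m in only_i:
            records.add(patients[m], ids[i])
        for m in only_j:
            records.add(patients[m], ids[j])

    for k in range(spec.n_diseases):
        if k in in_model:
            continue
        carriers = rng.choice(n, size=p_count, replace=False)
        for m in carriers:
            records.add(patients[m], ids[k])

    # Patient counts must survive a TSV round-trip, and the TSV carries one
    # row per diagnosis: give diagnosis-free patients a neutral filler code
    # ("799", ill-defined causes) that belongs to no planted pair.
    filler = DiseaseID("icd9", "799")
    for pt in patients:
        if not records.diagnoses(pt):
            records.add(pt, filler)
    return records


def make_toy_dag(
    spec: FixtureSpec, n_cross_links: int = 0
) -> OntologyDAG:
    """Rooted is_a tree of the spec's depth and branching.

    Terms are labelled T:0000001 (root) onward, breadth-first.  With
    branching b and depth d the tree has (b^(d+1) − 1)/(b − 1) terms.
    Optional extra part_of cross-links connect random non-adjacent
    levels, keeping the graph acyclic.
    """
    if spec.dag_depth < 1 or spec.dag_branching < 1:
        raise ValueError("dag_depth and dag_branching must be at least 1")
    rng = np.random.default_rng(spec.seed)
    b, d = spec.dag_branching, spec.dag_depth

    terms: list[str] = []
    parents: dict[str, set[tuple[str, str]]] = {}
    levels: list[list[str]] = []
    counter = 1

    def new_term() -> str:
        nonlocal counter
        t = f"T:{counter:07d}"
        counter += 1
        terms.append(t)
        return t

    levels.append([new_term()])
    for _ in range(d):
        nxt = []
        for parent in levels[-1]:
            for _ in range(b):
                child = new_term()
                parents.setdefault(child, set()).add((parent, "is_a"))
                nxt.append(child)
        levels.append(nxt)

    for _ in range(n_cross_links):
        # a part_of edge from a leaf-level term to a random level-1 term
        child = levels[-1][int(rng.integers(len(levels[-1])))]
        target = levels[1][int(rng.integers(len(levels[1])))]
        if (target, "is_a") not in parents.get(child, set()):
            parents.setdefault(child, set()).add((target, "part_of"))

    return OntologyDAG(terms=set(terms), parents=parents)


def figure8_multiplex(seed: int = 0, omega: float | np.ndarray = 0.5) -> MultiplexNetwork:
    """Three-layer, ten-disease multiplex integration example.

    Layers 'gene', 'pathway' and 'clinical' share the ten ICD-9 disease
    categories of :data:`FIGURE8_CODES`.  Edge weights are synthetic
    draws in (0, 1); in the pathway layer, disease 572 shares no pathway
    with the other nine, so its row and column are zero there.
    """
    rng = np.random.default_rng(seed)
    nodes = [DiseaseID("icd9", code) for code in FIGURE8_CODES]
    n = len(nodes)
    layers = []
    for name in ("gene", "pathway", "clinical"):
        raw = rng.uniform(0.05, 1.0, size=(n, n))
        w = np.triu(raw, 1)
        w = w + w.T
        if name == "pathway":
            idx = FIGURE8_CODES.index("572")
            w[idx, :] = 0.0
            w[:, idx] = 0.0
        layers.append(DiseaseLayer(name=name, nodes=list(nodes), weights=w))
    return MultiplexNetwork(layers=layers, omega=omega)
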