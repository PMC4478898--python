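"""Core types and I/O for disease-association evidence and clinical records.

Everything downstream works on three containers:

* :class:`AssociationTable` — a bipartite relation between diseases and
  evidence entities (genes, SNPs, CNVs, miRNAs, ontology terms,
  environmental factors).
* :class:`PatientRecords` — patient × diagnosis incidence, the raw material
  for prevalence, co-occurrence, relative risk and ϕ-correlation.
* :class:`IDMap` — many-to-many identifier cross-maps (OMIM ↔ ICD-9-CM,
  gene symbol ↔ Entrez, ...).

All tabular input is plain TSV (tab-separated, UTF-8, header required,
``#``-prefixed comment lines skipped).  Networks are written as GraphML
(via :mod:`networkx`) or TSV edge lists.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EntityKind",
    "DiseaseID",
    "IDMap",
    "AssociationTable",
    "PatientRecords",
    "FormatError",
    "read_association_table",
    "read_patient_records",
    "read_id_map",
    "map_ids",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """An input file violates its declared format."""


class EntityKind(str, enum.Enum):
    """Closed enumeration of the evidence types a disease can be linked to."""

    GENE = "gene"
    SNP = "snp"
    CNV = "cnv"
    MIRNA = "mirna"
    GO_TERM = "go_term"
    HPO_TERM = "hpo_term"
    ENV_FACTOR = "env_factor"
    PATHWAY = "pathway"


# ICD-9-CM: a 3-character category (numeric, or V/E prefixed) with an
# optional 1-2 digit decimal subdivision; E-codes use a 4-digit category.
_ICD9_RE = re.compile(r"^(\d{3}|V\d{2}|E\d{3})(\.\d{1,2})?$")
_OMIM_RE = re.compile(r"^\d{6}$")


@dataclass(frozen=True, order=True)
class DiseaseID:
    """A namespaced disease identifier: OMIM number or ICD-9-CM code.

    Equality and ordering are on ``(namespace, code)``.
    """

    namespace: str
    code: str

    def __post_init__(self) -> None:
        if self.namespace == "omim":
            if not _OMIM_RE.match(self.code):
                raise ValueError(f"invalid OMIM id {self.code!r}: must be 6 digits")
        elif self.namespace == "icd9":
            if not _ICD9_RE.match(self.code):
                raise ValueError(
                    f"invalid ICD-9-CM code {self.code!r}: expected a 3-character "
                    "category with optional dotted subdivision (e.g. '042', '042.1')"
                )
        else:
            raise ValueError(f"unknown disease namespace {self.namespace!r}")

    @classmethod
    def parse(cls, text: str) -> "DiseaseID":
        """Parse ``'omim:189907'``, ``'icd9:042.1'`` or a bare code.

        Bare 6-digit codes are read as OMIM ids; anything else must be a
        syntactically valid ICD-9-CM code.
        """
        text = text.strip()
        if ":" in text:
            ns, code = text.split(":", 1)
            return cls(ns.strip().lower(), code.strip())
        if _OMIM_RE.match(text):
            return cls("omim", text)
        return cls("icd9", text)

    def category(self) -> "DiseaseID":
        """The 3-digit ICD-9 category view: ``042.1 → 042``.

        OMIM ids have no category structure and are returned unchanged.
        """
        if self.namespace != "icd9" or "." not in self.code:
            return self
        return DiseaseID("icd9", self.code.split(".", 1)[0])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.namespace}:{self.code}"


@dataclass
class IDMap:
    """A many-to-many identifier cross-map.

    Lookups are total: an unmapped identifier maps to the empty set,
    never to an error.
    """

    pairs: set[tuple[str, str, str, str]] = field(default_factory=set)
    # each pair is (from_ns, from_id, to_ns, to_id)

    def add(self, from_ns: str, from_id: str, to_ns: str, to_id: str) -> None:
        self.pairs.add((from_ns, from_id, to_ns, to_id))
        self.pairs.add((to_ns, to_id, from_ns, from_id))

    def namespaces(self) -> set[str]:
        return {p[0] for p in self.pairs}

    def lookup(self, identifier: str, from_ns: str, to_ns: str) -> set[str]:
        return {
            to_id
            for (f_ns, f_id, t_ns, to_id) in self.pairs
            if f_ns == from_ns and f_id == identifier and t_ns == to_ns
        }


class AssociationTable:
    """Bipartite disease ↔ entity evidence with pure set semantics.

    Rows are unique on ``(disease, entity, kind)``; re-adding an existing
    row keeps the first weight.  ``profile(d, kind)`` is the entity set of
    one evidence type for one disease; its size is the ``N(G_i)`` used by
    the pairwise association scores.
    """

    def __init__(self) -> None:
        # (disease, kind) -> {entity: weight}
        self._profiles: dict[tuple[DiseaseID, EntityKind], dict[str, float]] = {}

    def add(
        self,
        disease: DiseaseID,
        entity: str,
        kind: EntityKind,
        weight: float = 1.0,
    ) -> None:
        if weight < 0:
            raise ValueError(f"association weight must be nonnegative, got {weight}")
        prof = self._profiles.setdefault((disease, kind), {})
        prof.setdefault(entity, float(weight))

    def __len__(self) -> int:
        return sum(len(p) for p in self._profiles.values())

    def diseases(self, kind: EntityKind | None = None) -> list[DiseaseID]:
        seen = {
            d
            for (d, k), prof in self._profiles.items()
            if prof and (kind is None or k == kind)
        }
        return sorted(seen)

    def profile(self, disease: DiseaseID, kind: EntityKind) -> frozenset[str]:
        """Entities of ``kind`` linked to ``disease`` (empty if absent)."""
        return frozenset(self._profiles.get((disease, kind), ()))

    def profile_size(self, disease: DiseaseID, kind: EntityKind) -> int:
        return len(self._profiles.get((disease, kind), ()))

    def weight(self, disease: DiseaseID, entity: str, kind: EntityKind) -> float:
        return self._profiles.get((disease, kind), {}).get(entity, 0.0)

    def entity_degree(self, entity: str, kind: EntityKind) -> int:
        """Number of diseases linked to ``entity`` — its bipartite degree."""
        return sum(
            1
            for (_, k), prof in self._profiles.items()
            if k == kind and entity in prof
        )

    def entities(self, kind: EntityKind) -> frozenset[str]:
        out: set[str] = set()
        for (_, k), prof in self._profiles.items():
            if k == kind:
                out.update(prof)
        return frozenset(out)

    def rows(self) -> Iterable[tuple[DiseaseID, str, EntityKind, float]]:
        for (d, k), prof in sorted(
            self._profiles.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            for entity in sorted(prof):
                yield d, entity, k, prof[entity]

    def truncated_to_categories(self) -> "AssociationTable":
        """Re-key every ICD-9 disease at 3-digit category resolution."""
        out = AssociationTable()
        for d, entity, kind, weight in self.rows():
            out.add(d.category(), entity, kind, weight)
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("disease_id\tentity_id\tentity_kind\tweight\n")
            for d, entity, kind, weight in self.rows():
                fh.write(f"{d}\t{entity}\t{kind.value}\t{weight:g}\n")


class PatientRecords:
    """Patient × diagnosis incidence with per-patient set semantics.

    A diagnosis listed twice for the same patient counts once; there is no
    visit-level multiplicity or temporal ordering.
    """

    def __init__(self) -> None:
        self._patients: dict[str, set[DiseaseID]] = {}

    def add(self, patient: str, disease: DiseaseID) -> None:
        self._patients.setdefault(patient, set()).add(disease)

    def register_patient(self, patient: str) -> None:
        """Record a patient with no diagnoses (counts toward N)."""
        self._patients.setdefault(patient, set())

    @property
    def n_patients(self) -> int:
        return len(self._patients)

    def patients(self) -> list[str]:
        return sorted(self._patients)

    def diagnoses(self, patient: str) -> frozenset[DiseaseID]:
        return frozenset(self._patients.get(patient, ()))

    def diseases(self) -> list[DiseaseID]:
        out: set[DiseaseID] = set()
        for ds in self._patients.values():
            out.update(ds)
        return sorted(out)

    def prevalence_count(self, disease: DiseaseID) -> int:
        """P_i: number of patients carrying ``disease``."""
        return sum(1 for ds in self._patients.values() if disease in ds)

    def cooccurrence_count(self, i: DiseaseID, j: DiseaseID) -> int:
        """C_ij: number of patients carrying both ``i`` and ``j`` (C_ii = P_i)."""
        if i == j:
            return self.prevalence_count(i)
        return sum(1 for ds in self._patients.values() if i in ds and j in ds)

    def indicator(self, disease: DiseaseID) -> list[int]:
        """Binary presence vector over patients in sorted-patient order."""
        return [int(disease in self._patients[p]) for p in sorted(self._patients)]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("patient_id\tdisease_code\n")
            for patient in sorted(self._patients):
                for d in sorted(self._patients[patient]):
                    fh.write(f"{patient}\t{d}\n")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_association_table(
    path: str | Path, kind_filter: EntityKind | None = None
) -> AssociationTable:
    """Read a disease↔entity TSV (``disease_id  entity_id  entity_kind [weight]``).

    Duplicate rows collapse to one; rows with malformed disease ids raise a
    :class:`FormatError` naming the offending row number.
    """
    df = _read_tsv(path, ["disease_id", "entity_id", "entity_kind"])
    table = AssociationTable()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, after the header line
        try:
            disease = DiseaseID.parse(str(row["disease_id"]))
            kind = EntityKind(str(row["entity_kind"]).strip())
        except ValueError as exc:
            raise FormatError(f"{path}: row {rownum}: {exc}") from exc
        if kind_filter is not None and kind != kind_filter:
            continue
        weight = 1.0
        if "weight" in df.columns and pd.notna(row.get("weight")):
            weight = float(row["weight"])
        table.add(disease, str(row["entity_id"]).strip(), kind, weight)
    return table


def read_patient_records(path: str | Path) -> PatientRecords:
    """Read a patient-diagnosis TSV (``patient_id  disease_code``)."""
    df = _read_tsv(path, ["patient_id", "disease_code"])
    records = PatientRecords()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2
        try:
            disease = DiseaseID.parse(str(row["disease_code"]))
        except ValueError as exc:
            raise FormatError(f"{path}: row {rownum}: {exc}") from exc
        records.add(str(row["patient_id"]).strip(), disease)
    return records


def read_id_map(path: str | Path) -> IDMap:
    """Read a cross-map TSV (``from_ns  from_id  to_ns  to_id``)."""
    df = _read_tsv(path, ["from_ns", "from_id", "to_ns", "to_id"])
    idmap = IDMap()
    for _, row in df.iterrows():
        idmap.add(
            str(row["from_ns"]).strip().lower(),
            str(row["from_id"]).strip(),
            str(row["to_ns"]).strip().lower(),
            str(row["to_id"]).strip(),
        )
    return idmap


def map_ids(
    ids: Iterable[str], from_ns: str, to_ns: str, idmap: IDMap
) -> dict[str, set[str]]:
    """Translate identifiers across namespaces; many-to-many is preserved.

    Unmapped ids map to the empty set and are reported with a warning —
    partial cross-maps are the norm for OMIM ↔ ICD-9.
    """
    known = idmap.namespaces()
    for ns in (from_ns, to_ns):
        if known and ns not in known:
            raise KeyError(f"namespace {ns!r} not present in the loaded id map")
    out: dict[str, set[str]] = {}
    for identifier in ids:
        targets = idmap.lookup(identifier, from_ns, to_ns)
        if not targets:
            logger.warning("id %s:%s has no %s mapping; dropped", from_ns, identifier, to_ns)
        out[identifier] = targets
    return out


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------

Edge = tuple[DiseaseID, DiseaseID, float]


def write_network(
    edges: Iterable[Edge], path: str | Path, format: str = "tsv"
) -> None:
    """Write a weighted disease–disease edge list as TSV or GraphML.

    Round-tripping through :func:`read_network` returns an identical edge
    set with weights preserved to full float precision.
    """
    edges = [(i, j, float(w)) for i, j, w in edges]
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for i, j, w in sorted(edges):
                fh.write(f"{i}\t{j}\t{w!r}\n")
    elif format == "graphml":
        g = nx.Graph()
        for i, j, w in edges:
            g.add_edge(str(i), str(j), weight=w)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}; use 'tsv' or 'graphml'")


def read_network(path: str | Path, format: str = "tsv") -> list[Edge]:
    """Read back a network written by :func:`write_network`."""
    if format == "tsv":
        df = _read_tsv(path, ["source", "target", "weight"])
        return [
            (DiseaseID.parse(r["source"]), DiseaseID.parse(r["target"]), float(r["weight"]))
            for _, r in df.iterrows()
        ]
    if format == "graphml":
        g = nx.read_graphml(path)
        return [
            (DiseaseID.parse(u), DiseaseID.parse(v), float(d["weight"]))
            for u, v, d in g.edges(data=True)
        ]
    raise ValueError(f"unknown network format {format!r}; use 'tsv' or 'graphml'")
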