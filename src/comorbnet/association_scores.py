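"""Pairwise disease–disease association scores from shared evidence.

Given a bipartite disease↔entity table, two diseases are compared through
the entities they share: a raw shared count, a product-normalized
similarity, the Jaccard index, the Adamic–Adar inverse-log-degree score,
a log-ratio interaction score, and (from clinical records) a mutual-
information weight.  Enrichment of a query gene list in a disease's
association set is scored with the one-sided hypergeometric test and
Benjamini–Hochberg FDR control.

All scores are symmetric in the disease pair and depend only on the set
content of the table, never on row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import AssociationTable, DiseaseID, EntityKind, PatientRecords

__all__ = [
    "EnrichmentQuery",
    "ScoreConfig",
    "UndefinedScoreError",
    "shared_count",
    "similarity",
    "hypergeom_pvalue",
    "bh_fdr",
    "jaccard_association",
    "adamic_adar",
    "interaction_score",
    "mutual_info_weight",
]


class UndefinedScoreError(ValueError):
    """A score's preconditions fail (empty profile, zero prevalence, ...).

    Callers decide whether to drop the pair or substitute zero.
    """


@dataclass(frozen=True)
class EnrichmentQuery:
    """One hypergeometric enrichment question.

    N_ref marked/unmarked reference genes, of which ``M_assoc`` are
    associated to the disease (or term); a query list of ``n_query`` genes
    contains ``k_overlap`` of the associated ones.
    """

    N_ref: int
    M_assoc: int
    n_query: int
    k_overlap: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k_overlap <= min(self.M_assoc, self.n_query)
            and self.M_assoc <= self.N_ref
            and self.n_query <= self.N_ref
        )
        if not ok:
            raise ValueError(f"inconsistent enrichment counts: {self}")


@dataclass(frozen=True)
class ScoreConfig:
    """Tunable knobs shared by the pairwise scores.

    z
        Pseudocount guarding the interaction score's logs when all counts
        are zero (default 1).
    log_base
        Base of every logarithm (default e; only relative/sign behaviour
        matters downstream).
    adamic_min_degree
        Minimum bipartite degree for an entity to contribute to the
        Adamic–Adar sum.  Degree-1 entities have log(degree) = 0 and are
        excluded by the standard convention (default 2).
    mi_pseudocount
        Optional additive count for the mutual-information weight when the
        pair never co-occurs; ``None`` (default) omits such pairs.
    """

    z: float = 1.0
    log_base: float = math.e
    adamic_min_degree: int = 2
    mi_pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("pseudocount z must be nonnegative")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")

    def log(self, x: float) -> float:
        return math.log(x) / math.log(self.log_base)


def shared_count(
    table: AssociationTable, kind: EntityKind, i: DiseaseID, j: DiseaseID
) -> int:
    """Number of entities of ``kind`` shared by diseases ``i`` and ``j``."""
    return len(table.profile(i, kind) & table.profile(j, kind))


def similarity(
    table: AssociationTable, kind: EntityKind, i: DiseaseID, j: DiseaseID
) -> float:
    """Shared-entity similarity |G_i ∩ G_j| / (|G_i| · |G_j|).

    The denominator is the plain product of the profile sizes, so the value
    is not bounded by 1; it is 1 for identical singletons and shrinks with
    profile size.
    """
    n_i = table.profile_size(i, kind)
    n_j = table.profile_size(j, kind)
    if n_i == 0 or n_j == 0:
        raise UndefinedScoreError(
            f"similarity undefined: empty {kind.value} profile for {i if n_i == 0 else j}"
        )
    return shared_count(table, kind, i, j) / (n_i * n_j)


def hypergeom_pvalue(q: EnrichmentQuery) -> float:
    """One-sided over-representation p-value, P(X ≥ k).

    X is hypergeometric with ``N_ref`` reference genes of which ``M_assoc``
    are associated, drawing ``n_query``.  Evaluated through the survival
    function rather than 1 − CDF, so tiny tail probabilities keep full
    relative precision.  ``k = 0`` gives exactly 1.
    """
    if q.k_overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(q.k_overlap - 1, q.N_ref, q.M_assoc, q.n_query))


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, in the input order."""
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    if not pvalues:
        return []
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(p) for p in adjusted]


def jaccard_association(
    table: AssociationTable, kind: EntityKind, i: DiseaseID, j: DiseaseID
) -> float:
    """Jaccard index |G_i ∩ G_j| / |G_i ∪ G_j| of the two profiles."""
    gi = table.profile(i, kind)
    gj = table.profile(j, kind)
    union = gi | gj
    if not union:
        raise UndefinedScoreError(
            f"Jaccard undefined: both {kind.value} profiles empty for {i}, {j}"
        )
    return len(gi & gj) / len(union)


def adamic_adar(
    table: AssociationTable,
    kind: EntityKind,
    i: DiseaseID,
    j: DiseaseID,
    config: ScoreConfig = ScoreConfig(),
) -> float:
    """Adamic–Adar score: Σ 1/log(degree(n)) over shared entities n.

    ``degree(n)`` is the entity's bipartite degree — the number of diseases
    it is linked to anywhere in the table.  Entities below
    ``config.adamic_min_degree`` contribute nothing.
    """
    total = 0.0
    for entity in table.profile(i, kind) & table.profile(j, kind):
        deg = table.entity_degree(entity, kind)
        if deg >= config.adamic_min_degree:
            total += 1.0 / config.log(deg)
    return total


def interaction_score(
    table: AssociationTable,
    kind: EntityKind,
    i: DiseaseID,
    j: DiseaseID,
    N_total: int,
    config: ScoreConfig = ScoreConfig(),
) -> float:
    """Log-ratio interaction score log(n_ij·N + Z) − log(|G_i|·|G_j| + Z).

    ``N_total`` is the size of the entity universe in the network.  The
    score is positive when the pair shares more entities than the product
    of their profile sizes predicts, negative when fewer; the pseudocount
    ``Z`` keeps the all-zero case finite (and exactly 0 with Z = 1).
    """
    if N_total < 1:
        raise ValueError("N_total must be a positive integer")
    n_ij = shared_count(table, kind, i, j)
    n_i = table.profile_size(i, kind)
    n_j = table.profile_size(j, kind)
    return config.log(n_ij * N_total + config.z) - config.log(n_i * n_j + config.z)


def mutual_info_weight(
    records: PatientRecords,
    i: DiseaseID,
    j: DiseaseID,
    config: ScoreConfig = ScoreConfig(),
) -> float | None:
    """Pointwise mutual information log(p(i,j) / (p(i)·p(j))) from records.

    Returns ``None`` for never-co-occurring pairs unless
    ``config.mi_pseudocount`` supplies an additive count.
    """
    n = records.n_patients
    p_i = records.prevalence_count(i)
    p_j = records.prevalence_count(j)
    if n == 0 or p_i == 0 or p_j == 0:
        raise UndefinedScoreError(f"mutual information undefined: zero prevalence for {i} or {j}")
    c_ij = records.cooccurrence_count(i, j)
    if c_ij == 0:
        if config.mi_pseudocount is None:
            return None
        c_ij = config.mi_pseudocount
    return config.log((c_ij / n) / ((p_i / n) * (p_j / n)))
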