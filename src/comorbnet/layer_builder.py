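"""Construction of per-evidence disease–disease network layers.

One generic builder covers every evidence type: diseases become nodes,
and an edge is drawn between two diseases when they share at least ``k``
entities of the layer's kind (optionally gated by a hypergeometric
enrichment test), weighted by a configurable pairwise score and
normalized into [0, 1] so the layer can enter a multiplex.

The six named presets (gene, SNP, CNV, miRNA, GO, HPO, environmental)
exposed by the command-line interface all route through
:func:`build_layer` with different :class:`LayerRecipe` settings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import association_scores as scores
from .data_model import AssociationTable, DiseaseID, EntityKind
from .ontology_semantics import OntologyDAG, term_similarity

__all__ = ["DiseaseLayer", "LayerRecipe", "build_layer", "seed_subnetwork", "PRESETS"]

SCORE_NAMES = {
    "shared_count",
    "similarity",
    "jaccard",
    "adamic_adar",
    "interaction",
    "semantic_bma",
}


@dataclass
class DiseaseLayer:
    """A weighted undirected disease–disease network for one evidence type.

    ``weights`` is symmetric with zero diagonal; the node order is shared
    with sibling layers of the same multiplex.
    """

    name: str
    nodes: list[DiseaseID]
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} does not match {n} nodes")
        if not np.allclose(w, w.T):
            raise ValueError("layer weight matrix must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    def index(self, node: DiseaseID) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"node {node} not in layer {self.name!r}") from None

    def edges(self) -> list[tuple[DiseaseID, DiseaseID, float]]:
        out = []
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] != 0.0:
                    out.append((self.nodes[i], self.nodes[j], float(self.weights[i, j])))
        return out


@dataclass(frozen=True)
class LayerRecipe:
    """How to turn an association table into one network layer.

    kind
        Evidence type read from the table.
    score
        Edge weight: one of shared_count, similarity, jaccard,
        adamic_adar, interaction, semantic_bma.
    min_shared
        Edge rule — diseases connect when they share at least this many
        entities (default 1).
    p_alpha
        Optional BH-adjusted hypergeometric gate on the overlap of the
        two profiles; ``None`` disables it.
    normalization
        'max' (divide by the largest weight), 'minmax' (affine map of the
        edge weights onto [0, 1]), or 'none'.
    """

    kind: EntityKind
    score: str = "jaccard"
    min_shared: int = 1
    p_alpha: float | None = None
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if self.score not in SCORE_NAMES:
            raise ValueError(f"unknown score {self.score!r}; choose from {sorted(SCORE_NAMES)}")
        if self.min_shared < 1:
            raise ValueError("min_shared must be at least 1")
        if self.normalization not in {"max", "minmax", "none"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")


# Per-evidence presets mirroring the toolkit's named functions: ontology
# layers use semantic best-match-average weights, molecular/environmental
# layers use the Jaccard index with a hypergeometric significance gate.
PRESETS: dict[str, LayerRecipe] = {
    "go": LayerRecipe(kind=EntityKind.GO_TERM, score="semantic_bma"),
    "hpo": LayerRecipe(kind=EntityKind.HPO_TERM, score="semantic_bma"),
    "snp": LayerRecipe(kind=EntityKind.SNP, score="jaccard", p_alpha=0.05),
    "cnv": LayerRecipe(kind=EntityKind.CNV, score="jaccard", p_alpha=0.05),
    "mirna": LayerRecipe(kind=EntityKind.MIRNA, score="jaccard", p_alpha=0.05),
    "env": LayerRecipe(kind=EntityKind.ENV_FACTOR, score="jaccard", p_alpha=0.05),
    "gene": LayerRecipe(kind=EntityKind.GENE, score="jaccard", p_alpha=0.05),
}


def _pair_score(
    table: AssociationTable,
    recipe: LayerRecipe,
    i: DiseaseID,
    j: DiseaseID,
    n_universe: int,
    dag: OntologyDAG | None,
) -> float:
    kind = recipe.kind
    if recipe.score == "shared_count":
        return float(scores.shared_count(table, kind, i, j))
    if recipe.score == "similarity":
        return scores.similarity(table, kind, i, j)
    if recipe.score == "jaccard":
        return scores.jaccard_association(table, kind, i, j)
    if recipe.score == "adamic_adar":
        return scores.adamic_adar(table, kind, i, j)
    if recipe.score == "interaction":
        return scores.interaction_score(table, kind, i, j, max(n_universe, 1))
    # semantic_bma: best-match-average ontology similarity of the two
    # term profiles (requires a DAG covering the annotated terms)
    if dag is None:
        raise ValueError("score 'semantic_bma' requires an ontology DAG")
    a = table.profile(i, kind) & dag.terms
    b = table.profile(j, kind) & dag.terms
    if not a or not b:
        return 0.0
    fwd = sum(max(term_similarity(dag, s, t) for t in b) for s in a) / len(a)
    rev = sum(max(term_similarity(dag, t, s) for s in a) for t in b) / len(b)
    return 0.5 * fwd + 0.5 * rev


def _normalize(w: np.ndarray, mode: str) -> np.ndarray:
    mask = w != 0.0
    if not mask.any() or mode == "none":
        return w
    vals = w[mask]
    if mode == "max":
        top = vals.max()
        if top <= 0:
            raise ValueError("max-normalization requires a positive maximum weight")
        return w / top
    # minmax over the present edges; constant weights map to 1
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(w)
    if hi == lo:
        out[mask] = 1.0
    else:
        out[mask] = (vals - lo) / (hi - lo)
    return out


def build_layer(
    table: AssociationTable,
    recipe: LayerRecipe,
    diseases: Sequence[DiseaseID],
    name: str | None = None,
    dag: OntologyDAG | None = None,
) -> DiseaseLayer:
    """Build one disease–disease layer from a bipartite evidence table.

    An edge (i, j) appears exactly when the edge rule holds — at least
    ``recipe.min_shared`` shared entities, and, if ``recipe.p_alpha`` is
    set, a BH-adjusted hypergeometric overlap p-value below it.  Edge
    weights are the recipe's score, normalized per the recipe; the
    diagonal is forced to zero.
    """
    if not diseases:
        raise ValueError("diseases list must be nonempty")
    nodes = list(diseases)
    n = len(nodes)
    n_universe = len(table.entities(recipe.kind))
    w = np.zeros((n, n))

    candidates: list[tuple[int, int]] = []
    pvals: list[float] = []
    for a in range(n):
        for b in range(a + 1, n):
            k_shared = scores.shared_count(table, recipe.kind, nodes[a], nodes[b])
            if k_shared < recipe.min_shared:
                continue
            candidates.append((a, b))
            if recipe.p_alpha is not None:
                q = scores.EnrichmentQuery(
                    N_ref=n_universe,
                    M_assoc=table.profile_size(nodes[a], recipe.kind),
                    n_query=table.profile_size(nodes[b], recipe.kind),
                    k_overlap=k_shared,
                )
                pvals.append(scores.hypergeom_pvalue(q))

    if recipe.p_alpha is not None and candidates:
        adjusted = scores.bh_fdr(pvals)
        candidates = [
            pair for pair, p in zip(candidates, adjusted) if p < recipe.p_alpha
        ]

    for a, b in candidates:
        try:
            val = _pair_score(table, recipe, nodes[a], nodes[b], n_universe, dag)
        except scores.UndefinedScoreError:
            continue
        w[a, b] = w[b, a] = val

    w = _normalize(w, recipe.normalization)
    return DiseaseLayer(name=name or recipe.kind.value, nodes=nodes, weights=w)


def seed_subnetwork(layer: DiseaseLayer, seed: DiseaseID, depth: int = 1) -> DiseaseLayer:
    """Induced subgraph of all nodes within ``depth`` hops of ``seed``."""
    if depth < 1:
        raise ValueError("depth must be a positive integer")
    start = layer.index(seed)
    keep = {start}
    frontier = {start}
    for _ in range(depth):
        nxt = set()
        for i in frontier:
            nxt.update(int(j) for j in np.flatnonzero(layer.weights[i]))
        frontier = nxt - keep
        keep |= nxt
        if not frontier:
            break
    order = sorted(keep)
    return DiseaseLayer(
        name=f"{layer.name}|{seed.code}",
        nodes=[layer.nodes[i] for i in order],
        weights=layer.weights[np.ix_(order, order)].copy(),
    )
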