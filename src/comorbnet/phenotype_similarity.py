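"""Phenotype-record and disease–disease similarity from feature profiles.

Two complementary views:

* a phenotype *record* is a weighted concept vector, compared by cosine
  similarity;
* a disease is a set of phenotypic features (HPO terms) with a pairwise
  feature-similarity kernel, compared by best-match averaging (BMA):
  each feature of one disease is matched to its most similar feature of
  the other, averaged, and the two directions are averaged to restore
  symmetry.

The feature kernel is pluggable — typically the ontology term similarity
from :mod:`comorbnet.ontology_semantics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .association_scores import UndefinedScoreError

__all__ = [
    "PhenotypeVector",
    "FeatureProfile",
    "cosine_similarity",
    "directed_bma",
    "symmetric_bma",
    "significant_pairs",
]


@dataclass(frozen=True)
class PhenotypeVector:
    """Weighted concept vector for one phenotype record.

    Weights may be term frequencies or binary indicators; absent concepts
    have weight 0.
    """

    weights: Mapping[str, float]

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


@dataclass(frozen=True)
class FeatureProfile:
    """A disease's phenotypic features plus a symmetric similarity kernel."""

    features: frozenset[str]
    sim: Callable[[str, str], float]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature profile must be nonempty")


def cosine_similarity(p_i: PhenotypeVector, p_j: PhenotypeVector) -> float:
    """Cosine of the angle between two phenotype weight vectors.

    Bounded in [0, 1] because weights are nonnegative.
    """
    ni, nj = p_i.norm(), p_j.norm()
    if ni == 0.0 or nj == 0.0:
        raise UndefinedScoreError("cosine similarity undefined for a zero vector")
    dot = sum(w * p_j.weights.get(k, 0.0) for k, w in p_i.weights.items())
    return dot / (ni * nj)


def directed_bma(d1: FeatureProfile, d2: FeatureProfile) -> float:
    """Average best-match similarity of d1's features against d2."""
    return sum(
        max(d1.sim(s, t) for t in d2.features) for s in d1.features
    ) / len(d1.features)


def symmetric_bma(d1: FeatureProfile, d2: FeatureProfile) -> float:
    """Best-match-average similarity symmetrized over both directions."""
    return 0.5 * directed_bma(d1, d2) + 0.5 * directed_bma(d2, d1)


def significant_pairs(
    scores: Mapping[tuple[str, str], float], percentile: float = 95.0
) -> dict[tuple[str, str], float]:
    """Keep the pairwise scores strictly above the given percentile.

    The edge-inclusion rule for phenotype-similarity networks: with no
    absolute significance cutoff available, an edge is drawn when its
    score exceeds the chosen percentile (default 95th) of all pairwise
    scores.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    if not scores:
        return {}
    cutoff = float(np.percentile(list(scores.values()), percentile))
    return {pair: s for pair, s in scores.items() if s > cutoff}
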