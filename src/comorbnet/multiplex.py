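"""Multiplex fusion of disease network layers via communicability.

A multiplex network stacks h disease–disease layers that share one node
list of size n; a disease is coupled to its own counterpart in every
other layer with a symmetric interlayer strength ω_ij ∈ [0, 1].  The
supra-adjacency matrix is the (n·h)×(n·h) block matrix with the layer
adjacencies A_i on the diagonal and ω_ij·I off it.

Fusion proceeds through communicability — the matrix exponential of the
supra matrix, which weights every walk between two node copies by the
reciprocal factorial of its length — and collapses the h×h grid of
communicability blocks into a single n×n integrated network by a
harmonic-mean-style pooling of the per-block entries.  Simpler
direct-path aggregations (mean / min / max over layers of one- and
two-step paths) and the plain edge-union aggregate are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .data_model import DiseaseID
from .layer_builder import DiseaseLayer

__all__ = [
    "MultiplexNetwork",
    "SupraMatrix",
    "CommunicabilityBlocks",
    "UndefinedFusionWarning",
    "build_supra",
    "r_direct",
    "communicability",
    "integrated_communicability",
    "aggregate_union",
]


class UndefinedFusionWarning(UserWarning):
    """A communicability block entry was nonpositive; its fused value is NaN."""


@dataclass
class MultiplexNetwork:
    """Ordered layers on one shared disease set + interlayer strengths.

    ``omega`` may be given as a scalar (uniform coupling) or a symmetric
    h×h matrix with entries in [0, 1]; the diagonal is unused.
    """

    layers: list[DiseaseLayer]
    omega: float | np.ndarray = 0.5

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a multiplex needs at least one layer")
        nodes = self.layers[0].nodes
        for layer in self.layers[1:]:
            if layer.nodes != nodes:
                raise ValueError(
                    f"layer {layer.name!r} does not share the node order of "
                    f"layer {self.layers[0].name!r}"
                )
        h = len(self.layers)
        if np.isscalar(self.omega):
            w = float(self.omega)
            if not 0.0 <= w <= 1.0:
                raise ValueError("omega must lie in [0, 1]")
            self.omega = np.full((h, h), w)
        else:
            om = np.asarray(self.omega, dtype=float)
            if om.shape != (h, h):
                raise ValueError(f"omega matrix must be {h}x{h}, got {om.shape}")
            if not np.allclose(om, om.T):
                raise ValueError("omega matrix must be symmetric")
            if om.min() < 0.0 or om.max() > 1.0:
                raise ValueError("omega entries must lie in [0, 1]")
            self.omega = om

    @property
    def n_nodes(self) -> int:
        return len(self.layers[0].nodes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def nodes(self) -> list[DiseaseID]:
        return self.layers[0].nodes


@dataclass
class SupraMatrix:
    """The (n·h)×(n·h) supra-adjacency matrix of a multiplex.

    Node p in layer i sits at flat index p + n·i; block (i, j) is the
    layer adjacency A_i when i = j and ω_ij·I otherwise.
    """

    matrix: np.ndarray
    n_nodes: int
    n_layers: int

    def block(self, i: int, j: int) -> np.ndarray:
        n = self.n_nodes
        return self.matrix[i * n : (i + 1) * n, j * n : (j + 1) * n]


@dataclass
class CommunicabilityBlocks:
    """exp(supra matrix), viewed as an h×h grid of n×n blocks."""

    matrix: np.ndarray
    n_nodes: int
    n_layers: int

    def block(self, i: int, j: int) -> np.ndarray:
        n = self.n_nodes
        return self.matrix[i * n : (i + 1) * n, j * n : (j + 1) * n]


def build_supra(mux: MultiplexNetwork) -> SupraMatrix:
    """Assemble the supra-adjacency block matrix of the multiplex."""
    n, h = mux.n_nodes, mux.n_layers
    m = np.zeros((n * h, n * h))
    eye = np.eye(n)
    for i in range(h):
        for j in range(h):
            blk = mux.layers[i].weights if i == j else mux.omega[i, j] * eye
            m[i * n : (i + 1) * n, j * n : (j + 1) * n] = blk
    return SupraMatrix(matrix=m, n_nodes=n, n_layers=h)


def r_direct(
    mux: MultiplexNetwork, p: DiseaseID, q: DiseaseID, mode: str = "mean"
) -> float:
    """Direct-path similarity of nodes p and q across all layers.

    Each layer i contributes its within-layer weight M|p_i q_i plus the
    two-step path weights M²|p_i q_j into every other layer j.  mode
    'mean' divides the summed contributions by h²; 'min'/'max' return the
    extreme per-layer contribution undivided.
    """
    if mode not in {"mean", "min", "max"}:
        raise ValueError(f"unknown mode {mode!r}; use 'mean', 'min' or 'max'")
    supra = build_supra(mux)
    nodes = mux.nodes
    pi = nodes.index(p) if p in nodes else -1
    qi = nodes.index(q) if q in nodes else -1
    if pi < 0 or qi < 0:
        raise KeyError(f"node {p if pi < 0 else q} not in the multiplex")
    n, h = mux.n_nodes, mux.n_layers
    m = supra.matrix
    m2 = m @ m
    terms = []
    for i in range(h):
        inner = m[pi + n * i, qi + n * i]
        for j in range(h):
            if j != i:
                inner += m2[pi + n * i, qi + n * j]
        terms.append(inner)
    if mode == "mean":
        return float(sum(terms) / h**2)
    return float(min(terms) if mode == "min" else max(terms))


def communicability(s: SupraMatrix) -> CommunicabilityBlocks:
    """Matrix exponential of the supra matrix.

    Equals the walk series Σ_k M^k / k!, so entry (p_i, q_j) counts every
    route between the two node copies, long walks discounted factorially.
    """
    if not np.all(np.isfinite(s.matrix)):
        raise ValueError("supra matrix entries must be finite")
    return CommunicabilityBlocks(
        matrix=expm(s.matrix), n_nodes=s.n_nodes, n_layers=s.n_layers
    )


def integrated_communicability(
    c: CommunicabilityBlocks, strict_harmonic: bool = False
) -> np.ndarray:
    """Collapse the h×h communicability blocks into one n×n fused network.

    For each node pair (p, q) the h² block entries [C_ij]_pq are pooled
    reciprocally:

        Ĉ_pq = h / ( Σ_i 1/[C_ii]_pq + Σ_{j≠k} 1/[C_jk]_pq )

    ``strict_harmonic=True`` replaces the numerator h with h², making the
    pool an exact harmonic mean of the h² entries.  The diagonal is
    forced to zero.  A nonpositive block entry (e.g. a disconnected pair
    under ω = 0) makes that pair's fusion undefined: the entry becomes
    NaN and an :class:`UndefinedFusionWarning` is emitted.
    """
    n, h = c.n_nodes, c.n_layers
    numerator = float(h * h if strict_harmonic else h)
    fused = np.zeros((n, n))
    bad_pairs = 0
    blocks = [[c.block(i, j) for j in range(h)] for i in range(h)]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            entries = [blocks[i][j][p, q] for i in range(h) for j in range(h)]
            if any(e <= 0.0 for e in entries):
                fused[p, q] = np.nan
                bad_pairs += 1
                continue
            fused[p, q] = numerator / sum(1.0 / e for e in entries)
    if bad_pairs:
        warnings.warn(
            f"{bad_pairs} node pair(s) had nonpositive communicability block "
            "entries; their fused values are NaN",
            UndefinedFusionWarning,
            stacklevel=2,
        )
    return fused


def aggregate_union(mux: MultiplexNetwork) -> DiseaseLayer:
    """Edge-union aggregate: an edge is present when any layer has it.

    The weight of an edge present in several layers is the maximum over
    layers, which keeps weights inside [0, 1].
    """
    stacked = np.stack([layer.weights for layer in mux.layers])
    return DiseaseLayer(
        name="aggregate", nodes=list(mux.nodes), weights=stacked.max(axis=0)
    )
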