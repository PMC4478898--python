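"""Relative risk and ϕ-correlation from patient–diagnosis records.

Two diseases are comorbid when they affect the same patients more often
than their independent prevalences predict.  With N patients, prevalence
counts P_i, P_j and co-occurrence count C_ij:

    RR_ij  = C_ij · N / (P_i · P_j)
    ϕ_ij   = (C_ij · N − P_i · P_j) / √(P_i P_j (N − P_i)(N − P_j))

RR compares observed co-occurrence with the random expectation; ϕ is the
Pearson correlation of the two binary diagnosis indicators and measures
the robustness of the association.  Whenever both are defined they agree
in the direction of dependence: RR > 1 exactly when ϕ > 0.

``comorbidity_map`` assembles a seed disease's significant partners:
RR above a floor and a one-sided Fisher exact test on the 2×2
co-occurrence table, Benjamini–Hochberg adjusted across the partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .association_scores import UndefinedScoreError, bh_fdr
from .data_model import DiseaseID, PatientRecords

__all__ = [
    "ComorbidityStatistics",
    "relative_risk",
    "phi_correlation",
    "comorbidity_map",
]


@dataclass(frozen=True)
class ComorbidityStatistics:
    """Comorbidity summary for one disease pair."""

    disease_i: DiseaseID
    disease_j: DiseaseID
    cooccurrence: int
    relative_risk: float
    phi: float
    p_value: float
    p_adjusted: float
    significant: bool


def relative_risk(records: PatientRecords, i: DiseaseID, j: DiseaseID) -> float:
    """Observed co-occurrence over prevalence-based expectation."""
    n = records.n_patients
    p_i = records.prevalence_count(i)
    p_j = records.prevalence_count(j)
    if n == 0 or p_i == 0 or p_j == 0:
        raise UndefinedScoreError(f"relative risk undefined: zero prevalence for {i} or {j}")
    return records.cooccurrence_count(i, j) * n / (p_i * p_j)


def phi_correlation(records: PatientRecords, i: DiseaseID, j: DiseaseID) -> float:
    """Pearson correlation of the two binary diagnosis indicators."""
    n = records.n_patients
    p_i = records.prevalence_count(i)
    p_j = records.prevalence_count(j)
    if not (0 < p_i < n and 0 < p_j < n):
        raise UndefinedScoreError(
            f"phi undefined: degenerate prevalence for {i} or {j} (all or no patients)"
        )
    c_ij = records.cooccurrence_count(i, j)
    return (c_ij * n - p_i * p_j) / math.sqrt(
        p_i * p_j * (n - p_i) * (n - p_j)
    )


def _fisher_one_sided(records: PatientRecords, i: DiseaseID, j: DiseaseID) -> float:
    """One-sided Fisher exact p-value for over-co-occurrence of i and j."""
    n = records.n_patients
    p_i = records.prevalence_count(i)
    p_j = records.prevalence_count(j)
    c = records.cooccurrence_count(i, j)
    table = [[c, p_i - c], [p_j - c, n - p_i - p_j + c]]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def comorbidity_map(
    records: PatientRecords,
    seed: DiseaseID,
    min_rr: float = 1.0,
    alpha: float = 0.05,
) -> list[ComorbidityStatistics]:
    """Significant comorbidity partners of ``seed``.

    Every other disease in the records is tested; a partner is kept when
    its relative risk exceeds ``min_rr`` AND its BH-adjusted one-sided
    Fisher p-value is below ``alpha``.  Results are sorted by relative
    risk descending, ties broken by disease code.
    """
    diseases = records.diseases()
    if seed not in diseases:
        raise KeyError(f"seed disease {seed} absent from the patient records")

    partners = [d for d in diseases if d != seed]
    tested: list[tuple[DiseaseID, int, float, float, float]] = []
    pvals: list[float] = []
    for j in partners:
        try:
            rr = relative_risk(records, seed, j)
            phi = phi_correlation(records, seed, j)
        except UndefinedScoreError:
            continue
        p = _fisher_one_sided(records, seed, j)
        tested.append((j, records.cooccurrence_count(seed, j), rr, phi, p))
        pvals.append(p)

    adjusted = bh_fdr(pvals)
    out = [
        ComorbidityStatistics(
            disease_i=seed,
            disease_j=j,
            cooccurrence=c,
            relative_risk=rr,
            phi=phi,
            p_value=p,
            p_adjusted=p_adj,
            significant=(rr > min_rr and p_adj < alpha),
        )
        for (j, c, rr, phi, p), p_adj in zip(tested, adjusted)
    ]
    kept = [s for s in out if s.significant]
    kept.sort(key=lambda s: (-s.relative_risk, s.disease_j.code))
    return kept
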