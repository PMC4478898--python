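# Methods

## Scope and model

`comorbnet` estimates disease–disease association from three families of
evidence and integrates them.

**Shared-entity scores.** Each evidence type (gene, SNP, CNV, miRNA, GO
term, HPO term, environmental factor, pathway) is a bipartite relation
between diseases and entities with pure set semantics: duplicate rows
collapse, row order never affects a score, and a disease absent from a
table simply has an empty profile. The pairwise scores are the shared
count, the Jaccard index, the product-normalized similarity
|∩|/(|G_i|·|G_j|), the Adamic–Adar sum Σ 1/log deg(n) over shared
entities, and the interaction score log(n_ij·N + Z) − log(|G_i|·|G_j| + Z).
Notes on the less standard ones:

- The product-normalized similarity uses the *plain product* of the two
  profile sizes in the denominator, not its square root, so it is not
  bounded by 1. A cosine-like variant would divide by the geometric
  mean; we keep the plain product as the definitional form and expose
  the Jaccard index for a bounded alternative.
- Adamic–Adar entities of bipartite degree 1 would divide by
  log(1) = 0; following the standard convention they are excluded via a
  configurable minimum degree (default 2).
- The interaction score's pseudocount Z (default 1) makes the all-zero
  case exactly 0 and guards the logs; its sign separates over- from
  under-represented pairs. All logarithms default to base e and the
  base is configurable; only relative and sign behaviour is consumed
  downstream.

**Enrichment.** Over-representation is tested with the one-sided
hypergeometric tail P(X ≥ k), evaluated through the survival function
rather than 1 − CDF so that p-values far below 1e-12 retain relative
precision; the finite-sum textbook form is kept in the test suite as an
exhaustive enumeration oracle for every universe size up to 12.
Multiple testing uses Benjamini–Hochberg step-up adjustment; both raw
and adjusted p-values are reported and the default significance level
is 0.05 applied after adjustment.

**Ontology semantics.** Terms are compared by max-propagated S-values
over the ancestral closure: S_a(a) = 1 and S_a(t) = max over children
t′ of t (within the closure of a) of w_e·S_a(t′). The recursion is
deliberately restricted to the anchor's own sub-DAG; children outside
it cannot contribute. Contribution factors are w_is_a = 0.8 and
w_part_of = 0.6 — the conventional choices for this family of measures
— and are configurable per relation. Set-level similarity follows the
best-match reading: each term of one set is matched with its most
similar term of the other, both directions pooled over |A| + |B|.
Self-similarity is returned as exactly 1.0 (numerator and denominator
coincide term by term; short-circuiting avoids a one-ulp float
artifact). OBO input is parsed with `obonet`, keeping only `is_a` and
`part_of` edges and dropping obsolete terms; a cyclic input is rejected
naming a term on the cycle.

**Phenotype similarity.** Phenotype records are weighted concept
vectors compared by cosine similarity; weights may be binary or
frequencies. Disease-level similarity over multiple phenotypic
features is the best-match average with a pluggable feature kernel,
symmetrized as the mean of the two directed averages. A
percentile-based edge threshold (default: keep scores above the 95th
percentile) is the declared rule for drawing phenotype-layer edges
when no absolute cutoff is given.

**Clinical comorbidity.** Diagnoses are per-patient sets: no visit
multiplicity, no temporal ordering. Relative risk RR = C·N/(P_i·P_j)
and the ϕ-correlation (Pearson correlation of the binary indicator
vectors) are computed from counts; both are undefined (raised as a
typed signal, never silently zero) at zero or degenerate prevalence.
A seed's comorbidity map keeps partners with RR above a floor
(default 1) and a BH-adjusted one-sided Fisher exact p-value below
0.05 — the exact-test gate is our declared choice of what "notably
greater than random expectation" means, consistent with the enrichment
machinery elsewhere in the package.

**Layer building.** One generic builder covers all evidence types: an
edge appears when two diseases share at least k entities (default 1),
optionally gated by the BH-adjusted hypergeometric overlap test, and
is weighted by the recipe's score. Presets: GO/HPO layers use the
semantic best-match average (degrading to Jaccard when no ontology is
supplied, since semantic weights need a DAG); SNP/CNV/miRNA/ENV/gene
layers use Jaccard with the enrichment gate at 0.05. Weights are
normalized into [0, 1] before multiplex use — 'minmax' (affine over
the present edges; an all-equal layer maps to 1) by default, 'max'
(divide by the maximum) or 'none' as alternatives. Note that minmax
maps the weakest edge to 0, effectively dropping it; 'max' preserves
all edges and is preferable for layers whose scores are already
positive.

**Multiplex fusion.** h layers sharing one node list of size n stack
into the (n·h)×(n·h) supra-adjacency matrix with layer adjacencies on
the diagonal blocks and ω_ij·I off it; ω is symmetric, in [0, 1], and
defaults to a uniform 0.5 — the midpoint of the dependence scale —
when not supplied. Communicability is the matrix exponential of the
supra matrix, computed by scipy's scaling-and-squaring and contracted
(in tests) to match a truncated power series to 1e-10. The integrated
network pools, for each node pair, the h² communicability block
entries reciprocally with numerator h. A strict harmonic mean of h²
terms would use numerator h²; the as-written form (numerator h) is the
default for fidelity to the method's definition, and
`strict_harmonic=True` switches to the h² numerator. Under the default
form, h identical decoupled layers with constant block entry c fuse to
c/h rather than c. With ω ≡ 0 the cross-layer blocks of the
exponential are exactly zero and the reciprocal pooling is undefined;
affected pairs are reported as NaN with a warning rather than raising.
Direct-path aggregation (mean over h² of one-step within-layer plus
two-step cross-layer path weights, or the min/max of the per-layer
terms) and the plain edge-union aggregate (weight = max across layers,
preserving [0, 1]) are provided as simpler alternatives.

## Synthetic data

The fixtures module emulates every input: bipartite tables with
*constructively planted* pairwise overlaps (a dedicated entity block
per planted pair, private padding up to the profile size), patient
cohorts with planted relative risks (C = round(RR·P_i·P_j/N) carriers
of both diseases placed exactly; infeasible targets raise), rooted
is_a ontology trees with optional part_of cross-links, and a built-in
three-layer, ten-disease multiplex whose disease 572 shares no pathway
with the other nine (its pathway row is zero) — the worked integration
example. Default cohort: 100 patients at 10% prevalence per disease;
default profiles: 5 entities per disease. Any patient left without a
diagnosis receives a neutral filler code (ICD-9 "799") so that the
patient count survives a TSV round-trip; the filler never belongs to a
planted pair.

Because planting is exact, scores on fixtures recover planted targets
deterministically; background diagnoses are independent Bernoulli
draws from a seeded generator, so everything is bit-reproducible.
What the fixtures do **not** emulate: realistic prevalence
distributions (real cohorts are heavy-tailed), correlated background
comorbidity, annotation bias in evidence tables, and ontology DAGs of
realistic depth and multiple parentage. Passing tests therefore
demonstrate correctness of the computations, not performance of the
scores on real clinical or omics data.

## Identifier handling

ICD-9-CM codes are validated as 3-character categories (numeric, V- or
E-prefixed) with optional 1–2 digit decimal subdivisions, and can be
truncated to category resolution for category-level layers; OMIM ids
are 6-digit strings. V/E codes are accepted by the validator though no
worked example exercises them. Cross-maps are many-to-many; unmapped
ids are dropped with a logged warning, never silently and never
fatally.

## Numerical and interface choices

- Undefined scores (empty profiles, zero prevalence) raise a typed
  `UndefinedScoreError`; callers decide between dropping the pair and
  substituting zero. Layer building drops such pairs.
- Network round-trips are set-exact: TSV weights are written with
  `repr` so a read-back reproduces them to the last bit; GraphML goes
  through networkx.
- The test and acceptance problem sizes (universes ≤ 12 for the
  exhaustive enrichment oracle, supra matrices ≤ 30×30, cohorts of
  ~100 patients, 50–100 randomized replicates for the oracle
  comparisons) were chosen as the smallest sizes that still exercise
  every code path and keep the whole suite in the seconds range.
- CLI exit codes: 2 for usage errors (bad option, missing file), 3 for
  empty or unmatched id lists, 4 for malformed input files.

## Known limitations

- The integrated-communicability pooling is O(n²·h²) in Python loops;
  fine for the hundreds-of-diseases scale it targets, not for
  genome-wide node sets.
- Phenotype→gene→disease propagation weights and any learned
  importance weighting are out of scope; the phenotype module consumes
  precomputed association tables only.
- Disease trajectories (time-ordered comorbidity) and survival
  prediction are out of scope.
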