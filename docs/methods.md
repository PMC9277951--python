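# Methods

This note documents the models, defaults and design choices behind the
package, in the spirit of a statistical-methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Phenotype and mid-parent heterosis

K⁺ content is percent of dry weight, (C·V)/(G·10⁶)·100, from the assay
concentration C in ppm, digest volume V in mL and dry sample weight G in g.
Mid-parent heterosis is MPH(%) = 100·(F₁ − MP)/MP with MP the arithmetic
mean of the two parental means. Replicates are aggregated by arithmetic
mean *before* the formula; field studies typically report plot-replicate
means and no alternative aggregation is standard. MPH is symmetric in the
parents and invariant to rescaling the trait. A zero or negative mid-parent
mean raises an error rather than flipping sign — K⁺ content and biomass are
non-negative, so this branch is unreachable in normal use. The strongest /
weakest screen is an argmax/argmin of MPH at one timepoint and trait, with
lexicographic tie-breaks for determinism. A one-way ANOVA p-value across
genotypes is provided as a convenience only; it is *not* a multiple range
test and is labelled as such.

## Synthetic data: what it emulates, what it does not

The simulator produces the statistical skeleton of a two-parent/F1 RNA-seq
experiment: gene-level counts, NB-distributed with variance μ + αμ², three
replicates per role, with genes planted in the twelve expression patterns.
Planted geometry per gene with base mean μ₀ and planted effect e (log₂):

- unequal parents sit at μ₀·2^(±e/2) (a full e apart);
- additive hybrids at the arithmetic mid-parent of the two parental means;
- dominant hybrids exactly at one parental mean;
- transgressive hybrids a further factor 2^e beyond the nearer parent.

Defaults and why:

- `n_reps = 3` — the design every trio RNA-seq study of this kind uses.
- `dispersion = 0.02` — biological CV ≈ 14 %, the regime of bulk RNA-seq on
  pooled plot samples (pooling several plants suppresses plant-to-plant
  variability). Chosen, together with the base-mean range, by an a-priori
  power calculation: the half-effect contrasts that separate additive and
  dominant patterns (|log₂FC| = 0.678 when e = 2) must be detectable at
  n = 3 without making the full-effect contrasts trivial.
- `base_mean_log_range = (ln 50, ln 2000)` — log-uniform expression of
  moderately to highly expressed genes, the stratum from which DEG
  classification actually draws; very low counts are handled by the DE
  filter instead.
- `effect_log2fc = 2.0` — a four-fold parental difference, large enough to
  be called reliably at n = 3, small enough that the derived half-effects
  are non-trivial.
- pattern mixture: 70 % null genes (exercises the DEG funnel), and the
  remaining 30 % split 6 / 7.2 / 16.8 between additive, dominant and
  overdominant so the planted overdominant share of non-additive genes is
  0.70; the weak-cross driver uses a 0.57 share. These are the study
  conditions every downstream recovery test refers to.

Not emulated: read-level artifacts (GC/length bias, mapping ambiguity),
per-gene dispersion variation, correlated genes, batch effects, and
annotation incompleteness. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under its own model, not
robustness to those real-data pathologies.

The phenotype generator plants an exact MPH per hybrid (noiseless F1 value
MP·(1 + MPH/100)) plus additive Gaussian replicate noise; `noise_sd` is a
free parameter, not an estimate of any particular study's measurement
error. Hybrid names encode their parents (`A×B` or `AxB`). The GO generator
assigns terms independently per gene (base probability 0.05), raising the
probability to 0.6 on a designated target set for "enriched" terms; the
homology generator gives every subject one strong hit and, with probability
½, a decoy failing at least one threshold; the Ct generator encodes a
planted log₂ fold change as a Ct shift of the same magnitude.

## Differential expression

The DE stage is deliberately self-contained and simple enough to validate
by simulation, rather than a re-implementation of any published tool's
estimators:

- **Normalization**: median-of-ratios against the per-gene geometric-mean
  reference, restricted to genes positive in all samples; factors rescaled
  to geometric mean 1. Errors name any all-zero sample.
- **Virtual mid-parent**: parent replicates are paired by index; each MP
  replicate is the arithmetic mean of one ♀ and one ♂ replicate on the
  normalized scale, rounded half-to-even back to integers, size factor 1.
  Building MP as explicit samples (rather than a model contrast) keeps the
  hybrid-vs-MP comparison structurally identical to the other contrasts.
- **Test**: per gene, log₂FC on group means of normalized counts with
  pseudo-count ½. Dispersion by method of moments from pooled within-group
  variances, floored at 1e−8, then shrunk 50 % toward a trended
  α(μ) = a₀ + a₁/μ least-squares fit (coefficients clipped at 0). Wald
  statistic = log₂FC / SE with the delta-method SE under the NB variance;
  two-sided p from the normal reference; BH adjustment over tested genes.
  Genes with fewer than 10 raw counts total across both groups are not
  tested.
- **Calling**: `up`/`down` require significance (raw p by default; adjusted
  p optional) *and* |log₂FC| ≥ 1. The fold threshold of 1 matches the DEG
  counts reported for this design; a stricter threshold of 2 circulates in
  some method descriptions and is exposed as a parameter.

Calibration is checked by simulation, not assumed: on all-null NB data
(10 000 genes, n = 3) the fraction of raw p ≤ 0.05 must lie in 0.05 ± 0.02,
and with planted |log₂FC| = 2 at μ = 500 sensitivity must reach 0.9 with
empirical FDR ≤ 0.1. The moment estimator at n = 3 is noisy and its floor
is asymmetric, which the 50 % trend shrinkage largely repairs; the residual
mild anti-conservatism (measured ≈ 0.06 at nominal 0.05) is within the
stated band.

## Pattern classification

The rule table over the four calls (hybrid-vs-♀ = c₁, hybrid-vs-♂ = c₂,
hybrid-vs-MP = c_MP, ♀-vs-♂ = c_PP) is this package's normative definition
of the twelve patterns:

| condition | pattern |
|---|---|
| c₁ = c₂ = ns | unclassified |
| c₁ = c₂ = down | P7 / P8 / P9 by c_PP ∈ {up, ns, down} |
| c₁ = c₂ = up | P10 / P11 / P12 by c_PP ∈ {down, ns, up} |
| c₁, c₂ opposite, c_MP = ns | P1 (♀ high) / P2 (♂ high) |
| exactly one of c₁, c₂ ns, c_MP ≠ ns | P3/P4 (hybrid = ♀, above/below ♂), P5/P6 (hybrid = ♂, above/below ♀) |
| anything else | conflicting |

The mid-parent call separates additive from dominant; for transgressive
genes it is intentionally ignored (transgression is determined by the two
parental comparisons alone). Inconsistent combinations — e.g.
additive-shaped but with a significant mid-parent shift — are recorded as
`conflicting` rather than forced into a bin, and conflicting/unclassified
genes never enter proportions. The table is total and single-valued over
all 3⁴ = 81 call combinations, verified against an independently written
oracle.

**DEG gate.** Classification operates on the DEG universe: genes called in
at least one of the four contrasts at the full thresholds (p ≤ 0.05,
|log₂FC| ≥ 1). Within that universe the four calls are taken
significance-only (no fold filter), because the additive and dominant
sub-effects sit at half the parental effect and a fold filter of 1 would
empty those classes by construction. Without the gate, null genes leak into
the dominant class through the correlated hybrid-vs-parent and
hybrid-vs-MP tests and bias the overdominant share downward; with it, the
planted share of 0.70 is recovered to within ±0.05 (checked over 20
simulations).

## Enrichment

One-sided over-representation only: p = P(X ≥ k) for X hypergeometric,
summed in log space (logpmf + logsumexp) so deep tails keep relative
precision (verified to < 1e−12 against exact rational enumeration for
N ≤ 200). Bonferroni multiplies by the number of *tested* terms — terms
with at least one set hit and background count K in [2, N/2]; testing only
hittable terms is a documented choice, as is Bonferroni itself rather than
FDR. Optional annotation propagation follows an is_a/part_of parent map
transitively (cycles rejected); full ontology parsing (obsolete terms,
relationship types) is out of scope. The default background is the set of
annotated genes present in the count matrix.

## Gene families

Query coverage is computed on the query: 100·(q_end − q_start + 1)/q_len,
because the queries are the characterized reference proteins whose span
should be matched; subject coverage would reward long subject sequences.
All three thresholds are strict inequalities, exactly as printed conditions
of the form "E-value < 1e−25, identity > 30, coverage > 30" demand; values
exactly at a threshold are dropped. Multiple HSPs per query–subject pair
are not merged — the best single HSP must pass (a documented
simplification). One family per subject, decided by bit score, then lower
E-value, then lexicographic query id. Phylogenetic verification is outside
the package; a candidate-id list is emitted for external tree building.

## qPCR

2^−ΔΔCt with amplification efficiency fixed at 2, replicates averaged on
the Ct scale before differencing (standard practice). Concordance with
RNA-seq reports the sign-agreement fraction (values within 1e−9 of zero
agree with anything) and the Spearman rank correlation over shared genes
(≥ 3 required). The control condition is an explicit argument — which
condition served as the reference in any given figure is a user decision.

## Orchestration and numerical conventions

The pipeline writes plain TSV everywhere plus one JSON summary; every
output carries a provenance header (package version, configuration hash,
seed). It draws no random numbers itself, so identical inputs and
configuration give byte-identical summaries. Stage failures abort with the
stage named; stages can be skipped by name. Floats round-trip through TSV
(`float_precision="round_trip"` on read). Ties anywhere (screening,
family assignment, enrichment ordering) break lexicographically so all
outputs are deterministic.

Problem sizes used by the shipped analyses and checks — 6 000-gene
matrices for the worked example, 10 000 genes for the null calibration,
20 000-gene simulations across 20 seeds for share recovery — were chosen
so every planted quantity is estimated with Monte-Carlo error well inside
the tolerance it is compared at.

## Known limitations

- The NB test is a plain Wald test; at n = 2 replicates it will be
  appreciably anti-conservative, and no continuity/t correction is applied.
- The trended dispersion fit is unweighted least squares on raw moment
  estimates; with very few tested genes it falls back to the median.
- The classifier inherits the DEG thresholds' arbitrariness; patterns near
  decision boundaries move between neighbouring bins under threshold
  changes (never between the two transgressive directions).
- Bonferroni over hittable terms is conservative when annotations overlap
  heavily (GO's DAG structure guarantees they do once propagated).
- The 2^−ΔΔCt model ignores amplification-efficiency deviations from 2.
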