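# kheterosis

Tools for dissecting **heterosis** (hybrid vigour) of leaf potassium content
in crop crosses at the transcriptome level. The package targets the standard
parent–parent–F1 ("trio") design: it screens hybrids for mid-parent
heterosis of K⁺ content, tests trio differential expression with a
self-contained negative-binomial model, classifies differentially expressed
genes into the twelve additive / dominant / overdominant expression
patterns, scores GO-term over-representation of the pattern gene sets,
identifies K⁺ channel/transporter family members from homology-search
tables, and checks RNA-seq fold changes against qPCR by the 2^−ΔΔCt method.
A synthetic-data module generates every input with planted ground truth, so
each stage is testable end to end without any external download.

## The statistics at the core

**Mid-parent heterosis.** For a hybrid with trait value F₁ and parents P₁,
P₂ (replicate means):

    MPH(%) = 100 · (F₁ − MP) / MP,   MP = (P₁ + P₂) / 2

K⁺ content is computed from flame-photometer readings as
K⁺% = (C·V)/(G·10⁶)·100 for assay concentration C (ppm), volume V (mL) and
dry weight G (g).

**Trio differential expression.** Counts are normalized by median-of-ratios
size factors; virtual mid-parent samples are built as per-replicate averages
of the normalized parental counts. Per gene, a Wald test on
log₂((μ̂_A + ½)/(μ̂_B + ½)) under an NB model (variance μ + αμ²) with
moment-based dispersion shrunk 50 % toward a trended α(μ) = a₀ + a₁/μ fit;
DEGs are called at p ≤ 0.05 and |log₂FC| ≥ 1.

**Expression patterns.** Each DEG's four calls — hybrid vs ♀, hybrid vs ♂,
hybrid vs mid-parent, ♀ vs ♂ — map to one of 12 patterns: P1–P2 additive
(hybrid at the mid-parent level between unequal parents), P3–P6 dominant
(hybrid matching one parent), P7–P9 transgressive below both parents,
P10–P12 above both. The headline statistic is the overdominant (P7–P12)
share of non-additive (P3–P12) genes.

**Enrichment, families, qPCR.** Over-representation uses the one-sided
hypergeometric tail P(X ≥ k) with Bonferroni control over tested terms.
Family membership takes BLAST tabular hits passing E < 1e−25, identity
> 30 % and query coverage > 30 % (all strict), best bit score per subject.
qPCR relative expression is 2^−ΔΔCt against a reference gene.

## Worked example

The `analysis/` scripts run the whole study on simulated data with planted
structure (strong cross `G70xGDH11`, weak cross `K326xGDH11`):

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_phenotype_heterosis.py
python analysis/03_trio_differential_expression.py
python analysis/04_expression_patterns.py
python analysis/05_go_enrichment.py
python analysis/06_gene_families.py
python analysis/07_qpcr_validation.py
```

Typical output of steps 02 and 04:

```
G70xGDH11 (k_content_percent) day 70: F1=2.482 MP=2.226 MPH=11.46%
K326xGDH11 (k_content_percent) day 70: F1=1.961 MP=1.884 MPH=4.08%
screen at day 70: strongest=G70xGDH11, weakest=K326xGDH11

G70xGDH11: ... overdominant share of non-additive = 71.75%
  planted share 0.700, estimated 0.717
K326xGDH11: ... overdominant share of non-additive = 59.43%
  planted share 0.569, estimated 0.594
```

The noiseless phenotype replicates recover the planted day-70 MPH values
(9.93 % and 3.98 %) exactly; with measurement noise (here σ = 0.03 on a
K⁺ content of ≈2 %) the estimates move to 11.46 % and 4.08 % while the
strong/weak ranking is preserved. The pattern stage recovers each cross's
planted overdominant share to within about two percentage points.
`analysis/08_full_pipeline.py` runs the same stages through the
orchestration layer and writes a single `summary.json`.

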