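"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates negative-binomial count matrices for a parent-parent-hybrid trio
with genes planted in the twelve additive / dominant / overdominant
expression patterns, K+ phenotype time series with configurable mid-parent
heterosis, toy GO annotations with enriched terms, toy homology-hit tables,
and toy qPCR Ct tables. Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import CountMatrix, TrioDesign
from .phenotype import PhenotypeRecord

PATTERNS = tuple(f"P{i}" for i in range(1, 13))
NULL_PATTERN = "null"

# Grouped categories of the twelve patterns: P1-P2 additive (hybrid at the
# mid-parent level between unequal parents), P3-P6 dominant (hybrid matching
# one parent), P7-P9 transgressive below both parents, P10-P12 above both.
CATEGORY_OF_PATTERN = {
    "P1": "additive",
    "P2": "additive",
    "P3": "dominant",
    "P4": "dominant",
    "P5": "dominant",
    "P6": "dominant",
    "P7": "overdominant_down",
    "P8": "overdominant_down",
    "P9": "overdominant_down",
    "P10": "overdominant_up",
    "P11": "overdominant_up",
    "P12": "overdominant_up",
}


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


def default_pattern_proportions() -> dict[str, float]:
    """Default planted mixture: 70% null genes, and a 6 / 7.2 / 16.8 percent
    split of additive / dominant / overdominant so that the overdominant share
    of non-additive genes is 0.70."""
    props = {NULL_PATTERN: 0.70, "P1": 0.03, "P2": 0.03}
    for p in ("P3", "P4", "P5", "P6"):
        props[p] = 0.018
    for p in ("P7", "P8", "P9", "P10", "P11", "P12"):
        props[p] = 0.028
    return props


@dataclass
class SimulationConfig:
    """Knobs of the trio count simulator.

    ``dispersion`` is the NB shape parameter (variance = mu + mu^2 *
    dispersion); ``effect_log2fc`` the magnitude of planted parental and
    transgressive shifts; ``base_mean_log_range`` bounds (natural log) of the
    log-uniform base expression level.
    """

    n_genes: int = 20_000
    n_reps: int = 3
    pattern_proportions: dict[str, float] = field(default_factory=default_pattern_proportions)
    base_mean_log_range: tuple[float, float] = (math.log(50.0), math.log(2000.0))
    dispersion: float = 0.02
    effect_log2fc: float = 2.0
    seed: int = 0
    size_factors: Sequence[float] | None = None  # optional per-sample library-size skew

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimulationError("n_genes must be positive")
        if self.n_reps < 2:
            raise SimulationError("n_reps must be >= 2 (downstream tests need variance)")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.effect_log2fc <= 0:
            raise SimulationError("effect_log2fc must be positive")
        allowed = set(PATTERNS) | {NULL_PATTERN}
        bad = set(self.pattern_proportions) - allowed
        if bad:
            raise SimulationError(f"unknown patterns in proportions: {sorted(bad)}")
        vals = list(self.pattern_proportions.values())
        if any(v < 0 for v in vals):
            raise SimulationError("pattern proportions must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise SimulationError(f"pattern proportions sum to {sum(vals)}, not 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth expected counts for one gene."""

    gene_id: str
    true_pattern: str  # P1..P12 or "null"
    mu_female: float
    mu_male: float
    mu_hybrid: float

    @property
    def category(self) -> str:
        return CATEGORY_OF_PATTERN.get(self.true_pattern, "none")


def planted_means(pattern: str, base_mu: float, effect_log2fc: float) -> tuple[float, float, float]:
    """Expected (female, male, hybrid) counts for one planted pattern.

    Unequal parents sit a full ``effect_log2fc`` apart (half a shift each side
    of the base mean); transgressive hybrids sit ``effect_log2fc`` beyond the
    nearer parent; additive hybrids at the arithmetic mid-parent.
    """
    hi = base_mu * 2.0 ** (effect_log2fc / 2.0)
    lo = base_mu * 2.0 ** (-effect_log2fc / 2.0)
    step = 2.0**effect_log2fc
    if pattern == NULL_PATTERN:
        return base_mu, base_mu, base_mu
    if pattern == "P1":  # female high, hybrid at mid-parent
        return hi, lo, (hi + lo) / 2.0
    if pattern == "P2":  # male high, hybrid at mid-parent
        return lo, hi, (hi + lo) / 2.0
    if pattern == "P3":  # hybrid = female, above male
        return hi, lo, hi
    if pattern == "P4":  # hybrid = female, below male
        return lo, hi, lo
    if pattern == "P5":  # hybrid = male, above female
        return lo, hi, hi
    if pattern == "P6":  # hybrid = male, below female
        return hi, lo, lo
    if pattern == "P7":  # below both, female > male
        return hi, lo, lo / step
    if pattern == "P8":  # below both, parents equal
        return base_mu, base_mu, base_mu / step
    if pattern == "P9":  # below both, female < male
        return lo, hi, lo / step
    if pattern == "P10":  # above both, female < male
        return lo, hi, hi * step
    if pattern == "P11":  # above both, parents equal
        return base_mu, base_mu, base_mu * step
    if pattern == "P12":  # above both, female > male
        return hi, lo, hi * step
    raise SimulationError(f"unknown pattern {pattern!r}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, variance mu + dispersion*mu^2); Poisson in the dispersion->0 limit."""
    if dispersion < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_trio_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, TrioDesign, list[PlantedTruth]]:
    """Simulate one trio's count matrix with planted expression patterns.

    Pattern labels are assigned by deterministic proportional allocation
    (largest-remainder rounding of ``n_genes * proportion``), then counts are
    drawn independently per gene x replicate from a negative binomial with the
    planted means and the common dispersion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels_order = [NULL_PATTERN] + list(PATTERNS)
    props = {k: config.pattern_proportions.get(k, 0.0) for k in labels_order}
    raw = {k: config.n_genes * v for k, v in props.items()}
    counts_per = {k: int(math.floor(v)) for k, v in raw.items()}
    short = config.n_genes - sum(counts_per.values())
    by_rem = sorted(labels_order, key=lambda k: (raw[k] - counts_per[k], k), reverse=True)
    for k in by_rem[:short]:
        counts_per[k] += 1

    labels = np.repeat(
        [labels_order.index(k) for k in labels_order],
        [counts_per[k] for k in labels_order],
    )
    rng.shuffle(labels)

    lo, hi = config.base_mean_log_range
    base_mu = np.exp(rng.uniform(lo, hi, size=config.n_genes))

    n_digits = len(str(config.n_genes))
    gene_ids = [f"gene_{i:0{n_digits}d}" for i in range(1, config.n_genes + 1)]
    truth: list[PlantedTruth] = []
    mu = np.empty((config.n_genes, 3))  # columns: female, male, hybrid
    for i, (lab_idx, mu0) in enumerate(zip(labels, base_mu)):
        pat = labels_order[lab_idx]
        f, m, h = planted_means(pat, float(mu0), config.effect_log2fc)
        mu[i] = (f, m, h)
        truth.append(PlantedTruth(gene_ids[i], pat, f, m, h))

    n = config.n_reps
    sample_ids = (
        [f"female_{r + 1}" for r in range(n)]
        + [f"male_{r + 1}" for r in range(n)]
        + [f"hybrid_{r + 1}" for r in range(n)]
    )
    if config.size_factors is not None:
        sf = np.asarray(config.size_factors, dtype=float)
        if sf.shape != (3 * n,) or (sf <= 0).any():
            raise SimulationError(f"size_factors must be {3 * n} positive values")
    else:
        sf = np.ones(3 * n)

    mat = np.empty((config.n_genes, 3 * n), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        role_idx = j // n
        mat[:, j] = _nb_draw(rng, mu[:, role_idx] * sf[j], config.dispersion)

    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    design = TrioDesign(
        hybrid_id="hybrid",
        samples={
            "female": sample_ids[:n],
            "male": sample_ids[n : 2 * n],
            "hybrid": sample_ids[2 * n :],
        },
    )
    return CountMatrix(counts), design, truth


def parse_cross(genotype: str) -> tuple[str, str] | None:
    """Split a hybrid name of the form ``femalexmale`` (x or U+00D7); None for inbreds."""
    for sep in ("×", "x"):
        if sep in genotype:
            female, _, male = genotype.partition(sep)
            if female and male:
                return female, male
    return None


def simulate_phenotype(
    genotypes: Sequence[str],
    timepoints: Sequence[int],
    target_mph: Mapping[str, float],
    noise_sd: float,
    seed: int,
    trait: str = "k_content_percent",
    n_reps: int = 3,
    parent_value_range: tuple[float, float] = (1.5, 3.0),
) -> list[PhenotypeRecord]:
    """Phenotype records with planted mid-parent heterosis.

    Hybrid genotype names must encode their parents (``AxB`` or ``A×B``);
    parents get trait values drawn once per genotype x timepoint from
    ``parent_value_range``, and each hybrid's noiseless value is
    ``MP * (1 + target_mph/100)``. Replicate noise is additive Gaussian.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    inbreds = [g for g in genotypes if parse_cross(g) is None]
    hybrids = [g for g in genotypes if parse_cross(g) is not None]
    for h in hybrids:
        female, male = parse_cross(h)
        for p in (female, male):
            if p not in inbreds:
                raise SimulationError(f"hybrid {h!r} references unknown parent {p!r}")

    records: list[PhenotypeRecord] = []
    for t in timepoints:
        parent_value = {g: rng.uniform(*parent_value_range) for g in inbreds}
        for g in inbreds:
            reps = parent_value[g] + rng.normal(0.0, noise_sd, size=n_reps) if noise_sd > 0 else np.full(n_reps, parent_value[g])
            records.append(PhenotypeRecord(g, int(t), trait, list(reps)))
        for h in hybrids:
            female, male = parse_cross(h)
            mp = (parent_value[female] + parent_value[male]) / 2.0
            value = mp * (1.0 + target_mph.get(h, 0.0) / 100.0)
            reps = value + rng.normal(0.0, noise_sd, size=n_reps) if noise_sd > 0 else np.full(n_reps, value)
            records.append(
                PhenotypeRecord(h, int(t), trait, list(reps), female_parent=female, male_parent=male)
            )
    return records


def simulate_go_annotation(
    gene_ids: Sequence[str],
    n_terms: int,
    enriched_term_fraction: float,
    target_set: Sequence[str],
    seed: int,
    base_prob: float = 0.05,
    enriched_prob: float = 0.6,
) -> dict[str, set[str]]:
    """Toy gene -> GO-term annotation with terms enriched in a target set.

    A fraction ``enriched_term_fraction`` of the terms annotate members of
    ``target_set`` with probability ``enriched_prob`` instead of
    ``base_prob``; with fraction 0 the assignment is independent of set
    membership. Every term ends up annotating at least one gene.
    """
    if n_terms < 1:
        raise SimulationError("n_terms must be >= 1")
    gene_ids = list(gene_ids)
    missing = set(target_set) - set(gene_ids)
    if missing:
        raise SimulationError(f"target_set genes not in gene_ids: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    in_target = np.isin(gene_ids, list(target_set))
    n_enriched = int(round(enriched_term_fraction * n_terms))
    annotation: dict[str, set[str]] = {g: set() for g in gene_ids}
    for ti in range(n_terms):
        term = f"GO:{ti + 1:07d}"
        p = np.full(len(gene_ids), base_prob)
        if ti < n_enriched:
            p[in_target] = enriched_prob
        hit = rng.random(len(gene_ids)) < p
        if not hit.any():
            hit[rng.integers(len(gene_ids))] = True
        for g, h in zip(gene_ids, hit):
            if h:
                annotation[g].add(term)
    return annotation


def simulate_homology_hits(
    query_families: Mapping[str, str],
    n_subjects: int,
    seed: int,
    q_len: int = 300,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, str]]:
    """Toy BLAST-tabular hit table for family identification.

    Each subject gets one strong hit from a randomly chosen query (passes the
    stringent thresholds) plus, with probability 1/2, one weak decoy hit
    (fails at least one threshold). Returns (hits, query lengths, query->family).
    """
    rng = np.random.default_rng(seed)
    queries = list(query_families)
    qlen = {q: q_len for q in queries}
    rows = []
    for si in range(n_subjects):
        subject = f"Ntab_{si + 1:04d}"
        q = queries[rng.integers(len(queries))]
        span = int(q_len * rng.uniform(0.5, 0.95))
        start = int(rng.integers(1, q_len - span + 1))
        rows.append(
            dict(
                query_id=q,
                subject_id=subject,
                percent_identity=float(rng.uniform(40, 90)),
                alignment_length=span,
                mismatches=int(span * 0.1),
                gap_opens=1,
                q_start=start,
                q_end=start + span - 1,
                s_start=1,
                s_end=span,
                evalue=float(10.0 ** rng.uniform(-120, -30)),
                bit_score=float(rng.uniform(150, 600)),
            )
        )
        if rng.random() < 0.5:  # decoy failing a threshold
            q2 = queries[rng.integers(len(queries))]
            mode = rng.integers(3)
            span = int(q_len * (0.1 if mode == 2 else rng.uniform(0.4, 0.9)))
            rows.append(
                dict(
                    query_id=q2,
                    subject_id=subject,
                    percent_identity=float(rng.uniform(10, 25)) if mode == 1 else float(rng.uniform(35, 60)),
                    alignment_length=span,
                    mismatches=int(span * 0.5),
                    gap_opens=2,
                    q_start=1,
                    q_end=span,
                    s_start=1,
                    s_end=span,
                    evalue=float(10.0 ** rng.uniform(-20, -5)) if mode == 0 else float(10.0 ** rng.uniform(-120, -40)),
                    bit_score=float(rng.uniform(30, 100)),
                )
            )
    return pd.DataFrame(rows), qlen, dict(query_families)


def simulate_ct_table(
    gene_log2fc: Mapping[str, float],
    seed: int,
    n_reps: int = 3,
    noise_sd: float = 0.1,
    reference_gene: str = "Actin",
    test_sample: str = "hybrid",
    control_sample: str = "parent",
) -> pd.DataFrame:
    """Toy qPCR Ct table encoding planted log2 fold changes (test over control).

    A fold change of ``x`` lowers the target's test-condition Ct by ``x``
    cycles relative to control, the reference gene being constant. Columns:
    sample_id, gene_id, ct, is_reference.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample in (test_sample, control_sample):
        for _ in range(n_reps):
            rows.append(
                dict(
                    sample_id=sample,
                    gene_id=reference_gene,
                    ct=20.0 + rng.normal(0.0, noise_sd),
                    is_reference=True,
                )
            )
    for gene, lfc in gene_log2fc.items():
        base_ct = float(rng.uniform(24, 30))
        for sample, delta in ((test_sample, -lfc), (control_sample, 0.0)):
            for _ in range(n_reps):
                rows.append(
                    dict(
                        sample_id=sample,
                        gene_id=gene,
                        ct=base_ct + delta + rng.normal(0.0, noise_sd),
                        is_reference=False,
                    )
                )
    return pd.DataFrame(rows)
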