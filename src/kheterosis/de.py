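"""Trio differential expression for parent-parent-hybrid crosses.

Self-contained negative-binomial testing over gene-level count matrices:
median-of-ratios normalization, construction of virtual mid-parent samples,
a per-gene Wald test with moment-based dispersion estimation shrunk toward a
trended mean-dispersion fit, and threshold-based DEG calling for the four
contrasts of a cross (hybrid vs each parent, hybrid vs mid-parent, and
parent vs parent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROLES = ("female", "male", "hybrid")
CONTRASTS = ("H_vs_P1", "H_vs_P2", "H_vs_MP", "P1_vs_P2")

#: per-gene result columns emitted by :func:`nb_test` / :func:`call_degs`
DE_COLUMNS = ("gene_id", "contrast", "log2fc", "stat", "p", "padj", "call")


class DEError(ValueError):
    """Raised for invalid count matrices, designs, or test configurations."""


@dataclass
class CountMatrix:
    """Gene x sample expression counts with optional per-sample size factors.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample. Values must
        be finite and non-negative; raw input matrices are integral, virtual
        mid-parent columns are rounded back to integers on construction.
    size_factors
        Per-sample normalization factors (geometric mean 1), or ``None``
        before :func:`normalize` has run.
    """

    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DEError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise DEError(f"duplicate sample id: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise DEError("counts must be finite and non-negative")
        if self.size_factors is not None:
            sf = self.size_factors.reindex(self.counts.columns)
            if sf.isna().any() or (sf <= 0).any():
                raise DEError("size factors must be positive and cover all samples")
            self.size_factors = sf

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def normalized(self) -> pd.DataFrame:
        """Counts divided by size factors (requires prior normalization)."""
        if self.size_factors is None:
            raise DEError("matrix has no size factors; call normalize() first")
        return self.counts / self.size_factors


@dataclass
class TrioDesign:
    """Binds the samples of one cross to roles female / male / hybrid."""

    hybrid_id: str
    samples: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.samples]
        if missing:
            raise DEError(f"design for {self.hybrid_id!r} missing roles: {missing}")
        seen: set[str] = set()
        for role in ROLES:
            ids = list(self.samples[role])
            if len(ids) < 2:
                raise DEError(
                    f"role {role!r} of {self.hybrid_id!r} has {len(ids)} replicate(s); "
                    "at least 2 are required"
                )
            overlap = seen.intersection(ids)
            if overlap:
                raise DEError(f"samples assigned to multiple roles: {sorted(overlap)}")
            seen.update(ids)
        self.samples = {r: list(self.samples[r]) for r in ROLES}


@dataclass(frozen=True)
class DEResult:
    """One gene's outcome for one contrast (first group over second)."""

    gene_id: str
    contrast: str
    log2fc: float
    p: float
    padj: float
    call: str  # up / down / ns


def normalize(cm: CountMatrix) -> CountMatrix:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    Size factors are rescaled to geometric mean 1, so normalized values stay
    on the raw-count scale. Genes with a zero in any sample do not enter the
    reference (their log geometric mean is -inf).
    """
    counts = cm.counts
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise DEError(f"sample {bad!r} has all-zero counts")
    vals = counts.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise DEError("no gene has positive counts in every sample")
    logv = np.log(vals[all_pos])
    log_ref = logv.mean(axis=1)
    log_ratios = logv - log_ref[:, None]
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    sf = pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")
    return CountMatrix(counts, sf)


def build_mid_parent(cm: CountMatrix, design: TrioDesign) -> tuple[CountMatrix, list[str]]:
    """Append virtual mid-parent samples, one per parent replicate pair.

    Each mid-parent replicate is the arithmetic mean of one female and one
    male replicate on the normalized scale, rounded half-to-even back to an
    integer count. Parent replicates are paired by index up to the shorter
    list. The new columns get size factor 1.
    """
    if cm.size_factors is None:
        cm = normalize(cm)
    female = list(design.samples["female"])
    male = list(design.samples["male"])
    n_mp = min(len(female), len(male))
    if n_mp < 2:
        raise DEError(f"only {n_mp} mid-parent replicate(s) constructible for {design.hybrid_id!r}")
    norm = cm.normalized()
    mp_ids = [f"{design.hybrid_id}_MP_{i + 1}" for i in range(n_mp)]
    mp_vals = {
        mp_id: np.rint((norm[f].to_numpy() + norm[m].to_numpy()) / 2.0)
        for mp_id, f, m in zip(mp_ids, female, male)
    }
    mp_df = pd.DataFrame(mp_vals, index=cm.gene_ids)
    counts = pd.concat([cm.counts, mp_df], axis=1)
    sf = pd.concat([cm.size_factors, pd.Series(1.0, index=mp_ids)])
    return CountMatrix(counts, sf), mp_ids


def _trend_fit(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of disp ~ a0 + a1/mean, coefficients clipped at 0."""
    keep = (mean > 1.0) & (disp > 1e-7)
    if keep.sum() < 10:
        return float(np.clip(np.median(disp), 1e-8, None)), 0.0
    x = 1.0 / mean[keep]
    y = disp[keep]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a0 = float(max(coef[0], 0.0))
    a1 = float(max(coef[1], 0.0))
    if a0 == 0.0 and a1 == 0.0:
        a0 = float(np.clip(np.median(y), 1e-8, None))
    return a0, a1


def nb_test(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast: str = "A_vs_B",
    pseudo: float = 0.5,
    min_total: int = 10,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test of group A over group B.

    For each gene the log2 fold change is ``log2((meanA + c) / (meanB + c))``
    on normalized counts with pseudo-count ``c``. The NB dispersion (variance
    ``mu + alpha * mu^2``) is estimated per gene by method of moments from the
    within-group variances, floored at 1e-8, and shrunk 50% toward a trended
    ``a0 + a1/mu`` fit across genes. The Wald statistic divides the log2 fold
    change by its delta-method standard error under the NB model; p-values are
    two-sided from the normal reference and BH-adjusted over tested genes.
    Genes with fewer than ``min_total`` raw counts summed over both groups are
    excluded from testing.

    Returns a DataFrame with columns log2fc, stat, p, padj, call (all 'ns';
    see :func:`call_degs`) indexed by gene id.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise DEError("each group needs at least 2 samples")
    if cm.size_factors is None:
        cm = normalize(cm)
    norm = cm.normalized()
    ya = norm[group_a].to_numpy(dtype=float)
    yb = norm[group_b].to_numpy(dtype=float)
    raw_total = cm.counts[group_a + group_b].sum(axis=1).to_numpy()
    tested = raw_total >= min_total
    na, nb = ya.shape[1], yb.shape[1]

    mean_a, mean_b = ya.mean(axis=1), yb.mean(axis=1)
    var_a, var_b = ya.var(axis=1, ddof=1), yb.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = np.where(mean_a > 0, (var_a - mean_a) / mean_a**2, 0.0)
        disp_b = np.where(mean_b > 0, (var_b - mean_b) / mean_b**2, 0.0)
    disp_mom = ((na - 1) * disp_a + (nb - 1) * disp_b) / (na + nb - 2)
    disp_mom = np.clip(disp_mom, 1e-8, None)

    overall = (na * mean_a + nb * mean_b) / (na + nb)
    a0, a1 = _trend_fit(overall[tested], disp_mom[tested])
    with np.errstate(divide="ignore"):
        disp_trend = np.clip(a0 + a1 / np.where(overall > 0, overall, np.nan), 1e-8, None)
    disp_trend = np.nan_to_num(disp_trend, nan=1e-8)
    disp = 0.5 * disp_mom + 0.5 * disp_trend

    inv_sf_a = (1.0 / cm.size_factors[group_a]).sum()
    inv_sf_b = (1.0 / cm.size_factors[group_b]).sum()
    # Var(mean of normalized counts) under NB: (mu * sum 1/s_j + alpha * mu^2 * n) / n^2
    var_mean_a = (mean_a * inv_sf_a + disp * mean_a**2 * na) / na**2
    var_mean_b = (mean_b * inv_sf_b + disp * mean_b**2 * nb) / nb**2

    log2fc = np.log2(mean_a + pseudo) - np.log2(mean_b + pseudo)
    ln2sq = np.log(2.0) ** 2
    se2 = var_mean_a / ((mean_a + pseudo) ** 2 * ln2sq) + var_mean_b / (
        (mean_b + pseudo) ** 2 * ln2sq
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))

    out = pd.DataFrame(
        {
            "contrast": contrast,
            "log2fc": log2fc,
            "stat": stat,
            "p": p,
            "padj": np.nan,
            "call": "ns",
        },
        index=cm.gene_ids.copy(),
    )
    out = out.loc[tested]
    out["padj"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    out.index.name = "gene_id"
    return out


def call_degs(
    results: pd.DataFrame,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Set the up / down / ns call from significance and fold-change thresholds.

    ``up`` requires significance (raw p by default, adjusted with
    ``use_adjusted``) and ``log2fc >= lfc_min``; ``down`` the mirror image;
    everything else is ``ns``. Returns a copy.
    """
    if not 0 < p_max <= 1:
        raise DEError(f"p_max must be in (0, 1], got {p_max}")
    if lfc_min < 0:
        raise DEError(f"lfc_min must be non-negative, got {lfc_min}")
    out = results.copy()
    pcol = out["padj"] if use_adjusted else out["p"]
    sig = pcol <= p_max
    out["call"] = "ns"
    out.loc[sig & (out["log2fc"] >= lfc_min), "call"] = "up"
    out.loc[sig & (out["log2fc"] <= -lfc_min), "call"] = "down"
    return out


def trio_contrasts(
    cm: CountMatrix,
    design: TrioDesign,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    use_adjusted: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run all four contrasts of one cross and call DEGs.

    Contrast keys: ``H_vs_P1`` (hybrid over female), ``H_vs_P2`` (hybrid over
    male), ``H_vs_MP`` (hybrid over virtual mid-parent), ``P1_vs_P2``
    (female over male).
    """
    if cm.size_factors is None:
        cm = normalize(cm)
    cm_mp, mp_ids = build_mid_parent(cm, design)
    groups = {
        "H_vs_P1": (design.samples["hybrid"], design.samples["female"]),
        "H_vs_P2": (design.samples["hybrid"], design.samples["male"]),
        "H_vs_MP": (design.samples["hybrid"], mp_ids),
        "P1_vs_P2": (design.samples["female"], design.samples["male"]),
    }
    out = {}
    for name, (ga, gb) in groups.items():
        res = nb_test(cm_mp, ga, gb, contrast=name)
        out[name] = call_degs(res, p_max=p_max, lfc_min=lfc_min, use_adjusted=use_adjusted)
    return out
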