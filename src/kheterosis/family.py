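"""Gene-family identification from homology-search tables.

Filters BLAST-tabular (outfmt 6) hits by the stringent thresholds used for
K+ channel/transporter families (E-value < 1e-25, percent identity > 30,
percent query coverage > 30, all strict) and assigns each surviving subject
sequence to the family of its best-scoring query.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

#: the 12 standard columns of BLAST tabular output (-outfmt 6)
BLAST6_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
)


class FamilyFilterError(ValueError):
    """Raised for malformed hit tables or missing query metadata."""


def read_blast6(path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file (no header, tab-separated)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST6_COLUMNS):
        raise FamilyFilterError(
            f"expected {len(BLAST6_COLUMNS)} tab-separated columns, found {df.shape[1]}"
        )
    df.columns = list(BLAST6_COLUMNS)
    return df


def _validate_hits(hits: pd.DataFrame) -> None:
    missing = [c for c in BLAST6_COLUMNS if c not in hits.columns]
    if missing:
        raise FamilyFilterError(f"hit table missing columns: {missing}")
    if (hits["q_start"] > hits["q_end"]).any():
        bad = hits.loc[hits["q_start"] > hits["q_end"]].iloc[0]
        raise FamilyFilterError(
            f"hit {bad['query_id']}->{bad['subject_id']} has q_start > q_end"
        )
    if (hits[["q_start", "q_end", "s_start"]].min(axis=None) < 1) or (hits["evalue"] < 0).any():
        raise FamilyFilterError("coordinates must be 1-based and E-values non-negative")


def query_coverage(hits: pd.DataFrame, q_len: Mapping[str, int]) -> pd.Series:
    """Percent of the query spanned by the alignment, from 1-based inclusive
    coordinates: 100 * (q_end - q_start + 1) / q_len."""
    missing = sorted(set(hits["query_id"]) - set(q_len))
    if missing:
        raise FamilyFilterError(f"no query length for: {missing[:10]}")
    lengths = hits["query_id"].map(q_len)
    return 100.0 * (hits["q_end"] - hits["q_start"] + 1) / lengths


def filter_hits(
    hits: pd.DataFrame,
    q_len: Mapping[str, int],
    evalue_max: float = 1e-25,
    identity_min: float = 30.0,
    coverage_min: float = 30.0,
) -> pd.DataFrame:
    """Keep hits passing all three stringent thresholds (strict inequalities):
    evalue < evalue_max, percent identity > identity_min, and percent query
    coverage > coverage_min. Row order is preserved."""
    _validate_hits(hits)
    cov = query_coverage(hits, q_len)
    keep = (
        (hits["evalue"] < evalue_max)
        & (hits["percent_identity"] > identity_min)
        & (cov > coverage_min)
    )
    out = hits.loc[keep].copy()
    out["query_coverage"] = cov[keep]
    return out


def assign_families(
    hits: pd.DataFrame, query_family_map: Mapping[str, str]
) -> pd.DataFrame:
    """Assign each subject to one family via its best surviving hit.

    The winning hit per subject has the highest bit score, ties broken by
    lower E-value then lexicographic query id. Input hits should already be
    filtered. Output columns: family, subject_id, plus the winning hit's
    fields, sorted by family then subject.
    """
    unmapped = sorted(set(hits["query_id"]) - set(query_family_map))
    if unmapped:
        raise FamilyFilterError(f"queries without a family: {unmapped[:10]}")
    if hits.empty:
        return pd.DataFrame(columns=["family", *hits.columns])
    ranked = hits.sort_values(
        ["subject_id", "bit_score", "evalue", "query_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.groupby("subject_id", sort=False).head(1).copy()
    best.insert(0, "family", best["query_id"].map(query_family_map))
    return best.sort_values(["family", "subject_id"], kind="mergesort").reset_index(drop=True)
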