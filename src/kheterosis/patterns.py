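"""Twelve-pattern classification of trio DEGs and grouped proportions.

Each gene's four contrast calls (hybrid vs female parent, hybrid vs male
parent, hybrid vs virtual mid-parent, female vs male) map to one of twelve
expression patterns: P1-P2 additive (hybrid at the mid-parent level between
unequal parents), P3-P6 dominant (hybrid matching one parent, differing from
the other), P7-P9 transgressive below both parents, P10-P12 transgressive
above both. Call combinations that fit no pattern are 'conflicting'; genes
not differing from either parent are 'unclassified'. The headline statistic
is the overdominant share of non-additive (P3-P12) genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simulate import CATEGORY_OF_PATTERN, PATTERNS, PlantedTruth

CALLS = ("up", "down", "ns")
CATEGORIES = ("additive", "dominant", "overdominant_down", "overdominant_up", "none")


class PatternError(ValueError):
    """Raised for invalid calls or mismatched gene sets."""


@dataclass(frozen=True)
class PatternAssignment:
    """One gene's expression-pattern label and grouped category."""

    gene_id: str
    pattern: str  # P1..P12, unclassified, conflicting
    category: str

    def __post_init__(self) -> None:
        expected = CATEGORY_OF_PATTERN.get(self.pattern, "none")
        if self.category != expected:
            raise PatternError(
                f"{self.gene_id!r}: pattern {self.pattern} implies category "
                f"{expected!r}, got {self.category!r}"
            )


@dataclass
class PatternSummary:
    """Counts per pattern, grouped category totals, and the overdominant
    fraction of non-additive genes (None when no non-additive genes exist)."""

    counts: dict[str, int]
    grouped: dict[str, int]
    overdominant_fraction_of_nonadditive: float | None

    def as_dict(self) -> dict:
        frac = self.overdominant_fraction_of_nonadditive
        return {
            "counts": dict(self.counts),
            "grouped": dict(self.grouped),
            "overdominant_fraction_of_nonadditive": frac,
            "overdominant_percent_of_nonadditive": (
                None if frac is None else round(100.0 * frac, 2)
            ),
        }


def _check_call(name: str, value: str) -> None:
    if value not in CALLS:
        raise PatternError(f"invalid {name} call token {value!r}; expected one of {CALLS}")


def classify_calls(call_p1: str, call_p2: str, call_mp: str, call_pp: str) -> tuple[str, str]:
    """Map one gene's four contrast calls to (pattern, category).

    Calls are hybrid-vs-female (``call_p1``), hybrid-vs-male (``call_p2``),
    hybrid-vs-midparent (``call_mp``) and female-vs-male (``call_pp``), with
    ``up`` meaning the first member is higher. Rules, in order:

    - both parental calls ``ns``: not a trio DEG -> ``unclassified``;
    - hybrid below both parents -> P7/P8/P9 by female-vs-male ``up``/``ns``/``down``;
    - hybrid above both parents -> P10/P11/P12 by female-vs-male ``down``/``ns``/``up``;
    - parental calls in opposite directions and mid-parent ``ns`` -> additive,
      P1 when the female parent is the higher one, P2 otherwise;
    - exactly one parental call ``ns`` and mid-parent significant -> dominant,
      P3/P4 hybrid matching the female (above/below the male), P5/P6 matching
      the male (above/below the female);
    - anything else -> ``conflicting``.
    """
    for name, value in (
        ("hybrid-vs-female", call_p1),
        ("hybrid-vs-male", call_p2),
        ("hybrid-vs-midparent", call_mp),
        ("female-vs-male", call_pp),
    ):
        _check_call(name, value)

    if call_p1 == "ns" and call_p2 == "ns":
        pattern = "unclassified"
    elif call_p1 == "down" and call_p2 == "down":
        pattern = {"up": "P7", "ns": "P8", "down": "P9"}[call_pp]
    elif call_p1 == "up" and call_p2 == "up":
        pattern = {"down": "P10", "ns": "P11", "up": "P12"}[call_pp]
    elif "ns" not in (call_p1, call_p2):  # opposite directions
        pattern = ("P1" if call_p1 == "down" else "P2") if call_mp == "ns" else "conflicting"
    elif call_mp != "ns":  # exactly one parental call ns, mid-parent significant
        if call_p1 == "ns":  # hybrid matches the female parent
            pattern = "P3" if call_p2 == "up" else "P4"
        else:  # hybrid matches the male parent
            pattern = "P5" if call_p1 == "up" else "P6"
    else:
        pattern = "conflicting"
    return pattern, CATEGORY_OF_PATTERN.get(pattern, "none")


def classify_genes(
    de_tables: Mapping[str, pd.DataFrame], deg_gate: Iterable[str] | None = None
) -> pd.DataFrame:
    """Classify every gene from the four per-contrast DE tables.

    ``de_tables`` maps contrast names ``H_vs_P1``, ``H_vs_P2``, ``H_vs_MP``,
    ``P1_vs_P2`` to DataFrames indexed by gene id with a ``call`` column.
    Genes absent from a table (e.g. dropped by the low-count filter) count as
    ``ns`` for that contrast. When ``deg_gate`` is given, only genes in it
    (typically the DEGs of at least one contrast under the full p and
    fold-change thresholds) are classified; the rest are ``unclassified``.
    Returns a DataFrame indexed by gene id with ``pattern`` and ``category``
    columns.
    """
    required = ("H_vs_P1", "H_vs_P2", "H_vs_MP", "P1_vs_P2")
    missing = [c for c in required if c not in de_tables]
    if missing:
        raise PatternError(f"missing contrast tables: {missing}")
    genes: pd.Index = de_tables["H_vs_P1"].index
    for c in required[1:]:
        genes = genes.union(de_tables[c].index)
    calls = {
        c: de_tables[c]["call"].reindex(genes, fill_value="ns") for c in required
    }
    gate = None if deg_gate is None else set(deg_gate)
    rows = [
        classify_calls(calls["H_vs_P1"][g], calls["H_vs_P2"][g], calls["H_vs_MP"][g], calls["P1_vs_P2"][g])
        if (gate is None or g in gate)
        else ("unclassified", "none")
        for g in genes
    ]
    out = pd.DataFrame(rows, index=genes, columns=["pattern", "category"])
    out.index.name = "gene_id"
    return out


def deg_union(funnel_tables: Mapping[str, pd.DataFrame]) -> set[str]:
    """Genes called up or down in at least one contrast — the DEG universe
    the classifier operates on."""
    genes: set[str] = set()
    for table in funnel_tables.values():
        genes.update(table.index[table["call"] != "ns"])
    return genes


def summarize_patterns(assignments: pd.DataFrame | Iterable[PatternAssignment]) -> PatternSummary:
    """Tally patterns and grouped categories; compute the overdominant share.

    The share is (P7..P12) / (P3..P12); conflicting and unclassified genes
    never enter it. An empty denominator yields ``None`` (reported as NA).
    """
    if not isinstance(assignments, pd.DataFrame):
        assignments = pd.DataFrame(
            [(a.gene_id, a.pattern, a.category) for a in assignments],
            columns=["gene_id", "pattern", "category"],
        ).set_index("gene_id")
    tally = assignments["pattern"].value_counts()
    counts = {p: int(tally.get(p, 0)) for p in PATTERNS}
    counts["unclassified"] = int(tally.get("unclassified", 0))
    counts["conflicting"] = int(tally.get("conflicting", 0))
    grouped = {c: 0 for c in CATEGORIES}
    for pattern, category in CATEGORY_OF_PATTERN.items():
        grouped[category] += counts[pattern]
    grouped["none"] = counts["unclassified"] + counts["conflicting"]
    overdominant = grouped["overdominant_down"] + grouped["overdominant_up"]
    non_additive = overdominant + grouped["dominant"]
    frac = overdominant / non_additive if non_additive > 0 else None
    return PatternSummary(counts=counts, grouped=grouped, overdominant_fraction_of_nonadditive=frac)


def recover_proportions(
    truth: Sequence[PlantedTruth], assignments: pd.DataFrame
) -> dict:
    """Confusion summary of assigned patterns against planted truth.

    Returns per-pattern precision/recall plus the planted and estimated
    overdominant fractions of non-additive genes. Gene sets must match.
    """
    truth_ids = {t.gene_id for t in truth}
    assigned_ids = set(assignments.index)
    if truth_ids != assigned_ids:
        extra = sorted(assigned_ids - truth_ids)[:3]
        missing = sorted(truth_ids - assigned_ids)[:3]
        raise PatternError(f"gene-set mismatch (extra={extra}, missing={missing})")
    true_pattern = pd.Series({t.gene_id: t.true_pattern for t in truth})
    pred = assignments["pattern"]
    per_pattern = {}
    for p in PATTERNS:
        tp = int(((true_pattern == p) & (pred == p)).sum())
        n_true = int((true_pattern == p).sum())
        n_pred = int((pred == p).sum())
        per_pattern[p] = {
            "n_true": n_true,
            "n_pred": n_pred,
            "precision": tp / n_pred if n_pred else None,
            "recall": tp / n_true if n_true else None,
        }
    truth_categories = true_pattern.map(lambda p: CATEGORY_OF_PATTERN.get(p, "none"))
    planted_od = int(truth_categories.isin(["overdominant_down", "overdominant_up"]).sum())
    planted_nonadd = planted_od + int((truth_categories == "dominant").sum())
    summary = summarize_patterns(assignments)
    return {
        "per_pattern": per_pattern,
        "planted_overdominant_fraction": (
            planted_od / planted_nonadd if planted_nonadd else None
        ),
        "estimated_overdominant_fraction": summary.overdominant_fraction_of_nonadditive,
    }
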