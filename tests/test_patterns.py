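import itertools

import pandas as pd
import pytest

from kheterosis.patterns import (
    PatternError,
    classify_calls,
    classify_genes,
    deg_union,
    recover_proportions,
    summarize_patterns,
)

CALLS = ("up", "down", "ns")


def oracle_pattern(c_p1, c_p2, c_mp, c_pp):
    """Independently written reference for the 12-pattern rule table.

    Reasoning from the hybrid's position relative to the parents rather than
    from the rule order: both-parent calls place the hybrid below both
    (transgressive down), above both (transgressive up), between (additive
    candidates) or level with one parent (dominant candidates).
    """
    sig1, sig2 = c_p1 != "ns", c_p2 != "ns"
    if not sig1 and not sig2:
        return "unclassified"
    if sig1 and sig2 and c_p1 == c_p2 == "down":
        return {"up": "P7", "ns": "P8", "down": "P9"}[c_pp]
    if sig1 and sig2 and c_p1 == c_p2 == "up":
        return {"down": "P10", "ns": "P11", "up": "P12"}[c_pp]
    if sig1 and sig2:  # between the parents: additive only if MP-like
        if c_mp != "ns":
            return "conflicting"
        return "P1" if c_p1 == "down" else "P2"
    # level with exactly one parent: dominant needs a real mid-parent shift
    if c_mp == "ns":
        return "conflicting"
    if not sig1:  # matches the female parent
        return "P3" if c_p2 == "up" else "P4"
    return "P5" if c_p1 == "up" else "P6"


def test_rule_table_agrees_with_oracle_on_all_81_combinations():
    for combo in itertools.product(CALLS, repeat=4):
        pattern, category = classify_calls(*combo)
        assert pattern == oracle_pattern(*combo), combo


def test_classification_is_total_and_single_valued():
    seen = [classify_calls(*combo) for combo in itertools.product(CALLS, repeat=4)]
    assert len(seen) == 81
    labels = {p for p, _ in seen}
    assert labels <= {f"P{i}" for i in range(1, 13)} | {"unclassified", "conflicting"}
    # every one of the 12 patterns is reachable
    assert {f"P{i}" for i in range(1, 13)} <= labels


@pytest.mark.parametrize(
    "combo, expected",
    [
        (("up", "up", "up", "ns"), "P11"),
        (("down", "down", "down", "up"), "P7"),
        (("ns", "ns", "ns", "up"), "unclassified"),
        (("up", "down", "ns", "up"), "P2"),
        (("ns", "up", "up", "down"), "P3"),
    ],
)
def test_known_call_combinations(combo, expected):
    assert classify_calls(*combo)[0] == expected


def test_invalid_call_token_rejected():
    with pytest.raises(PatternError):
        classify_calls("up", "sideways", "ns", "ns")


def test_weakening_calls_never_flips_transgressive_direction():
    # Strengthening DEG thresholds can only turn calls into ns; such a change
    # must never move a gene between the up- and down-transgressive groups.
    def weaker(call):
        return (call, "ns") if call != "ns" else ("ns",)

    for combo in itertools.product(CALLS, repeat=4):
        _, cat = classify_calls(*combo)
        if cat not in ("overdominant_up", "overdominant_down"):
            continue
        opposite = "overdominant_down" if cat == "overdominant_up" else "overdominant_up"
        for weaker_combo in itertools.product(*(weaker(c) for c in combo)):
            assert classify_calls(*weaker_combo)[1] != opposite


def _assignments(patterns_by_gene):
    df = pd.DataFrame(
        [(g, p, {"P1": "additive", "P2": "additive"}.get(p)) for g, p in patterns_by_gene.items()],
        columns=["gene_id", "pattern", "category"],
    ).set_index("gene_id")
    from kheterosis.simulate import CATEGORY_OF_PATTERN

    df["category"] = df["pattern"].map(lambda p: CATEGORY_OF_PATTERN.get(p, "none"))
    return df[["pattern", "category"]]


def test_summary_counts_and_grouped_totals_are_consistent():
    # published-scale example: up-overdominant 632+617+1498, down 317+1350+429
    per_pattern = {"P10": 632, "P11": 617, "P12": 1498, "P7": 317, "P8": 1350, "P9": 429}
    genes = {}
    i = 0
    for pat, n in per_pattern.items():
        for _ in range(n):
            genes[f"g{i}"] = pat
            i += 1
    summary = summarize_patterns(_assignments(genes))
    od = summary.grouped["overdominant_up"] + summary.grouped["overdominant_down"]
    assert od == 4843
    assert summary.overdominant_fraction_of_nonadditive == pytest.approx(1.0)
    assert sum(summary.counts.values()) == sum(summary.grouped.values())


def test_summary_fraction_na_when_all_additive():
    genes = {f"g{i}": "P1" for i in range(10)}
    summary = summarize_patterns(_assignments(genes))
    assert summary.overdominant_fraction_of_nonadditive is None
    assert summary.as_dict()["overdominant_percent_of_nonadditive"] is None


def test_summary_fraction_half_for_even_split():
    genes = {f"d{i}": "P3" for i in range(50)} | {f"o{i}": "P11" for i in range(50)}
    summary = summarize_patterns(_assignments(genes))
    assert summary.overdominant_fraction_of_nonadditive == pytest.approx(0.5)


def make_tables(calls_by_gene):
    genes = list(calls_by_gene)
    contrasts = ("H_vs_P1", "H_vs_P2", "H_vs_MP", "P1_vs_P2")
    return {
        c: pd.DataFrame({"call": [calls_by_gene[g][i] for g in genes]}, index=genes)
        for i, c in enumerate(contrasts)
    }


def test_classify_genes_respects_deg_gate():
    tables = make_tables({"a": ("up", "up", "up", "ns"), "b": ("up", "up", "up", "ns")})
    gated = classify_genes(tables, deg_gate={"a"})
    assert gated.loc["a", "pattern"] == "P11"
    assert gated.loc["b", "pattern"] == "unclassified"


def test_deg_union_collects_called_genes():
    tables = make_tables({"a": ("up", "ns", "ns", "ns"), "b": ("ns", "ns", "ns", "ns")})
    assert deg_union(tables) == {"a"}


def test_recover_proportions_diagonal_in_noiseless_limit():
    from kheterosis.simulate import PlantedTruth, planted_means

    truth, assignment = [], {}
    for i, pat in enumerate([f"P{k}" for k in range(1, 13)]):
        f, m, h = planted_means(pat, 100.0, 2.0)
        truth.append(PlantedTruth(f"g{i}", pat, f, m, h))
        assignment[f"g{i}"] = pat
    rec = recover_proportions(truth, _assignments(assignment))
    for pat, scores in rec["per_pattern"].items():
        assert scores["precision"] == 1.0 and scores["recall"] == 1.0
    assert rec["estimated_overdominant_fraction"] == pytest.approx(0.6)  # 6 of 10 non-additive


def test_recover_proportions_rejects_gene_set_mismatch():
    from kheterosis.simulate import PlantedTruth

    truth = [PlantedTruth("g0", "null", 1.0, 1.0, 1.0)]
    with pytest.raises(PatternError):
        recover_proportions(truth, _assignments({"other": "P1"}))
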