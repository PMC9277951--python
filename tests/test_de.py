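import numpy as np
import pandas as pd
import pytest

from kheterosis.de import (
    CountMatrix,
    DEError,
    TrioDesign,
    build_mid_parent,
    call_degs,
    nb_test,
    normalize,
    trio_contrasts,
)

from conftest import make_two_group_matrix


class TestNormalize:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]}, index=["a", "b", "c"])
        cm = normalize(CountMatrix(counts))
        assert np.allclose(cm.size_factors, 1.0)

    def test_doubling_a_sample_doubles_its_relative_factor(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=["a", "b", "c"])
        cm = normalize(CountMatrix(counts))
        assert cm.size_factors["s2"] / cm.size_factors["s1"] == pytest.approx(2.0)

    def test_toy_matrix_matches_hand_computed_median_of_ratios(self, toy_matrix):
        cm = normalize(toy_matrix)
        assert cm.size_factors["s1"] == pytest.approx(2.0**-0.5, rel=1e-12)
        assert cm.size_factors["s2"] == pytest.approx(2.0**0.5, rel=1e-12)

    def test_geometric_mean_of_factors_is_one(self, small_trio):
        cm, _, _ = small_trio
        sf = normalize(cm).size_factors
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_on_normalized_values(self, toy_matrix):
        norm = normalize(toy_matrix).normalized()
        again = normalize(CountMatrix(norm))
        assert np.allclose(again.size_factors, 1.0, atol=1e-9)

    def test_all_zero_sample_rejected_by_name(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(DEError, match="empty"):
            normalize(CountMatrix(counts))


class TestMidParent:
    def make(self, female, male, hybrid=((5, 5), (5, 5))):
        rows = {}
        ids = ["f1", "f2", "m1", "m2", "h1", "h2"]
        data = np.column_stack([np.array(female).T, np.array(male).T, np.array(hybrid).T])
        counts = pd.DataFrame(data, index=[f"g{i}" for i in range(data.shape[0])], columns=ids)
        cm = CountMatrix(counts, pd.Series(1.0, index=ids))
        design = TrioDesign("H", {"female": ["f1", "f2"], "male": ["m1", "m2"], "hybrid": ["h1", "h2"]})
        return cm, design

    def test_identical_parents_reproduced(self):
        cm, design = self.make(female=[(10, 20)] * 2, male=[(10, 20)] * 2)
        out, mp_ids = build_mid_parent(cm, design)
        assert len(mp_ids) == 2
        assert (out.counts[mp_ids].to_numpy() == np.array([[10, 10], [20, 20]])).all()

    def test_arithmetic_mean_of_paired_replicates(self):
        cm, design = self.make(female=[(100, 100)] * 2, male=[(200, 200)] * 2)
        out, mp_ids = build_mid_parent(cm, design)
        assert (out.counts[mp_ids].to_numpy() == 150).all()

    def test_opposing_replicate_profiles_average_flat(self):
        # parent replicate values (10,20) and (30,20) pair to (20,20)
        cm, design = self.make(female=[(10, 10), (20, 20)], male=[(30, 30), (20, 20)])
        out, mp_ids = build_mid_parent(cm, design)
        assert (out.counts[mp_ids].to_numpy() == 20).all()

    def test_rounding_is_half_to_even(self):
        cm, design = self.make(female=[(100, 100)] * 2, male=[(201, 201)] * 2)
        out, mp_ids = build_mid_parent(cm, design)
        assert (out.counts[mp_ids].to_numpy() == 150).all()  # 150.5 -> 150


class TestNbTest:
    def test_identical_groups_are_ns_with_zero_lfc(self):
        counts = pd.DataFrame(
            np.tile([[100], [400], [50]], 6), index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(6)],
        )
        res = call_degs(nb_test(normalize(CountMatrix(counts)), ["s0", "s1", "s2"], ["s3", "s4", "s5"]))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["call"] == "ns").all()

    def test_antisymmetry_of_groups(self):
        cm, ga, gb = make_two_group_matrix(
            np.full(300, 200.0), np.full(300, 800.0), seed=12
        )
        ab = nb_test(cm, ga, gb)
        ba = nb_test(cm, gb, ga)
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-10)
        assert np.allclose(ab["p"], ba["p"], atol=1e-12)

    def test_low_count_genes_excluded(self):
        counts = pd.DataFrame(
            [[0, 1, 0, 1, 0, 0], [100, 90, 110, 95, 105, 100]],
            index=["low", "ok"], columns=[f"s{i}" for i in range(6)],
        )
        res = nb_test(normalize(CountMatrix(counts)), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert list(res.index) == ["ok"]

    def test_degenerate_group_sizes_rejected(self, toy_matrix):
        with pytest.raises(DEError):
            nb_test(toy_matrix, ["s1"], ["s2"])

    def test_type_one_error_rate_near_nominal(self, null_trio):
        cm, design, _ = null_trio
        res = nb_test(normalize(cm), design.samples["hybrid"], design.samples["female"])
        rate = (res["p"] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_fold_changes_recovered_with_power_and_fdr(self):
        # |log2fc| = 2 planted in 10% of genes at mu=500, n=3, dispersion 0.05
        n, n_eff = 4000, 400
        mu_b = np.full(n, 500.0)
        mu_a = mu_b.copy()
        mu_a[:n_eff] *= 4.0
        cm, ga, gb = make_two_group_matrix(mu_a, mu_b, dispersion=0.05, seed=3)
        res = call_degs(nb_test(cm, ga, gb))
        effect = res.iloc[:n_eff]
        null = res.iloc[n_eff:]
        sensitivity = (effect["call"] == "up").mean()
        n_false = (null["call"] != "ns").sum()
        n_called = (res["call"] != "ns").sum()
        assert sensitivity >= 0.9
        assert n_false / max(n_called, 1) <= 0.1


class TestCallDegs:
    @pytest.mark.parametrize(
        "p, lfc, expected",
        [(0.01, 1.5, "up"), (0.01, 0.5, "ns"), (0.2, 3.0, "ns"), (0.01, -1.5, "down")],
    )
    def test_threshold_logic(self, p, lfc, expected):
        df = pd.DataFrame({"log2fc": [lfc], "p": [p], "padj": [p], "call": ["ns"]}, index=["g"])
        assert call_degs(df)["call"].iloc[0] == expected

    def test_invalid_p_max_rejected(self):
        df = pd.DataFrame({"log2fc": [1.0], "p": [0.01], "padj": [0.01], "call": ["ns"]}, index=["g"])
        with pytest.raises(DEError):
            call_degs(df, p_max=0.0)

    def test_adjusted_p_switch(self):
        df = pd.DataFrame({"log2fc": [2.0], "p": [0.01], "padj": [0.2], "call": ["ns"]}, index=["g"])
        assert call_degs(df)["call"].iloc[0] == "up"
        assert call_degs(df, use_adjusted=True)["call"].iloc[0] == "ns"


def test_trio_contrasts_produces_all_four_tables(small_trio):
    cm, design, _ = small_trio
    tables = trio_contrasts(normalize(cm), design)
    assert set(tables) == {"H_vs_P1", "H_vs_P2", "H_vs_MP", "P1_vs_P2"}
    for table in tables.values():
        assert {"log2fc", "p", "padj", "call"} <= set(table.columns)
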