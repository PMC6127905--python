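import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquesig.differential import (
    pearson_age,
    plugin_fdr,
    round_half_away,
    significant_sets,
    ttest_genes,
    union_over_ages,
)
from plaquesig.io import SampleTable, ValidationError


def _frame(rows: dict, samples) -> pd.DataFrame:
    return pd.DataFrame(rows, index=samples).T


class TestTtestGenes:
    def test_closed_form_example(self):
        values = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["gA"],
                              columns=list("abcdef"))
        result = ttest_genes(values, ["a", "b", "c"], ["d", "e", "f"])
        row = result.table.loc["gA"]
        assert row["t"] == pytest.approx(-3.6742, abs=1e-4)
        assert row["p"] == pytest.approx(0.0213, abs=5e-4)
        assert row["direction"] == "down"

    def test_degenerate_variance_policy(self):
        values = pd.DataFrame([[2.0] * 6], index=["gA"], columns=list("abcdef"))
        row = ttest_genes(values, list("abc"), list("def")).table.loc["gA"]
        assert row["t"] == 0.0
        assert row["p"] == 1.0
        assert row["fold_change"] == 1.0

    def test_group_swap_symmetry(self, rng):
        values = pd.DataFrame(rng.normal(size=(30, 8)),
                              index=[f"g{i}" for i in range(30)],
                              columns=list("abcdefgh"))
        fwd = ttest_genes(values, list("abcd"), list("efgh")).table
        rev = ttest_genes(values, list("efgh"), list("abcd")).table
        np.testing.assert_allclose(fwd["t"], -rev["t"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-12)
        np.testing.assert_allclose(fwd["fold_change"], 1 / rev["fold_change"], rtol=1e-12)

    def test_null_rejection_rate_at_five_percent(self, rng):
        values = pd.DataFrame(rng.normal(size=(2000, 12)),
                              columns=[f"s{i}" for i in range(12)])
        result = ttest_genes(values, [f"s{i}" for i in range(6)],
                             [f"s{i}" for i in range(6, 12)])
        rate = (result.table["p"] < 0.05).mean()
        # 95% binomial envelope around 0.05 for n = 2000
        margin = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) <= margin + 1e-9

    def test_small_group_rejected(self):
        values = pd.DataFrame([[1, 2, 3]], index=["g"], columns=list("abc"))
        with pytest.raises(ValidationError, match=">= 2"):
            ttest_genes(values, ["a"], ["b", "c"])

    def test_matches_scipy_oracle(self, rng):
        values = pd.DataFrame(rng.normal(size=(50, 9)),
                              columns=[f"s{i}" for i in range(9)])
        ga, gb = [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 9)]
        result = ttest_genes(values, ga, gb)
        t_ref, p_ref = stats.ttest_ind(values[ga], values[gb], axis=1, equal_var=True)
        np.testing.assert_allclose(result.table["t"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(result.table["p"], p_ref, rtol=1e-12)


class TestPearsonAge:
    def _samples(self, ages):
        return SampleTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(ages))],
            "strain": "TgCRND8", "genotype": "TG",
            "age_months": ages, "tissue_class": "whole_cortex"}))

    def test_perfect_correlations(self):
        ages = [1.5, 3.0, 4.5, 6.0, 10.0]
        samples = self._samples(ages)
        values = pd.DataFrame([ages, [-a for a in ages]], index=["pos", "neg"],
                              columns=samples.sample_ids)
        result = pearson_age(values, samples)
        assert result.rho["pos"] == pytest.approx(1.0)
        assert result.rho["neg"] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self, rng):
        ages = rng.uniform(1, 15, size=10)
        samples = self._samples(list(ages))
        values = pd.DataFrame(rng.normal(size=(25, 10)), columns=samples.sample_ids)
        result = pearson_age(values, samples)
        for g in values.index:
            x = values.loc[g].to_numpy()
            xc, ac = x - x.mean(), ages - ages.mean()
            expected = (xc @ ac) / np.sqrt((xc @ xc) * (ac @ ac))
            assert result.rho[g] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_reports_zero(self):
        samples = self._samples([1.0, 2.0, 3.0])
        values = pd.DataFrame([[5.0, 5.0, 5.0]], index=["flat"],
                              columns=samples.sample_ids)
        assert pearson_age(values, samples).rho["flat"] == 0.0

    def test_constant_age_rejected(self):
        samples = self._samples([6.0, 6.0, 6.0])
        values = pd.DataFrame([[1.0, 2.0, 3.0]], columns=samples.sample_ids)
        with pytest.raises(ValidationError, match="constant"):
            pearson_age(values, samples)


class TestPluginFdr:
    @pytest.mark.parametrize("n_detected,alpha,n_sig,expected", [
        (12461, 0.001, 82, 15),
        (15857, 0.001, 43, 37),
        (15857, 0.001, 42, 38),
        (15857, 0.001, 86, 18),
        (15857, 0.001, 11, 100),
        (15857, 0.001, 58, 27),
        (1000, 0.001, 1000, 0),
        (1000, 0.001, 0, 100),
    ])
    def test_reproduces_printed_percentages(self, n_detected, alpha, n_sig, expected):
        assert plugin_fdr(n_detected, alpha, n_sig).fdr_percent == expected

    def test_antitone_in_significant_count(self):
        values = [plugin_fdr(10_000, 0.001, k).fdr_percent for k in range(10, 200, 10)]
        assert values == sorted(values, reverse=True)

    def test_isotone_in_alpha_and_detected(self):
        by_alpha = [plugin_fdr(10_000, a, 50).fdr_percent
                    for a in (0.0001, 0.0005, 0.001, 0.002)]
        assert by_alpha == sorted(by_alpha)
        by_n = [plugin_fdr(n, 0.001, 50).fdr_percent
                for n in (5_000, 10_000, 20_000)]
        assert by_n == sorted(by_n)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            plugin_fdr(10, 0.001, 20)
        with pytest.raises(ValidationError):
            plugin_fdr(10, 1.5, 2)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(1.5) == 2
        assert round_half_away(2.4) == 2
        assert round_half_away(-0.5) == -1


class TestSignificantSets:
    @staticmethod
    def _result(ps, directions):
        table = pd.DataFrame({
            "t": 0.0, "p": ps, "mean_a": 0.0, "mean_b": 0.0,
            "fold_change": 1.0, "direction": directions,
        }, index=[f"g{i}" for i in range(len(ps))])
        from plaquesig.differential import DGEResult
        return DGEResult(table)

    def test_nothing_significant_gives_absent_sets(self):
        res = self._result([0.5] * 5, ["up"] * 5)
        sig = significant_sets(res)
        assert sig.up is None and sig.down is None and sig.percent_up is None

    @pytest.mark.parametrize("n_up,n_down,expected", [(464, 118, 80), (125, 110, 53)])
    def test_percent_up_matches_reported_arithmetic(self, n_up, n_down, expected):
        ps = [1e-5] * (n_up + n_down)
        directions = ["up"] * n_up + ["down"] * n_down
        assert significant_sets(self._result(ps, directions)).percent_up == expected

    def test_partition_matches_hand_enumeration(self, rng):
        ps = rng.uniform(0, 0.01, size=10)
        directions = rng.choice(["up", "down"], size=10)
        sig = significant_sets(self._result(list(ps), list(directions)), alpha=0.005)
        expect_up = {f"g{i}" for i in range(10) if ps[i] < 0.005 and directions[i] == "up"}
        expect_down = {f"g{i}" for i in range(10) if ps[i] < 0.005 and directions[i] == "down"}
        assert (sig.up.members if sig.up else set()) == expect_up
        assert (sig.down.members if sig.down else set()) == expect_down


class TestUnionOverAges:
    @staticmethod
    def _result(genes, ps, directions):
        table = pd.DataFrame({
            "t": 0.0, "p": ps, "mean_a": 0.0, "mean_b": 0.0,
            "fold_change": 1.0, "direction": directions}, index=genes)
        from plaquesig.differential import DGEResult
        return DGEResult(table)

    def test_single_age_is_identity(self):
        res = self._result(["a", "b", "c"], [1e-4, 0.5, 1e-4], ["up", "up", "down"])
        union = union_over_ages([res])
        assert union.members.members == {"a", "c"}
        assert union.directions["a"] == "up"
        assert union.directions["c"] == "down"

    def test_consistent_sign_across_ages(self):
        r1 = self._result(["a", "b"], [1e-4, 0.5], ["up", "up"])
        r2 = self._result(["a", "b"], [1e-4, 1e-4], ["up", "down"])
        union = union_over_ages([r1, r2])
        assert union.directions["a"] == "up"
        assert union.directions["b"] == "down"

    def test_tie_goes_up(self):
        r1 = self._result(["a"], [1e-4], ["up"])
        r2 = self._result(["a"], [1e-4], ["down"])
        assert union_over_ages([r1, r2]).directions["a"] == "up"

    def test_matches_brute_force_over_five_ages(self, rng):
        genes = [f"g{i}" for i in range(100)]
        results = []
        for _ in range(5):
            results.append(self._result(
                genes, list(rng.uniform(0, 0.01, size=100)),
                list(rng.choice(["up", "down"], size=100))))
        union = union_over_ages(results, alpha=0.001)
        brute = set()
        for r in results:
            brute |= set(r.table.index[r.table["p"] < 0.001])
        assert union.members.members == brute

    def test_inconsistent_universe_rejected(self):
        r1 = self._result(["a", "b"], [0.5, 0.5], ["up", "up"])
        r2 = self._result(["a", "c"], [0.5, 0.5], ["up", "up"])
        with pytest.raises(ValidationError, match="universe"):
            union_over_ages([r1, r2])
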