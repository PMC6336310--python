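"""Factorial ANOVA, Tukey contrasts, variance statistic, regression, marker screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vdjrep.model import Design, DesignRow
from vdjrep.stats import (
    ANOVA_TERMS,
    animal_variance,
    anova_by_feature,
    compare_variance,
    marker_screen,
    threeway_anova,
    tukey_posthoc,
    usage_regression,
    whole_animal_variation,
)
from vdjrep.synthetic import default_design, simulate_tpm
from vdjrep.usage import UsageTable


def _values(design, fn):
    return pd.Series({a: fn(design[a]) for a in design.animal_ids}, dtype=float)


class TestThreewayAnova:
    def test_constant_response_is_degenerate(self, design2):
        res = threeway_anova(_values(design2, lambda r: 3.0), design2)
        assert res.degenerate
        assert all(res.p(t) == 1.0 for t in ANOVA_TERMS)

    def test_constructed_aos_contrast(self, design2, rng):
        noise = dict(zip(design2.animal_ids, 0.01 * rng.standard_normal(len(design2))))
        vals = _values(design2, lambda r: 10.0 * r.aos) + pd.Series(noise)
        res = threeway_anova(vals, design2)
        assert res.p("AOS") < 1e-6
        for term in ("TT", "CpG", "AOSxTT", "AOSxTTxCpG"):
            assert res.p(term) > 0.05

    def test_factor_order_invariance_on_balanced_design(self, design2, rng):
        """Balanced type-I SS match under any factor permutation; spot-check
        by comparing against a reordered design frame."""
        vals = pd.Series(rng.standard_normal(len(design2)), index=design2.animal_ids)
        res = threeway_anova(vals, design2)
        # relabel factors: swap aos <-> cpg in the design, swap terms back
        swapped = Design(
            [
                DesignRow(r.animal_id, aos=r.cpg, tt=r.tt, cpg=r.aos, trial=r.trial)
                for r in design2
            ]
        )
        res_swapped = threeway_anova(vals, swapped)
        assert res.p("AOS") == pytest.approx(res_swapped.p("CpG"), rel=1e-9)
        assert res.p("CpG") == pytest.approx(res_swapped.p("AOS"), rel=1e-9)
        assert res.p("AOSxTT") == pytest.approx(res_swapped.p("TTxCpG"), rel=1e-9)

    def test_empty_cell_rejected_with_cell_name(self):
        design = default_design(2)
        crippled = Design([r for r in design if r.cell != "-+-"])
        vals = pd.Series(1.0, index=crippled.animal_ids)
        with pytest.raises(ValueError, match=r"-\+-"):
            threeway_anova(vals, crippled)

    def test_anova_by_feature_tidy_output(self, design2, rng):
        pct = pd.DataFrame(
            rng.random((len(design2), 3)) * 10,
            index=design2.animal_ids,
            columns=["g1", "g2", "g3"],
        )
        table = UsageTable(axis="V", percent=pct, counts=pct)
        tidy = anova_by_feature(table, design2)
        assert len(tidy) == 3 * len(ANOVA_TERMS)
        assert set(tidy.columns) == {"feature", "term", "F", "p", "significant"}


class TestTukey:
    def test_equal_means_not_significant(self, rng):
        groups = pd.Series(["a"] * 6 + ["b"] * 6)
        vals = pd.Series(np.r_[rng.normal(5, 0.1, 6), rng.normal(5, 0.1, 6)])
        out = tukey_posthoc(vals, groups)
        assert not out["reject"].any()

    def test_shifted_group_detected(self, rng):
        groups = pd.Series(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        vals = pd.Series(
            np.r_[rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(10, 1, 6)]
        )
        out = tukey_posthoc(vals, groups)
        c_rows = out[(out["group_a"] == "c") | (out["group_b"] == "c")]
        other = out[~out.index.isin(c_rows.index)]
        assert c_rows["reject"].all()
        assert not other["reject"].any()

    def test_adjusted_p_at_least_unadjusted(self, rng):
        """Tukey-adjusted p >= the pooled-variance pairwise t-test p."""
        groups = pd.Series(sum([[g] * 5 for g in "abcd"], []))
        vals = pd.Series(rng.standard_normal(20) + groups.map({"a": 0, "b": 0.5, "c": 1, "d": 2}))
        out = tukey_posthoc(vals, groups)
        mse = vals.groupby(groups).transform(lambda x: x - x.mean()).pow(2).sum() / (20 - 4)
        se = np.sqrt(2 * mse / 5)
        for _, row in out.iterrows():
            t = abs(row["difference"]) / se
            p_unadj = 2 * sps.t.sf(t, df=16)
            assert row["p_adj"] >= p_unadj - 1e-9

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_posthoc(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))


class TestAnimalVariance:
    def _table(self, data):
        pct = pd.DataFrame(data)
        return UsageTable(axis="V", percent=pct, counts=pct)

    def test_printed_formula_example(self):
        # two animals at 10% and 20% on one feature: mean 15, each deviation^2 = 25
        table = self._table({"g": {"m1": 10.0, "m2": 20.0}})
        var = animal_variance(table)
        assert var.loc["m1", "g"] == 25.0 and var.loc["m2", "g"] == 25.0

    def test_identical_animals_have_zero_variation(self):
        table = self._table({"g1": {"m1": 40.0, "m2": 40.0}, "g2": {"m1": 60.0, "m2": 60.0}})
        assert (whole_animal_variation(table) == 0).all()

    def test_brute_force_oracle(self, rng):
        for _ in range(25):
            n_a, n_f = int(rng.integers(2, 12)), int(rng.integers(1, 15))
            pct = pd.DataFrame(
                rng.random((n_a, n_f)) * 100,
                index=[f"m{i}" for i in range(n_a)],
                columns=[f"g{j}" for j in range(n_f)],
            )
            table = self._table(pct.to_dict())
            var = animal_variance(table)
            totals = whole_animal_variation(table)
            for a in pct.index:
                expected_total = 0.0
                for f in pct.columns:
                    mean = sum(pct.loc[x, f] for x in pct.index) / n_a
                    dev2 = (pct.loc[a, f] - mean) ** 2
                    assert var.loc[a, f] == pytest.approx(dev2)
                    expected_total += dev2
                assert totals[a] == pytest.approx(expected_total)


class TestCompareVariance:
    def test_identical_variances_no_contrasts(self, design2):
        totals = pd.Series(5.0, index=design2.animal_ids)
        comp = compare_variance(totals, design2)
        assert comp.global_p == 1.0
        assert not comp.contrasts["reject"].any()

    def test_inflated_group_detected(self, design4, rng):
        base = pd.Series(
            rng.normal(10, 1, len(design4)), index=design4.animal_ids
        ).abs()
        inflated = base.copy()
        for a in design4.animal_ids:
            if design4[a].cell == "+++":
                inflated[a] *= 100
        comp = compare_variance(inflated, design4)
        hits = comp.contrasts[comp.contrasts["reject"]]
        assert len(hits) > 0
        assert all("+++" in (r["group_a"], r["group_b"]) for _, r in hits.iterrows())
        assert comp.global_p < 0.01

    def test_needs_two_per_group(self, design2):
        totals = pd.Series(1.0, index=design2.animal_ids[:9])
        with pytest.raises(ValueError):
            compare_variance(totals, design2)


class TestUsageRegression:
    def test_identical_vectors_r2_one(self):
        v = pd.Series([1.0, 5.0, 10.0, 20.0], index=list("abcd"))
        r2, p = usage_regression(v, v)
        assert r2 == pytest.approx(1.0)

    def test_affine_invariance(self):
        a = pd.Series([1.0, 5.0, 10.0, 20.0], index=list("abcd"))
        r2, _ = usage_regression(a, 2 * a + 7)
        assert r2 == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self, rng):
        r2s = []
        for _ in range(20):
            a = pd.Series(rng.random(200))
            b = pd.Series(rng.random(200))
            r2s.append(usage_regression(a, b)[0])
        assert np.mean(r2s) < 0.05

    def test_zero_variance_predictor_rejected(self):
        a = pd.Series([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            usage_regression(a, pd.Series([1.0, 2.0, 3.0, 4.0]))


class TestMarkerScreen:
    def _tpm(self, design, plus_mean, minus_mean, sd=0.0, rng=None, gene="CD138"):
        vals = {}
        for a in design.animal_ids:
            mean = plus_mean if design[a].aos else minus_mean
            vals[a] = mean if rng is None else max(mean + sd * rng.standard_normal(), 1e-3)
        return pd.DataFrame([vals], index=[gene])

    def test_sign_convention(self, design2):
        tpm = self._tpm(design2, plus_mean=10.0, minus_mean=21.5)
        res = marker_screen(tpm, design2, "AOS")[0]
        assert res.fold_change == pytest.approx(-2.15)

    def test_identical_means_fc_plus_one_not_flagged(self, design2):
        tpm = self._tpm(design2, 10.0, 10.0)
        res = marker_screen(tpm, design2, "AOS")[0]
        assert res.fold_change == 1.0 and not res.flagged

    def test_small_fold_change_never_flagged_even_if_significant(self, design4, rng):
        # a -1.40 fold change with tiny p must not pass the two-fold gate
        tpm = self._tpm(design4, plus_mean=100.0, minus_mean=140.0, sd=1.0, rng=rng)
        res = marker_screen(tpm, design4, "AOS")[0]
        assert res.p_value < 0.01
        assert -1.5 < res.fold_change < -1.3
        assert not res.flagged

    def test_large_fold_change_with_significance_flagged(self, design4, rng):
        tpm = self._tpm(design4, plus_mean=40.0, minus_mean=100.0, sd=2.0, rng=rng)
        res = marker_screen(tpm, design4, "AOS")[0]
        assert res.flagged and res.fold_change < -2.0

    def test_zero_mean_level_reported_undefined(self, design2):
        tpm = self._tpm(design2, 0.0, 10.0)
        res = marker_screen(tpm, design2, "AOS")[0]
        assert not res.defined and not res.flagged

    def test_flag_is_exact_conjunction(self, design4):
        tpm = simulate_tpm([f"g{i}" for i in range(30)], design4, [], seed=17)
        for factor in ("AOS", "TT", "CpG"):
            for res in marker_screen(tpm, design4, factor):
                assert res.flagged == (abs(res.fold_change) > 2.0 and res.p_value < 0.05)
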