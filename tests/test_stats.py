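import itertools

import numpy as np
import pandas as pd
import pytest

from dmdc import (
    filter_property_regression,
    one_way_filter_anova,
    three_way_anova,
    tukey_hsd,
)
from dmdc.stats import filter_predictors, significance_tier

FACTORS = ("age_group", "drug", "location")
LEVELS = {
    "age_group": ("Younger", "Older"),
    "drug": ("CX614", "vehicle"),
    "location": ("center", "outer"),
}


def factorial_frame(rng, n_per_cell=20, age_shift=0.0):
    rows = []
    for a, d, l in itertools.product(*LEVELS.values()):
        mu = age_shift if a == "Older" else 0.0
        for v in mu + rng.standard_normal(n_per_cell):
            rows.append(
                {"dimension": v, "age_group": a, "drug": d, "location": l}
            )
    return pd.DataFrame(rows)


class TestThreeWayAnova:
    def test_pure_age_shift_detected(self, rng):
        tbl = factorial_frame(rng, n_per_cell=20, age_shift=2.0)
        aov = three_way_anova(tbl, "dimension", FACTORS)
        assert aov.effect("age_group")["p"] < 0.001
        for e in ("drug", "location", "age_group x drug",
                  "age_group x drug x location"):
            assert aov.effect(e)["p"] > 0.001

    def test_effect_layout(self, rng):
        aov = three_way_anova(factorial_frame(rng), "dimension", FACTORS)
        assert list(aov.table["effect"]) == [
            "age_group", "drug", "location",
            "age_group x drug", "age_group x location", "drug x location",
            "age_group x drug x location",
        ]
        assert ((aov.table["p"] >= 0) & (aov.table["p"] <= 1)).all()
        assert (aov.table["F"] >= 0).all()

    def test_constant_response_zero_f(self, rng):
        tbl = factorial_frame(rng)
        tbl["dimension"] = 3.14
        aov = three_way_anova(tbl, "dimension", FACTORS)
        assert (aov.table["F"] == 0.0).all()

    def test_discarded_rows_excluded(self, rng):
        tbl = factorial_frame(rng, n_per_cell=10, age_shift=5.0)
        tbl["discarded"] = False
        tbl["converged"] = True
        poison = tbl.copy()
        poison["dimension"] += 1e6 * rng.standard_normal(len(poison))
        poison["discarded"] = True
        aov = three_way_anova(pd.concat([tbl, poison]), "dimension", FACTORS)
        assert aov.effect("age_group")["p"] < 0.001

    def test_balanced_type2_equals_classical_decomposition(self, rng):
        """On a balanced 2x2x2 design Type-II must reduce to the classical
        factorial sums of squares computed directly from cell means."""
        tbl = factorial_frame(rng, n_per_cell=6, age_shift=1.0)
        aov = three_way_anova(tbl, "dimension", FACTORS)

        # independent oracle: textbook balanced SS from marginal means
        y = tbl["dimension"].to_numpy()
        n = len(y)
        grand = y.mean()
        cells = tbl.groupby(list(FACTORS), sort=True)["dimension"]
        sse = float(((y - cells.transform("mean")) ** 2).sum())
        df_err = n - 8

        def ss_main(f):
            means = tbl.groupby(f)["dimension"].mean()
            counts = tbl.groupby(f)["dimension"].size()
            return float((counts * (means - grand) ** 2).sum())

        for f in FACTORS:
            f_oracle = (ss_main(f) / 1.0) / (sse / df_err)
            assert aov.effect(f)["F"] == pytest.approx(f_oracle, rel=1e-8)

    def test_single_level_factor_rejected(self, rng):
        tbl = factorial_frame(rng)
        tbl["drug"] = "CX614"
        with pytest.raises(ValueError, match="drug"):
            three_way_anova(tbl, "dimension", FACTORS)


class TestOneWayFilterAnova:
    def _tbl(self, rng, n_groups=10, n=10, shift=0.0):
        rows = []
        for g in range(n_groups):
            mu = shift if g == 0 else 0.0
            for v in mu + rng.standard_normal(n):
                rows.append({"filter_name": f"f{g}", "dimension": v})
        return pd.DataFrame(rows)

    def test_identical_groups_f_near_zero(self):
        base = np.arange(10, dtype=float)
        tbl = pd.DataFrame(
            [{"filter_name": g, "dimension": v}
             for g in ("a", "b") for v in base]
        )
        aov = one_way_filter_anova(tbl, "dimension")
        assert aov.table["F"][0] == pytest.approx(0.0, abs=1e-12)
        assert aov.table["p"][0] == pytest.approx(1.0, abs=1e-9)

    def test_strong_shift_significant(self, rng):
        aov = one_way_filter_anova(self._tbl(rng, shift=5.0), "dimension")
        assert aov.table["p"][0] < 1e-6

    def test_ten_groups_give_nine_df(self, rng):
        aov = one_way_filter_anova(self._tbl(rng), "dimension")
        assert aov.table["df_num"][0] == 9


class TestTukey:
    def _tbl(self, rng, shift_group=None, n_groups=5, n=10):
        rows = []
        for g in range(n_groups):
            mu = 5.0 if g == shift_group else 0.0
            for v in mu + rng.standard_normal(n):
                rows.append({"filter_name": f"f{g}", "dimension": v})
        return pd.DataFrame(rows)

    def test_identical_groups_nothing_significant(self, rng):
        out = tukey_hsd(self._tbl(rng), "dimension", "filter_name")
        assert not out.table["significant"].any()

    def test_one_shifted_group_flags_exactly_its_pairs(self, rng):
        out = tukey_hsd(self._tbl(rng, shift_group=0), "dimension",
                        "filter_name")
        sig = out.table[out.table["significant"]]
        assert len(sig) == 4
        assert all("f0" in (r.group1, r.group2) for r in sig.itertuples())

    def test_small_group_inestimable(self, rng):
        tbl = self._tbl(rng)
        tbl = pd.concat(
            [tbl, pd.DataFrame([{"filter_name": "tiny", "dimension": 0.0}])]
        )
        out = tukey_hsd(tbl, "dimension", "filter_name")
        tiny = out.table[
            (out.table["group1"] == "tiny") | (out.table["group2"] == "tiny")
        ]
        assert len(tiny) == 5 and not tiny["estimable"].any()

    def test_adjusted_p_matches_scipy_oracle(self, rng):
        """Adjusted p's agree with an independent studentized-range
        implementation wherever decisions are made (p < 0.2)."""
        from scipy.stats import tukey_hsd as scipy_tukey

        data = [rng.standard_normal(8) + (2.0 if i == 0 else 0.0)
                for i in range(5)]
        tbl = pd.DataFrame(
            [{"filter_name": f"g{i}", "dimension": v}
             for i, d in enumerate(data) for v in d]
        )
        mine = tukey_hsd(tbl, "dimension", "filter_name").table
        ref = scipy_tukey(*data)
        for r in mine.itertuples():
            i, j = int(r.group1[1]), int(r.group2[1])
            p_ref = ref.pvalue[i, j]
            assert (r.p_adj <= 0.05) == (p_ref <= 0.05)
            if p_ref < 0.2:
                assert r.p_adj == pytest.approx(p_ref, abs=1e-4)

    def test_significance_tiers(self):
        assert significance_tier(0.05) == "*"
        assert significance_tier(0.009) == "**"
        assert significance_tier(5e-5) == "***"
        assert significance_tier(0.06) == "n.s."


class TestFilterRegression:
    def test_nyquist_substitution_for_unbounded_edges(self):
        preds = filter_predictors(fs=1000.0).set_index("filter_name")
        assert preds.loc["hp100", "central_tendency"] == 300.0
        assert preds.loc["hp100", "range"] == 400.0
        assert preds.loc["lp100", "central_tendency"] == 50.0
        assert preds.loc["no_filter", "range"] == 500.0
        assert preds.loc["composite_4_100_swr", "range"] == 196.0

    def test_perfectly_collinear_summaries(self):
        preds = filter_predictors()
        summary = preds[["filter_name"]].copy()
        summary["dimension"] = 0.01 * preds["central_tendency"] + 2.0
        fit = filter_property_regression(summary, "central_tendency")
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.01)

    def test_ten_points_eight_df(self, rng):
        summary = filter_predictors()[["filter_name"]].copy()
        summary["dimension"] = rng.standard_normal(10)
        fit = filter_property_regression(summary, "range")
        assert fit.df == 8

    def test_zero_variance_predictor_rejected(self, rng):
        summary = pd.DataFrame(
            {"filter_name": ["theta"], "dimension": [1.0]}
        )
        with pytest.raises(ValueError, match="variance"):
            filter_property_regression(summary, "range")
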