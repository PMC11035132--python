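"""Group-comparison layer: factorial ANOVAs, Tukey HSD, filter regressions.

Dimension, Volume and the wavelet band summaries are compared across age,
drug and maze location (or alternation) by three-way ANOVA with Type-II sums
of squares -- the discard rule leaves cells unbalanced, and Type II reduces
to the classical balanced decomposition when cells are balanced.  Collapsed
across factors, the ten filter conditions are compared by one-way ANOVA with
Tukey honest-significant-difference post hocs.  Filter-property regressions
relate per-filter summaries to the band's central tendency or range, with
unbounded edges replaced by the Nyquist frequency.
"""

from __future__ import annotations

import dataclasses
import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats
from statsmodels.stats.libqsturng import psturng

from .filters import FilterSpec, registry

__all__ = [
    "AnovaTable",
    "PairwiseTable",
    "RegressionFit",
    "three_way_anova",
    "one_way_filter_anova",
    "tukey_hsd",
    "filter_property_regression",
    "filter_predictors",
    "significance_tier",
]


@dataclasses.dataclass
class AnovaTable:
    """Per-effect F/p/df rows, effects ordered main -> two-way -> three-way."""

    table: pd.DataFrame  # columns: effect, F, p, df_num, df_den, estimable

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect {name!r}")
        return rows.iloc[0]


@dataclasses.dataclass
class PairwiseTable:
    """Tukey HSD adjusted pairwise comparisons with significance tiers."""

    table: pd.DataFrame  # columns: group1, group2, diff, p_adj, significant, tier


@dataclasses.dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float
    t: float
    p: float
    df: int
    predictor: str
    response: str


def significance_tier(p: float) -> str:
    """The printed star convention: * <=0.05, ** <0.01, *** <0.0001."""
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def _clean(tbl: pd.DataFrame, response: str, factors: list[str]) -> pd.DataFrame:
    cols = [response, *factors]
    data = tbl[cols].dropna().copy()
    for f in factors:
        data[f] = data[f].astype(str)
    if "discarded" in tbl.columns or "converged" in tbl.columns:
        mask = pd.Series(True, index=tbl.index)
        if "discarded" in tbl.columns:
            mask &= ~tbl["discarded"].astype(bool)
        if "converged" in tbl.columns:
            mask &= tbl["converged"].astype(bool)
        data = data.loc[mask.reindex(data.index, fill_value=False)]
    return data


def three_way_anova(
    tbl: pd.DataFrame, response: str, factors: tuple[str, str, str]
) -> AnovaTable:
    """Full-factorial three-way ANOVA (Type-II sums of squares).

    Rows flagged ``discarded`` or unconverged are excluded before modeling.
    Effects whose cells are empty are reported as inestimable, not invented.
    """
    f1, f2, f3 = factors
    data = _clean(tbl, response, list(factors))
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 observed levels")
    formula = f"Q('{response}') ~ C(Q('{f1}')) * C(Q('{f2}')) * C(Q('{f3}'))"
    model = smf.ols(formula, data=data).fit()
    if np.allclose(data[response].var(ddof=0), 0.0):
        # constant response: F = 0 for every effect by convention
        effects = _effect_names(factors)
        rows = [
            {"effect": e, "F": 0.0, "p": 1.0, "df_num": np.nan,
             "df_den": model.df_resid, "estimable": True}
            for e in effects
        ]
        return AnovaTable(table=pd.DataFrame(rows))
    aov = sm.stats.anova_lm(model, typ=2)
    rows = []
    for e, sm_name in zip(_effect_names(factors), _sm_terms(factors, response)):
        if sm_name in aov.index:
            r = aov.loc[sm_name]
            f_val, p_val = float(r["F"]), float(r["PR(>F)"])
            estimable = np.isfinite(f_val)
            rows.append(
                {"effect": e, "F": f_val if estimable else np.nan,
                 "p": p_val if estimable else np.nan,
                 "df_num": float(r["df"]), "df_den": float(model.df_resid),
                 "estimable": bool(estimable)}
            )
        else:
            rows.append({"effect": e, "F": np.nan, "p": np.nan,
                         "df_num": np.nan, "df_den": np.nan, "estimable": False})
    return AnovaTable(table=pd.DataFrame(rows))


def _effect_names(factors: tuple[str, str, str]) -> list[str]:
    f1, f2, f3 = factors
    return [
        f1, f2, f3,
        f"{f1} x {f2}", f"{f1} x {f3}", f"{f2} x {f3}",
        f"{f1} x {f2} x {f3}",
    ]


def _sm_terms(factors: tuple[str, str, str], response: str) -> list[str]:
    def c(f: str) -> str:
        return f"C(Q('{f}'))"

    f1, f2, f3 = factors
    return [
        c(f1), c(f2), c(f3),
        f"{c(f1)}:{c(f2)}", f"{c(f1)}:{c(f3)}", f"{c(f2)}:{c(f3)}",
        f"{c(f1)}:{c(f2)}:{c(f3)}",
    ]


def one_way_filter_anova(
    tbl: pd.DataFrame, response: str, group: str = "filter_name"
) -> AnovaTable:
    """Single-factor ANOVA across filter conditions (data already collapsed)."""
    data = _clean(tbl, response, [group])
    groups = [g[response].to_numpy() for _, g in data.groupby(group)]
    if len(groups) < 2:
        raise ValueError("need >= 2 filter groups")
    if np.allclose(np.var(data[response], ddof=0), 0.0):
        f_val, p_val = 0.0, 1.0
    else:
        f_val, p_val = sstats.f_oneway(*groups)
    df_num = len(groups) - 1
    df_den = len(data) - len(groups)
    return AnovaTable(
        table=pd.DataFrame(
            [{"effect": group, "F": float(f_val), "p": float(p_val),
              "df_num": df_num, "df_den": df_den, "estimable": True}]
        )
    )


@lru_cache(maxsize=64)
def _studentized_range_grid(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated q -> p curve for interpolation (smooth and monotone)."""
    q = np.linspace(0.02, 12.0, 600)
    p = np.asarray(psturng(q, k, df), dtype=float).ravel()
    return q, p


def _tukey_p(q_obs: np.ndarray, k: int, df: int) -> np.ndarray:
    """Adjusted p from the studentized range; exact tail where the
    interpolation table saturates (needed to resolve the p<0.0001 tier)."""
    qg, pg = _studentized_range_grid(k, df)
    p = np.interp(q_obs, qg, pg)
    # exact where the table saturates and around the 0.05 decision boundary
    refine = (p <= 1.5e-3) | ((p > 0.02) & (p < 0.12))
    refine &= np.isfinite(q_obs)
    if refine.any():
        p[refine] = sstats.studentized_range.sf(q_obs[refine], k, df)
    return np.clip(p, 0.0, 1.0)


def tukey_hsd(
    tbl: pd.DataFrame, response: str, group: str, alpha: float = 0.05
) -> PairwiseTable:
    """All pairwise comparisons via the studentized range distribution
    (Tukey-Kramer standard errors for unequal group sizes).

    Groups with fewer than 2 observations make their pairs inestimable.
    """
    data = _clean(tbl, response, [group])
    sizes = data.groupby(group).size()
    valid = sizes[sizes >= 2].index
    small = sorted(set(sizes.index) - set(valid))
    sub = data[data[group].isin(valid)]
    rows = []
    if len(valid) >= 2:
        stats = sub.groupby(group)[response].agg(["mean", "size", "var"])
        names = [str(g) for g in stats.index]
        k = len(names)
        n_tot = int(stats["size"].sum())
        df_err = n_tot - k
        mse = float(
            ((stats["size"] - 1) * stats["var"]).sum() / df_err
        )
        means = stats["mean"].to_numpy()
        ns = stats["size"].to_numpy(dtype=float)
        pairs = list(itertools.combinations(range(k), 2))
        diffs = np.array([means[j] - means[i] for i, j in pairs])
        se = np.array(
            [np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j])) for i, j in pairs]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            q_obs = np.where(
                se > 0,
                np.abs(diffs) / np.where(se > 0, se, 1.0),
                np.where(np.abs(diffs) > 0, np.inf, 0.0),
            )
        p_adj = _tukey_p(q_obs, k, df_err)
        for (i, j), diff, p in zip(pairs, diffs, p_adj):
            p = float(p)
            rows.append(
                {"group1": names[i], "group2": names[j],
                 "diff": float(diff), "p_adj": p,
                 "significant": p <= alpha, "tier": significance_tier(p),
                 "estimable": True}
            )
    for g1, g2 in itertools.combinations(sorted(sizes.index), 2):
        if g1 in small or g2 in small:
            rows.append(
                {"group1": str(g1), "group2": str(g2), "diff": np.nan,
                 "p_adj": np.nan, "significant": False, "tier": "n.s.",
                 "estimable": False}
            )
    return PairwiseTable(table=pd.DataFrame(rows))


def filter_predictors(fs: float = 1000.0) -> pd.DataFrame:
    """Central tendency and range per filter, Nyquist-substituted.

    A missing upper bound (high-pass, no filter) is replaced by fs/2; a
    missing lower bound (low-pass, no filter) by 0.  The composite condition
    spans the union of its component bands.
    """
    rows = []
    for name, spec in registry().items():
        lo, hi = spec.effective_edges(fs)
        rows.append(
            {"filter_name": name, "central_tendency": 0.5 * (lo + hi),
             "range": hi - lo}
        )
    return pd.DataFrame(rows)


def filter_property_regression(
    summary: pd.DataFrame,
    predictor: str = "central_tendency",
    response: str = "dimension",
    fs: float = 1000.0,
) -> RegressionFit:
    """Linear regression of a per-filter summary statistic on a band property.

    ``summary`` must have one row per filter (column ``filter_name``) and the
    response column (e.g. a mean or IQR of Dimension or Volume).
    """
    if predictor not in ("central_tendency", "range"):
        raise ValueError(f"unknown predictor {predictor!r}")
    preds = filter_predictors(fs)
    merged = summary.merge(preds, on="filter_name", how="inner")
    x = merged[predictor].to_numpy(dtype=float)
    y = merged[response].to_numpy(dtype=float)
    if np.allclose(x.var(), 0.0):
        raise ValueError("predictor has zero variance: degenerate fit")
    res = sstats.linregress(x, y)
    df = len(x) - 2
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        t=float(res.slope / res.stderr) if res.stderr > 0 else np.inf,
        p=float(res.pvalue),
        df=df,
        predictor=predictor,
        response=response,
    )


def band_spec(name: str) -> FilterSpec:
    """Convenience: the registry entry for a named band."""
    return registry()[name]
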