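"""Group comparisons, correlations, property GLMs, and moderation.

This layer mirrors the downstream statistics of a case-control network
study: two-sample comparisons with Cohen's d effect sizes, Pearson
correlations among cognitive scores with Bonferroni correction,
group-by-global-property interaction GLMs on the AUC summaries, and
moderated multiple regression with percentile-bootstrap confidence
intervals for the interaction (the PROCESS-style analysis, 5000
resamples by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._errors import CollinearityError, DegenerateInputError, SchemaError

__all__ = [
    "EffectSize",
    "ModerationFit",
    "cohens_d",
    "group_tests",
    "correlation_matrix",
    "property_interaction_glm",
    "moderation_analysis",
]


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float


def cohens_d(mean1, sd1, n1, mean2, sd2, n2, ci_level: float = 0.95) -> EffectSize:
    """Absolute Cohen's d with its normal-approximation CI.

    d = |mean1 - mean2| / s_pooled with the pooled SD over both groups;
    the CI uses SE = sqrt(1/n1 + 1/n2 + d^2 / (2 (n1 + n2))).
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    diff = abs(mean1 - mean2)
    if pooled == 0.0:
        if diff == 0.0:
            return EffectSize(0.0, 0.0, 0.0)
        raise DegenerateInputError("zero pooled SD with unequal means: infinite effect")
    d = diff / pooled
    se = np.sqrt(1.0 / n1 + 1.0 / n2 + d**2 / (2.0 * (n1 + n2)))
    zq = sps.norm.ppf(0.5 + ci_level / 2.0)
    return EffectSize(float(d), float(d - zq * se), float(d + zq * se))


def group_tests(
    table: pd.DataFrame,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    group_col: str = "group",
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group comparisons: t-test + Cohen's d or chi-square per variable."""
    if group_col not in table.columns:
        raise SchemaError(f"missing group column {group_col!r}")
    levels = list(pd.unique(table[group_col]))
    if len(levels) != 2:
        raise SchemaError(f"group column must have exactly two levels, found {levels}")
    a = table[table[group_col] == levels[0]]
    b = table[table[group_col] == levels[1]]
    rows = []
    for var in continuous:
        x, y = a[var].dropna(), b[var].dropna()
        t, p = sps.ttest_ind(x, y, equal_var=not welch)
        eff = cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
        rows.append({
            "variable": var, "kind": "continuous", "test": "welch-t" if welch else "t",
            f"mean_{levels[0]}": x.mean(), f"sd_{levels[0]}": x.std(ddof=1),
            f"n_{levels[0]}": len(x),
            f"mean_{levels[1]}": y.mean(), f"sd_{levels[1]}": y.std(ddof=1),
            f"n_{levels[1]}": len(y),
            "stat": float(t), "p": float(p),
            "cohens_d": eff.d, "d_ci_low": eff.ci_low, "d_ci_high": eff.ci_high,
        })
    for var in categorical:
        ct = pd.crosstab(table[group_col], table[var])
        res = sps.chi2_contingency(ct, correction=False)
        rows.append({
            "variable": var, "kind": "categorical", "test": "chi2",
            f"n_{levels[0]}": int(ct.loc[levels[0]].sum()),
            f"n_{levels[1]}": int(ct.loc[levels[1]].sum()),
            "stat": float(res.statistic), "p": float(res.pvalue),
        })
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame,
    columns: Sequence[str],
    correction: str = "bonferroni",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with Bonferroni-adjusted p-values.

    Returns a tidy frame (var1, var2, n, r, p, p_adj); constant columns
    yield NaN sentinels for their pairs. The Bonferroni family defaults
    to the number of tested pairs but can be declared explicitly.
    """
    pairs = list(combinations(columns, 2))
    m = family_size if family_size is not None else len(pairs)
    rows = []
    for v1, v2 in pairs:
        sub = table[[v1, v2]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({v1}, {v2}): fewer than 3 complete rows")
        x, y = sub[v1].to_numpy(float), sub[v2].to_numpy(float)
        if x.std() == 0.0 or y.std() == 0.0:
            r = p = p_adj = float("nan")
        else:
            r, p = sps.pearsonr(x, y)
            p_adj = min(1.0, m * p)
        rows.append({"var1": v1, "var2": v2, "n": len(sub),
                     "r": float(r), "p": float(p), "p_adj": float(p_adj)})
    out = pd.DataFrame(rows)
    out.attrs["family_size"] = m
    out.attrs["correction"] = correction
    return out


def property_interaction_glm(
    table: pd.DataFrame,
    properties: pd.DataFrame,
    score: str,
    group_col: str = "group",
    reference: str = "HC",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Group-by-property GLMs on the AUC summaries, one property at a time.

    For each property column, fits score ~ group + property +
    group:property and reports the three non-intercept terms with
    Bonferroni-adjusted interaction p-values (family = number of
    properties by default).
    """
    common = table.index.intersection(properties.index)
    if len(common) < 10:
        raise SchemaError("fewer than 10 subjects shared between tables")
    tab = table.loc[common]
    props = properties.loc[common]
    metrics = [c for c in props.columns if not c.endswith("__coverage")]
    m = family_size if family_size is not None else len(metrics)
    levels = list(pd.unique(tab[group_col]))
    if reference not in levels or len(levels) != 2:
        raise SchemaError(f"need two groups with reference {reference!r}")
    other = next(g for g in levels if g != reference)
    g = (tab[group_col] == other).to_numpy(float)
    y = tab[score].to_numpy(float)

    rows = []
    skipped = []
    for metric in metrics:
        x = props[metric].to_numpy(float)
        keep = ~np.isnan(x)
        # undefined-value sentinels (e.g. assortativity on degenerate
        # graphs) shrink the usable sample; too few rows -> skip metric
        if keep.sum() < 10 or len(np.unique(g[keep])) < 2:
            skipped.append(metric)
            continue
        xm, gm, ym = x[keep], g[keep], y[keep]
        if xm.std() == 0.0:
            raise CollinearityError(
                f"property {metric!r} is constant across subjects", aliased=(metric,)
            )
        X = pd.DataFrame({
            "const": 1.0, f"group[{other}]": gm, metric: xm,
            f"group[{other}]:{metric}": gm * xm,
        })
        # a near-constant property (e.g. a graph metric that is pinned at
        # one value for almost every subject) gives an ill-conditioned
        # design; skip it rather than report meaningless coefficients
        if np.linalg.cond(X.to_numpy()) > 1e8:
            skipped.append(metric)
            continue
        res = sm.OLS(ym, X).fit()
        for term in X.columns[1:]:
            rows.append({
                "property": metric, "term": term,
                "B": float(res.params[term]), "SE": float(res.bse[term]),
                "stat": float(res.tvalues[term]), "p": float(res.pvalues[term]),
                "p_adj": float(min(1.0, m * res.pvalues[term])),
            })
    out = pd.DataFrame(rows)
    out.attrs["family_size"] = m
    out.attrs["skipped"] = skipped
    return out


@dataclass
class ModerationFit:
    """Moderated-regression result with bootstrap CI for the interaction."""

    dependent: str
    independent: str
    moderator: str
    coefficients: pd.Series          # b0, b_x, b_m, b_xm (centered scale)
    interaction: float               # raw b_xm
    interaction_std: float           # fully standardized interaction coefficient
    interaction_p: float
    ci_low: float
    ci_high: float
    simple_slopes: pd.DataFrame      # slope of y on x at m = mean -/+ 1 SD
    n: int
    n_boot: int
    rng_seed: int
    ci_level: float


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


def moderation_analysis(
    y,
    x,
    m,
    n_boot: int = 5000,
    rng_seed: int = 0,
    ci_level: float = 0.95,
    names: tuple[str, str, str] = ("y", "x", "m"),
) -> ModerationFit:
    """Moderated multiple regression with percentile-bootstrap CI.

    Regresses y on mean-centered x, m and their product; the interaction
    coefficient's CI comes from case-resampling percentile bootstrap
    (``n_boot`` draws, deterministic given ``rng_seed``). Simple slopes
    of y on x are reported at moderator mean -/+ 1 SD. The standardized
    interaction coefficient (all three variables z-scored before the
    product is formed) is reported alongside the raw one.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    n = len(y)
    if not (len(x) == len(m) == n):
        raise ValueError("y, x, m must share length")
    if n < 20:
        raise ValueError(f"moderation needs n >= 20, got {n}")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    xc = x - x.mean()
    mc = m - m.mean()
    X = np.column_stack([np.ones(n), xc, mc, xc * mc])
    if np.linalg.matrix_rank(X) < 4 or np.linalg.cond(X.T @ X) > 1e12:
        raise CollinearityError("near-singular moderation design")
    res = sm.OLS(y, X).fit()
    beta = res.params
    p_int = float(res.pvalues[3])

    # standardized coefficient: z-score y, x, m, then form the product
    sx, sm_, sy = x.std(ddof=1), m.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sm_ == 0.0 or sy == 0.0:
        raise DegenerateInputError("constant variable in moderation analysis")
    Zs = np.column_stack([np.ones(n), xc / sx, mc / sm_, (xc / sx) * (mc / sm_)])
    beta_std = _ols_beta(Zs, (y - y.mean()) / sy)

    # batched percentile bootstrap of the interaction coefficient
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Xb = X[idx]                              # (B, n, 4)
    yb = y[idx]                              # (B, n)
    G = np.einsum("bni,bnj->bij", Xb, Xb)
    c = np.einsum("bni,bn->bi", Xb, yb)
    boots = np.linalg.solve(G, c[..., None])[:, 3, 0]
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])

    sd_m = m.std(ddof=1)
    slopes = pd.DataFrame(
        {
            "m_value": [m.mean() - sd_m, m.mean() + sd_m],
            "slope": [beta[1] - sd_m * beta[3], beta[1] + sd_m * beta[3]],
        },
        index=["mean-1sd", "mean+1sd"],
    )
    return ModerationFit(
        dependent=names[0], independent=names[1], moderator=names[2],
        coefficients=pd.Series(beta, index=["const", "x", "m", "x:m"]),
        interaction=float(beta[3]),
        interaction_std=float(beta_std[3]),
        interaction_p=p_int,
        ci_low=float(lo), ci_high=float(hi),
        simple_slopes=slopes,
        n=n, n_boot=n_boot, rng_seed=rng_seed, ci_level=ci_level,
    )
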