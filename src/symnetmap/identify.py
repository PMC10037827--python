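"""Symptom-based network node selection.

A generalized linear model (Gaussian-identity by default) relates the
behavioral score to the ipsilateral hippocampus-cortex Fisher-z FC
values, the group factor, and group-by-FC interaction terms. With the
reference group coded 0, each FC coefficient is the reference group's
simple slope and coefficient + interaction is the other group's; a
cortical node joins the network when its selection statistic is
significant at ``alpha`` AND the node is consensus structurally
connected. The hippocampal seed is always a member of its own network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._errors import CollinearityError, SampleSizeError, SchemaError
from .fc import seed_target_z
from .structural import WMConnectionTable

__all__ = ["GLMSpec", "GLMFit", "NetworkDefinition", "fit_symptom_glm", "select_nodes"]

SELECTION_RULES = ("simple_slope", "any_group_slope", "interaction")


@dataclass(frozen=True)
class GLMSpec:
    """Model specification for one hemisphere's node-selection GLM."""

    score: str
    pairs: tuple  # ((seed, target), ...) ipsilateral pairs in one model
    group_col: str = "group"
    reference: str = "HC"
    covariates: tuple = ()
    family: str = "gaussian"
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.family != "gaussian":
            raise NotImplementedError("only the Gaussian-identity family is supported")


@dataclass
class GLMFit:
    """Fitted node-selection model.

    ``terms`` holds one row per design column (B, SE, stat, p);
    ``simple_slopes`` one row per (pair, group) with the group-specific
    slope reconstructed from the coefficients and their covariance.
    """

    terms: pd.DataFrame
    simple_slopes: pd.DataFrame
    n: int
    df_resid: float
    deviance: float
    groups: tuple
    spec: GLMSpec


@dataclass
class NetworkDefinition:
    """Selected node set for one hemisphere plus the selection evidence."""

    seed: str
    hemisphere: str | None
    nodes: list
    selection_pvalues: pd.Series
    rule: dict
    warning: str | None = None


def _pair_col(seed, target):
    return f"FC_{seed}-{target}"


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that do not increase the design rank, by greedy scan."""
    aliased, kept = [], np.empty((X.shape[0], 0))
    rank = 0
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            aliased.append(name)
    return aliased


def fit_symptom_glm(
    pheno: pd.DataFrame,
    fc: Mapping[str, pd.DataFrame],
    spec: GLMSpec,
) -> GLMFit:
    """Fit the group-by-FC interaction GLM for one hemisphere.

    Wald tests use a t reference with residual degrees of freedom; the
    fit is the Gaussian maximum-likelihood (equivalently OLS) solution.
    """
    if spec.group_col not in pheno.columns:
        raise SchemaError(f"phenotype table lacks group column {spec.group_col!r}")
    if spec.score not in pheno.columns:
        raise SchemaError(f"phenotype table lacks score column {spec.score!r}")
    groups = list(pd.unique(pheno[spec.group_col]))
    if len(groups) != 2:
        raise SchemaError(f"need exactly two groups, found {groups}")
    if spec.reference not in groups:
        raise SchemaError(f"reference group {spec.reference!r} not present")
    other = next(g for g in groups if g != spec.reference)

    if len(set(spec.pairs)) != len(spec.pairs):
        dupes = [p for p in set(spec.pairs) if spec.pairs.count(p) > 1]
        raise CollinearityError(
            f"duplicated FC pairs are exactly aliased: {dupes}",
            aliased=[_pair_col(*p) for p in dupes],
        )
    zdf = seed_target_z(fc, spec.pairs).loc[pheno.index]
    if zdf.isna().any().any() or pheno[spec.score].isna().any():
        raise SchemaError("missing FC or score values for included subjects")

    y = pheno[spec.score].to_numpy(dtype=float)
    g = (pheno[spec.group_col] == other).to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"const": np.ones(len(pheno))}
    cols[f"group[{other}]"] = g
    for (seed, target) in spec.pairs:
        name = _pair_col(seed, target)
        cols[name] = zdf[name].to_numpy(dtype=float)
    for cov in spec.covariates:
        cols[cov] = pheno[cov].to_numpy(dtype=float)
    for (seed, target) in spec.pairs:
        name = _pair_col(seed, target)
        cols[f"group[{other}]:{name}"] = g * cols[name]

    X = pd.DataFrame(cols, index=pheno.index)
    n, k = X.shape
    if n <= k + 5:
        raise SampleSizeError(f"n = {n} subjects for {k} model terms; need n > terms + 5")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        aliased = _aliased_columns(X.to_numpy(), list(X.columns))
        raise CollinearityError(
            f"rank-deficient design; aliased terms: {aliased}", aliased=aliased
        )

    res = sm.OLS(y, X).fit()
    df_resid = float(res.df_resid)
    terms = pd.DataFrame(
        {"B": res.params, "SE": res.bse, "stat": res.tvalues, "p": res.pvalues}
    )
    V = res.cov_params()

    rows = []
    for (seed, target) in spec.pairs:
        name = _pair_col(seed, target)
        iname = f"group[{other}]:{name}"
        b_ref, se_ref = res.params[name], res.bse[name]
        rows.append((name, spec.reference, b_ref, se_ref))
        b_oth = res.params[name] + res.params[iname]
        se_oth = np.sqrt(
            V.loc[name, name] + V.loc[iname, iname] + 2.0 * V.loc[name, iname]
        )
        rows.append((name, other, b_oth, se_oth))
    slopes = pd.DataFrame(rows, columns=["pair", "group", "slope", "SE"])
    slopes["stat"] = slopes["slope"] / slopes["SE"]
    slopes["p"] = 2.0 * sps.t.sf(np.abs(slopes["stat"]), df_resid)
    slopes = slopes.set_index(["pair", "group"])

    return GLMFit(
        terms=terms,
        simple_slopes=slopes,
        n=n,
        df_resid=df_resid,
        deviance=float(res.ssr),
        groups=(spec.reference, other),
        spec=spec,
    )


def select_nodes(
    fit: GLMFit,
    wm: WMConnectionTable,
    alpha: float | None = None,
    rule: str = "simple_slope",
    slope_group: str | None = None,
) -> NetworkDefinition:
    """Select network nodes from a fitted GLM and the structural consensus.

    Rules
    -----
    ``simple_slope``
        p-value of the designated group's simple slope (default the
        reference group), invariant to how the group factor is coded.
    ``any_group_slope``
        significant if either group's simple slope passes ``alpha``.
    ``interaction``
        p-value of the group-by-FC interaction term.
    """
    if rule not in SELECTION_RULES:
        raise ValueError(f"rule must be one of {SELECTION_RULES}, got {rule!r}")
    alpha = fit.spec.alpha if alpha is None else alpha
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    slope_group = fit.groups[0] if slope_group is None else slope_group
    if slope_group not in fit.groups:
        raise SchemaError(f"slope_group {slope_group!r} not among {fit.groups}")

    seed = fit.spec.pairs[0][0]
    connected = set(wm.connected_regions)
    other = fit.groups[1]

    pvals = {}
    for (s, target) in fit.spec.pairs:
        name = _pair_col(s, target)
        if rule == "simple_slope":
            p = fit.simple_slopes.loc[(name, slope_group), "p"]
        elif rule == "any_group_slope":
            p = fit.simple_slopes.loc[[(name, g) for g in fit.groups], "p"].min()
        else:
            p = fit.terms.loc[f"group[{other}]:{name}", "p"]
        pvals[target] = float(p)
    pvalues = pd.Series(pvals, name="p").rename_axis("node")

    candidates = [t for t in pvals if t in connected]
    selected = [t for t in candidates if pvals[t] < alpha]
    warning = None
    if not candidates:
        warning = (
            f"empty candidate set for seed {seed}: no modeled pair is "
            "consensus structurally connected"
        )
        warnings.warn(warning, stacklevel=2)

    hemi = seed.rsplit(".", 1)[-1] if "." in seed else None
    return NetworkDefinition(
        seed=seed,
        hemisphere=hemi,
        nodes=[seed] + sorted(selected),
        selection_pvalues=pvalues,
        rule={
            "rule": rule,
            "alpha": alpha,
            "slope_group": slope_group if rule == "simple_slope" else None,
            "multiplicity_correction": "none (uncorrected at the selection step)",
        },
        warning=warning,
    )
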