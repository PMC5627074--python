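"""Multinomial logistic models for pattern frequencies and the
random-intercept model for amplicon strand effects.

The multinomial model treats each read's pattern as a categorical outcome
with softmax-linear dependence on design factors (strand, replicate,
group). The fit maximises the exact multinomial likelihood on the cell
count table with a fixed small ridge penalty (1e-6) on the coefficients,
which guarantees a unique optimum even under complete separation — the
situation that actually arises when a pattern is abundant on one strand
and absent from the other. Residual deviance follows the -2*loglik
convention, so nested-model comparisons reduce to deviance differences.

Strand effects on methylation *levels* across replicate samples use a
linear mixed model (level ~ strand, random intercept per sample): REML for
the variance components, and a likelihood-ratio test of ML fits with and
without strand for the asymmetry p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .patterns import PatternTable
from .simdata import ErrorModel

__all__ = [
    "MultinomFit",
    "LmmFit",
    "cells_from_table",
    "fit_multinomial",
    "lrt_factor",
    "compare_groups",
    "fit_strand_lmm",
]

RIDGE = 1e-6
#: |coefficient| beyond which separation is suspected despite the ridge.
SEPARATION_COEF = 15.0


class ModelError(ValueError):
    pass


@dataclass
class MultinomFit:
    design: tuple[str, ...]
    feature_names: tuple[str, ...]
    patterns: tuple[str, ...]  # non-reference outcome categories
    reference: str
    coef: pd.DataFrame  # index = feature, columns = non-reference patterns
    loglik: float
    residual_deviance: float
    df: int
    wald: pd.DataFrame  # pattern, term, coef, se, z, p
    ridge: float = RIDGE
    separation_suspected: bool = False
    n_obs: float = 0.0

    def strand_wald(self, term: str = "strand") -> pd.DataFrame:
        """Per-pattern Wald tests for one factor's coefficients."""
        return self.wald[self.wald["term"].str.startswith(term)].reset_index(drop=True)


@dataclass
class LmmFit:
    beta_strand: float
    sigma2_sample: float
    sigma2_resid: float
    p_strand: float
    n_obs: int
    method: str = "lmm"

    @property
    def asymmetric(self) -> bool:
        return self.p_strand < 0.05


def cells_from_table(
    table: PatternTable, use_em: bool = False, err: ErrorModel | None = None
) -> pd.DataFrame:
    """Tidy cell table (strand, replicate, group, sample, pattern, count).

    ``use_em=True`` replaces raw counts with EM-estimated frequencies
    scaled by the stratum coverage (effective counts), mirroring analyses
    run on estimated rather than observed pattern frequencies.
    """
    cells = table.counts.copy()
    if use_em:
        from .patterns import estimate_frequencies_em

        est = estimate_frequencies_em(table, err or ErrorModel())
        cov = table.coverage().set_index(["sample", "strand"])["coverage"]
        merged = est.freqs.merge(
            cells[["sample", "replicate", "group", "strand"]].drop_duplicates(),
            on=["sample", "strand"],
        )
        merged["count"] = merged.apply(
            lambda r: r["freq"] * cov.loc[(r["sample"], r["strand"])], axis=1
        )
        cells = merged[["sample", "replicate", "group", "strand", "pattern", "count"]]
    return cells


def _design_matrix(cells: pd.DataFrame, design: list[str]) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Intercept + treatment-coded dummies; single-level factors dropped."""
    kept = []
    for f in design:
        if f not in cells.columns:
            raise ModelError(f"design factor {f!r} missing from cells")
        if cells[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped from design")
        else:
            kept.append(f)
    combos = cells[kept].drop_duplicates().reset_index(drop=True) if kept else pd.DataFrame(
        {"_const": [1]}
    )
    cols: list[np.ndarray] = [np.ones(len(combos))]
    names = ["(Intercept)"]
    for f in kept:
        levels = sorted(combos[f].astype(str).unique())
        for lev in levels[1:]:
            cols.append((combos[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    return X, names, combos


def fit_multinomial(
    counts: pd.DataFrame | PatternTable,
    design: list[str],
    ridge: float = RIDGE,
) -> MultinomFit:
    """Ridge-stabilised ML fit of a softmax-linear pattern model.

    ``counts``: tidy cell frame with a ``pattern`` and ``count`` column
    plus the design factor columns (or a :class:`PatternTable`). The
    reference pattern is the most abundant pooled pattern (ties broken by
    lexicographic order). Deterministic: the penalised likelihood is
    strictly convex.
    """
    cells = counts.counts if isinstance(counts, PatternTable) else counts
    if cells.empty or cells["pattern"].nunique() < 2:
        raise ModelError("need >= 2 patterns to fit a multinomial model")
    X, names, combos = _design_matrix(cells, list(design))
    kept_factors = [n.split("[")[0] for n in names[1:]]
    pooled = cells.groupby("pattern")["count"].sum().sort_values(ascending=False)
    top = pooled[pooled == pooled.iloc[0]]
    reference = sorted(top.index)[0]
    others = sorted(p for p in pooled.index if p != reference)
    cats = [reference] + others
    K, P, C = len(cats), X.shape[1], len(combos)

    # cell x category count matrix aligned with combos
    key_cols = [c for c in combos.columns if c != "_const"]
    if key_cols:
        idx = {tuple(map(str, row)): i for i, row in enumerate(combos[key_cols].astype(str).itertuples(index=False))}
        cell_idx = [
            idx[tuple(map(str, t))]
            for t in cells[key_cols].astype(str).itertuples(index=False)
        ]
    else:
        cell_idx = [0] * len(cells)
    cat_idx = {c: j for j, c in enumerate(cats)}
    N = np.zeros((C, K))
    for ci, pat, cnt in zip(cell_idx, cells["pattern"], cells["count"]):
        N[ci, cat_idx[pat]] += cnt
    row_tot = N.sum(axis=1)

    def unpack(theta):
        return theta.reshape(P, K - 1)

    def nll_grad(theta):
        B = unpack(theta)
        eta = np.concatenate([np.zeros((C, 1)), X @ B], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        expo = np.exp(eta)
        Z = expo.sum(axis=1)
        logp = eta - np.log(Z)[:, None]
        ll = float((N * logp).sum())
        probs = expo / Z[:, None]
        resid = probs[:, 1:] * row_tot[:, None] - N[:, 1:]
        grad = X.T @ resid + ridge * B
        return -ll + 0.5 * ridge * float((B**2).sum()), grad.ravel()

    theta0 = np.zeros(P * (K - 1))
    res = optimize.minimize(
        nll_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    B = unpack(res.x)
    eta = np.concatenate([np.zeros((C, 1)), X @ B], axis=1)
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)
    loglik = float((N * np.log(np.maximum(probs, np.finfo(float).tiny))).sum())

    # exact Hessian of the penalised NLL for Wald covariances
    H = np.zeros((P * (K - 1), P * (K - 1)))
    for c in range(C):
        p = probs[c, 1:]
        W = np.diag(p) - np.outer(p, p)
        H += row_tot[c] * np.kron(W, np.outer(X[c], X[c]))
    H += ridge * np.eye(P * (K - 1))
    cov = np.linalg.inv(H)
    # theta layout is (P, K-1) raveled row-major: index = f*(K-1) + k.
    # kron(W, xx^T) layout is (K-1, P) blocks, i.e. index = k*P + f;
    # permute covariance into theta layout.
    perm = np.array([[k * P + f for k in range(K - 1)] for f in range(P)]).ravel()
    cov = cov[np.ix_(perm, perm)]
    se = np.sqrt(np.diag(cov)).reshape(P, K - 1)
    z = np.where(se > 0, B / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    wald = pd.DataFrame(
        [
            {
                "pattern": cats[k + 1],
                "term": names[f],
                "coef": B[f, k],
                "se": se[f, k],
                "z": z[f, k],
                "p": pvals[f, k],
            }
            for f in range(P)
            for k in range(K - 1)
        ]
    )
    coef = pd.DataFrame(B, index=names, columns=cats[1:])
    return MultinomFit(
        design=tuple(dict.fromkeys(kept_factors)),
        feature_names=tuple(names),
        patterns=tuple(cats[1:]),
        reference=reference,
        coef=coef,
        loglik=loglik,
        residual_deviance=-2.0 * loglik,
        df=P * (K - 1),
        wald=wald,
        ridge=ridge,
        separation_suspected=bool(np.abs(B).max() > SEPARATION_COEF),
        n_obs=float(row_tot.sum()),
    )


def lrt_factor(full: MultinomFit, reduced: MultinomFit) -> tuple[float, int, float]:
    """Likelihood-ratio (deviance) comparison of nested multinomial fits."""
    if not set(reduced.feature_names) <= set(full.feature_names):
        raise ModelError(
            f"reduced design {reduced.feature_names} is not nested in {full.feature_names}"
        )
    dd = reduced.residual_deviance - full.residual_deviance
    if dd < -1e-6 * max(1.0, abs(full.residual_deviance)):
        raise ModelError(f"nested deviance inversion: {dd}")
    dd = max(dd, 0.0)
    df = full.df - reduced.df
    p = float(stats.chi2.sf(dd, df)) if df > 0 else 1.0
    return float(dd), int(df), p


def compare_groups(
    tables: dict[str, PatternTable] | pd.DataFrame,
    design: list[str] = ("strand", "replicate", "group"),
    alpha: float = 0.05,
    use_em: bool = False,
    err: ErrorModel | None = None,
) -> dict:
    """Per-pattern group (caste) tests from a strand+replicate+group model.

    ``tables`` is either a combined tidy cell frame or a mapping
    group -> PatternTable. Returns the fit, the per-pattern group Wald
    table, and the fraction of patterns significant at ``alpha``.
    """
    if isinstance(tables, dict):
        frames = []
        for group, tab in tables.items():
            cells = cells_from_table(tab, use_em=use_em, err=err)
            cells = cells.assign(group=group)
            frames.append(cells)
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = tables
    if cells["group"].nunique() < 2:
        raise ModelError("compare_groups needs >= 2 groups")
    fit = fit_multinomial(cells, list(design))
    gw = fit.wald[fit.wald["term"].str.startswith("group")]
    per_pattern = gw.groupby("pattern")["p"].min().reset_index()
    frac = float((per_pattern["p"] < alpha).mean()) if len(per_pattern) else 0.0
    return {
        "fit": fit,
        "group_wald": gw.reset_index(drop=True),
        "per_pattern_p": per_pattern,
        "fraction_significant": frac,
    }


def fit_strand_lmm(levels: pd.DataFrame) -> LmmFit:
    """Strand effect on methylation level with a random intercept per sample.

    ``levels``: columns ``sample``, ``strand`` (plus|minus), ``level``,
    optionally ``unit`` (CpG identifier for the single-sample fallback).
    ``beta_strand`` is the plus-minus fixed effect. With a single sample
    the mixed model is degenerate and a paired t-test across units is used
    instead (flagged in ``method``).
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = levels.copy()
    missing = {"sample", "strand", "level"} - set(df.columns)
    if missing:
        raise ModelError(f"levels frame missing columns {sorted(missing)}")
    if df["sample"].nunique() < 2:
        warnings.warn("single sample: falling back to a paired t-test across units")
        if "unit" not in df.columns:
            raise ModelError("single-sample fallback needs a 'unit' column")
        wide = df.pivot_table(index="unit", columns="strand", values="level")
        if not {"plus", "minus"} <= set(wide.columns):
            raise ModelError("both strands required per sample")
        t, p = stats.ttest_rel(wide["plus"], wide["minus"])
        d = wide["plus"] - wide["minus"]
        return LmmFit(
            beta_strand=float(d.mean()),
            sigma2_sample=float("nan"),
            sigma2_resid=float(d.var(ddof=1)),
            p_strand=float(p),
            n_obs=len(df),
            method="paired_t",
        )
    df["strand"] = pd.Categorical(df["strand"], categories=["minus", "plus"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        reml = smf.mixedlm("level ~ strand", df, groups=df["sample"]).fit(reml=True)
        full = smf.mixedlm("level ~ strand", df, groups=df["sample"]).fit(reml=False)
        null = smf.mixedlm("level ~ 1", df, groups=df["sample"]).fit(reml=False)
    with np.errstate(invalid="ignore"):
        lr = 2.0 * (np.float64(full.llf) - np.float64(null.llf))
    if np.isfinite(lr):
        p_strand = float(stats.chi2.sf(max(lr, 0.0), df=1))
    else:
        # ML likelihood can degenerate when the sample variance hits the
        # boundary; fall back to the Wald test on the REML fixed effect
        z = reml.fe_params["strand[T.plus]"] / reml.bse_fe["strand[T.plus]"]
        p_strand = float(2.0 * stats.norm.sf(abs(z)))
    return LmmFit(
        beta_strand=float(reml.fe_params["strand[T.plus]"]),
        sigma2_sample=float(reml.cov_re.iloc[0, 0]),
        sigma2_resid=float(reml.scale),
        p_strand=p_strand,
        n_obs=len(df),
        method="lmm",
    )
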