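"""Clone-size classification and the regression layer.

Multinomial logistic association of standardized polygenic scores with
clone-size categories (none / small / large, split at a VAF threshold) or
disease subtypes (control / ET / PV / MF), Benjamini-Hochberg FDR,
bidirectional stepwise AIC model selection and family-wise significance
gates. Odds ratios are reported per 1 s.d. of the standardized predictor
with Wald 95% confidence intervals, and the baseline outcome category is
``control`` (or ``none`` for clone categories).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core_io import CohortTable, _log_stage

Z975 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class CloneCall:
    individual_id: str
    vaf: float            # NaN when no clone
    category: str         # none / small / large


@dataclass
class AssociationResult:
    predictor: str
    outcome_category: str
    or_per_sd: float
    ci_low: float
    ci_high: float
    pvalue: float
    fdr_adjusted_p: float = float("nan")
    beta: float = float("nan")
    se: float = float("nan")


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation in a logistic fit."""


def classify_clones(cohort: CohortTable, threshold: float = 0.1
                    ) -> list[CloneCall]:
    """Split carriers into small (VAF < threshold) and large (VAF >= threshold).

    A missing VAF means no clone was observed (category ``none``); the
    boundary VAF belongs to the large category.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0,1)")
    calls = []
    vafs = cohort.df["vaf"] if "vaf" in cohort.df.columns else pd.Series(
        np.nan, index=cohort.df.index)
    for ind, vaf in zip(cohort.df["id"], vafs):
        if pd.isna(vaf):
            calls.append(CloneCall(str(ind), float("nan"), "none"))
        else:
            vaf = float(vaf)
            if not (0.0 < vaf <= 1.0):
                raise ValueError(f"vaf {vaf} outside (0,1]")
            cat = "large" if vaf >= threshold else "small"
            calls.append(CloneCall(str(ind), vaf, cat))
    counts = pd.Series([c.category for c in calls]).value_counts().to_dict()
    _log_stage("classify_clones", **{f"n_{k}": v for k, v in counts.items()})
    return calls


def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify aliased columns via incremental rank
        aliased, kept = [], []
        for j, col in enumerate(X.columns):
            trial = arr[:, [X.columns.get_loc(c) for c in kept] + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                aliased.append(col)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def fit_multinomial(data: pd.DataFrame, outcome: str,
                    predictors: list[str], covariates: list[str] | None = None,
                    reference: str = "control") -> list[AssociationResult]:
    """Maximum-likelihood multinomial logistic fit with Wald inference.

    Returns one result per (predictor, non-reference category): OR =
    exp(coefficient) per unit (1 s.d. for standardized PGSs), Wald 95% CI
    and p-value. Perfect separation and rank-deficient designs raise.
    """
    covariates = covariates or []
    cols = predictors + covariates
    df = data[[outcome] + cols].dropna()
    cats = list(pd.unique(df[outcome]))
    if reference not in cats:
        raise ValueError(f"reference category {reference!r} absent from outcome")
    others = sorted(c for c in cats if c != reference)
    order = [reference] + others
    codes = df[outcome].map({c: i for i, c in enumerate(order)}).to_numpy()
    counts = df[outcome].value_counts()
    empty = [c for c in order if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(f"empty outcome categories: {empty}")
    X = sm.add_constant(df[cols].astype(float), has_constant="add")
    _check_design(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes, X)
        fit = model.fit(method="newton", maxiter=200, disp=False)
    params = np.asarray(fit.params)      # k_vars x (k_cat - 1)
    bse = np.asarray(fit.bse)
    if not np.isfinite(params).all() or np.abs(params).max() > 20:
        bad = np.unravel_index(np.nanargmax(np.abs(params)), params.shape)
        raise SeparationError(
            f"separation suspected for predictor {X.columns[bad[0]]!r}, "
            f"category {others[bad[1]]!r}")
    results = []
    for pred in predictors:
        i = list(X.columns).index(pred)
        for k, cat in enumerate(others):
            b, s = float(params[i, k]), float(bse[i, k])
            p = 2.0 * norm.sf(abs(b / s)) if s > 0 else float("nan")
            results.append(AssociationResult(
                predictor=pred, outcome_category=cat,
                or_per_sd=float(np.exp(b)),
                ci_low=float(np.exp(b - Z975 * s)),
                ci_high=float(np.exp(b + Z975 * s)),
                pvalue=float(p), beta=b, se=s))
    _log_stage("fit_multinomial", outcome=outcome, n=len(df),
               categories=len(order))
    return results


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def add_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    """Fill ``fdr_adjusted_p`` across a family of association results."""
    if not results:
        return results
    adj = bh_fdr([r.pvalue for r in results])
    for r, a in zip(results, adj):
        r.fdr_adjusted_p = float(a)
    return results


def stepwise_select(data: pd.DataFrame, outcome: str,
                    candidates: list[str],
                    initial: list[str] | None = None) -> list[str]:
    """Bidirectional greedy AIC search over linear-model predictors.

    Starts from ``initial`` (default: all candidates), considers all single
    additions and deletions each step, and moves to the lowest-AIC
    neighbour until no move improves AIC. Ties break deterministically by
    predictor name. The returned model's AIC never exceeds the initial
    model's.
    """
    if initial is None:
        initial = list(candidates)
    df = data[[outcome] + sorted(set(candidates) | set(initial))].dropna()
    n = len(df)
    if n <= len(candidates) + 2:
        raise ValueError("too few observations for stepwise selection")
    y = df[outcome].astype(float)

    def aic_of(preds: tuple[str, ...]) -> float:
        X = sm.add_constant(df[list(preds)].astype(float), has_constant="add") \
            if preds else pd.DataFrame({"const": np.ones(n)}, index=df.index)
        return float(sm.OLS(y, X).fit().aic)

    current = tuple(sorted(initial))
    current_aic = aic_of(current)
    while True:
        moves = []
        for c in sorted(candidates):
            if c not in current:
                moves.append(tuple(sorted(current + (c,))))
        for c in current:
            moves.append(tuple(x for x in current if x != c))
        best, best_aic = None, current_aic
        for mv in sorted(moves):
            a = aic_of(mv)
            if a < best_aic - 1e-10:
                best, best_aic = mv, a
        if best is None:
            break
        current, current_aic = best, best_aic
    _log_stage("stepwise_select", outcome=outcome, selected=len(current))
    return list(current)


def significance_gate(pvalues, alpha: float = 0.05, family: str = "bonferroni",
                      m_tests: int = 1) -> np.ndarray:
    """Family-wise significance flags.

    ``bonferroni``: p < alpha / m_tests (so alpha=0.05, m=44 gives the
    0.0011 cut and m=8 the 0.00625 cut); ``fdr``: BH-adjusted p < alpha.
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    p = np.asarray(list(pvalues), dtype=float)
    if family == "bonferroni":
        return p < alpha / m_tests
    if family == "fdr":
        return bh_fdr(p) < alpha
    raise ValueError(f"unknown family {family!r}")
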