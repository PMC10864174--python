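"""Conditional variance explained, bootstrap uncertainty, liability-scale
conversion under case-control ascertainment, and the relative-difference
(delta R^2) germline-contribution decomposition.

Observed-scale R^2 for quantitative traits is the ordinary least-squares
partial R^2 (type-II sums of squares): for predictor v,
partial_r2(v) = (RSS_without_v - RSS_full)/TSS. For binary disease
outcomes, observed-scale R^2 is the coefficient of determination of a
linear-probability fit of the 0/1 outcome on the predictors (the standard
observed-scale convention in liability-transformation work; unlike
correlation with a logistic linear predictor, it is monotone under model
nesting, so nested-model differences are non-negative). It is then mapped
to the unobserved liability scale with the ascertainment-aware
transformation

    R2_liability = R2_observed * [K(1-K)/z^2] * [K(1-K)/(P(1-P))],

where K is population prevalence, P the case proportion in the ascertained
sample, and z the standard-normal density at the liability threshold
Phi^-1(1-K). Liability conversion applies to disease models only, never to
quantitative blood-trait models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, f as f_dist

from .core_io import _log_stage


@dataclass
class VariancePartition:
    variable: str
    partial_r2: float
    se: float = float("nan")
    pvalue: float = float("nan")


@dataclass
class LiabilityParams:
    """Prevalence and ascertainment parameters of the liability model.

    ``threshold_density_z`` is always recomputed as phi(Phi^-1(1-K)), never
    user-supplied.
    """

    prevalence_K: float
    case_proportion_P: float
    threshold_density_z: float = field(init=False)

    def __post_init__(self):
        for name, v in (("prevalence_K", self.prevalence_K),
                        ("case_proportion_P", self.case_proportion_P)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must be strictly inside (0,1)")
        self.threshold_density_z = float(norm.pdf(norm.ppf(1.0 - self.prevalence_K)))

    @property
    def multiplier(self) -> float:
        K, P, z = self.prevalence_K, self.case_proportion_P, self.threshold_density_z
        return (K * (1 - K) / z ** 2) * (K * (1 - K) / (P * (1 - P)))


@dataclass
class DeltaR2Report:
    component: str
    r2_full: float
    r2_reduced: float
    delta_r2_percent: float


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def partial_r2(data: pd.DataFrame, outcome: str, predictors: list[str],
               covariates: list[str] | None = None) -> list[VariancePartition]:
    """Per-predictor variance explained conditional on all other variables.

    partial_r2(v) = (RSS_without_v - RSS_full)/TSS with an F-test p-value
    for the single-column block. The full design (intercept + predictors +
    covariates) must be full rank.
    """
    covariates = covariates or []
    cols = list(predictors) + list(covariates)
    df = data[[outcome] + cols].dropna()
    y = df[outcome].to_numpy(dtype=float)
    n = len(df)
    X_full = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float)
                                             for c in cols])
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        aliased, kept = [], [np.ones((n, 1))]
        for c in cols:
            trial = np.column_stack(kept + [df[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                kept.append(df[c].to_numpy(dtype=float).reshape(-1, 1))
            else:
                aliased.append(c)
        raise ValueError(f"rank-deficient design; aliased predictors: {aliased}")
    tss = float(np.sum((y - y.mean()) ** 2))
    rss_full = _ols_rss(y, X_full)
    dof = n - X_full.shape[1]
    out = []
    for v in predictors:
        keep = [c for c in cols if c != v]
        X_red = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float)
                                                for c in keep])
        rss_red = _ols_rss(y, X_red)
        pr2 = max(rss_red - rss_full, 0.0) / tss
        if rss_full > 0 and dof > 0:
            F = (rss_red - rss_full) / (rss_full / dof)
            p = float(f_dist.sf(max(F, 0.0), 1, dof))
        else:
            p = 0.0 if rss_red > rss_full else 1.0
        out.append(VariancePartition(variable=v, partial_r2=float(pr2), pvalue=p))
    _log_stage("partial_r2", outcome=outcome, n=n, predictors=len(predictors))
    return out


def bootstrap_se(data: pd.DataFrame, outcome: str, predictors: list[str],
                 covariates: list[str] | None = None, n_boot: int = 1000,
                 seed: int = 0) -> dict[str, float]:
    """Nonparametric case-resampling bootstrap of the partial-R^2 vector.

    Each replicate resamples rows with replacement and recomputes the full
    decomposition; a rank-deficient resample is redrawn (at most 10 tries).
    Returns the bootstrap standard deviation per predictor.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    covariates = covariates or []
    df = data[[outcome] + list(predictors) + list(covariates)].dropna()
    df = df.reset_index(drop=True)
    n = len(df)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(predictors)))
    for b in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                parts = partial_r2(df.iloc[idx], outcome, predictors, covariates)
                break
            except ValueError:
                continue
        else:
            raise ValueError("bootstrap resamples persistently rank-deficient")
        boot[b] = [p.partial_r2 for p in parts]
    return {v: float(np.std(boot[:, j], ddof=1))
            for j, v in enumerate(predictors)}


def partial_r2_with_se(data: pd.DataFrame, outcome: str, predictors: list[str],
                       covariates: list[str] | None = None,
                       n_boot: int = 1000, seed: int = 0
                       ) -> list[VariancePartition]:
    parts = partial_r2(data, outcome, predictors, covariates)
    ses = bootstrap_se(data, outcome, predictors, covariates, n_boot, seed)
    for p in parts:
        p.se = ses[p.variable]
    return parts


def liability_transform(r2_observed: float, params: LiabilityParams) -> float:
    """Map observed-scale R^2 to the liability scale under ascertainment.

    Linear and strictly increasing in ``r2_observed``; the result is
    clipped to [0,1] with a warning if the multiplier pushes it beyond.
    """
    if not (0.0 <= r2_observed < 1.0):
        raise ValueError("r2_observed must lie in [0,1)")
    r2_l = r2_observed * params.multiplier
    if r2_l > 1.0:
        warnings.warn("liability-scale R^2 clipped to 1", stacklevel=2)
        r2_l = 1.0
    return float(r2_l)


@dataclass
class DiseaseModelFit:
    """A fitted binary disease model with its observed-scale R^2."""

    outcome: str
    predictors: tuple[str, ...]
    r2_observed: float
    n: int


def fit_disease_model(data: pd.DataFrame, outcome: str,
                      predictors: list[str]) -> DiseaseModelFit:
    """Linear-probability fit of a 0/1 disease indicator.

    Observed-scale R^2 is the OLS coefficient of determination of the 0/1
    outcome on the predictors. A logistic-linear-predictor correlation was
    considered and rejected: it is not monotone when predictors are added,
    which would let a nested-model difference go negative.
    """
    df = data[[outcome] + list(predictors)].dropna()
    y = df[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("disease outcome must be 0/1")
    X = np.column_stack([np.ones(len(df))] +
                        [df[c].to_numpy(dtype=float) for c in predictors])
    rss = _ols_rss(y, X)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else max(1.0 - rss / tss, 0.0)
    return DiseaseModelFit(outcome=outcome, predictors=tuple(predictors),
                           r2_observed=float(r2), n=len(df))


def delta_r2(full: DiseaseModelFit, reduced: DiseaseModelFit,
             params: LiabilityParams, component: str = "") -> DeltaR2Report:
    """Relative difference in liability-scale variance explained,
    delta R^2 (%) = 100 * (R2_full - R2_reduced) / R2_full.

    The reduced model's predictors must be a subset of the full model's and
    both fits must use identical rows. Both R^2 values are converted to the
    liability scale before differencing (the multiplier cancels when K and
    P are shared, leaving the ratio scale-invariant).
    """
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("reduced model predictors must be a subset of the "
                         "full model's")
    if full.n != reduced.n:
        raise ValueError("full and reduced models must be fit on identical rows")
    r2f = liability_transform(full.r2_observed, params)
    r2r = liability_transform(reduced.r2_observed, params)
    if r2f == 0:
        raise ValueError("delta R^2 undefined when the full model explains "
                         "no variance")
    dropped = sorted(set(full.predictors) - set(reduced.predictors))
    return DeltaR2Report(
        component=component or "+".join(dropped),
        r2_full=r2f, r2_reduced=r2r,
        delta_r2_percent=float(100.0 * (r2f - r2r) / r2f))
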