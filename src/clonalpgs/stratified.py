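"""Driver-mutation-stratified quintile odds ratios and median-split
enrichment tests within somatic-mutation carriers.

Quintile contrasts compare the top (or bottom) fifth of the polygenic-score
distribution with the middle three fifths, excluding the opposite extreme,
in the combined case + control set. The enrichment test splits carriers at
the within-carrier PGS median and asks whether *healthy* carriers are
enriched in the low-PGS half: it is reported in the protection orientation
(low-PGS group coded 1, healthy coded 1), so OR > 1 means a low PGS
protects carriers from the disease label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import fisher_exact, nchypergeom_fisher, norm

from .core_io import CohortTable, VALID_DRIVER_CLASSES, _log_stage

Z975 = float(norm.ppf(0.975))


@dataclass
class QuintileResult:
    pgs_name: str
    stratum: str
    contrast: str            # top_vs_middle / bottom_vs_middle
    or_estimate: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_cases: int


@dataclass
class EnrichmentResult:
    pgs_name: str
    subtype: str
    or_estimate: float       # unadjusted 2x2, protection orientation
    ci_low: float
    ci_high: float
    pvalue: float
    counts: tuple[int, int, int, int]   # low-healthy, low-diseased, high-healthy, high-diseased
    adjusted_or: float = float("nan")
    adjusted_ci_low: float = float("nan")
    adjusted_ci_high: float = float("nan")
    adjusted_p: float = float("nan")
    corrected: bool = False             # Haldane-Anscombe 0.5 applied


def assign_quintiles(pgs: np.ndarray) -> np.ndarray:
    """Quintile labels 0..4 with lower-interpolation edges; exact-edge ties
    go to the lower quintile, so assignment is order-independent."""
    pgs = np.asarray(pgs, dtype=float)
    edges = np.quantile(pgs, [0.2, 0.4, 0.6, 0.8], method="lower")
    return np.searchsorted(edges, pgs, side="left")


def _logit_or(y: np.ndarray, x: np.ndarray,
              covariates: np.ndarray | None = None):
    X = x.reshape(-1, 1) if covariates is None else np.column_stack(
        [x, covariates])
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    b, s = float(fit.params[1]), float(fit.bse[1])
    p = 2.0 * norm.sf(abs(b / s)) if s > 0 else float("nan")
    return np.exp(b), np.exp(b - Z975 * s), np.exp(b + Z975 * s), p


def quintile_contrast(pgs: np.ndarray, case_indicator: np.ndarray,
                      covariates: np.ndarray | None = None,
                      pgs_name: str = "PGS", stratum: str = "all"
                      ) -> tuple[QuintileResult, QuintileResult]:
    """Top-vs-middle and bottom-vs-middle logistic odds ratios.

    Quintile boundaries are computed on the combined case + control sample;
    each contrast excludes the opposite extreme quintile. An empty
    quintile-by-case cell raises, naming the cell.
    """
    pgs = np.asarray(pgs, dtype=float)
    y = np.asarray(case_indicator, dtype=float)
    q = assign_quintiles(pgs)
    results = []
    for contrast, extreme, excluded in (("top_vs_middle", 4, 0),
                                        ("bottom_vs_middle", 0, 4)):
        keep = q != excluded
        sub_q, sub_y = q[keep], y[keep]
        indicator = (sub_q == extreme).astype(float)
        for grp, gname in ((1.0, f"quintile {extreme}"), (0.0, "middle quintiles")):
            for cls, cname in ((1.0, "cases"), (0.0, "controls")):
                if not np.any((indicator == grp) & (sub_y == cls)):
                    raise ValueError(f"empty cell: {cname} in {gname} "
                                     f"({contrast})")
        cov = covariates[keep] if covariates is not None else None
        or_, lo, hi, p = _logit_or(sub_y, indicator, cov)
        results.append(QuintileResult(
            pgs_name=pgs_name, stratum=stratum, contrast=contrast,
            or_estimate=float(or_), ci_low=float(lo), ci_high=float(hi),
            pvalue=float(p), n_cases=int(y.sum())))
    _log_stage("quintile_contrast", stratum=stratum, n=len(pgs))
    return results[0], results[1]


def _exact_or_ci(a: int, b: int, c: int, d: int, alpha: float = 0.05):
    """Exact OR confidence interval by inverting the Fisher noncentral
    hypergeometric distribution (conditional on both margins)."""
    n1, n0 = a + b, c + d          # rows: low / high
    m1 = a + c                     # first-column (healthy) total
    total = a + b + c + d
    lo_support = max(0, m1 - n0)
    hi_support = min(m1, n1)

    def cdf_ge(psi):   # P(X >= a | psi)
        return float(nchypergeom_fisher.sf(a - 1, total, n1, m1, psi))

    def cdf_le(psi):   # P(X <= a | psi)
        return float(nchypergeom_fisher.cdf(a, total, n1, m1, psi))

    if a == lo_support:
        lower = 0.0
    else:
        lower = brentq(lambda s: cdf_ge(np.exp(s)) - alpha / 2, -50, 50)
        lower = float(np.exp(lower))
    if a == hi_support:
        upper = float("inf")
    else:
        upper = brentq(lambda s: cdf_le(np.exp(s)) - alpha / 2, -50, 50)
        upper = float(np.exp(upper))
    return lower, upper


def enrichment_test(carriers: CohortTable, pgs_col: str, subtype: str,
                    covariates: list[str] | None = None,
                    pgs_name: str | None = None) -> EnrichmentResult:
    """Median-split enrichment of healthy carriers in the low-PGS half.

    Input rows must all be somatic-mutation carriers with diagnosis either
    ``control`` (healthy carrier) or the tested subtype. The split is at
    the within-carrier PGS median with ties to the low group. Returns the
    covariate-free 2x2 odds ratio with an exact CI (Haldane-Anscombe 0.5
    correction, flagged, when a margin is zero) alongside a
    covariate-adjusted logistic odds ratio.
    """
    if subtype not in ("ET", "PV"):
        raise ValueError("subtype must be ET or PV")
    df = carriers.df
    sub = df[df["diagnosis"].isin(["control", subtype])].copy()
    if sub.empty:
        raise ValueError("no carriers with the requested labels")
    pgs = sub[pgs_col].to_numpy(dtype=float)
    low = pgs <= np.median(pgs)
    healthy = (sub["diagnosis"] == "control").to_numpy()
    a = int(np.sum(low & healthy))        # low-PGS healthy
    b = int(np.sum(low & ~healthy))       # low-PGS diseased
    c = int(np.sum(~low & healthy))       # high-PGS healthy
    d = int(np.sum(~low & ~healthy))      # high-PGS diseased
    corrected = min(a + b, c + d, a + c, b + d) == 0 or 0 in (a, b, c, d)
    if min(a + b, c + d, a + c, b + d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_ = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        lo, hi = or_ * np.exp(-Z975 * se), or_ * np.exp(Z975 * se)
        pval = 1.0
    else:
        if 0 in (b, c):
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            or_ = (aa * dd) / (bb * cc)
        else:
            or_ = (a * d) / (b * c)
        lo, hi = _exact_or_ci(a, b, c, d)
        pval = float(fisher_exact([[a, b], [c, d]])[1])
    result = EnrichmentResult(
        pgs_name=pgs_name or pgs_col, subtype=subtype,
        or_estimate=float(or_), ci_low=float(lo), ci_high=float(hi),
        pvalue=pval, counts=(a, b, c, d), corrected=bool(corrected))
    cov_arr = None
    if covariates:
        cov_arr = sub[covariates].to_numpy(dtype=float)
        if np.all(np.ptp(cov_arr, axis=0) == 0):
            cov_arr = None   # constant covariates carry no information
    if 0 not in (a, b, c, d):   # separation-free adjusted fit is possible
        try:
            or_a, lo_a, hi_a, p_a = _logit_or(healthy.astype(float),
                                              low.astype(float), cov_arr)
            result.adjusted_or = float(or_a)
            result.adjusted_ci_low = float(lo_a)
            result.adjusted_ci_high = float(hi_a)
            result.adjusted_p = float(p_a)
        except Exception:
            pass   # adjusted fit can fail on tiny strata; the 2x2 OR stands
    _log_stage("enrichment_test", subtype=subtype, n=len(sub))
    return result


def stratify_by_driver(cohort: CohortTable) -> dict[str, np.ndarray]:
    """Partition case rows by driver-mutation class.

    Returns positional row indices for ``JAK2het``, ``CALR_MPL``, ``TN``
    and ``all`` (disjoint and exhaustive over cases)."""
    df = cohort.df
    cases = df["diagnosis"].isin(["ET", "PV", "MF"]).to_numpy()
    classes = df["driver_class"].to_numpy(dtype=object)
    unknown = {c for c in classes[cases] if c is not None
               and not (isinstance(c, float) and np.isnan(c))} \
        - set(VALID_DRIVER_CLASSES)
    if unknown:
        raise ValueError(f"unknown driver class: {sorted(unknown)[0]!r}")
    missing = [i for i in np.flatnonzero(cases)
               if classes[i] is None or (isinstance(classes[i], float)
                                         and np.isnan(classes[i]))]
    if missing:
        raise ValueError("driver_class missing for some cases")
    strata = {name: np.flatnonzero(cases & (classes == name))
              for name in VALID_DRIVER_CLASSES}
    strata["all"] = np.flatnonzero(cases)
    return strata
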