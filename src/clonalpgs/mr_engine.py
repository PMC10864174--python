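"""Two-sample Mendelian randomization: instrument construction and the four
standard estimators with pleiotropy, outlier, distortion and reverse-
causality testing.

All estimators operate on harmonized per-instrument summary pairs
(bx, sx) for the exposure (trait s.d. units) and (by, sy) for the outcome
(log-odds units), and report the causal log-odds of the outcome per 1 s.d.
of the exposure. Heterogeneity is handled with a multiplicative
random-effects scale max(1, sqrt(Q / df)) that never deflates the
fixed-effect standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm, t as t_dist

from .core_io import AnalysisConfig, GwasSummary, logger, _log_stage
from .pgs_engine import LdReference

Z975 = float(norm.ppf(0.975))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effect pairs, oriented to the exposure
    effect allele."""

    variant_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    eaf: np.ndarray = field(default=None)

    def __post_init__(self):
        for name in ("bx", "sx", "by", "sy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.eaf is None:
            self.eaf = np.full(len(self.variant_ids), np.nan)
        self.eaf = np.asarray(self.eaf, dtype=float)
        if not ((self.sx > 0).all() and (self.sy > 0).all()):
            raise ValueError("instrument standard errors must be > 0")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, idx) -> "InstrumentSet":
        idx = np.asarray(idx)
        return InstrumentSet([self.variant_ids[i] for i in idx],
                             self.bx[idx], self.sx[idx],
                             self.by[idx], self.sy[idx], self.eaf[idx])


@dataclass
class MrResult:
    method: str
    estimate: float            # log-OR of outcome per exposure s.d.
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_instruments: int
    egger_intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")

    @property
    def or_per_sd(self) -> float:
        return float(np.exp(self.estimate))


# ---------------------------------------------------------------------------
# harmonization and instrument selection
# ---------------------------------------------------------------------------


def harmonize(exposure: GwasSummary, outcome: GwasSummary) -> InstrumentSet:
    """Align outcome records to the exposure effect allele.

    Swapped-allele outcome records get their effect sign flipped (and
    frequency complemented); palindromic variants (A/T or C/G) with
    MAF > 0.4 are strand-ambiguous and dropped; incompatible allele pairs
    are dropped. Drop counts are logged.
    """
    out_by_id = outcome.by_id()
    ids, bx, sx, by, sy, eaf = [], [], [], [], [], []
    n_pal = n_bad = 0
    for e in exposure.records:
        o = out_by_id.get(e.variant_id)
        if o is None or not e.has_stats or not o.has_stats:
            continue
        if e.is_palindromic and e.maf > 0.4:
            n_pal += 1
            continue
        if (o.effect_allele, o.other_allele) == (e.effect_allele, e.other_allele):
            b_out = o.beta
        elif (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
            b_out = -o.beta
        else:
            n_bad += 1
            continue
        ids.append(e.variant_id)
        bx.append(e.beta); sx.append(e.se)
        by.append(b_out); sy.append(o.se)
        eaf.append(e.eaf)
    if n_pal or n_bad:
        logger.info("harmonize: dropped %d palindromic and %d incompatible "
                    "variants", n_pal, n_bad)
    if not ids:
        raise ValueError("no shared variants between exposure and outcome")
    return InstrumentSet(ids, bx, sx, by, sy, eaf)


def _ld_r2(ld_ref: LdReference, ids: list[str]) -> np.ndarray:
    index = {v.variant_id: j for j, v in enumerate(ld_ref.variants)}
    cols = [index[i] for i in ids]
    X = ld_ref.standardized()[:, cols]
    r = (X.T @ X) / X.shape[0]
    return r ** 2


def select_instruments(exposure_discovery: GwasSummary,
                       exposure_external: GwasSummary,
                       outcome: GwasSummary, ld_ref: LdReference,
                       config: AnalysisConfig | None = None,
                       p_discovery: float | None = None,
                       exclude_outcome_associated: bool = False) -> InstrumentSet:
    """Dual-threshold instrument selection with LD pruning and guards.

    Keeps variants genome-wide significant in the discovery cohort and
    nominally significant (p < ``external_p``) in the external cohort;
    prunes greedily at reference r^2 >= ``ld_prune_r2`` keeping the smaller
    discovery p; drops variants whose allele frequency differs from the
    reference by more than ``freq_diff_max``. Exposure effect sizes are
    taken from the EXTERNAL cohort (avoiding winner's-curse/overlap bias);
    outcome effects are harmonized to the same alleles. The optional
    exclusion filter removes instruments associated with the outcome
    (p < 1e-6), correlated with such a variant (r^2 > 0.01) or within a
    10-Mb window of one.
    """
    cfg = config or AnalysisConfig()
    p_disc = cfg.gws_p if p_discovery is None else p_discovery
    disc = {r.variant_id: r for r in exposure_discovery.records if r.has_stats}
    ext = {r.variant_id: r for r in exposure_external.records if r.has_stats}
    ref_freq = {v.variant_id: (v.eaf, v.effect_allele, v.other_allele)
                for v in ld_ref.variants}

    candidates = []
    for vid, d in disc.items():
        e = ext.get(vid)
        if e is None or d.maf < cfg.maf_min:
            continue
        if not (d.pvalue < p_disc and e.pvalue < cfg.external_p):
            continue
        if vid in ref_freq:
            f_ref, ea, oa = ref_freq[vid]
            if (d.effect_allele, d.other_allele) == (oa, ea):
                f_ref = 1.0 - f_ref
            elif (d.effect_allele, d.other_allele) != (ea, oa):
                continue
            if abs(d.eaf - f_ref) > cfg.freq_diff_max:
                continue
        else:
            continue  # absent from reference: no LD information
        candidates.append(d)
    if len(candidates) < 3:
        raise ValueError(f"only {len(candidates)} candidate instruments survive "
                         "the dual-threshold and frequency filters")

    # greedy LD pruning keeping the smaller discovery p
    candidates.sort(key=lambda r: (r.pvalue, r.variant_id))
    ids = [r.variant_id for r in candidates]
    r2 = _ld_r2(ld_ref, ids)
    kept, removed = [], np.zeros(len(ids), dtype=bool)
    for i in range(len(ids)):
        if removed[i]:
            continue
        kept.append(i)
        removed |= r2[i] >= cfg.ld_prune_r2
        removed[i] = True
    pruned = [candidates[i] for i in kept]

    if exclude_outcome_associated:
        out_recs = {r.variant_id: r for r in outcome.records if r.has_stats}
        hits = [r for r in outcome.records
                if r.has_stats and r.pvalue < 1e-6]
        hit_ids = {r.variant_id for r in hits}
        drop = set(hit_ids)
        if hits:
            all_ids = [r.variant_id for r in pruned] + [r.variant_id for r in hits]
            avail = {v.variant_id for v in ld_ref.variants}
            all_ids = [i for i in dict.fromkeys(all_ids) if i in avail]
            r2x = _ld_r2(ld_ref, all_ids)
            pos_of = {i: k for k, i in enumerate(all_ids)}
            for rec in pruned:
                if rec.variant_id not in pos_of:
                    continue
                for h in hits:
                    if h.variant_id not in pos_of:
                        continue
                    same_chr = rec.chrom == h.chrom
                    near = same_chr and abs(rec.pos - h.pos) <= 5_000_000
                    if near or r2x[pos_of[rec.variant_id], pos_of[h.variant_id]] > 0.01:
                        drop.add(rec.variant_id)
                        break
        pruned = [r for r in pruned if r.variant_id not in drop]

    if len(pruned) < 3:
        raise ValueError(f"only {len(pruned)} instruments survive selection")

    # effects from the external cohort, harmonized to discovery alleles
    exp_records = []
    for d in pruned:
        e = ext[d.variant_id]
        if (e.effect_allele, e.other_allele) == (d.effect_allele, d.other_allele):
            beta, eaf = e.beta, e.eaf
        elif (e.effect_allele, e.other_allele) == (d.other_allele, d.effect_allele):
            beta, eaf = -e.beta, 1.0 - e.eaf
        else:
            continue
        exp_records.append(replace(e, effect_allele=d.effect_allele,
                                   other_allele=d.other_allele, beta=beta,
                                   eaf=eaf))
    exposure = GwasSummary(trait_name=exposure_discovery.trait_name,
                           records=exp_records, cohort_label="external")
    inst = harmonize(exposure, outcome)
    if len(inst) < 3:
        raise ValueError(f"only {len(inst)} instruments after harmonization")
    _log_stage("select_instruments", trait=exposure_discovery.trait_name,
               n_instruments=len(inst))
    return inst


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def wald_ratio(bx: float, by: float, sy: float) -> tuple[float, float]:
    """Single-instrument ratio estimate (internal oracle helper)."""
    return by / bx, sy / abs(bx)


def _wrap(method: str, est: float, se: float, m: int, df: int | None = None,
          **extra) -> MrResult:
    if df is None:
        p = 2.0 * norm.sf(abs(est / se)) if se > 0 else (0.0 if est else 1.0)
        q = Z975
    else:
        p = 2.0 * t_dist.sf(abs(est / se), df) if se > 0 else (0.0 if est else 1.0)
        q = float(t_dist.ppf(0.975, df))
    return MrResult(method=method, estimate=float(est), se=float(se),
                    ci_low=float(est - q * se), ci_high=float(est + q * se),
                    pvalue=float(p), n_instruments=m, **extra)


def mr_ivw(inst: InstrumentSet) -> MrResult:
    """Inverse-variance-weighted estimate (weighted no-intercept regression
    of by on bx with weights 1/sy^2) under multiplicative random effects."""
    m = len(inst)
    if m < 2:
        raise ValueError("IVW requires at least 2 instruments")
    w = 1.0 / inst.sy ** 2
    s2 = float(np.sum(w * inst.bx ** 2))
    est = float(np.sum(w * inst.bx * inst.by)) / s2
    se_fixed = np.sqrt(1.0 / s2)
    q_stat = float(np.sum(w * (inst.by - est * inst.bx) ** 2))
    scale = max(1.0, np.sqrt(q_stat / (m - 1)))
    return _wrap("ivw", est, se_fixed * scale, m)


def mr_egger(inst: InstrumentSet) -> MrResult:
    """Weighted regression of by on bx *with* intercept; the intercept
    estimates the average directional pleiotropy. bx is oriented
    non-negative (flipping by in tandem) before fitting."""
    m = len(inst)
    if m < 3:
        raise ValueError("Egger requires at least 3 instruments")
    flip = np.sign(inst.bx)
    flip[flip == 0] = 1.0
    x = inst.bx * flip
    y = inst.by * flip
    w = 1.0 / inst.sy ** 2
    X = np.column_stack([np.ones(m), x])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ y)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid ** 2))
    scale2 = max(1.0, rss_w / (m - 2))
    cov = np.linalg.inv(A) * scale2
    se = np.sqrt(np.diag(cov))
    res = _wrap("egger", coef[1], se[1], m, df=m - 2,
                egger_intercept=float(coef[0]), intercept_se=float(se[0]))
    ip = 2.0 * t_dist.sf(abs(coef[0] / se[0]), m - 2) if se[0] > 0 else \
        (0.0 if coef[0] else 1.0)
    res.intercept_p = float(ip)
    return res


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Percentile-interpolated weighted median at cumulative weight 0.5."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    q = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, q, v))


def mr_median(inst: InstrumentSet, weighted: bool = True,
              n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Simple or weighted median of per-instrument Wald ratios.

    Weighted version uses weights bx^2/sy^2 (inverse variance of the ratio
    to first order); standard errors come from a seeded parametric
    bootstrap resampling bx ~ N(bx, sx), by ~ N(by, sy).
    """
    m = len(inst)
    if m < 3:
        raise ValueError("median estimators require at least 3 instruments")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap standard errors",
                      stacklevel=2)

    def estimate(bx, by):
        ratios = by / bx
        w = (bx ** 2) / inst.sy ** 2 if weighted else np.ones(m)
        return weighted_median(ratios, w)

    est = estimate(inst.bx, inst.by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(inst.bx, inst.sx)
        bys = rng.normal(inst.by, inst.sy)
        boots[b] = estimate(bxs, bys)
    se = float(np.std(boots, ddof=1))
    method = "weighted_median" if weighted else "simple_median"
    return _wrap(method, est, se, m)


# ---------------------------------------------------------------------------
# PRESSO-style outlier analysis
# ---------------------------------------------------------------------------


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_indices: list[int]
    outlier_pvalues: np.ndarray
    distortion_p: float            # NaN when no outliers flagged
    outlier_corrected: MrResult | None


def _loo_ivw(bx, by, sy):
    """Leave-one-out IVW estimates for every instrument, vectorized."""
    w = 1.0 / sy ** 2
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx ** 2, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx ** 2)


def mr_presso(inst: InstrumentSet, n_sim: int = 2000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """Residual-sum-of-squares global pleiotropy test with per-instrument
    outlier flags and a distortion test.

    The observed statistic is the weighted sum of squared leave-one-out IVW
    residuals. Its null distribution is simulated parametrically: each
    replicate draws by* ~ N(bx * beta_loo, sy) and recomputes the statistic.
    Per-instrument outlier p-values compare each observed squared residual
    with its simulated distribution (Bonferroni-flagged at
    ``outlier_alpha``/m). The distortion test compares the observed change
    in IVW after removing flagged outliers with the change from removing
    random same-size subsets.
    """
    m = len(inst)
    if m < 4:
        raise ValueError("PRESSO requires at least 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)
    w = 1.0 / inst.sy ** 2
    beta_loo = _loo_ivw(inst.bx, inst.by, inst.sy)
    resid_obs = inst.by - inst.bx * beta_loo
    rss_obs = float(np.sum(w * resid_obs ** 2))

    by_sim = rng.normal(inst.bx * beta_loo, inst.sy, size=(n_sim, m))
    beta_loo_sim = _loo_ivw(inst.bx[None, :], by_sim, inst.sy[None, :])
    resid_sim = by_sim - inst.bx[None, :] * beta_loo_sim
    rss_sim = np.sum(w[None, :] * resid_sim ** 2, axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    sq_obs = w * resid_obs ** 2
    sq_sim = w[None, :] * resid_sim ** 2
    outlier_p = (1 + np.sum(sq_sim >= sq_obs[None, :], axis=0)) / (n_sim + 1)
    flagged = np.flatnonzero(outlier_p < outlier_alpha / m)

    distortion_p = float("nan")
    corrected = None
    if flagged.size and flagged.size <= m - 2:
        keep = np.setdiff1d(np.arange(m), flagged)
        corrected = mr_ivw(inst.subset(keep))
        full = mr_ivw(inst)
        d_obs = corrected.estimate - full.estimate
        d_sim = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(m, size=flagged.size, replace=False)
            sub = np.setdiff1d(np.arange(m), drop)
            wk = w[sub]
            d_sim[b] = (np.sum(wk * inst.bx[sub] * inst.by[sub]) /
                        np.sum(wk * inst.bx[sub] ** 2)) - full.estimate
        distortion_p = float(
            (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))
    _log_stage("mr_presso", m=m, outliers=int(flagged.size))
    return PressoResult(global_rss=rss_obs, global_p=global_p,
                        outlier_indices=[int(i) for i in flagged],
                        outlier_pvalues=outlier_p,
                        distortion_p=distortion_p,
                        outlier_corrected=corrected)


# ---------------------------------------------------------------------------
# decision rule and reverse direction
# ---------------------------------------------------------------------------


@dataclass
class MrVerdict:
    significant: bool
    rationale: str


def mr_decision(results: dict[str, MrResult],
                alpha_bonf: float = 0.0042) -> MrVerdict:
    """Headline significance rule across the four estimators.

    Significant iff the IVW p-value clears the Bonferroni threshold, all
    four point estimates share a sign, and the Egger intercept is not
    significantly different from 0 (p > 0.05).
    """
    required = ("ivw", "egger", "simple_median", "weighted_median")
    missing = [k for k in required if k not in results]
    if missing:
        raise ValueError(f"missing MR methods: {missing}")
    failures = []
    ivw = results["ivw"]
    if not ivw.pvalue < alpha_bonf:
        failures.append(f"p_ivw={ivw.pvalue:.3g} >= {alpha_bonf}")
    signs = {np.sign(results[k].estimate) for k in required}
    if len(signs) > 1:
        failures.append("inconsistent effect directions across methods")
    ip = results["egger"].intercept_p
    if not ip > 0.05:
        failures.append(f"egger intercept p={ip:.3g} <= 0.05 (pleiotropy)")
    if failures:
        return MrVerdict(False, "; ".join(failures))
    return MrVerdict(True, "p_ivw below threshold, consistent directions, "
                           "no directional pleiotropy")


def run_mr(inst: InstrumentSet, seed: int = 0,
           n_boot: int = 1000) -> dict[str, MrResult]:
    """All four estimators on one harmonized instrument set."""
    return {
        "ivw": mr_ivw(inst),
        "egger": mr_egger(inst),
        "simple_median": mr_median(inst, weighted=False, n_boot=n_boot, seed=seed),
        "weighted_median": mr_median(inst, weighted=True, n_boot=n_boot,
                                     seed=seed + 1),
    }


def reverse_mr(outcome_as_exposure: GwasSummary, trait_as_outcome: GwasSummary,
               ld_ref: LdReference, config: AnalysisConfig | None = None,
               external: GwasSummary | None = None, seed: int = 0
               ) -> dict[str, MrResult]:
    """Forward machinery with roles swapped and a relaxed instrument
    threshold (p < 1e-6) for the new exposure."""
    cfg = config or AnalysisConfig()
    ext = external if external is not None else outcome_as_exposure
    inst = select_instruments(outcome_as_exposure, ext, trait_as_outcome,
                              ld_ref, cfg, p_discovery=cfg.reverse_p)
    return run_mr(inst, seed=seed)
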