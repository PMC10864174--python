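"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, a population-biobank design in which
inherited polygenic variation in blood-cell traits influences selection on a
somatically acquired driver mutation (JAK2 V617F):

* hard-call genotypes in Hardy-Weinberg proportions, with block-wise AR(1)
  linkage disequilibrium induced on latent Gaussian haplotypes;
* additive polygenic traits with configurable heritability (trait variance 1);
* stochastic clone acquisition whose log-odds increase linearly with the
  liability trait, and logit-normal clone sizes (VAF) so that a fixed VAF
  cut-off splits carriers into small and large clones;
* threshold-defined ET/PV/MF diagnosis labels with JAK2-het / CALR+MPL /
  triple-negative driver classes;
* per-variant association scans producing GWAS summary statistics for
  disjoint discovery / external / target partitions.

Because variants affect clone status only through the trait (unless
pleiotropy is injected explicitly), the generated data satisfy the MR
exclusion restriction by construction, so the trait-to-clone log-odds slope
``alpha1`` is recoverable by instrumental-variable estimators.

The whole generator is a pure function of :class:`SimTruth` (including its
seed): per-operation random streams are derived from the seed with fixed
offsets, so identical truth gives identical output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, t as t_dist

from .core_io import CohortTable, GwasSummary, VariantRecord, _log_stage

_BASES = np.array(list("ACGT"))
# per-operation offsets for derived random streams
_STREAMS = {"genotypes": 1, "traits": 2, "clones": 3, "diagnosis": 4,
            "split": 5, "covariates": 6, "pleiotropy": 7}


@dataclass
class TraitSpec:
    name: str
    m_causal: int
    h2: float

    def __post_init__(self):
        if not (0.0 < self.h2 < 1.0):
            raise ValueError(f"h2={self.h2} outside (0,1)")
        if self.m_causal < 0:
            raise ValueError("m_causal must be >= 0")


@dataclass
class CloneModel:
    """Clone-acquisition and clone-size model.

    ``alpha0``: baseline log-odds of harboring a detectable clone
    (logit(0.003) matches a 0.3% population carrier rate).
    ``alpha1``: log-odds of clone per s.d. of the liability trait (the
    causal selection effect MR should recover).
    VAF of carriers is expit(Normal(vaf_mu + vaf_gamma * liability, vaf_sigma)).
    """

    alpha0: float = float(logit(0.003))
    alpha1: float = 0.4
    vaf_mu: float = -2.8   # expit(-2.8) ~= 0.057, near the observed median VAF
    vaf_gamma: float = 0.5
    vaf_sigma: float = 1.0
    liability_trait: str = ""   # defaults to the first trait


@dataclass
class DiagnosisThresholds:
    et_trait: str = ""
    et_cut: float = 2.5
    pv_trait: str = ""
    pv_cut: float = 2.8
    clone_boost: float = 2.0   # added to the trait as clone_boost * VAF for carriers
    mf_frac: float = 0.1       # fraction of cases relabelled MF (label-only)


@dataclass
class SimTruth:
    """Ground-truth generator parameters (the study conditions)."""

    m_variants: int = 400
    n_individuals: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.0
    traits: list[TraitSpec] = field(default_factory=lambda: [TraitSpec("PCT", 200, 0.3)])
    clone_model: CloneModel = field(default_factory=CloneModel)
    diagnosis_thresholds: DiagnosisThresholds = field(default_factory=DiagnosisThresholds)
    driver_class_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)  # JAK2het, CALR_MPL, TN
    pleiotropy_frac: float = 0.0    # fraction of causal variants with a direct clone effect
    pleiotropy_scale: float = 0.0   # direct per-allele log-odds effect magnitude
    seed: int = 0

    def __post_init__(self):
        if self.m_variants <= 0 or self.n_individuals <= 0:
            raise ValueError("m_variants and n_individuals must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for spec in self.traits:
            if spec.m_causal > self.m_variants:
                raise ValueError(f"{spec.name}: m_causal exceeds m_variants")
        if abs(sum(self.driver_class_probs) - 1.0) > 1e-12:
            raise ValueError("driver_class_probs must sum to 1")
        if not self.clone_model.liability_trait:
            self.clone_model.liability_trait = self.traits[0].name
        if not self.diagnosis_thresholds.et_trait:
            self.diagnosis_thresholds.et_trait = self.traits[0].name
        if not self.diagnosis_thresholds.pv_trait:
            self.diagnosis_thresholds.pv_trait = self.traits[-1].name

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class VariantStub:
    """Variant metadata without effect statistics."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float


@dataclass
class GenotypeMatrix:
    dosages: np.ndarray              # n x m int8 in {0,1,2}
    variants: list[VariantStub]
    sample_ids: list[str]

    def __post_init__(self):
        n, m = self.dosages.shape
        if m != len(self.variants) or n != len(self.sample_ids):
            raise ValueError("inconsistent genotype matrix dimensions")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> dict[str, int]:
        return {v.variant_id: j for j, v in enumerate(self.variants)}

    def subset_rows(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[rows], self.variants,
                              [self.sample_ids[i] for i in rows])


@dataclass
class TraitSet:
    """Simulated trait values and per-variant true effects."""

    values: pd.DataFrame                       # n x traits, variance ~ 1
    genetic_values: pd.DataFrame               # additive genetic component
    true_effects: dict[str, np.ndarray]        # trait -> per-allele effect per variant
    causal_indices: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(truth: SimTruth) -> GenotypeMatrix:
    """Hard-call dosages under Hardy-Weinberg with block AR(1) LD.

    Two latent haplotype Gaussians per individual follow an AR(1) process
    with correlation ``ld_rho`` along variants within each ``ld_block_size``
    block; thresholding each at the allele-frequency quantile yields hard
    calls whose adjacent-variant dosage correlation grows with ``ld_rho``.
    """
    rng = truth.rng("genotypes")
    n, m = truth.n_individuals, truth.m_variants
    mafs = rng.uniform(truth.maf_range[0], truth.maf_range[1], size=m)
    thresholds = norm.ppf(1.0 - mafs)
    rho = truth.ld_rho
    if not (0.0 <= rho < 1.0):
        raise ValueError("ld_rho must be in [0,1)")
    dosages = np.zeros((n, m), dtype=np.int8)
    scale = np.float32(math.sqrt(1.0 - rho * rho))
    rho32 = np.float32(rho)
    thresholds32 = thresholds.astype(np.float32)
    for _hap in range(2):
        z = rng.standard_normal((n, m), dtype=np.float32)
        if rho > 0:
            for j in range(1, m):
                if j % truth.ld_block_size != 0:  # new block restarts the chain
                    z[:, j] = rho32 * z[:, j - 1] + scale * z[:, j]
        dosages += z > thresholds32

    # non-palindromic allele pairs, alternating layout (deterministic)
    pair_rng = truth.rng("genotypes").spawn(1)[0]
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
             ("A", "C"), ("G", "T")]
    pair_idx = pair_rng.integers(0, len(pairs), size=m)
    variants = []
    for j in range(m):
        ea, oa = pairs[pair_idx[j]]
        variants.append(VariantStub(
            variant_id=f"rs{j + 1}", chrom="1", pos=1 + j * 100_000,
            effect_allele=ea, other_allele=oa,
            eaf=float(dosages[:, j].mean() / 2.0)))
    sample_ids = [f"I{i + 1}" for i in range(n)]
    _log_stage("simulate_genotypes", seed=truth.seed, n=n, m=m)
    return GenotypeMatrix(dosages=dosages, variants=variants, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_traits(genotypes: GenotypeMatrix, truth: SimTruth) -> TraitSet:
    """Additive polygenic traits with unit variance and heritability h2.

    Per-causal-variant effects are Normal(0, h2/m_causal) on the
    standardized-dosage scale, i.e. Normal(0, h2/(m_causal * 2f(1-f))) per
    allele; environmental noise is Normal(0, 1-h2).
    """
    rng = truth.rng("traits")
    freqs = np.array([v.eaf for v in genotypes.variants])
    sd = np.sqrt(np.maximum(2.0 * freqs * (1.0 - freqs), 1e-12))
    values, genetic, effects, causal = {}, {}, {}, {}
    dos = genotypes.dosages.astype(np.float32)
    for spec in truth.traits:
        beta_allele = np.zeros(genotypes.m)
        idx = rng.choice(genotypes.m, size=spec.m_causal, replace=False) \
            if spec.m_causal else np.array([], dtype=int)
        if spec.m_causal:
            u = rng.normal(0.0, math.sqrt(spec.h2 / spec.m_causal), size=spec.m_causal)
            beta_allele[idx] = u / sd[idx]
        g = dos @ beta_allele - float(2.0 * freqs @ beta_allele)
        noise = rng.normal(0.0, math.sqrt(1.0 - spec.h2), size=genotypes.n)
        values[spec.name] = g + noise
        genetic[spec.name] = g
        effects[spec.name] = beta_allele
        causal[spec.name] = np.sort(idx)
    _log_stage("simulate_traits", seed=truth.seed, traits=len(truth.traits))
    return TraitSet(values=pd.DataFrame(values), genetic_values=pd.DataFrame(genetic),
                    true_effects=effects, causal_indices=causal)


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------


@dataclass
class CloneSim:
    carrier: np.ndarray   # bool
    vaf: np.ndarray       # float, NaN for non-carriers


def simulate_clones(liability: np.ndarray, truth: SimTruth,
                    genotypes: GenotypeMatrix | None = None,
                    pleiotropy_effects: np.ndarray | None = None) -> CloneSim:
    """Bernoulli clone acquisition and logit-normal VAF.

    P(clone) = expit(alpha0 + alpha1 * liability [+ direct pleiotropic
    genotype effects when injected]); carriers get
    VAF = expit(Normal(vaf_mu + vaf_gamma * liability, vaf_sigma)) in (0,1);
    non-carriers have missing VAF.
    """
    cm = truth.clone_model
    rng = truth.rng("clones")
    liability = np.asarray(liability, dtype=float)
    eta = cm.alpha0 + cm.alpha1 * liability
    if pleiotropy_effects is not None:
        if genotypes is None:
            raise ValueError("pleiotropy_effects requires genotypes")
        eta = eta + genotypes.dosages.astype(np.float32) @ pleiotropy_effects
    carrier = rng.random(liability.shape[0]) < expit(eta)
    vaf = np.full(liability.shape[0], np.nan)
    k = int(carrier.sum())
    if k:
        latent = rng.normal(cm.vaf_mu + cm.vaf_gamma * liability[carrier],
                            cm.vaf_sigma if cm.vaf_sigma > 0 else 0.0)
        vaf[carrier] = expit(latent)
    _log_stage("simulate_clones", seed=truth.seed, carriers=k)
    return CloneSim(carrier=carrier, vaf=vaf)


def pleiotropy_effects(truth: SimTruth, traits: TraitSet) -> np.ndarray | None:
    """Optional direct clone-log-odds effects for a subset of causal variants.

    Off by default; when on, a ``pleiotropy_frac`` share of the liability
    trait's causal variants receives a directional per-allele effect of
    magnitude ``pleiotropy_scale``, oriented with the trait-increasing
    allele (the canonical directional-pleiotropy setting that biases
    ratio-based estimators but is absorbed by an intercept). This violates
    the exclusion restriction for the chosen instruments.
    """
    if truth.pleiotropy_frac <= 0 or truth.pleiotropy_scale <= 0:
        return None
    rng = truth.rng("pleiotropy")
    trait = truth.clone_model.liability_trait
    causal = traits.causal_indices[trait]
    k = int(round(truth.pleiotropy_frac * len(causal)))
    if k == 0:
        return None
    chosen = rng.choice(causal, size=k, replace=False)
    effects = np.zeros(len(traits.true_effects[trait]))
    orient = np.sign(traits.true_effects[trait][chosen])
    orient[orient == 0] = 1.0
    effects[chosen] = rng.uniform(0.5, 1.5, size=k) * truth.pleiotropy_scale * orient
    return effects


# ---------------------------------------------------------------------------
# diagnosis
# ---------------------------------------------------------------------------


def assign_diagnosis(traits: TraitSet, clones: CloneSim, truth: SimTruth
                     ) -> pd.DataFrame:
    """Threshold-defined ET/PV/MF labels with driver-mutation classes.

    ET when et_trait + clone_boost*VAF (carriers) exceeds ``et_cut``; PV
    analogously; when both criteria are met the label with the larger
    threshold exceedance wins (ties deterministically to ET). A configurable
    fraction of cases is relabelled MF (label-only; MF has no separate
    mechanism). Driver classes are drawn from ``driver_class_probs`` among
    cases, after which JAK2het cases are coerced to carriers (drawing a VAF
    where needed) and CALR_MPL / TN cases to non-carriers (these classes are
    JAK2-negative by definition).
    """
    th = truth.diagnosis_thresholds
    cm = truth.clone_model
    rng = truth.rng("diagnosis")
    n = len(clones.carrier)
    vaf0 = np.nan_to_num(clones.vaf, nan=0.0)
    et_score = traits.values[th.et_trait].to_numpy() + th.clone_boost * vaf0
    pv_score = traits.values[th.pv_trait].to_numpy() + th.clone_boost * vaf0
    et_exceed = et_score - th.et_cut
    pv_exceed = pv_score - th.pv_cut
    diagnosis = np.full(n, "control", dtype=object)
    is_et = (et_exceed > 0) & ((pv_exceed <= 0) | (et_exceed >= pv_exceed))
    is_pv = (pv_exceed > 0) & ~is_et
    diagnosis[is_et] = "ET"
    diagnosis[is_pv] = "PV"
    case_idx = np.flatnonzero(diagnosis != "control")
    if th.mf_frac > 0 and len(case_idx):
        mf = case_idx[rng.random(len(case_idx)) < th.mf_frac]
        diagnosis[mf] = "MF"

    driver = np.full(n, None, dtype=object)
    carrier = clones.carrier.copy()
    vaf = clones.vaf.copy()
    if len(case_idx):
        classes = rng.choice(np.array(["JAK2het", "CALR_MPL", "TN"]),
                             size=len(case_idx), p=list(truth.driver_class_probs))
        driver[case_idx] = classes
        jak2 = case_idx[classes == "JAK2het"]
        need_vaf = jak2[~carrier[jak2]]
        carrier[jak2] = True
        if len(need_vaf):
            liab = traits.values[cm.liability_trait].to_numpy()[need_vaf]
            vaf[need_vaf] = expit(rng.normal(cm.vaf_mu + cm.vaf_gamma * liab,
                                             max(cm.vaf_sigma, 0.0)))
        negatives = case_idx[classes != "JAK2het"]
        carrier[negatives] = False
        vaf[negatives] = np.nan
    _log_stage("assign_diagnosis", seed=truth.seed, cases=len(case_idx))
    return pd.DataFrame({"diagnosis": diagnosis, "driver_class": driver,
                         "carrier": carrier, "vaf": vaf})


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------


def _residualize(y: np.ndarray, covariates: np.ndarray | None):
    """Project out an intercept plus covariates (Frisch-Waugh-Lovell)."""
    n = y.shape[0]
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef, X.shape[1]


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                   tol: float = 1e-10):
    """Plain Newton-Raphson logistic MLE; returns (beta, se) or None."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = logit(min(max(y.mean(), 1e-9), 1 - 1e-9))
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        if not np.isfinite(w).all() or w.max() < 1e-12:
            return None
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    if np.abs(beta).max() > 30:   # quasi-separation
        return None
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    return beta, np.sqrt(np.diag(cov))


def association_scan(genotypes: GenotypeMatrix, outcome: np.ndarray,
                     covariates: np.ndarray | None = None,
                     trait_name: str = "trait", cohort_label: str = "",
                     binary: bool | None = None,
                     variant_subset: Sequence[int] | None = None) -> GwasSummary:
    """Per-variant marginal regression (linear or logistic) with covariates.

    Quantitative outcomes use ordinary least squares via residualization
    (exact OLS coefficients by Frisch-Waugh-Lovell); binary outcomes use a
    per-variant Newton-Raphson logistic fit. Monomorphic variants (or exact
    covariate collinearity) are emitted with missing statistics.
    """
    outcome = np.asarray(outcome, dtype=float)
    if outcome.shape[0] != genotypes.n:
        raise ValueError("outcome length does not match genotypes")
    if binary is None:
        binary = set(np.unique(outcome)) <= {0.0, 1.0}
    cols = range(genotypes.m) if variant_subset is None else variant_subset
    cols = list(cols)
    n = genotypes.n
    records: list[VariantRecord] = []

    if not binary:
        y_res, p_cov = _residualize(outcome, covariates)
        dos = genotypes.dosages[:, cols].astype(np.float64)
        if covariates is None:
            g_res = dos - dos.mean(axis=0)
        else:
            X = np.column_stack([np.ones(n), covariates])
            coef, *_ = np.linalg.lstsq(X, dos, rcond=None)
            g_res = dos - X @ coef
        sxx = np.einsum("ij,ij->j", g_res, g_res)
        sxy = y_res @ g_res
        syy = float(y_res @ y_res)
        df = n - p_cov - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = sxy / sxx
            rss = np.maximum(syy - beta * sxy, 0.0)
            se = np.sqrt(rss / df / sxx)
            tstat = beta / se
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
        mono = sxx <= 1e-12
        beta[mono] = np.nan
        se[mono] = np.nan
        pvals = np.where(mono, np.nan, pvals)
        stats = zip(beta, se, pvals)
    else:
        out = []
        base = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), covariates])
        for j in cols:
            g = genotypes.dosages[:, j].astype(np.float64)
            if g.std() <= 1e-12:
                out.append((np.nan, np.nan, np.nan))
                continue
            X = np.column_stack([base, g])
            fit = _logistic_irls(X, outcome)
            if fit is None:
                out.append((np.nan, np.nan, np.nan))
                continue
            b, s = fit[0][-1], fit[1][-1]
            pv = 2.0 * norm.sf(abs(b / s)) if s > 0 else np.nan
            out.append((b, s, pv))
        stats = out

    for j, (b, s, pv) in zip(cols, stats):
        v = genotypes.variants[j]
        f = float(genotypes.dosages[:, j].mean() / 2.0)
        records.append(VariantRecord(
            variant_id=v.variant_id, chrom=v.chrom, pos=v.pos,
            effect_allele=v.effect_allele, other_allele=v.other_allele,
            eaf=min(max(f, 1e-9), 1 - 1e-9),
            beta=float(b), se=float(s),
            pvalue=float(min(max(pv, 5e-324), 1.0)) if np.isfinite(pv) else float("nan"),
            n=n))
    _log_stage("association_scan", cohort=cohort_label, m=len(records), binary=binary)
    return GwasSummary(trait_name=trait_name, records=records, cohort_label=cohort_label)


# ---------------------------------------------------------------------------
# partitions and cohort assembly
# ---------------------------------------------------------------------------


def split_cohorts(n: int, fractions: Sequence[float], truth: SimTruth
                  ) -> list[np.ndarray]:
    """Disjoint exhaustive seed-deterministic row partitions."""
    fractions = list(fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be > 0")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = truth.rng("split")
    perm = rng.permutation(n)
    bounds = np.floor(np.cumsum(fractions) * n + 0.5).astype(int)
    bounds[-1] = n
    parts, start = [], 0
    for b in bounds:
        parts.append(np.sort(perm[start:b]))
        start = b
    return parts


def build_cohort(genotypes: GenotypeMatrix, traits: TraitSet, clones: CloneSim,
                 diagnosis: pd.DataFrame, truth: SimTruth,
                 rows: np.ndarray | None = None) -> CohortTable:
    """Assemble the per-individual cohort table (optionally a row subset)."""
    rng = truth.rng("covariates")
    n = genotypes.n
    covs = pd.DataFrame({
        "age": np.round(rng.uniform(40, 70, size=n), 1),
        "sex": rng.integers(0, 2, size=n),
        "batch": rng.integers(0, 2, size=n),
    })
    for k in range(1, 11):
        covs[f"pc{k}"] = rng.standard_normal(n)
    df = pd.concat([pd.Series(genotypes.sample_ids, name="id"), covs,
                    traits.values, diagnosis.reset_index(drop=True)], axis=1)
    if rows is not None:
        df = df.iloc[rows]
    return CohortTable(df.reset_index(drop=True))


@dataclass
class SimulatedStudy:
    """Everything one end-to-end generator run produces."""

    truth: SimTruth
    genotypes: GenotypeMatrix
    traits: TraitSet
    clones: CloneSim
    cohort: CohortTable
    partitions: dict[str, np.ndarray]


def simulate_study(truth: SimTruth,
                   fractions: Sequence[float] = (0.5, 0.2, 0.3)) -> SimulatedStudy:
    """Run the full generator: genotypes, traits, clones, labels, partitions.

    Partitions emulate the two-cohort GWAS design: ``discovery`` (instrument
    selection), ``external`` (independent weight re-estimation) and
    ``target`` (outcome GWAS / individual-level analyses).
    """
    genotypes = simulate_genotypes(truth)
    traits = simulate_traits(genotypes, truth)
    liab = traits.values[truth.clone_model.liability_trait].to_numpy()
    pleio = pleiotropy_effects(truth, traits)
    clones = simulate_clones(liab, truth, genotypes=genotypes,
                             pleiotropy_effects=pleio)
    diagnosis = assign_diagnosis(traits, clones, truth)
    cohort = build_cohort(genotypes, traits, clones, diagnosis, truth)
    disc, ext, target = split_cohorts(truth.n_individuals, fractions, truth)
    return SimulatedStudy(
        truth=truth, genotypes=genotypes, traits=traits, clones=clones,
        cohort=cohort,
        partitions={"discovery": disc, "external": ext, "target": target})
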