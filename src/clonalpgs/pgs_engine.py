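"""Conditional-joint SNP selection against an LD reference, and allele-aware
polygenic scoring.

The selection routine implements the summary-statistics stepwise procedure
used to refine GWAS hits into an approximately independent SNP set: starting
from the most significant variant, variants are added greedily whenever
their *conditional* association p-value (given the current set, with
between-variant correlations taken from a reference dosage panel and zeroed
beyond a physical window) stays below the threshold. Joint effects for the
selected set come from the same summary-based multiple-regression identity,

    beta_joint (standardized) = R^-1 b_marginal (standardized),

where R is the windowed reference correlation matrix and standardized
marginal effects are b_j * sqrt(2 f_j (1 - f_j)). Residual variance is
tracked as 1 minus the explained standardized variance, and per-variant
sample-size differences are ignored (single-cohort synthetic setting) — a
deliberate simplification of the full published conditional-joint
estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .core_io import GwasSummary, _log_stage, logger
from .synthetic_cohort import GenotypeMatrix, VariantStub


@dataclass
class LdReference:
    """Reference dosage panel providing between-variant correlations."""

    dosages: np.ndarray
    variants: list[VariantStub]
    sample_ids: list[str]

    def __post_init__(self):
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD reference")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("inconsistent LD reference dimensions")
        if len(self.sample_ids) < 50:
            warnings.warn("LD reference has fewer than 50 samples; correlation "
                          "estimates will be noisy", stacklevel=2)

    @classmethod
    def from_genotypes(cls, genotypes: GenotypeMatrix,
                       rows: np.ndarray | None = None) -> "LdReference":
        g = genotypes if rows is None else genotypes.subset_rows(rows)
        return cls(dosages=g.dosages, variants=list(g.variants),
                   sample_ids=list(g.sample_ids))

    def standardized(self) -> np.ndarray:
        x = self.dosages.astype(np.float64)
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = np.inf   # monomorphic -> zero column, zero correlation
        return x / sd

    def frequencies(self) -> np.ndarray:
        return self.dosages.astype(float).mean(axis=0) / 2.0


@dataclass(frozen=True)
class PgsEntry:
    variant_id: str
    effect_allele: str
    other_allele: str
    weight: float


@dataclass
class PgsModel:
    """variant -> (effect allele, joint per-allele weight) scoring object."""

    trait_name: str
    entries: list[PgsEntry]

    def __post_init__(self):
        ids = [e.variant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in PGS model")
        if not all(math.isfinite(e.weight) for e in self.entries):
            raise ValueError("non-finite PGS weight")

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# conditional-joint selection
# ---------------------------------------------------------------------------


def cojo_select(summary: GwasSummary, ld_ref: LdReference,
                p_threshold: float = 5e-8, window_bp: int = 10_000_000,
                maf_min: float = 0.01) -> PgsModel:
    """Greedy stepwise conditional selection with joint-effect reporting.

    Variants absent from the reference are dropped (logged); the MAF
    restriction applies first. Correlations between variants on different
    chromosomes, or further apart than ``window_bp``, are taken as zero.
    Candidates with reference r^2 > 0.9 to any selected variant become
    ineligible; a singular selected-set correlation matrix drops the
    last-added variant and continues.
    """
    ref_index = {v.variant_id: j for j, v in enumerate(ld_ref.variants)}
    recs = [r for r in summary.records if r.has_stats]
    absent = [r for r in recs if r.variant_id not in ref_index]
    if absent:
        logger.info("cojo_select: %d summary variants absent from reference",
                    len(absent))
    recs = [r for r in recs if r.variant_id in ref_index and r.maf >= maf_min]
    recs = sorted(recs, key=lambda r: (r.chrom, r.pos, r.variant_id))
    if not recs:
        return PgsModel(trait_name=summary.trait_name, entries=[])

    m = len(recs)
    ref_cols = np.array([ref_index[r.variant_id] for r in recs])
    X = ld_ref.standardized()[:, ref_cols]
    n_ref = X.shape[0]
    chrom = np.array([r.chrom for r in recs])
    pos = np.array([r.pos for r in recs])
    freqs = np.array([r.eaf for r in recs])
    sd = np.sqrt(2.0 * freqs * (1.0 - freqs))
    b_std = np.array([r.beta for r in recs]) * sd
    se_std = np.array([r.se for r in recs]) * sd
    pvals = np.array([r.pvalue for r in recs])

    def windowed_corr_with(j: int) -> np.ndarray:
        r = (X.T @ X[:, j]) / n_ref
        mask = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window_bp)
        r[~mask] = 0.0
        r[j] = 1.0
        return r

    start = int(np.lexsort((np.array([r.variant_id for r in recs]), pvals))[0])
    if pvals[start] >= p_threshold:
        return PgsModel(trait_name=summary.trait_name, entries=[])

    selected = [start]
    eligible = np.ones(m, dtype=bool)
    eligible[start] = False
    C = windowed_corr_with(start).reshape(m, 1)   # correlations candidates x selected
    eligible &= C[:, 0] ** 2 <= 0.9

    while eligible.any():
        R = C[selected, :]                         # k x k selected correlation
        try:
            Rinv = np.linalg.inv(R)
        except np.linalg.LinAlgError:
            Rinv = None
        if Rinv is None or np.linalg.cond(R) > 1e8:
            dropped = selected.pop()
            logger.info("cojo_select: singular LD submatrix, dropping %s",
                        recs[dropped].variant_id)
            C = C[:, :-1]
            if not selected:
                break
            continue
        beta_joint = Rinv @ b_std[selected]
        sigma2 = max(1.0 - float(b_std[selected] @ beta_joint), 1e-6)
        cand = np.flatnonzero(eligible)
        rcs = C[cand, :]                           # candidates x selected
        A = rcs @ Rinv
        denom = 1.0 - np.einsum("ij,ij->i", A, rcs)
        ok = denom > 1e-6
        # conditional se anchored on the marginal se: reduces exactly to the
        # summary se when the selected set is orthogonal to the candidate
        with np.errstate(divide="ignore", invalid="ignore"):
            b_cond = (b_std[cand] - rcs @ (Rinv @ b_std[selected])) / denom
            se_cond = se_std[cand] * np.sqrt(sigma2 / denom)
            z = np.abs(b_cond / se_cond)
        p_cond = 2.0 * norm.sf(z)
        p_cond[~ok] = 1.0
        best_local = int(np.lexsort(
            (np.array([recs[c].variant_id for c in cand]), p_cond))[0])
        if p_cond[best_local] >= p_threshold:
            break
        j = int(cand[best_local])
        selected.append(j)
        eligible[j] = False
        new_col = windowed_corr_with(j)
        C = np.column_stack([C, new_col])
        eligible &= new_col ** 2 <= 0.9

    selected = sorted(selected, key=lambda j: (chrom[j], pos[j]))
    R = np.empty((len(selected), len(selected)))
    cols = {}
    for a, j in enumerate(selected):
        cols[j] = windowed_corr_with(j)
    for a, j in enumerate(selected):
        for b, k in enumerate(selected):
            R[a, b] = cols[j][k]
    beta_joint_std = np.linalg.solve(R, b_std[selected])
    entries = []
    for w, j in zip(beta_joint_std, selected):
        r = recs[j]
        entries.append(PgsEntry(r.variant_id, r.effect_allele, r.other_allele,
                                float(w / sd[j])))
    _log_stage("cojo_select", trait=summary.trait_name, selected=len(entries),
               candidates=m)
    return PgsModel(trait_name=summary.trait_name, entries=entries)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def compute_pgs(genotypes: GenotypeMatrix, model: PgsModel) -> np.ndarray:
    """Allele-aware weighted dosage sum.

    A model entry whose alleles match the cohort variant directly
    contributes ``weight * dosage``; an exact allele swap contributes
    ``weight * (2 - dosage)``; incompatible allele pairs are skipped with a
    logged count.
    """
    index = genotypes.variant_index()
    score = np.zeros(genotypes.n)
    skipped = 0
    for e in model.entries:
        j = index.get(e.variant_id)
        if j is None:
            skipped += 1
            continue
        v = genotypes.variants[j]
        d = genotypes.dosages[:, j].astype(np.float64)
        if (e.effect_allele, e.other_allele) == (v.effect_allele, v.other_allele):
            score += e.weight * d
        elif (e.effect_allele, e.other_allele) == (v.other_allele, v.effect_allele):
            score += e.weight * (2.0 - d)
        else:
            skipped += 1
    if skipped:
        logger.info("compute_pgs: skipped %d unmatched model entries", skipped)
    _log_stage("compute_pgs", trait=model.trait_name,
               entries=len(model.entries), skipped=skipped)
    return score


def standardize_pgs(raw: np.ndarray, reference_group: np.ndarray | None = None
                    ) -> np.ndarray:
    """(score - mean_ref) / sd_ref with the sample (n-1) denominator.

    ``reference_group`` indexes (or masks) the individuals defining the
    reference distribution; default is the full cohort. Downstream odds
    ratios are per 1 s.d. of this reference distribution.
    """
    raw = np.asarray(raw, dtype=float)
    ref = raw if reference_group is None else raw[reference_group]
    if ref.size == 0:
        raise ValueError("empty reference group")
    sd = float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0
    if not sd > 0:
        raise ValueError("zero variance in PGS reference group")
    return (raw - float(ref.mean())) / sd


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform Phi^-1((rank - 0.5)/n).

    Average ranks for ties; missing values stay missing. All-identical
    non-missing values carry no order information and raise.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = ~np.isnan(values)
    x = values[mask]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("all values identical: no order information")
    ranks = rankdata(x, method="average")
    out[mask] = norm.ppf((ranks - 0.5) / x.size)
    return out
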