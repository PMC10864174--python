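"""End-to-end orchestration of the inference chain on a simulated study.

The chain mirrors the analysis design: discovery GWAS -> conditional-joint
SNP selection -> polygenic scoring and standardization in the target
cohort -> clone-size-stratified multinomial association -> two-sample MR of
the trait on clone positivity -> liability-scale variance partitioning of
disease labels -> driver-stratified quintile and enrichment analyses.
Everything is a deterministic function of the simulation truth (seed
included) and the analysis configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AnalysisConfig, CohortTable, GwasSummary, _log_stage
from .synthetic_cohort import (SimTruth, SimulatedStudy, association_scan,
                               simulate_study)
from .pgs_engine import (LdReference, PgsModel, cojo_select, compute_pgs,
                         standardize_pgs)
from . import assoc as assoc_mod
from . import mr_engine


def run_mr_study(truth: SimTruth, config: AnalysisConfig | None = None,
                 fractions=(0.5, 0.2, 0.3), ld_ref_size: int = 3000
                 ) -> dict:
    """Lean two-sample MR run: generator -> exposure scans -> instrument
    selection -> outcome scan on the candidate instruments -> IVW/Egger.

    The outcome (clone-positivity) logistic scan is restricted to the
    variants that already pass the dual exposure thresholds, since only
    those can become instruments. Returns the instrument set and the IVW
    and Egger results (the bootstrap-based median estimators are skipped
    here; use :func:`run_pipeline` for the full report).
    """
    from .synthetic_cohort import (pleiotropy_effects, simulate_clones,
                                   simulate_genotypes, simulate_traits,
                                   split_cohorts)
    cfg = config or AnalysisConfig(seed=truth.seed)
    g = simulate_genotypes(truth)
    ts = simulate_traits(g, truth)
    liab = ts.values[truth.clone_model.liability_trait].to_numpy()
    pe = pleiotropy_effects(truth, ts)
    cl = simulate_clones(liab, truth, genotypes=g, pleiotropy_effects=pe)
    disc, ext, target = split_cohorts(truth.n_individuals, fractions, truth)
    s_disc = association_scan(g.subset_rows(disc), liab[disc],
                              trait_name=truth.clone_model.liability_trait,
                              cohort_label="discovery")
    s_ext = association_scan(g.subset_rows(ext), liab[ext],
                             trait_name=truth.clone_model.liability_trait,
                             cohort_label="external")
    ext_p = {r.variant_id: r.pvalue for r in s_ext.records if r.has_stats}
    cand = [r.variant_id for r in s_disc.records
            if r.has_stats and r.pvalue < cfg.gws_p
            and ext_p.get(r.variant_id, 1.0) < cfg.external_p]
    index = g.variant_index()
    outcome = association_scan(
        g.subset_rows(target), cl.carrier[target].astype(float), binary=True,
        trait_name="clone_positivity", cohort_label="target",
        variant_subset=[index[v] for v in cand])
    ref_rng = np.random.default_rng(truth.seed + 104729)
    ref_rows = np.sort(ref_rng.choice(disc, size=min(ld_ref_size, len(disc)),
                                      replace=False))
    ld_ref = LdReference.from_genotypes(g, ref_rows)
    inst = mr_engine.select_instruments(s_disc, s_ext, outcome, ld_ref, cfg)
    return {"instruments": inst, "ivw": mr_engine.mr_ivw(inst),
            "egger": mr_engine.mr_egger(inst), "clones": cl,
            "truth_effects": ts.true_effects}


@dataclass
class PipelineResult:
    study: SimulatedStudy
    pgs_models: dict[str, PgsModel]
    target_cohort: CohortTable                  # with standardized pgs_* columns
    clone_association: list                     # AssociationResult list
    mr_results: dict[str, "mr_engine.MrResult"]
    mr_verdict: "mr_engine.MrVerdict"
    presso: "mr_engine.PressoResult | None"
    extras: dict = field(default_factory=dict)


def run_pipeline(truth: SimTruth, config: AnalysisConfig | None = None,
                 ld_ref_size: int = 4000, n_boot: int = 500,
                 run_presso: bool = False) -> PipelineResult:
    """Run the full chain on one simulated study."""
    cfg = config or AnalysisConfig(seed=truth.seed)
    study = simulate_study(truth)
    disc, ext, target = (study.partitions["discovery"],
                         study.partitions["external"],
                         study.partitions["target"])
    liability_trait = truth.clone_model.liability_trait

    # LD reference: a random subset of discovery individuals
    ref_rng = np.random.default_rng(truth.seed + 104729)
    ref_rows = np.sort(ref_rng.choice(disc, size=min(ld_ref_size, len(disc)),
                                      replace=False))
    ld_ref = LdReference.from_genotypes(study.genotypes, ref_rows)

    # per-trait discovery/external GWAS and PGS models
    pgs_models: dict[str, PgsModel] = {}
    gwas_disc: dict[str, GwasSummary] = {}
    gwas_ext: dict[str, GwasSummary] = {}
    geno_disc = study.genotypes.subset_rows(disc)
    geno_ext = study.genotypes.subset_rows(ext)
    geno_target = study.genotypes.subset_rows(target)
    for spec in truth.traits:
        y = study.traits.values[spec.name].to_numpy()
        gwas_disc[spec.name] = association_scan(
            geno_disc, y[disc], trait_name=spec.name, cohort_label="discovery")
        gwas_ext[spec.name] = association_scan(
            geno_ext, y[ext], trait_name=spec.name, cohort_label="external")
        pgs_models[spec.name] = cojo_select(
            gwas_disc[spec.name], ld_ref, p_threshold=cfg.gws_p,
            window_bp=cfg.cojo_window_bp, maf_min=cfg.maf_min)

    # scored, standardized target cohort
    tdf = study.cohort.df.iloc[target].reset_index(drop=True).copy()
    for name, model in pgs_models.items():
        raw = compute_pgs(geno_target, model) if len(model) else np.zeros(
            geno_target.n)
        if len(model) and np.std(raw, ddof=1) > 0:
            tdf[f"pgs_{name}"] = standardize_pgs(raw)
        else:
            tdf[f"pgs_{name}"] = 0.0
    target_cohort = CohortTable(tdf)

    # clone-size-stratified multinomial association
    calls = assoc_mod.classify_clones(target_cohort, cfg.vaf_threshold)
    tdf["clone_category"] = [c.category for c in calls]
    covars = ["age", "sex"] + [f"pc{k}" for k in range(1, 11)]
    pgs_cols = [f"pgs_{s.name}" for s in truth.traits
                if len(pgs_models[s.name])]
    clone_assoc = []
    if pgs_cols and (tdf["clone_category"] != "none").sum() >= 20:
        clone_assoc = assoc_mod.fit_multinomial(
            tdf, "clone_category", pgs_cols, covars, reference="none")
        assoc_mod.add_fdr(clone_assoc)

    # two-sample MR: trait (discovery instruments, external weights) -> clone
    clone_y = study.clones.carrier.astype(float)
    outcome_gwas_full = association_scan(
        geno_target, clone_y[target], trait_name="clone_positivity",
        cohort_label="target", binary=True)
    inst = mr_engine.select_instruments(
        gwas_disc[liability_trait], gwas_ext[liability_trait],
        outcome_gwas_full, ld_ref, cfg)
    mr_results = mr_engine.run_mr(inst, seed=truth.seed, n_boot=n_boot)
    verdict = mr_engine.mr_decision(mr_results, alpha_bonf=cfg.mr_alpha_bonf)
    presso = None
    if run_presso and len(inst) >= 4:
        presso = mr_engine.mr_presso(inst, n_sim=2000, seed=truth.seed)

    _log_stage("run_pipeline", seed=truth.seed, n=truth.n_individuals,
               m=truth.m_variants, instruments=len(inst))
    return PipelineResult(
        study=study, pgs_models=pgs_models, target_cohort=target_cohort,
        clone_association=clone_assoc, mr_results=mr_results,
        mr_verdict=verdict, presso=presso,
        extras={"instruments": inst, "ld_ref": ld_ref,
                "gwas_discovery": gwas_disc, "gwas_external": gwas_ext,
                "outcome_gwas": outcome_gwas_full,
                "target_rows": target})
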