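import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from clonalpgs import (CloneModel, DiagnosisThresholds, SimTruth, TraitSpec,
                       association_scan, assign_diagnosis, simulate_clones,
                       simulate_genotypes, simulate_traits, split_cohorts)


def truth_with(**kwargs) -> SimTruth:
    base = dict(m_variants=60, n_individuals=5000, seed=7)
    base.update(kwargs)
    if "traits" not in base:
        m_causal = min(30, base["m_variants"] // 2 or 1)
        base["traits"] = [TraitSpec("PCT", m_causal, 0.3)]
    return SimTruth(**base)


class TestSimulateGenotypes:
    def test_independent_variants_when_rho_zero(self):
        g = simulate_genotypes(truth_with(ld_rho=0.0, m_variants=50))
        d = g.dosages.astype(float)
        corr = np.corrcoef(d.T)
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.mean(np.abs(off)) < 0.02

    def test_adjacent_correlation_increases_with_rho(self):
        def mean_adjacent(rho):
            t = truth_with(ld_rho=rho, ld_block_size=10, m_variants=50)
            d = simulate_genotypes(t).dosages.astype(float)
            rs = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
                  for j in range(49) if (j + 1) % 10 != 0]
            return float(np.mean(rs))

        assert mean_adjacent(0.0) < mean_adjacent(0.4) < mean_adjacent(0.8)

    def test_same_seed_bit_identical(self):
        a = simulate_genotypes(truth_with())
        b = simulate_genotypes(truth_with())
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert [v.variant_id for v in a.variants] == [v.variant_id for v in b.variants]

    def test_half_frequency_band(self):
        g = simulate_genotypes(truth_with(maf_range=(0.5, 0.5)))
        freqs = g.dosages.mean(axis=0) / 2.0
        assert ((freqs >= 0.45) & (freqs <= 0.55)).all()

    def test_hardy_weinberg_proportions(self):
        g = simulate_genotypes(truth_with(n_individuals=20000, m_variants=10,
                                          maf_range=(0.3, 0.3)))
        het = (g.dosages == 1).mean(axis=0)
        np.testing.assert_allclose(het, 2 * 0.3 * 0.7, atol=0.02)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            SimTruth(m_variants=0, n_individuals=10)


class TestSimulateTraits:
    def test_heritability_recovered_in_regression(self):
        t = truth_with(n_individuals=20000, m_variants=200,
                       traits=[TraitSpec("PCT", 100, 0.3)])
        g = simulate_genotypes(t)
        ts = simulate_traits(g, t)
        y = ts.values["PCT"].to_numpy()
        gv = ts.genetic_values["PCT"].to_numpy()
        r2 = np.corrcoef(y, gv)[0, 1] ** 2
        assert 0.27 <= r2 <= 0.33
        assert 0.9 <= y.var() <= 1.1

    def test_zero_causal_variants_pure_noise(self):
        t = truth_with(traits=[TraitSpec("PCT", 0, 0.3)])
        g = simulate_genotypes(t)
        ts = simulate_traits(g, t)
        assert np.all(ts.genetic_values["PCT"] == 0)
        assert np.all(ts.true_effects["PCT"] == 0)

    def test_doubling_effects_quadruples_genetic_variance(self):
        t = truth_with()
        g = simulate_genotypes(t)
        ts = simulate_traits(g, t)
        dos = g.dosages.astype(float)
        beta = ts.true_effects["PCT"]
        var1 = (dos @ beta).var()
        var2 = (dos @ (2 * beta)).var()
        assert var2 == pytest.approx(4 * var1, rel=1e-10)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            TraitSpec("PCT", 10, 1.5)


class TestSimulateClones:
    def test_baseline_carrier_rate_without_selection(self):
        t = truth_with(n_individuals=100_000, m_variants=2,
                       traits=[TraitSpec("PCT", 0, 0.3)],
                       clone_model=CloneModel(alpha0=float(logit(0.003)),
                                              alpha1=0.0))
        rng = np.random.default_rng(3)
        liab = rng.standard_normal(100_000)
        cl = simulate_clones(liab, t)
        rate = cl.carrier.mean()
        assert 0.002 <= rate <= 0.004

    def test_selection_raises_carrier_liability(self):
        t = truth_with(clone_model=CloneModel(alpha0=float(logit(0.05)),
                                              alpha1=0.5))
        rng = np.random.default_rng(4)
        liab = rng.standard_normal(5000)
        cl = simulate_clones(liab, t)
        assert liab[cl.carrier].mean() > liab[~cl.carrier].mean()

    def test_degenerate_vaf_model_constant(self):
        t = truth_with(clone_model=CloneModel(alpha0=0.0, alpha1=0.0,
                                              vaf_mu=-2.0, vaf_gamma=0.0,
                                              vaf_sigma=0.0))
        cl = simulate_clones(np.zeros(2000), t)
        vafs = cl.vaf[cl.carrier]
        np.testing.assert_allclose(vafs, expit(-2.0), rtol=1e-12)

    def test_noncarriers_have_missing_vaf(self):
        t = truth_with()
        cl = simulate_clones(np.zeros(3000), t)
        assert np.isnan(cl.vaf[~cl.carrier]).all()
        v = cl.vaf[cl.carrier]
        assert ((v > 0) & (v < 1)).all()


class TestAssignDiagnosis:
    def test_all_controls_without_exceedance(self):
        t = truth_with(diagnosis_thresholds=DiagnosisThresholds(
            et_trait="PCT", et_cut=50.0, pv_trait="PCT", pv_cut=50.0))
        g = simulate_genotypes(t)
        ts = simulate_traits(g, t)
        cl = simulate_clones(ts.values["PCT"].to_numpy(), t)
        cl.carrier[:] = False
        cl.vaf[:] = np.nan
        diag = assign_diagnosis(ts, cl, t)
        assert (diag["diagnosis"] == "control").all()

    def test_case_status_independent_of_carrier_when_no_boost(self):
        t = truth_with(n_individuals=40000,
                       clone_model=CloneModel(alpha0=float(logit(0.05)),
                                              alpha1=0.0),
                       diagnosis_thresholds=DiagnosisThresholds(
                           et_trait="PCT", et_cut=1.5, pv_trait="PCT",
                           pv_cut=50.0, clone_boost=0.0, mf_frac=0.0))
        g = simulate_genotypes(t)
        ts = simulate_traits(g, t)
        cl = simulate_clones(ts.values["PCT"].to_numpy(), t)
        diag = assign_diagnosis(ts, cl, t)
        # regression of pre-coercion clone status on case status given trait
        y = cl.carrier.astype(float)
        X = sm.add_constant(pd.DataFrame({
            "case": (diag["diagnosis"] != "control").astype(float),
            "trait": ts.values["PCT"]}))
        fit = sm.Logit(y, X).fit(disp=False)
        assert abs(fit.params["case"]) < 3 * fit.bse["case"]

    def test_raising_cut_weakly_decreases_et(self):
        counts = []
        for cut in (1.5, 2.0, 2.5):
            t = truth_with(diagnosis_thresholds=DiagnosisThresholds(
                et_trait="PCT", et_cut=cut, pv_trait="PCT", pv_cut=50.0,
                mf_frac=0.0))
            g = simulate_genotypes(t)
            ts = simulate_traits(g, t)
            cl = simulate_clones(ts.values["PCT"].to_numpy(), t)
            diag = assign_diagnosis(ts, cl, t)
            counts.append((diag["diagnosis"] == "ET").sum())
        assert counts[0] >= counts[1] >= counts[2]

    def test_driver_class_constraints(self, small_study):
        df = small_study.cohort.df
        cases = df[df["diagnosis"] != "control"]
        jak2 = cases[cases["driver_class"] == "JAK2het"]
        assert jak2["carrier"].all()
        assert jak2["vaf"].notna().all()
        negatives = cases[cases["driver_class"].isin(["CALR_MPL", "TN"])]
        assert not negatives["carrier"].any()
        assert cases["driver_class"].notna().all()
        assert df.loc[df["diagnosis"] == "control", "driver_class"].isna().all()


class TestAssociationScan:
    def test_null_trait_type_one_error(self):
        t = truth_with(m_variants=200, n_individuals=4000)
        g = simulate_genotypes(t)
        rng = np.random.default_rng(12)
        y = rng.standard_normal(4000)
        s = association_scan(g, y)
        pvals = np.array([r.pvalue for r in s.records])
        frac = (pvals < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_beta_matches_ols_oracle(self):
        t = truth_with(m_variants=5, n_individuals=800)
        g = simulate_genotypes(t)
        rng = np.random.default_rng(5)
        cov = rng.standard_normal((800, 2))
        y = 0.3 * g.dosages[:, 2] + cov @ [0.5, -0.2] + rng.standard_normal(800)
        s = association_scan(g, y, covariates=cov)
        X = sm.add_constant(np.column_stack([cov, g.dosages[:, 2]]))
        oracle = sm.OLS(y, X).fit()
        assert s.records[2].beta == pytest.approx(oracle.params[-1], abs=1e-10)
        assert s.records[2].se == pytest.approx(oracle.bse[-1], rel=1e-8)

    def test_logistic_beta_matches_statsmodels(self):
        t = truth_with(m_variants=4, n_individuals=3000)
        g = simulate_genotypes(t)
        rng = np.random.default_rng(6)
        eta = -2.0 + 0.4 * g.dosages[:, 1]
        y = (rng.random(3000) < expit(eta)).astype(float)
        s = association_scan(g, y, binary=True)
        X = sm.add_constant(g.dosages[:, 1].astype(float))
        oracle = sm.Logit(y, X).fit(disp=False)
        assert s.records[1].beta == pytest.approx(oracle.params[1], abs=1e-6)
        assert s.records[1].se == pytest.approx(oracle.bse[1], rel=1e-5)

    def test_constant_dosage_missing_stats(self):
        t = truth_with(m_variants=3, n_individuals=200)
        g = simulate_genotypes(t)
        g.dosages[:, 0] = 1
        y = np.random.default_rng(0).standard_normal(200)
        s = association_scan(g, y)
        assert not s.records[0].has_stats
        assert s.records[1].has_stats

    def test_outcome_length_mismatch(self):
        t = truth_with(m_variants=3, n_individuals=100)
        g = simulate_genotypes(t)
        with pytest.raises(ValueError):
            association_scan(g, np.zeros(99))


class TestSplitCohorts:
    def test_sizes_and_exhaustive(self):
        t = truth_with()
        parts = split_cohorts(1000, (0.5, 0.25, 0.25), t)
        assert [len(p) for p in parts] == [500, 250, 250]
        assert set(np.concatenate(parts).tolist()) == set(range(1000))

    def test_deterministic(self):
        t = truth_with()
        a = split_cohorts(1000, (0.6, 0.4), t)
        b = split_cohorts(1000, (0.6, 0.4), t)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_cohorts(100, (1.0, 0.0), truth_with())


def test_generator_is_pure_function_of_truth(small_truth, small_study):
    from clonalpgs import simulate_study
    again = simulate_study(small_truth)
    np.testing.assert_array_equal(again.genotypes.dosages,
                                  small_study.genotypes.dosages)
    pd.testing.assert_frame_equal(again.cohort.df, small_study.cohort.df)


def test_carrier_prevalence_monotone_in_alpha0():
    rates = []
    rng = np.random.default_rng(9)
    liab = rng.standard_normal(30000)
    for a0 in (logit(0.002), logit(0.01), logit(0.05)):
        t = truth_with(clone_model=CloneModel(alpha0=float(a0), alpha1=0.3))
        rates.append(simulate_clones(liab, t).carrier.mean())
    assert rates[0] < rates[1] < rates[2]


def test_vaf_quantiles_monotone_in_vaf_mu():
    rng = np.random.default_rng(10)
    liab = rng.standard_normal(20000)
    medians = []
    for mu in (-3.5, -2.5, -1.5):
        t = truth_with(clone_model=CloneModel(alpha0=float(logit(0.2)),
                                              alpha1=0.0, vaf_mu=mu))
        cl = simulate_clones(liab, t)
        medians.append(np.nanmedian(cl.vaf))
    assert medians[0] < medians[1] < medians[2]
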