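import numpy as np
import pytest

from clonalpgs import (GwasSummary, InstrumentSet, VariantRecord, harmonize,
                       mr_decision, mr_egger, mr_ivw, mr_median, mr_presso)
from clonalpgs.mr_engine import MrResult, wald_ratio, weighted_median


def rec(vid, ea, oa, beta, eaf=0.3, se=0.02, p=1e-9, chrom="1", pos=100,
        n=10000):
    return VariantRecord(vid, chrom, pos, ea, oa, eaf, beta, se, p, n)


def random_instruments(m=10, seed=0, slope=0.3, intercept=0.0, noise=0.0):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.05, 0.4, size=m) * rng.choice([-1, 1], size=m)
    sx = rng.uniform(0.005, 0.02, size=m)
    sy = rng.uniform(0.02, 0.1, size=m)
    by = intercept * np.sign(bx) + slope * bx + noise * rng.normal(size=m) * sy
    return InstrumentSet([f"rs{i}" for i in range(m)], bx, sx, by, sy)


class TestHarmonize:
    def test_swapped_alleles_flip_effect_sign(self):
        exp = GwasSummary("T", [rec("rs1", "A", "G", 0.2, eaf=0.3)])
        out = GwasSummary("clone", [rec("rs1", "G", "A", -0.1, eaf=0.7)])
        inst = harmonize(exp, out)
        assert inst.by[0] == pytest.approx(0.1)
        assert inst.eaf[0] == pytest.approx(0.3)

    def test_ambiguous_palindromic_dropped(self):
        exp = GwasSummary("T", [rec("rs1", "A", "T", 0.2, eaf=0.45),
                                rec("rs2", "C", "G", 0.2, eaf=0.55, pos=200)])
        out = GwasSummary("clone", [rec("rs1", "A", "T", 0.1, eaf=0.45),
                                    rec("rs2", "C", "G", 0.1, eaf=0.55, pos=200)])
        with pytest.raises(ValueError):
            harmonize(exp, out)

    def test_unambiguous_palindromic_kept(self):
        exp = GwasSummary("T", [rec("rs1", "A", "T", 0.2, eaf=0.1)])
        out = GwasSummary("clone", [rec("rs1", "A", "T", 0.1, eaf=0.1)])
        assert len(harmonize(exp, out)) == 1

    def test_incompatible_pairs_dropped(self):
        exp = GwasSummary("T", [rec("rs1", "A", "G", 0.2),
                                rec("rs2", "A", "G", 0.2, pos=200)])
        out = GwasSummary("clone", [rec("rs1", "A", "C", 0.1),
                                    rec("rs2", "A", "G", 0.1, pos=200)])
        inst = harmonize(exp, out)
        assert inst.variant_ids == ["rs2"]

    def test_empty_intersection_rejected(self):
        exp = GwasSummary("T", [rec("rs1", "A", "G", 0.2)])
        out = GwasSummary("clone", [rec("rs9", "A", "G", 0.1)])
        with pytest.raises(ValueError):
            harmonize(exp, out)


class TestIvw:
    def test_single_instrument_wald_ratio(self):
        est, se = wald_ratio(0.5, 0.1, 0.2)
        assert est == pytest.approx(0.2)
        assert se == pytest.approx(0.4)

    def test_equal_ratios_no_heterogeneity_scaling(self):
        bx = np.array([0.1, 0.2, 0.3])
        inst = InstrumentSet(["a", "b", "c"], bx, 0.01 * np.ones(3),
                             0.25 * bx, np.array([0.02, 0.05, 0.03]))
        res = mr_ivw(inst)
        assert res.estimate == pytest.approx(0.25, rel=1e-12)
        w = 1 / inst.sy ** 2
        assert res.se == pytest.approx(np.sqrt(1 / np.sum(w * bx ** 2)), rel=1e-12)

    def test_matches_weighted_least_squares_oracle(self):
        inst = random_instruments(m=10, seed=3, noise=1.0)
        res = mr_ivw(inst)
        w = 1 / inst.sy ** 2
        slope = np.sum(w * inst.bx * inst.by) / np.sum(w * inst.bx ** 2)
        assert res.estimate == pytest.approx(slope, abs=1e-10)

    def test_requires_two_instruments(self):
        inst = random_instruments(m=10).subset([0])
        with pytest.raises(ValueError):
            mr_ivw(inst)


class TestEgger:
    def test_exact_affine_relation_recovered(self):
        inst = random_instruments(m=8, seed=1)
        inst.bx = np.abs(inst.bx)
        inst.by = 0.1 + 0.3 * inst.bx
        res = mr_egger(inst)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert res.estimate == pytest.approx(0.3, abs=1e-10)

    def test_proportional_relation_zero_intercept(self):
        inst = random_instruments(m=8, seed=2)
        inst.by = 0.3 * np.abs(inst.bx) * np.sign(inst.bx)
        res = mr_egger(inst)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_with_intercept_oracle(self):
        inst = random_instruments(m=15, seed=4, noise=1.5)
        res = mr_egger(inst)
        flip = np.sign(inst.bx)
        x, y = inst.bx * flip, inst.by * flip
        w = 1 / inst.sy ** 2
        X = np.column_stack([np.ones(len(inst)), x])
        coef = np.linalg.solve((X.T * w) @ X, (X.T * w) @ y)
        assert res.egger_intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.estimate == pytest.approx(coef[1], abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger(random_instruments(m=10).subset([0, 1]))


class TestMedian:
    def test_simple_median_of_ratios(self):
        inst = InstrumentSet(["a", "b", "c"], np.ones(3), 0.01 * np.ones(3),
                             np.array([0.1, 0.2, 0.9]), 0.05 * np.ones(3))
        res = mr_median(inst, weighted=False, n_boot=200, seed=0)
        assert res.estimate == pytest.approx(0.2)

    def test_equal_weights_match_simple(self):
        bx = np.full(5, 0.2)
        sy = np.full(5, 0.05)
        by = np.array([0.01, 0.03, 0.05, 0.02, 0.08])
        inst = InstrumentSet(list("abcde"), bx, 0.01 * np.ones(5), by, sy)
        simple = mr_median(inst, weighted=False, n_boot=150, seed=1)
        weighted = mr_median(inst, weighted=True, n_boot=150, seed=1)
        assert weighted.estimate == pytest.approx(simple.estimate, rel=1e-12)

    def test_weighted_median_matches_cumulative_scan_oracle(self):
        inst = InstrumentSet(list("abcd"), np.array([0.1, 0.2, 0.3, 0.4]),
                             0.01 * np.ones(4),
                             np.array([0.01, 0.08, 0.06, 0.2]),
                             np.array([0.02, 0.04, 0.03, 0.08]))
        res = mr_median(inst, weighted=True, n_boot=150, seed=2)
        ratios = inst.by / inst.bx
        weights = inst.bx ** 2 / inst.sy ** 2
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order]
        q = (np.cumsum(w) - 0.5 * w) / w.sum()
        # brute-force scan of the piecewise-linear cumulative weight function
        below = np.flatnonzero(q < 0.5).max()
        expected = r[below] + (r[below + 1] - r[below]) * \
            (0.5 - q[below]) / (q[below + 1] - q[below])
        assert res.estimate == pytest.approx(expected, rel=1e-12)
        assert res.estimate == pytest.approx(weighted_median(ratios, weights),
                                             rel=1e-12)

    def test_bootstrap_seeded_reproducible(self):
        inst = random_instruments(m=12, seed=5, noise=1.0)
        a = mr_median(inst, weighted=True, n_boot=300, seed=9)
        b = mr_median(inst, weighted=True, n_boot=300, seed=9)
        assert a.se == b.se

    def test_small_bootstrap_warns(self):
        inst = random_instruments(m=5, seed=6)
        with pytest.warns(UserWarning):
            mr_median(inst, n_boot=50, seed=0)


class TestPresso:
    def test_clean_proportional_set_is_null(self):
        inst = random_instruments(m=12, seed=7, noise=0.3)
        res = mr_presso(inst, n_sim=1000, seed=0)
        assert res.global_p > 0.2
        assert res.outlier_indices == []
        assert np.isnan(res.distortion_p)

    def test_displaced_instrument_flagged(self):
        flagged = 0
        for seed in range(10):
            inst = random_instruments(m=21, seed=100 + seed, noise=1.0)
            inst.by = inst.by.copy()
            inst.by[5] += 10 * inst.sy[5]
            res = mr_presso(inst, n_sim=2000, seed=seed)
            flagged += 5 in res.outlier_indices
        assert flagged >= 9

    def test_outlier_corrected_estimate_reported(self):
        inst = random_instruments(m=21, seed=42, noise=1.0)
        inst.by = inst.by.copy()
        inst.by[3] += 12 * inst.sy[3]
        res = mr_presso(inst, n_sim=1500, seed=1)
        if res.outlier_indices:
            assert res.outlier_corrected is not None
            assert not np.isnan(res.distortion_p)

    def test_requires_four_instruments(self):
        with pytest.raises(ValueError):
            mr_presso(random_instruments(m=10).subset([0, 1, 2]), n_sim=1000)


class TestDecision:
    def make_results(self, p_ivw=0.001, signs=(1, 1, 1, 1), intercept_p=0.84):
        methods = ("ivw", "egger", "simple_median", "weighted_median")
        out = {}
        for m, s in zip(methods, signs):
            r = MrResult(method=m, estimate=0.4 * s, se=0.1, ci_low=0.2 * s,
                         ci_high=0.6 * s, pvalue=p_ivw, n_instruments=50)
            if m == "egger":
                r.intercept_p = intercept_p
            out[m] = r
        return out

    def test_consistent_significant_pattern(self):
        v = mr_decision(self.make_results())
        assert v.significant

    def test_direction_clause_fails(self):
        v = mr_decision(self.make_results(signs=(1, -1, 1, 1)))
        assert not v.significant and "direction" in v.rationale

    def test_ivw_threshold_clause(self):
        v = mr_decision(self.make_results(p_ivw=0.01), alpha_bonf=0.0042)
        assert not v.significant

    def test_pleiotropy_clause(self):
        v = mr_decision(self.make_results(intercept_p=0.01))
        assert not v.significant and "intercept" in v.rationale

    def test_missing_method_rejected(self):
        res = self.make_results()
        del res["egger"]
        with pytest.raises(ValueError):
            mr_decision(res)


class TestInvariances:
    def test_sign_flip_of_single_instrument_invariant(self):
        inst = random_instruments(m=9, seed=11, noise=1.0)
        flipped = InstrumentSet(inst.variant_ids, inst.bx.copy(), inst.sx,
                                inst.by.copy(), inst.sy)
        flipped.bx[2] *= -1
        flipped.by[2] *= -1
        for fn in (mr_ivw, mr_egger):
            assert fn(inst).estimate == pytest.approx(fn(flipped).estimate,
                                                      rel=1e-12)
        a = mr_median(inst, weighted=True, n_boot=100, seed=3)
        b = mr_median(flipped, weighted=True, n_boot=100, seed=3)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)

    def test_ivw_equals_egger_when_intercept_zero(self):
        inst = random_instruments(m=10, seed=12)
        inst.by = 0.3 * inst.bx   # exact proportionality, intercept 0
        assert mr_ivw(inst).estimate == pytest.approx(
            mr_egger(inst).estimate, abs=1e-10)

    def test_egger_intercept_type_one_error(self):
        """Under no pleiotropy the intercept test should reject ~5%."""
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            m = 60
            bx = rng.uniform(0.05, 0.3, size=m)
            sx = np.full(m, 0.005)
            sy = rng.uniform(0.03, 0.08, size=m)
            by = 0.3 * bx + sy * rng.standard_normal(m)
            inst = InstrumentSet([f"r{i}" for i in range(m)], bx, sx, by, sy)
            rejections += mr_egger(inst).intercept_p < 0.05
        assert 0.02 <= rejections / reps <= 0.08
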