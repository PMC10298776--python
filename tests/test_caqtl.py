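import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from caqtlkit import caqtl as cq
from caqtlkit.synthdata import (
    SimConfig,
    make_ground_truth,
    simulate_genotypes,
    simulate_peak_counts,
)
from tests.conftest import oracle_loglik


def _simulate_pair(rng, n=10, depth=200.0, pi=0.5, psi=0.5, delta=0.0,
                   phi=0.1, theta=0.02, maf=0.3, inf_frac=0.2):
    """Direct NB + BB draw for one peak-variant pair."""
    g = rng.binomial(2, maf, size=n)
    s = np.exp(rng.normal(0, 0.25, n))
    mu = s * depth * ((2 - g) * (1 - pi) + g * pi)
    y = rng.poisson(rng.gamma(1 / phi, mu * phi))
    het = np.flatnonzero(g == 1)
    p = pi * (1 - psi) / (pi * (1 - psi) + (1 - pi) * psi)
    pp = p * (1 - 2 * delta) + delta
    d = rng.binomial(y[het].astype(int), inf_frac)
    if theta > 0:
        probs = rng.beta(pp / theta, (1 - pp) / theta, size=d.shape)
    else:
        probs = pp
    a = rng.binomial(d, probs)
    keep = d > 0
    return y.astype(float), s, g, (het[keep], (d - a)[keep], a[keep])


class TestGradient:
    @pytest.mark.parametrize("has_bb", [True, False])
    def test_analytic_matches_finite_difference(self, has_bb):
        rng = np.random.default_rng(5)
        y = rng.poisson(80, 12).astype(float)
        s = np.exp(rng.normal(0, 0.2, 12))
        g = rng.integers(0, 3, 12).astype(float)
        C = rng.normal(0, 1, (12, 2))
        a = rng.integers(0, 15, 5).astype(float)
        r = rng.integers(0, 15, 5).astype(float)
        names = cq._layout(has_bb, True, 2)
        fun = cq._make_objective(y, np.log(s), g, C, a, r, has_bb, names, {})
        if has_bb:
            x0 = np.array([0.62, 0.47, 0.02, np.log(70), np.log(0.08),
                           np.log(0.04), 0.05, -0.1])
        else:
            x0 = np.array([0.62, np.log(70), np.log(0.08), 0.05, -0.1])
        _, grad = fun(x0)
        num = approx_fprime(x0, lambda x: fun(x)[0], 1e-7)
        assert np.allclose(grad, num, rtol=1e-3, atol=1e-3)


class TestFitJointModel:
    def test_no_information_gives_null(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100, 10).astype(float)
        s = np.ones(10)
        g = np.ones(10)  # all heterozygous, balanced counts
        het = np.arange(10)
        a = np.full(10, 10.0)
        r = np.full(10, 10.0)
        res = cq.fit_joint_model(y, (het, r, a), g, s)
        assert abs(res.pi_hat - 0.5) < 0.05
        assert res.lrt_p > 0.5

    def test_parameter_recovery_planted_pi(self):
        rng = np.random.default_rng(42)
        hats = []
        for _ in range(40):
            y, s, g, al = _simulate_pair(rng, depth=500.0, pi=0.75)
            res = cq.fit_joint_model(y, al, g, s)
            hats.append(res.pi_hat)
        assert abs(np.median(hats) - 0.75) < 0.05

    def test_grid_oracle_small_instance(self):
        """Optimizer matches an exhaustive pi x psi grid at fixed nuisances."""
        rng = np.random.default_rng(7)
        y, s, g, al = _simulate_pair(rng, n=4, depth=20.0, pi=0.7, maf=0.5,
                                     inf_frac=0.5)
        lam, phi, theta = 20.0, 0.1, 0.02
        fix = {"delta": 0.0, "loglam": np.log(lam), "logphi": np.log(phi),
               "logtheta": np.log(theta)}
        res = cq.fit_joint_model(y, al, g, s, fix=fix, psi_prior=0.0)
        het, ref_c, alt_c = al
        ll_fit = oracle_loglik(y, s, g, alt_c, ref_c, res.pi_hat, res.psi_hat,
                               0.0, lam, phi, theta)
        grid = np.arange(0.01, 1.0, 0.01)
        ll_grid = max(
            oracle_loglik(y, s, g, alt_c, ref_c, pi, psi, 0.0, lam, phi, theta)
            for pi in grid for psi in grid
        )
        assert ll_fit >= ll_grid - 1e-4

    def test_sign_consistency(self):
        rng = np.random.default_rng(17)
        above = 0
        n_rep = 30
        for _ in range(n_rep):
            y, s, g, al = _simulate_pair(rng, depth=800.0, pi=0.7)
            res = cq.fit_joint_model(y, al, g, s)
            above += res.pi_hat > 0.5
        assert above >= 0.9 * n_rep

    def test_offsets_must_be_positive(self):
        with pytest.raises(ValueError):
            cq.fit_joint_model(np.ones(4), None, np.ones(4), np.zeros(4))


class TestPopulationOnly:
    def test_equals_joint_without_allelic_records(self):
        rng = np.random.default_rng(3)
        y, s, g, _ = _simulate_pair(rng, pi=0.7)
        r1 = cq.fit_joint_model(y, None, g, s)
        r2 = cq.fit_population_only(y, g, s)
        assert r1.pi_hat == pytest.approx(r2.pi_hat, abs=1e-6)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-6)

    def test_joint_beats_population_only_power(self):
        rng = np.random.default_rng(11)
        p_joint, p_pop = [], []
        for _ in range(60):
            y, s, g, al = _simulate_pair(rng, n=10, depth=150.0, pi=0.65)
            p_joint.append(cq.fit_joint_model(y, al, g, s).lrt_p)
            p_pop.append(cq.fit_population_only(y, g, s).lrt_p)
        pow_joint = np.mean(np.array(p_joint) < 0.01)
        pow_pop = np.mean(np.array(p_pop) < 0.01)
        assert pow_joint > pow_pop

    def test_null_calibration_both_modes(self):
        rng = np.random.default_rng(29)
        p_joint, p_pop = [], []
        for _ in range(150):
            y, s, g, al = _simulate_pair(rng, n=10, depth=100.0, pi=0.5)
            p_joint.append(cq.fit_joint_model(y, al, g, s).lrt_p)
            p_pop.append(cq.fit_population_only(y, g, s).lrt_p)
        assert stats.kstest(p_joint, "uniform").pvalue > 0.01
        assert stats.kstest(p_pop, "uniform").pvalue > 0.01


class TestFilterTestable:
    @pytest.fixture()
    def setup(self, cohort):
        genotypes, truth, tensor = cohort
        return genotypes, tensor

    def test_low_depth_peak_excluded(self, setup):
        genotypes, tensor = setup
        ct = tensor.cell_types[0]
        shallow = tensor.totals[ct].copy()
        # force first peak below the >5 mean-read threshold
        shallow[:, 0] = 4
        tensor2 = type(tensor)(
            peaks=tensor.peaks, sample_ids=tensor.sample_ids,
            totals={ct: shallow}, allelic={ct: tensor.allelic[ct]},
            offsets={ct: tensor.offsets[ct]},
        )
        pairs = cq.filter_testable(tensor2, genotypes, ct)
        assert tensor.peaks["peak_id"].iloc[0] not in set(pairs["peak_id"])

    def test_mean_just_below_threshold_excluded(self, setup):
        genotypes, tensor = setup
        ct = tensor.cell_types[0]
        m = tensor.totals[ct].mean(axis=0)
        pairs = cq.filter_testable(tensor, genotypes, ct)
        tested = set(pairs["peak_id"])
        for k, pid in enumerate(tensor.peaks["peak_id"]):
            if m[k] <= 5.0:
                assert pid not in tested

    def test_het_below_two_excluded(self, setup):
        genotypes, tensor = setup
        ct = tensor.cell_types[0]
        het = (genotypes.dosage == 1).sum(axis=0)
        pairs = cq.filter_testable(tensor, genotypes, ct)
        het_of = dict(zip(genotypes.variant_ids, het))
        assert all(het_of[v] >= 2 for v in pairs["variant_id"])

    def test_nearby_peak_variant_included(self):
        """Variant in a peak 9 kb from the tested peak's edge is included."""
        from caqtlkit.types import AllelicCounts, CohortGenotypes, PeakCountTensor

        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1000, 10400],
             "end": [1400, 10800], "peak_id": ["pkA", "pkB"]}
        )
        # variant inside pkB, 9 kb from pkA's right edge
        dosage = np.array([[0], [1], [1], [2], [1]])
        genotypes = CohortGenotypes(
            chrom=np.array(["chr1"]), positions=np.array([10501]),
            ref=np.array(["A"]), alt=np.array(["G"]), dosage=dosage,
            variant_ids=np.array(["v1"]), sample_ids=[f"s{i}" for i in range(5)],
        )
        totals = np.full((5, 2), 50)
        tensor = PeakCountTensor(
            peaks=peaks, sample_ids=genotypes.sample_ids,
            totals={"ct": totals},
            allelic={"ct": AllelicCounts(pd.DataFrame(
                columns=["variant_id", "sample", "ref_count", "alt_count"]))},
            offsets={"ct": np.ones(5)},
        )
        pairs = cq.filter_testable(tensor, genotypes, "ct", window_bp=10_000)
        assert {("pkA", "v1"), ("pkB", "v1")} <= set(
            zip(pairs["peak_id"], pairs["variant_id"])
        )
        far = cq.filter_testable(tensor, genotypes, "ct", window_bp=8_000)
        assert ("pkA", "v1") not in set(zip(far["peak_id"], far["variant_id"]))

    def test_empty_tensor_gives_empty_list(self):
        from caqtlkit.types import PeakCountTensor

        empty = PeakCountTensor(
            peaks=pd.DataFrame(columns=["chrom", "start", "end", "peak_id"]),
            sample_ids=[], totals={}, allelic={}, offsets={},
        )
        cfg = SimConfig(seed=0, n_variants=10, n_peaks=5)
        g = simulate_genotypes(cfg)
        assert len(cq.filter_testable(empty, g, "ct")) == 0


class TestAdjustWithinPeak:
    def _result(self, p, pos, vid="v"):
        return cq.CaQtlResult(
            peak_id="pk", variant_id=vid, position=pos, pi_hat=0.5,
            psi_hat=0.5, delta_hat=0.0, lambda_hat=1, phi_hat=1, theta_hat=1,
            loglik=0, loglik_null=0, lrt_p=p, n_het=3, n_classes=3,
            converged=True,
        )

    def test_single_variant(self):
        out = cq.adjust_within_peak([self._result(0.03, 100)])
        assert out[0].adj_p == pytest.approx(0.03)
        assert out[0].lead

    def test_bonferroni_arithmetic(self):
        rs = [self._result(p, i, f"v{i}") for i, p in enumerate([0.01, 0.5, 0.2, 0.9])]
        out = cq.adjust_within_peak(rs)
        lead = next(r for r in out if r.lead)
        assert lead.adj_p == pytest.approx(0.04)
        assert lead.variant_id == "v0"

    def test_tie_broken_by_position(self):
        rs = [self._result(0.05, 500, "far"), self._result(0.05, 100, "near")]
        out = cq.adjust_within_peak(rs)
        lead = next(r for r in out if r.lead)
        assert lead.variant_id == "near"

    def test_exactly_one_lead(self):
        rs = [self._result(0.2, i, f"v{i}") for i in range(5)]
        out = cq.adjust_within_peak(rs)
        assert sum(r.lead for r in out) == 1

    def test_adj_p_at_least_raw_p(self):
        rs = [self._result(p, i, f"v{i}") for i, p in enumerate([0.3, 0.6, 0.9])]
        for r in cq.adjust_within_peak(rs):
            assert r.adj_p >= r.lrt_p


class TestEmpiricalFdr:
    def test_hand_worked_example(self):
        real = np.array([0.001, 0.01, 0.2, 0.5])
        perms = [np.array([0.15, 0.3, 0.6, 0.9]), np.array([0.05, 0.4, 0.7, 0.8])]
        threshold, sig = cq.empirical_fdr(real, perms, alpha=0.10)
        assert threshold == pytest.approx(0.01)
        assert sig.sum() == 2

    def test_permuted_all_one_everything_significant(self):
        real = np.array([0.2, 0.5, 0.9])
        threshold, sig = cq.empirical_fdr(real, [np.ones(3)], alpha=0.10)
        assert sig.all()

    def test_null_real_rarely_significant(self):
        rng = np.random.default_rng(8)
        fracs = []
        for _ in range(50):
            real = rng.uniform(size=50)
            perms = [rng.uniform(size=50) for _ in range(2)]
            _, sig = cq.empirical_fdr(real, perms, alpha=0.10)
            fracs.append(sig.mean())
        assert np.mean(fracs) < 0.05

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            cq.empirical_fdr(np.array([0.1]), [], alpha=0.1)


class TestBhQvalues:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        ours = cq.bh_qvalues(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


class TestQcFilter:
    def _frame(self, psi, delta):
        return pd.DataFrame(
            {"psi_hat": [psi], "delta_hat": [delta], "converged": [True]}
        )

    def test_low_psi_fails(self):
        assert not cq.qc_filter(self._frame(0.15, 0.0))["qc_pass"].iloc[0]

    def test_high_delta_fails(self):
        assert not cq.qc_filter(self._frame(0.5, 0.12))["qc_pass"].iloc[0]

    def test_clean_fit_passes(self):
        assert cq.qc_filter(self._frame(0.5, 0.01))["qc_pass"].iloc[0]

    def test_boundary_values_pass(self):
        assert cq.qc_filter(self._frame(0.2, 0.1))["qc_pass"].iloc[0]
        assert cq.qc_filter(self._frame(0.8, 0.1))["qc_pass"].iloc[0]


class TestGenotypeClassDiagnostics:
    def test_fisher_arithmetic(self):
        df = pd.DataFrame(
            {
                "n_classes": [3] * 100 + [2] * 200,
                "significant": [True] * 10 + [False] * 90 + [True] * 5 + [False] * 195,
            }
        )
        out = cq.genotype_class_diagnostics(df)
        assert out["odds_ratio"] == pytest.approx((10 * 195) / (90 * 5), rel=1e-9)
        table = np.array([[10, 90], [5, 195]])
        assert out["p_value"] == pytest.approx(
            stats.fisher_exact(table)[1], rel=1e-9
        )

    def test_equal_rates_or_near_one(self):
        df = pd.DataFrame(
            {"n_classes": [3] * 100 + [2] * 100,
             "significant": ([True] * 10 + [False] * 90) * 2}
        )
        assert cq.genotype_class_diagnostics(df)["odds_ratio"] == pytest.approx(1.0)

    def test_no_significant_not_evaluable(self):
        df = pd.DataFrame({"n_classes": [3, 2], "significant": [False, False]})
        out = cq.genotype_class_diagnostics(df)
        assert not out["evaluable"]


class TestMapCaqtl:
    def test_deterministic_and_recovers_planted(self, small_config, cohort):
        genotypes, truth, tensor = cohort
        ct = tensor.cell_types[0]
        df1, info1 = cq.map_caqtl(tensor, genotypes, ct, seed=4)
        df2, _ = cq.map_caqtl(tensor, genotypes, ct, seed=4)
        pd.testing.assert_frame_equal(df1, df2)
        leads = df1[df1["lead"]]
        assert (leads.groupby("peak_id").size() == 1).all()
        sig_peaks = set(leads.loc[leads["significant"], "peak_id"])
        planted = truth.caqtl_peak_ids() & set(leads["peak_id"])
        if sig_peaks:
            hits = len(sig_peaks & planted) / len(sig_peaks)
            assert hits > 0.5
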