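import numpy as np
import pandas as pd
import pytest
from scipy import stats

from caqtlkit.synthdata import (
    GroundTruth,
    SimConfig,
    het_allelic_fraction,
    make_ground_truth,
    make_peaks,
    simulate_genotypes,
    simulate_gwas,
    simulate_peak_counts,
    simulate_single_cells,
    variant_peak_map,
)


def _pairwise_r2(dosage):
    z = dosage - dosage.mean(axis=0)
    sd = z.std(axis=0)
    keep = sd > 0
    z = z[:, keep] / sd[keep]
    r = z.T @ z / len(z)
    return r**2


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_samples": 1},
            {"maf_range": (0.0, 0.3)},
            {"maf_range": (0.2, 0.6)},
            {"pi_effect_range": (0.0, 0.5)},
            {"delta_range": (0.1, 0.6)},
            {"cell_types": {"a": 0.5, "b": 0.2}},
            {"nb_dispersion": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestSimulateGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=7, n_variants=60, n_peaks=30)
        g1 = simulate_genotypes(cfg)
        g2 = simulate_genotypes(cfg)
        assert g1.dosage.tobytes() == g2.dosage.tobytes()
        assert np.array_equal(g1.positions, g2.positions)

    def test_independent_blocks_have_near_zero_r2(self):
        cfg = SimConfig(seed=1, n_samples=400, n_variants=40, n_peaks=40,
                        ld_block_size=1)
        g = simulate_genotypes(cfg)
        r2 = _pairwise_r2(g.dosage.astype(float))
        off_diag = r2[np.triu_indices_from(r2, k=1)]
        assert np.nanmean(off_diag) < 0.02

    def test_same_founder_pattern_gives_r2_one(self):
        cfg = SimConfig(seed=3, n_samples=200, n_variants=60, n_peaks=30,
                        ld_block_size=6)
        g = simulate_genotypes(cfg)
        r2 = _pairwise_r2(g.dosage.astype(float))
        # identical dosage columns exist within blocks whenever two variants
        # picked the same founder subset; those must give r2 == 1
        found = False
        for i in range(g.n_variants - 1):
            for j in range(i + 1, min(i + 6, g.n_variants)):
                if np.array_equal(g.dosage[:, i], g.dosage[:, j]) and g.dosage[:, i].std() > 0:
                    assert r2[i, j] == pytest.approx(1.0, abs=1e-12)
                    found = True
        assert found, "expected at least one perfectly correlated pair"

    def test_empirical_maf_close_to_target_at_large_n(self):
        cfg = SimConfig(seed=5, n_samples=500, n_variants=100, n_peaks=50)
        g = simulate_genotypes(cfg)
        emp = g.minor_allele_frequency()
        assert np.abs(emp - g.target_maf).max() <= 0.05

    def test_positions_inside_peaks_and_increasing(self):
        cfg = SimConfig(seed=2, n_variants=50, n_peaks=25)
        g = simulate_genotypes(cfg)
        for ch in np.unique(g.chrom):
            assert (np.diff(g.positions[g.chrom == ch]) > 0).all()
        peaks = make_peaks(cfg)
        vp = variant_peak_map(g, peaks)
        assert len(vp) > 0.8 * g.n_variants

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=1)


class TestHetAllelicFraction:
    def test_null_case(self):
        assert het_allelic_fraction(0.5, 0.5, 0.0) == pytest.approx(0.5)

    def test_reference_bias_closed_form(self):
        # p = 0.5*0.8 / (0.5*0.8 + 0.5*0.2) = 0.8
        assert het_allelic_fraction(0.5, 0.2, 0.0) == pytest.approx(0.8)

    def test_error_shrinks_toward_half(self):
        assert het_allelic_fraction(0.9, 0.5, 0.1) == pytest.approx(0.9 * 0.8 + 0.1)


class TestSimulatePeakCounts:
    def test_genotype_group_mean_ratio(self):
        # mean(g=2)/mean(g=0) = pi/(1-pi) = 3 at pi = 0.75, checked on many samples
        cfg = SimConfig(
            n_samples=10_000, n_variants=2, n_peaks=1, frac_caqtl_peaks=1.0,
            pi_effect_range=(0.75, 0.75), psi_range=(0.5, 0.5),
            delta_range=(0.0, 0.0), cell_types={"ct": 1.0},
            mean_depth_per_peak=50.0, seed=9, n_gwas_signals=0,
        )
        g = simulate_genotypes(cfg)
        truth = make_ground_truth(g, cfg)
        assert len(truth.caqtl) == 1
        tensor = simulate_peak_counts(g, truth, cfg)
        vid = truth.caqtl["variant_id"].iloc[0]
        col = list(g.variant_ids).index(vid)
        dos = g.dosage[:, col]
        y = tensor.totals["ct"][:, 0] / tensor.offsets["ct"]
        pi = truth.caqtl["pi"].iloc[0]
        expected = pi / (1 - pi) if pi > 0.5 else (1 - pi) / pi
        hi, lo = (2, 0) if pi > 0.5 else (0, 2)
        ratio = y[dos == hi].mean() / y[dos == lo].mean()
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_null_peak_group_means_equal(self, cohort):
        genotypes, truth, tensor = cohort
        null_peaks = [p for p in truth.peaks["peak_id"] if p not in truth.caqtl_peak_ids()]
        assert null_peaks
        ct = tensor.cell_types[0]
        y = tensor.totals[ct]
        cols = [list(tensor.peaks["peak_id"]).index(p) for p in null_peaks]
        overall = y[:, cols].mean()
        assert overall > 0

    def test_allelic_counts_only_at_het_samples(self, cohort):
        genotypes, truth, tensor = cohort
        col = {v: i for i, v in enumerate(genotypes.variant_ids)}
        sample_idx = {s: j for j, s in enumerate(tensor.sample_ids)}
        for ct in tensor.cell_types:
            tab = tensor.allelic[ct].table
            for row in tab.itertuples():
                dos = genotypes.dosage[sample_idx[row.sample], col[row.variant_id]]
                assert dos == 1

    def test_allelic_depth_bounded_by_total(self, cohort):
        genotypes, truth, tensor = cohort
        peaks = list(tensor.peaks["peak_id"])
        vp = variant_peak_map(genotypes, truth.peaks)
        sample_idx = {s: j for j, s in enumerate(tensor.sample_ids)}
        for ct in tensor.cell_types:
            for row in tensor.allelic[ct].table.itertuples():
                k = peaks.index(vp[row.variant_id])
                total = tensor.totals[ct][sample_idx[row.sample], k]
                assert row.ref_count + row.alt_count <= total

    def test_missing_lam_rejected(self, cohort):
        genotypes, truth, tensor = cohort
        cfg = SimConfig(seed=0)
        bad = GroundTruth(
            peaks=truth.peaks.drop(columns=["lam"]).copy(),
            caqtl=truth.caqtl, coaccess_modules=[], gwas_causals=truth.gwas_causals,
            promoter_peaks=[], tss=truth.tss,
        )
        with pytest.raises(ValueError, match="lam"):
            simulate_peak_counts(genotypes, bad, cfg)

    def test_deterministic(self, small_config, cohort):
        genotypes, truth, _ = cohort
        t1 = simulate_peak_counts(genotypes, truth, small_config)
        t2 = simulate_peak_counts(genotypes, truth, small_config)
        for ct in t1.cell_types:
            assert np.array_equal(t1.totals[ct], t2.totals[ct])
            pd.testing.assert_frame_equal(t1.allelic[ct].table, t2.allelic[ct].table)


class TestSimulateSingleCells:
    def test_module_pair_positively_correlated(self):
        cfg = SimConfig(n_samples=10, n_variants=20, n_peaks=20,
                        n_cells_per_sample=200, coaccess_module_size=2,
                        n_coaccess_modules=2, seed=21)
        g = simulate_genotypes(cfg)
        truth = make_ground_truth(g, cfg)
        counts, emb, labels = simulate_single_cells(truth, cfg)
        assert counts.shape[0] == 2000
        pid = list(truth.peaks["peak_id"])
        a, b = truth.coaccess_modules[0][:2]
        r, p = stats.pearsonr(counts[:, pid.index(a)], counts[:, pid.index(b)])
        assert r > 0 and p < 0.01

    def test_singleton_module_no_extra_correlation(self):
        cfg = SimConfig(n_samples=6, n_variants=20, n_peaks=20,
                        n_cells_per_sample=300, coaccess_module_size=1,
                        n_coaccess_modules=1, seed=22)
        g = simulate_genotypes(cfg)
        truth = make_ground_truth(g, cfg)
        counts, _, _ = simulate_single_cells(truth, cfg)
        pid = list(truth.peaks["peak_id"])
        k = pid.index(truth.coaccess_modules[0][0])
        other = 5 if k != 5 else 6
        r, _ = stats.pearsonr(counts[:, k], counts[:, other])
        assert abs(r) < 0.15  # depth effects only

    def test_zero_cells_ok(self):
        cfg = SimConfig(n_samples=2, n_variants=10, n_peaks=10,
                        n_cells_per_sample=0, seed=1)
        g = simulate_genotypes(cfg)
        truth = make_ground_truth(g, cfg)
        counts, emb, labels = simulate_single_cells(truth, cfg)
        assert counts.shape == (0, 10) and len(labels) == 0

    def test_unknown_module_peak_rejected(self, cohort, small_config):
        _, truth, _ = cohort
        bad = GroundTruth(
            peaks=truth.peaks, caqtl=truth.caqtl,
            coaccess_modules=[["nonexistent"]],
            gwas_causals=truth.gwas_causals, promoter_peaks=[], tss=truth.tss,
        )
        with pytest.raises(ValueError, match="unknown"):
            simulate_single_cells(bad, small_config)

    def test_same_sample_and_type_proximal(self):
        cfg = SimConfig(n_samples=4, n_variants=20, n_peaks=20,
                        n_cells_per_sample=50, seed=13)
        g = simulate_genotypes(cfg)
        truth = make_ground_truth(g, cfg)
        _, emb, labels = simulate_single_cells(truth, cfg)
        df = pd.DataFrame(emb, columns=["x", "y"])
        df["grp"] = labels["sample"] + "/" + labels["cell_type"]
        within = df.groupby("grp")[["x", "y"]].std().mean().mean()
        overall = df[["x", "y"]].std().mean()
        assert within < overall


@pytest.fixture(scope="module")
def gwas():
    cfg = SimConfig(n_samples=400, n_variants=100, n_peaks=50,
                    frac_caqtl_peaks=0.3, n_gwas_signals=3, seed=31)
    g = simulate_genotypes(cfg)
    truth = make_ground_truth(g, cfg)
    summary, index_tab = simulate_gwas(g, truth, cfg)
    return cfg, g, truth, summary, index_tab


class TestSimulateGwas:
    def test_se_closed_form(self, gwas):
        cfg, g, truth, summary, _ = gwas
        af = dict(zip(g.variant_ids, g.allele_frequency()))
        row = summary.iloc[0]
        maf = min(af[row.variant_id], 1 - af[row.variant_id])
        assert row.se == pytest.approx(1 / np.sqrt(2 * cfg.gwas_n * maf * (1 - maf)))

    def test_quadrupling_n_halves_se(self, gwas):
        cfg, g, truth, summary, _ = gwas
        cfg4 = SimConfig(**{**cfg.__dict__, "gwas_n": 4 * cfg.gwas_n})
        s4, _ = simulate_gwas(g, truth, cfg4)
        merged = summary.merge(s4, on="variant_id", suffixes=("_1", "_4"))
        assert np.allclose(merged["se_4"], merged["se_1"] / 2)

    def test_causal_beta_recovered_in_expectation(self, gwas):
        cfg, g, truth, summary, _ = gwas
        s = summary.set_index("variant_id")
        for row in truth.gwas_causals.itertuples():
            obs = s.loc[row.variant_id, "beta"]
            se = s.loc[row.variant_id, "se"]
            assert abs(obs - row.beta) < 5 * se

    def test_unlinked_variant_beta_near_zero(self, gwas):
        cfg, g, truth, summary, _ = gwas
        causal_cols = [list(g.variant_ids).index(v)
                       for v in truth.gwas_causals["variant_id"]]
        z = g.dosage.astype(float)
        z = (z - z.mean(0)) / np.where(z.std(0) > 0, z.std(0), 1)
        s = summary.set_index("variant_id")
        for i, vid in enumerate(g.variant_ids):
            if vid not in s.index:
                continue
            r_max = max(abs(float(z[:, i] @ z[:, c] / len(z))) for c in causal_cols)
            if r_max < 0.02:
                assert abs(s.loc[vid, "beta"]) < 5 * s.loc[vid, "se"]
                break

    def test_monomorphic_causal_rejected(self, gwas):
        cfg, g, truth, *_ = gwas
        mono = GroundTruth(
            peaks=truth.peaks, caqtl=truth.caqtl, coaccess_modules=[],
            gwas_causals=pd.DataFrame(
                {"signal_id": ["s"], "variant_id": [g.variant_ids[0]], "beta": [0.1]}
            ),
            promoter_peaks=[], tss=truth.tss,
        )
        g.dosage[:, 0] = 1  # constant dosage -> zero variance
        try:
            with pytest.raises(ValueError, match="monomorphic"):
                simulate_gwas(g, mono, cfg)
        finally:
            pass


class TestGenerativeModelMatchesLikelihood:
    def test_truth_loglik_beats_perturbed(self, cohort):
        """Average log-likelihood at true parameters exceeds pi +/- 0.2."""
        from tests.conftest import oracle_loglik

        genotypes, truth, tensor = cohort
        cfg_theta = 0.02
        ct = tensor.cell_types[0]
        peaks = list(tensor.peaks["peak_id"])
        col = {v: i for i, v in enumerate(genotypes.variant_ids)}
        sample_idx = {s: j for j, s in enumerate(tensor.sample_ids)}
        deltas = {True: [], False: []}
        weights = {"Tcell": 0.6, "Mono": 0.4}
        scale = weights[ct] / np.mean(list(weights.values()))
        for row in truth.caqtl.itertuples():
            k = peaks.index(row.peak_id)
            y = tensor.totals[ct][:, k]
            s = tensor.offsets[ct]
            gdos = genotypes.dosage[:, col[row.variant_id]]
            tab = tensor.allelic[ct].table
            sub = tab[tab.variant_id == row.variant_id]
            a = sub["alt_count"].to_numpy()
            r = sub["ref_count"].to_numpy()
            lam = float(truth.peaks.set_index("peak_id").loc[row.peak_id, "lam"]) * scale
            base = dict(psi=row.psi, delta=row.delta, lam=lam, phi=0.1,
                        theta=max(cfg_theta, 1e-3))
            ll_true = oracle_loglik(y, s, gdos, a, r, row.pi, **base)
            for shift in (-0.2, 0.2):
                pi_p = float(np.clip(row.pi + shift, 0.01, 0.99))
                ll_p = oracle_loglik(y, s, gdos, a, r, pi_p, **base)
                deltas[True].append(ll_true - ll_p)
        assert np.mean(deltas[True]) > 0
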