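"""Synthetic GWAS generator: genotype structure, trait model, scan
calibration, and the paired-study construction."""

import numpy as np
import pytest
from scipy import stats as sps
import statsmodels.api as sm

import locusfdr as lf
from locusfdr.simulate import (LinearScan, assign_effects, association_scan,
                               inverse_normal_transform, make_paired_studies,
                               simulate_genotypes, simulate_phenotype,
                               simulate_phenotypes_multi, truth_noise_scale)


def null_config(n=800, M=400, n_blocks=40, **kw):
    base = dict(n_test=n, n_truth=n, M=M, n_blocks=n_blocks, n_causal=0,
                hsq=0.0, reps=2)
    base.update(kw)
    return lf.SimStudyConfig(**base)


class TestGenotypes:
    def test_dosage_values_and_frequency(self):
        cfg = null_config(n=2000, M=100, n_blocks=10)
        G = simulate_genotypes(cfg, 0)
        vals = np.unique(G.dosages)
        assert set(vals).issubset({0.0, 1.0, 2.0})
        np.testing.assert_allclose(G.dosages.mean(axis=0) / 2, G.mafs,
                                   atol=0.05)

    def test_zero_rho_gives_independent_variants(self):
        cfg = null_config(n=4000, M=40, n_blocks=4, rho=0.0)
        G = simulate_genotypes(cfg, 1)
        ld = G.to_ldsource()
        r2 = [ld.r2(G.ids[i], G.ids[i + 1]) for i in range(0, 39)]
        assert np.max(r2) < 0.01

    def test_high_rho_adjacent_ld(self):
        # 100 independent blocks of 2 at rho=0.95: adjacent dosage r^2
        # exceeds 0.5 in at least 95% of them
        cfg = null_config(n=5000, M=200, n_blocks=100, rho=0.95,
                          maf_range=(0.3, 0.3001))
        G = simulate_genotypes(cfg, 7)
        ld = G.to_ldsource()
        r2 = np.array([ld.r2(G.ids[2 * b], G.ids[2 * b + 1])
                       for b in range(100)])
        assert np.mean(r2 > 0.5) >= 0.95

    def test_ld_decays_with_lag(self):
        cfg = null_config(n=5000, M=30, n_blocks=1, rho=0.9)
        G = simulate_genotypes(cfg, 3)
        ld = G.to_ldsource()
        lags = [1, 5, 15, 29]
        r2 = [ld.r2(G.ids[0], G.ids[k]) for k in lags]
        assert all(a > b for a, b in zip(r2, r2[1:]))

    def test_blocks_beyond_clump_window(self):
        cfg = null_config(M=40, n_blocks=4)
        G = simulate_genotypes(cfg, 0)
        starts = [G.pos[s] for s, _, _ in G.blocks]
        ends = [G.pos[e - 1] for _, e, _ in G.blocks]
        assert all(s2 - e1 > 1_000_000 for e1, s2 in zip(ends, starts[1:]))
        assert all(e - s < 200_000 for s, e in zip(starts, ends))

    def test_deterministic(self):
        cfg = null_config()
        a = simulate_genotypes(cfg, 5)
        b = simulate_genotypes(cfg, 5)
        np.testing.assert_array_equal(a.dosages, b.dosages)


class TestTruthModel:
    def test_null_model(self):
        cfg = null_config()
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        assert tm.hsq["trait1"] == 0.0
        assert tm.causal_ids["trait1"] == []

    def test_explained_variance_formula_explicit_effects(self):
        cfg = lf.SimStudyConfig(n_test=20_000, n_truth=20_000, M=50,
                                n_blocks=5, n_causal=5, maf_range=(0.5, 0.5),
                                effect_law=[0.1, -0.1, 0.2, 0.05, 0.15],
                                reps=2)
        G = simulate_genotypes(cfg, 2)
        tm = assign_effects(G, cfg, 3)
        # at MAF 0.5 each dosage variance is ~2*0.5*0.5 = 0.5
        expect = 0.5 * sum(t**2 for t in [0.1, 0.1, 0.2, 0.05, 0.15])
        assert tm.hsq["trait1"] == pytest.approx(expect, rel=0.1)

    def test_calibrated_halfnormal_hits_target_hsq(self):
        cfg = lf.SimStudyConfig(n_test=5000, n_truth=5000, M=500, n_blocks=50,
                                n_causal=20, hsq=0.3, reps=2)
        G = simulate_genotypes(cfg, 4)
        tm = assign_effects(G, cfg, 5)
        trait = tm.trait_names[0]
        idx = [int(np.flatnonzero(G.ids == v)[0])
               for v in tm.causal_ids[trait]]
        gvar = G.dosages[:, idx].astype(float).var(axis=0)
        th = np.array([tm.theta[trait][v] for v in tm.causal_ids[trait]])
        assert float(np.sum(gvar * th**2)) == pytest.approx(0.3, rel=1e-6)

    def test_one_causal_per_block(self):
        cfg = lf.SimStudyConfig(n_test=500, n_truth=500, M=200, n_blocks=20,
                                n_causal=12, hsq=0.2, reps=2)
        G = simulate_genotypes(cfg, 6)
        tm = assign_effects(G, cfg, 7)
        blocks = [G.block_of(v) for v in tm.causal_ids["trait1"]]
        assert len(set(blocks)) == 12

    def test_effect_recovery_within_3se(self):
        # regression of the trait on a causal dosage recovers theta
        cfg = lf.SimStudyConfig(n_test=2000, n_truth=2000, M=200, n_blocks=20,
                                n_causal=5, hsq=0.2, reps=2)
        G = simulate_genotypes(cfg, 3)
        tm = assign_effects(G, cfg, 4)
        trait = tm.trait_names[0]
        ok = 0
        for seed in range(200):
            y = simulate_phenotype(G, tm, 2000 + seed)
            vid = tm.causal_ids[trait][seed % 5]
            j = int(np.flatnonzero(G.ids == vid)[0])
            res = sps.linregress(G.dosages[:, j].astype(float), y)
            ok += abs(res.slope - tm.theta[trait][vid]) <= 3 * res.stderr
        assert ok >= 190  # ~99.7% nominal coverage, 200 trials

    def test_excess_hsq_rejected(self):
        cfg = lf.SimStudyConfig(n_test=500, n_truth=500, M=50, n_blocks=5,
                                n_causal=2, maf_range=(0.5, 0.5),
                                effect_law=[2.0, 2.0], reps=2)
        G = simulate_genotypes(cfg, 1)
        with pytest.raises(ValueError):
            assign_effects(G, cfg, 2)


class TestPhenotype:
    def test_unit_variance(self):
        cfg = lf.SimStudyConfig(n_test=20_000, n_truth=20_000, M=100,
                                n_blocks=10, n_causal=5, hsq=0.25, reps=2)
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        y = simulate_phenotype(G, tm, 2)
        assert np.var(y) == pytest.approx(1.0, abs=0.03)

    def test_null_trait_is_standard_normal(self):
        cfg = null_config(n=20_000, M=10, n_blocks=1)
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        y = simulate_phenotype(G, tm, 2)
        assert np.mean(y) == pytest.approx(0.0, abs=0.03)
        assert np.var(y) == pytest.approx(1.0, abs=0.03)

    def test_same_seed_identical(self):
        cfg = null_config()
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        np.testing.assert_array_equal(simulate_phenotype(G, tm, 9),
                                      simulate_phenotype(G, tm, 9))

    def test_inverse_normal_transform(self):
        rng = np.random.default_rng(0)
        y = rng.exponential(size=5001)
        t = inverse_normal_transform(y)
        # rank-preserving and marginally standard normal
        assert np.array_equal(np.argsort(y), np.argsort(t))
        assert np.mean(t) == pytest.approx(0.0, abs=1e-6)
        assert np.var(t) == pytest.approx(1.0, abs=0.01)

    def test_multi_trait_residual_correlation_recovered(self):
        cfg = lf.SimStudyConfig(n_test=20_000, n_truth=20_000, M=100,
                                n_blocks=10, n_causal=0, hsq=0.0, L=2,
                                sigma=[[1.0, 0.5], [0.5, 1.0]], reps=2)
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        Y = simulate_phenotypes_multi(G, tm, 2)
        assert np.corrcoef(Y.T)[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_multi_trait_single_column_consistent(self):
        cfg = lf.SimStudyConfig(n_test=2000, n_truth=2000, M=100, n_blocks=10,
                                n_causal=3, hsq=0.2, L=1, reps=2)
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        Y = simulate_phenotypes_multi(G, tm, 2)
        assert Y.shape == (2000, 1)
        assert np.var(Y[:, 0]) == pytest.approx(1.0, abs=0.05)

    def test_null_cross_trait_z_uncorrelated(self):
        cfg = lf.SimStudyConfig(n_test=3000, n_truth=3000, M=600, n_blocks=60,
                                n_causal=0, hsq=0.0, L=2,
                                sigma=[[1.0, 0.0], [0.0, 1.0]], reps=2)
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        Y = simulate_phenotypes_multi(G, tm, 2)
        z = np.column_stack([association_scan(G, Y[:, l]).table["Z"]
                             for l in range(2)])
        assert abs(np.corrcoef(z.T)[0, 1]) < 3 / np.sqrt(600)


class TestScan:
    def test_matches_statsmodels_ols(self):
        cfg = null_config(n=500, M=50, n_blocks=5)
        G = simulate_genotypes(cfg, 0)
        tm = assign_effects(G, cfg, 1)
        y = simulate_phenotype(G, tm, 2)
        st = association_scan(G, y)
        t = st.table.set_index("SNP")
        for j in (0, 17, 49):
            X = sm.add_constant(G.dosages[:, j].astype(float))
            fit = sm.OLS(y, X).fit()
            row = t.loc[G.ids[j]]
            assert row["BETA"] == pytest.approx(fit.params[1], rel=1e-4)
            assert row["SE"] == pytest.approx(fit.bse[1], rel=1e-4)
            assert row["P"] == pytest.approx(fit.pvalues[1], rel=1e-3)

    def test_perfect_signal(self):
        cfg = null_config(n=2000, M=20, n_blocks=2)
        G = simulate_genotypes(cfg, 1)
        y = 0.1 * G.dosages[:, 3].astype(float)
        st = association_scan(G, y)
        assert st.table.set_index("SNP").loc[G.ids[3], "P"] <= 1e-290

    def test_z_equals_beta_over_se(self):
        cfg = null_config()
        G = simulate_genotypes(cfg, 2)
        tm = assign_effects(G, cfg, 1)
        st = association_scan(G, simulate_phenotype(G, tm, 3))
        np.testing.assert_allclose(st.table["Z"],
                                   st.table["BETA"] / st.table["SE"],
                                   rtol=1e-10)

    def test_null_rejection_rate_and_lambda(self):
        cfg = null_config(n=1000, M=5000, n_blocks=50)
        G = simulate_genotypes(cfg, 4)
        tm = assign_effects(G, cfg, 1)
        engine = LinearScan(G)
        fracs, lams = [], []
        for seed in range(50):
            st = engine.scan(simulate_phenotype(G, tm, 100 + seed))
            fracs.append(float((st.table["P"] < 0.05).mean()))
            lams.append(lf.lambda_gc(st))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.05) <= 3 * se + 1e-4
        assert 0.95 <= np.mean(lams) <= 1.05

    def test_null_lead_pvalues_pass_ks_uniformity(self):
        # KS requires independent observations: use one variant per block
        # (blocks are independent by construction)
        cfg = null_config(n=800, M=400, n_blocks=80)
        G = simulate_genotypes(cfg, 5)
        tm = assign_effects(G, cfg, 1)
        engine = LinearScan(G)
        lead_cols = [G.ids[s] for s, _, _ in G.blocks]
        fails = 0
        for seed in range(100):
            st = engine.scan(simulate_phenotype(G, tm, 500 + seed))
            p = st.table.set_index("SNP").loc[lead_cols, "P"]
            fails += sps.kstest(p, "uniform").pvalue < 0.01
        assert fails <= 5

    def test_constant_column_skipped(self, make_stats):
        rng = np.random.default_rng(0)
        dos = np.column_stack([np.full(100, 1.0),
                               rng.binomial(2, 0.4, 100)]).astype(np.float32)
        G = lf.GenotypeMatrix(dos, np.array(["c", "v"], dtype=object),
                              np.array(["1", "1"], dtype=object),
                              np.array([100, 200]), np.array([0.5, 0.4]),
                              [(0, 2, 0.0)])
        st = association_scan(G, rng.standard_normal(100))
        assert list(st.table["SNP"]) == ["v"]


class TestPairedStudies:
    def test_deterministic(self):
        cfg = lf.SimStudyConfig(n_test=500, n_truth=2500, M=100, n_blocks=10,
                                n_causal=3, hsq=0.3, reps=2)
        a = make_paired_studies(cfg, 13)
        b = make_paired_studies(cfg, 13)
        np.testing.assert_array_equal(a.test.table["P"], b.test.table["P"])
        np.testing.assert_array_equal(a.truth_stats.table["P"],
                                      b.truth_stats.table["P"])

    def test_truth_powered_beyond_test(self):
        # with 10x the sample size, truth detects a superset of test
        # detections at 5e-8 in nearly every seed
        cfg = lf.SimStudyConfig(n_test=2000, n_truth=20_000, M=300,
                                n_blocks=30, n_causal=6, hsq=0.35, reps=2)
        good = 0
        for seed in range(20):
            pair = make_paired_studies(cfg, seed)
            t = pair.test.table
            u = pair.truth_stats.table
            test_hits = set(t.loc[t["P"] < 5e-8, "SNP"])
            truth_hits = set(u.loc[u["P"] < 5e-8, "SNP"])
            good += test_hits <= truth_hits
        assert good >= 18

    def test_truth_n_reported(self):
        cfg = lf.SimStudyConfig(n_test=500, n_truth=5000, M=50, n_blocks=5,
                                n_causal=2, hsq=0.2, reps=2)
        pair = make_paired_studies(cfg, 1)
        assert (pair.truth_stats.table["N"] == 5000).all()
        assert (pair.test.table["N"] == 500).all()
        assert truth_noise_scale(cfg) == pytest.approx(np.sqrt(0.1))

    def test_genotyped_truth_mode(self):
        cfg = lf.SimStudyConfig(n_test=400, n_truth=1200, M=50, n_blocks=5,
                                n_causal=2, hsq=0.25, truth_mode="genotyped",
                                reps=2)
        pair = make_paired_studies(cfg, 3)
        assert pair.genotypes.n == 1200
        assert (pair.truth_stats.table["N"] == 1200).all()
        assert (pair.test.table["N"] == 400).all()
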