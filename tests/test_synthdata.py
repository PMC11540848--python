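"""Generator contracts: HWE, LD structure, trait architecture, GWAS scenarios."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xqtl.synthdata import (
    SimConfig,
    simulate_genotypes,
    simulate_gwas,
    simulate_psm_table,
    simulate_traits,
)
from xqtl.tmt_quant import make_impurity, quantify


class TestGenotypes:
    def test_dosage_bounds_and_polymorphism(self, small_geno):
        assert small_geno.dosages.min() >= 0 and small_geno.dosages.max() <= 2
        maf = small_geno.empirical_maf()
        assert (maf > 0).all() and (maf <= 0.5).all()
        # no constant columns
        assert (small_geno.dosages.std(axis=0) > 0).all()

    def test_refuses_tiny_cohort(self):
        with pytest.raises(ValueError, match="n_samples"):
            simulate_genotypes(SimConfig(n_samples=29))

    def test_zero_ld_gives_independent_blocks(self):
        cfg = SimConfig(n_samples=2000, n_variants=60, n_blocks=3, ld_rho=0.0, seed=2)
        g = simulate_genotypes(cfg)
        blocks = g.variants["block"].to_numpy()
        offdiag = []
        for b in range(3):
            idx = np.flatnonzero(blocks == b)
            r = np.corrcoef(g.dosages[:, idx], rowvar=False)
            offdiag.append(np.abs(r[np.triu_indices_from(r, k=1)]).mean())
        assert np.mean(offdiag) < 0.1

    def test_forced_half_frequency(self):
        cfg = SimConfig(n_samples=2000, n_variants=40, n_blocks=2, maf_range=(0.5, 0.5), seed=3)
        g = simulate_genotypes(cfg)
        # empirical MAF within a generous binomial CI of 0.5 (4 sd of phat)
        sd = np.sqrt(0.5 * 0.5 / (2 * 2000))
        assert (np.abs(g.empirical_maf() - 0.5) < 4 * sd + 1e-12).all()

    def test_lag1_dosage_correlation_matches_bruteforce_oracle(self):
        """Lag-1 dosage correlation agrees with a direct large-n haplotype
        simulation of the same thresholded AR(1) model."""
        rho, freq, n = 0.8, 0.3, 5000
        cfg = SimConfig(n_samples=n, n_variants=10, n_blocks=1, ld_rho=rho,
                        maf_range=(freq, freq), seed=4)
        g = simulate_genotypes(cfg)
        r_emp = np.mean([
            np.corrcoef(g.dosages[:, j], g.dosages[:, j + 1])[0, 1] for j in range(9)
        ])

        # independent brute-force oracle at 10x sample size: two latent
        # normals with correlation rho, thresholded at Phi^-1(freq)
        rng = np.random.default_rng(12345)
        N = 10 * n
        z1 = rng.standard_normal((2, N))
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal((2, N))
        thr = stats.norm.ppf(freq)
        d1 = (z1 < thr).sum(axis=0)
        d2 = (z2 < thr).sum(axis=0)
        r_oracle = np.corrcoef(d1, d2)[0, 1]
        assert abs(r_emp - r_oracle) < 0.05

    def test_hwe_holds(self):
        cfg = SimConfig(n_samples=2000, n_variants=200, n_blocks=10, seed=5)
        g = simulate_genotypes(cfg)
        n_fail = 0
        for j in range(g.n_variants):
            counts = np.bincount(g.dosages[:, j].astype(int), minlength=3)
            p_hat = (counts[1] + 2 * counts[2]) / (2 * counts.sum())
            exp = counts.sum() * np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2])
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.nansum((counts - exp) ** 2 / np.where(exp > 0, exp, np.nan))
            if stats.chi2.sf(chi2, df=1) < 0.001:
                n_fail += 1
        assert n_fail / g.n_variants <= 0.005

    def test_fixed_seed_reproducible(self, small_cfg):
        a = simulate_genotypes(small_cfg)
        b = simulate_genotypes(small_cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_shared_panel_frequencies(self, small_cfg, small_geno):
        g2 = simulate_genotypes(
            small_cfg, rng=np.random.default_rng(99), freqs=small_geno.variants["freq_pop"].to_numpy()
        )
        np.testing.assert_allclose(
            g2.variants["freq_pop"], small_geno.variants["freq_pop"], rtol=0, atol=0
        )


class TestTraits:
    def test_truth_table_exhaustive(self, small_cfg, small_traits):
        mrna, prot, truth = small_traits
        assert len(truth) == small_cfg.n_blocks
        assert truth["gene_id"].is_unique
        assert set(truth["class"]) <= {"dependent", "independent"}
        assert mrna.n_traits == prot.n_traits == len(truth)

    def test_full_mediation_fraction(self, small_geno):
        cfg = SimConfig(n_samples=200, n_variants=100, n_blocks=5, mediation_fraction=1.0, seed=11)
        _, _, truth = simulate_traits(small_geno, cfg)
        assert (truth["class"] == "dependent").all()

    def test_cis_slope_recovery_vs_normal_equations_oracle(self):
        """OLS slope of mRNA on causal dosage recovers beta=0.5 within 3 SE,
        checked against a hand-rolled normal-equations fit."""
        cfg = SimConfig(n_samples=500, n_variants=40, n_blocks=4, cis_effect_beta=0.5,
                        noise_sd=1.0, n_hidden_factors=0, seed=6, mediation_fraction=1.0)
        g = simulate_genotypes(cfg)
        mrna, _, truth = simulate_traits(g, cfg)
        gs = g.standardized()
        for i, row in truth.iterrows():
            x = gs[:, int(row["causal_index"])]
            y = mrna.values[i]
            # normal equations with intercept
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            se = np.sqrt(resid @ resid / (len(y) - 2) / (x @ x - len(x) * x.mean() ** 2))
            assert abs(beta[1] - 0.5) < 3 * se

    def test_causal_variant_within_cis_window(self, small_geno, small_traits):
        mrna, _, truth = small_traits
        meta = mrna.traits.set_index("gene_id")
        variants = small_geno.variants.set_index("id")
        for _, row in truth.iterrows():
            v = variants.loc[row["causal_variant"]]
            assert abs(int(v["pos"]) - int(meta.loc[row["gene_id"], "tss"])) <= 1_000_000


class TestGwas:
    def test_null_scenario_calibrated(self, small_cfg, small_geno, small_traits):
        _, _, truth = small_traits
        fracs = [
            (simulate_gwas(small_geno, truth, "null", small_cfg, n_gwas=500,
                           rng=np.random.default_rng(800 + k)).records["p"] < 0.05).mean()
            for k in range(10)
        ]
        assert 0.03 < np.mean(fracs) < 0.07

    def test_invalid_scenario_rejected(self, small_cfg, small_geno, small_traits):
        with pytest.raises(ValueError, match="scenario"):
            simulate_gwas(small_geno, small_traits[2], "reverse-causal", small_cfg)

    def test_summary_invariants(self, small_cfg, small_geno, small_traits):
        gw = simulate_gwas(small_geno, small_traits[2], "causal", small_cfg,
                           rng=np.random.default_rng(9))
        r = gw.records
        assert (r["se"] > 0).all()
        np.testing.assert_allclose(r["z"], r["b"] / r["se"], atol=1e-8)


class TestPsmGenerator:
    def test_channel_count_29_batches(self):
        psm, truth, cmap = simulate_psm_table(3, 29, seed=1, missing_fraction=0.0)
        labels = {(b, c) for b, labs in psm.channel_labels.items() for c in range(len(labs))}
        assert len(labels) == 29 * 11
        assert truth.shape[1] == 29 * 10  # distinct sample channels

    def test_zero_noise_identity_roundtrip(self):
        """With identity impurity and no noise, filter + summarize + bridge
        reproduce the true IS-centered relative abundances exactly.

        Channel normalization is exercised separately (it removes channel
        loadings, which are absent here, under the assumption that sample
        effects median out — only approximately true at a handful of
        proteins)."""
        from xqtl.tmt_quant import bridge_batches, filter_psms, summarize_proteins

        psm, truth, _ = simulate_psm_table(
            8, 2, impurity=None, seed=2, noise_sd=0.0, channel_loading_sd=0.0,
            low_intensity_fraction=0.0, missing_fraction=0.0,
        )
        step = filter_psms(psm)
        per_batch = {b: summarize_proteins(step, batch=b) for b in step.batches()}
        mat = bridge_batches(per_batch, step.channel_labels)
        shared = mat.index.intersection(truth.index)
        rec = mat.loc[shared, truth.columns].to_numpy()
        tru = truth.loc[shared].to_numpy()
        # IS-centered truth: log2 sample - log2 mean of batch samples
        for b in range(2):
            cols = slice(b * 10, (b + 1) * 10)
            lin = 2.0 ** tru[:, cols]
            tru[:, cols] = np.log2(lin / lin.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(rec, tru, atol=1e-9)

    def test_noisy_roundtrip_high_correlation(self):
        """Full chain at noise_sd=0.05 recovers log2 abundances with r > 0.99.

        Needs a realistic protein count: median normalization assumes the
        per-channel median of true sample effects is ~0, which holds at
        hundreds of proteins but not at a handful."""
        psm, truth, _ = simulate_psm_table(
            300, 2, impurity=None, seed=4, noise_sd=0.05, channel_loading_sd=0.2,
            psm_per_protein=10, low_intensity_fraction=0.0, missing_fraction=0.0,
        )
        mat = quantify(psm)
        shared = mat.index.intersection(truth.index)
        rec = mat.loc[shared, truth.columns].to_numpy()
        tru = truth.loc[shared].to_numpy()
        # the chain estimates IS-centered log2 abundance, batch by batch
        for b in range(2):
            cols = slice(b * 10, (b + 1) * 10)
            lin = 2.0 ** tru[:, cols]
            tru[:, cols] = np.log2(lin / lin.mean(axis=1, keepdims=True))
        ok = ~np.isnan(rec)  # proteins may drop out of a batch entirely
        r = np.corrcoef(rec[ok], tru[ok])[0, 1]
        assert r > 0.99

    def test_impurity_mixing_roundtrip(self):
        M = make_impurity(11, 0.05)
        psm_mixed, truth, _ = simulate_psm_table(5, 1, impurity=M.matrix, seed=3,
                                                 missing_fraction=0.0)
        psm_clean, _, _ = simulate_psm_table(5, 1, impurity=None, seed=3,
                                             missing_fraction=0.0)
        from xqtl.tmt_quant import correct_impurity

        rec = correct_impurity(psm_mixed, M)
        np.testing.assert_allclose(rec.intensities, psm_clean.intensities, rtol=1e-8)
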