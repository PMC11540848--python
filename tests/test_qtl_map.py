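"""Nominal scans, permutation calibration, Storey q-values, trans thresholds,
and annotation summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_trait_matrix
from xqtl.qtl_map import (
    WindowConfig,
    annotation_product,
    estimate_pi0,
    map_cis,
    nominal_scan,
    permutation_pass,
    storey_qvalues,
    summarize_annotations,
    to_qtltools_table,
    trans_threshold,
)
from xqtl.synthdata import SimConfig, simulate_genotypes


@pytest.fixture(scope="module")
def panel():
    cfg = SimConfig(n_samples=200, n_variants=30, n_blocks=1, ld_rho=0.6, seed=3)
    return simulate_genotypes(cfg)


class TestNominalScan:
    def test_slopes_match_normal_equations_oracle(self, panel):
        """Slopes and p-values equal a closed-form two-parameter OLS fit."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.standard_normal(200) + rng.uniform(-0.3, 0.3) * panel.dosages[:, rng.integers(30)]
            nom = next(iter(nominal_scan(make_trait_matrix(y), panel).values()))
            j = rng.integers(30)
            x = panel.dosages[:, j]
            X = np.column_stack([np.ones(200), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            se = np.sqrt(resid @ resid / 198 / ((x - x.mean()) @ (x - x.mean())))
            assert abs(nom["b"].iloc[j] - beta[1]) < 1e-10
            assert abs(nom["se"].iloc[j] - se) < 1e-10

    def test_null_pvalues_uniform(self, panel):
        rng = np.random.default_rng(1)
        pvals = np.concatenate(
            [
                next(iter(nominal_scan(make_trait_matrix(rng.standard_normal(200)), panel).values()))["p"]
                for _ in range(400)
            ]
        )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_association_stays_finite(self, panel):
        y = panel.dosages[:, 10].copy()
        nom = next(iter(nominal_scan(make_trait_matrix(y), panel).values()))
        assert nom["p"].iloc[10] == np.finfo(float).tiny
        assert nom["b"].iloc[10] == pytest.approx(1.0)
        assert np.isfinite(nom["b"]).all()

    def test_trans_mode_excludes_cis(self, panel):
        tm = make_trait_matrix(np.random.default_rng(2).standard_normal(200))
        scans = nominal_scan(tm, panel, WindowConfig(), mode="trans")
        assert len(next(iter(scans.values()))) == 0  # all variants are cis here

    def test_empty_window_is_not_an_error(self, panel):
        tm = make_trait_matrix(np.random.default_rng(3).standard_normal(200), chrom="chr9")
        scans = nominal_scan(tm, panel, WindowConfig(), mode="cis")
        assert len(next(iter(scans.values()))) == 0


class TestPermutationPass:
    def test_single_variant_window_collapses_to_nominal(self, panel):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(200)
        nom = next(iter(nominal_scan(make_trait_matrix(y), panel).values())).iloc[[7]].reset_index(drop=True)
        rec = permutation_pass(y, nom, panel.dosages[:, [7]], R=100, rng=rng)
        assert rec["adjusted_p"] == rec["direct_empirical_p"] == rec["nominal_p"]

    def test_null_adjusted_p_uniform_mean(self, panel):
        """Over null traits, beta-adjusted empirical p has mean ~0.5."""
        rng = np.random.default_rng(5)
        T = 200
        adj = []
        for i in range(T):
            y = rng.standard_normal(200)
            nom = next(iter(nominal_scan(make_trait_matrix(y), panel).values()))
            rec = permutation_pass(y, nom, panel.dosages, R=300, rng=np.random.default_rng((5, i)))
            adj.append(rec["adjusted_p"])
        adj = np.array(adj)
        assert abs(adj.mean() - 0.5) < 3 * adj.std() / np.sqrt(T)

    def test_adjusted_monotone_in_observed_p(self, panel):
        """Holding the fitted null fixed, the adjusted p increases with the
        observed minimum nominal p."""
        rng = np.random.default_rng(6)
        y = rng.standard_normal(200)
        nom = next(iter(nominal_scan(make_trait_matrix(y), panel).values()))
        rec = permutation_pass(y, nom, panel.dosages, R=500, rng=rng)
        a, b = rec["beta_shape1"], rec["beta_shape2"]
        grid = np.linspace(1e-6, 0.9, 50)
        cdf = stats.beta.cdf(grid, a, b)
        assert (np.diff(cdf) >= 0).all()

    def test_label_invariance(self, panel):
        """Jointly permuting samples in genotypes and trait leaves the
        mapping result unchanged."""
        rng = np.random.default_rng(7)
        y = 0.4 * panel.dosages[:, 12] + rng.standard_normal(200)
        perm = rng.permutation(200)
        from xqtl.synthdata import GenotypeMatrix

        g2 = GenotypeMatrix(panel.dosages[perm], panel.variants.copy(), list(np.array(panel.samples)))
        rec1 = map_cis(make_trait_matrix(y), panel, WindowConfig(n_permutations=2000), seed=9)
        rec2 = map_cis(make_trait_matrix(y[perm]), g2, WindowConfig(n_permutations=2000), seed=9)
        assert rec1["variant_id"].iloc[0] == rec2["variant_id"].iloc[0]
        assert rec1["nominal_p"].iloc[0] == pytest.approx(rec2["nominal_p"].iloc[0], rel=1e-12)
        assert rec1["slope"].iloc[0] == pytest.approx(rec2["slope"].iloc[0], rel=1e-12)
        # the permutation stream sees relabeled samples, so the empirical
        # null agrees only to Monte-Carlo accuracy
        assert rec1["adjusted_p"].iloc[0] == pytest.approx(rec2["adjusted_p"].iloc[0], abs=0.03)


class TestStoreyQ:
    def test_all_ones(self):
        np.testing.assert_array_equal(storey_qvalues(np.ones(50), pi0=1.0), np.ones(50))

    def test_pi0_one_equals_bh_oracle(self):
        """With pi0 fixed at 1, q-values equal Benjamini-Hochberg adjusted
        p-values from statsmodels (independent implementation)."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=500) ** 2
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(9)
        assert 0.9 <= estimate_pi0(rng.uniform(size=10_000)) <= 1.0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=300)
        q = storey_qvalues(p, pi0=0.7)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.1, 1.2]))


class TestTransThreshold:
    @pytest.mark.parametrize(
        "nv,nt,expect",
        [
            (8_101_465, 11_608, 5.3e-13),  # genome-wide proteome scan scale
            (1, 1, 0.05),
            (10, 10, 5e-4),
        ],
    )
    def test_values(self, nv, nt, expect):
        assert trans_threshold(nv, nt) == pytest.approx(expect, rel=0.02)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            trans_threshold(0, 10)


class TestAnnotationSummary:
    @pytest.mark.parametrize(
        "exonic,nonsyn,expect",
        [(15.13, 75.63, 11.44), (5.43, 33.64, 1.83)],
    )
    def test_nonsyn_product(self, exonic, nonsyn, expect):
        assert annotation_product(exonic, nonsyn) == pytest.approx(expect, abs=0.005)

    def test_tss_fraction_from_counts(self):
        assert 100.0 * 5605 / 9960 == pytest.approx(56.28, abs=0.005)

    def test_summary_on_constructed_records(self):
        records = pd.DataFrame(
            dict(
                trait_id=["t1", "t2", "t3", "t4"],
                variant_id=["v1", "v2", "v3", "v1"],
                tss_distance=[5000, -20_000, 1000, 5000],
                qvalue=[0.01, 0.01, 0.01, 0.01],
            )
        )
        variants = pd.DataFrame(
            dict(
                id=["v1", "v2", "v3"],
                anno_class=["exonic_nonsyn", "intronic", "exonic_syn"],
            )
        )
        out = summarize_annotations(records, variants)
        assert out["n_significant"] == 4
        assert out["exonic_pct"] == pytest.approx(75.0)
        assert out["nonsyn_within_exonic_pct"] == pytest.approx(100 * 2 / 3)
        assert out["tss_within_pct"] == pytest.approx(75.0)
        assert out["pleiotropic_variants"] == ["v1"]


def test_qtltools_table_layout(panel):
    rng = np.random.default_rng(11)
    tm = make_trait_matrix(0.5 * panel.dosages[:, 15] + rng.standard_normal(200))
    rec = map_cis(tm, panel, WindowConfig(n_permutations=200), seed=1)
    table = to_qtltools_table(rec, tm, panel)
    assert list(table.columns)[:5] == [
        "phenotype_id", "phenotype_chrom", "phenotype_start", "phenotype_end", "strand",
    ]
    assert table["slope"].iloc[0] == -table["phenotype_id"].map(
        rec.set_index("trait_id")["beta"]
    ).iloc[0]
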