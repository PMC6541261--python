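"""Expression filtering, TMM, precision weights, moderated t, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coreseq.diffexpr import (
    NormFactors,
    apply_contrast,
    bh_adjust,
    contrast_vector,
    de_table,
    filter_low_expression,
    fit_and_moderate,
    group_means_design,
    interaction_contrast,
    run_de,
    standard_contrasts,
    tmm_factors,
    trigamma_inverse,
    voom_transform,
    _fit_inverse_chisq_prior,
)
from coreseq.quantify import CountMatrix, SampleInfo
from coreseq.simulate import simulate_counts

from conftest import rank_auc


def make_cm(counts, species=None, days=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    species = species or ["A"] * n
    days = days or [0] * n
    reps = {}
    samples = []
    for i, (sp, d) in enumerate(zip(species, days)):
        reps[(sp, d)] = reps.get((sp, d), 0) + 1
        samples.append(SampleInfo(f"s{i}", sp, d, reps[(sp, d)]))
    return CountMatrix(genes=[f"g{i}" for i in range(counts.shape[0])],
                       samples=samples, counts=counts)


class TestExpressionFilter:
    def test_gene_passing_in_exactly_min_samples_is_kept(self):
        rng = np.random.default_rng(0)
        n_samples = 23
        counts = rng.integers(0, 5, size=(5, n_samples))
        lib_target = 1_000_000
        counts[0] = 0
        counts[1, :] = lib_target // n_samples  # deep filler so libs are stable
        thr_counts = None
        cm = make_cm(counts)
        thr = 10 * cm.library_sizes().mean() / 1e6
        # gene 2: >= thr in exactly 3 samples
        counts2 = counts.copy()
        counts2[2, :] = 0
        counts2[2, :3] = int(np.ceil(thr)) + 1
        cm = make_cm(counts2)
        kept = filter_low_expression(cm, min_cpm=10, min_samples=3)
        assert "g2" in kept.genes
        assert "g0" not in kept.genes  # all-zero gene removed

    def test_kept_set_equals_brute_force_row_scan(self):
        rng = np.random.default_rng(1)
        counts = rng.negative_binomial(2, 0.01, size=(200, 8))
        cm = make_cm(counts)
        kept = filter_low_expression(cm, min_cpm=10, min_samples=3)
        thr = 10 * counts.sum(axis=0).mean() / 1e6
        expected = [f"g{i}" for i in range(200)
                    if sum(c >= thr for c in counts[i]) >= 3]
        assert kept.genes == expected


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, size=(400, 1))
        cm = make_cm(np.hstack([col, col]))
        f = tmm_factors(cm)
        assert np.allclose(f.factors, 1.0)

    def test_pure_depth_scaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(3)
        col = rng.poisson(100, size=(400, 1))
        cm = make_cm(np.hstack([col, 2 * col]))
        f = tmm_factors(cm)
        assert np.allclose(f.factors, 1.0)

    def test_inflated_gene_block_pulls_factor_down(self):
        # one sample has a block of inflated genes; its factor must drop
        # below 1, matching a direct trimmed-mean computation's sign
        rng = np.random.default_rng(4)
        base = rng.poisson(200, size=(300, 1))
        inflated = base.copy()
        inflated[:30] *= 8
        cm = make_cm(np.hstack([base, base, inflated]))
        f = tmm_factors(cm)
        assert f.factors[2] < 1.0
        # brute-force check of the direction: the median M value (vs sample 0)
        # of the non-inflated majority is negative after depth normalization
        N, R = cm.counts[:, 2].sum(), cm.counts[:, 0].sum()
        M = np.log2((cm.counts[30:, 2] / N) / (cm.counts[30:, 0] / R))
        assert np.median(M) < 0

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(rng.uniform(10, 500, size=(500, 1)), size=(500, 6))
        f = tmm_factors(make_cm(counts))
        assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0, abs=1e-12)


class TestVoom:
    def test_logcpm_arithmetic_for_zero_count(self):
        counts = np.zeros((3, 4), dtype=int)
        counts[1:] = 50
        cm = make_cm(counts, days=[0, 0, 7, 7])
        design = group_means_design(cm.samples)
        factors = NormFactors(factors=np.ones(4), lib_sizes=np.full(4, 1e6))
        fit = voom_transform(cm, design, factors)
        assert fit.logcpm[0, 0] == pytest.approx(
            np.log2(0.5 / (1e6 + 1) * 1e6), abs=1e-9)
        assert fit.logcpm[0, 0] == pytest.approx(-1.0000014, abs=1e-6)

    def test_homoscedastic_data_gives_near_equal_weights(self):
        # counts built as 2^N(mu_g, 0.15) with deep means: log2 counts have the
        # same variance at every abundance, so the trend is flat and weights
        # are equal within 10%
        rng = np.random.default_rng(6)
        n_genes, n = 800, 12
        mu = rng.uniform(8, 14, size=(n_genes, 1))
        counts = np.round(2.0 ** (mu + rng.normal(0, 0.15, size=(n_genes, n))))
        cm = make_cm(counts.astype(np.int64), days=[0] * 6 + [7] * 6)
        design = group_means_design(cm.samples)
        fit = voom_transform(cm, design, tmm_factors(cm))
        w = fit.weights
        assert (w > 0).all()
        assert np.abs(w / w.mean() - 1).max() < 0.10

    def test_rank_deficient_design_rejected(self):
        counts = np.ones((5, 4), dtype=int) * 10
        cm = make_cm(counts, days=[0, 0, 7, 7])
        design = group_means_design(cm.samples)
        bad = design.matrix.copy()
        bad[:, 1] = bad[:, 0]
        from coreseq.diffexpr import DesignMatrix

        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix(matrix=bad, labels=design.labels, samples=design.samples)


@pytest.fixture(scope="module")
def small_fit():
    cm, _ = simulate_counts(n_genes=400, n_rep=3, dispersion=0.1, seed=20)
    design = group_means_design(cm.samples)
    voom = voom_transform(cm, design, tmm_factors(cm))
    return voom, design


class TestModeration:
    def test_d0_zero_limit_equals_ordinary_t(self, small_fit):
        voom, design = small_fit
        fits = fit_and_moderate(voom, design, d0_override=0.0)
        c = contrast_vector(design, ["A_d7"], ["A_d0"])
        res = apply_contrast(fits, c)
        # ordinary WLS t computed independently per gene
        X, W, Y = design.matrix, voom.weights, voom.logcpm
        for g in [0, 17, 399]:
            w = W[g]
            XtWX = X.T @ (w[:, None] * X)
            beta = np.linalg.solve(XtWX, X.T @ (w * Y[g]))
            resid = Y[g] - X @ beta
            dg = X.shape[0] - X.shape[1]
            s2 = (w * resid**2).sum() / dg
            t_ref = (c @ beta) / np.sqrt(s2 * c @ np.linalg.inv(XtWX) @ c)
            assert res.t[g] == pytest.approx(t_ref, abs=1e-10)

    def test_d0_infinite_limit_pools_all_variances(self, small_fit):
        voom, design = small_fit
        fits = fit_and_moderate(voom, design, d0_override=np.inf)
        assert np.allclose(fits.sigma2_post, fits.s0_sq)

    def test_prior_recovery_within_15_percent(self):
        rng = np.random.default_rng(7)
        d0, s0_sq, dg, G = 4.0, 2.0, 18.0, 5000
        sigma2_g = s0_sq * d0 / rng.chisquare(d0, G)
        s2 = sigma2_g * rng.chisquare(dg, G) / dg
        d0_hat, s0_hat = _fit_inverse_chisq_prior(s2, dg)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s0_hat - s0_sq) / s0_sq < 0.15

    def test_trigamma_inverse_inverts(self):
        from scipy.special import polygamma

        for y in (0.1, 1.0, 7.3, 40.0):
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)

    def test_identical_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 1.7)
        d0, s0 = _fit_inverse_chisq_prior(s2, 10.0)
        assert np.isinf(d0)


class TestContrasts:
    def test_interaction_vector_is_difference_of_differences(self):
        cm, _ = simulate_counts(n_genes=20, n_rep=2, seed=0)
        design = group_means_design(cm.samples)
        c = interaction_contrast(design, "A", "B", 7)
        expect = {lab: 0.0 for lab in design.labels}
        expect.update({"A_d7": 1.0, "A_d0": -1.0, "B_d7": -1.0, "B_d0": 1.0})
        assert dict(zip(design.labels, c)) == expect

    def test_null_t_statistics_follow_moderated_t_distribution(self):
        cm, _ = simulate_counts(n_genes=2000, n_rep=4, dispersion=0.1,
                                frac_de=0.0, seed=31)
        results, fits, _ = run_de(cm)
        res = results["interaction_d7_vs_d0"]
        ks = stats.kstest(res.t, "t", args=(res.df_total,))
        assert ks.pvalue > 0.01

    def test_planted_interaction_genes_rank_first(self):
        cm, truth = simulate_counts(n_genes=2000, n_rep=4, dispersion=0.1,
                                    frac_de=0.1, interaction_lfc=2.0, seed=32)
        results, _, _ = run_de(cm)
        res = results["interaction_d7_vs_d0"]
        labels = np.array([truth.de_genes[g] != 0 for g in res.genes])
        assert rank_auc(np.abs(res.t), labels) > 0.95

    def test_zero_contrast_rejected(self):
        cm, _ = simulate_counts(n_genes=50, n_rep=2, seed=1)
        design = group_means_design(cm.samples)
        voom = voom_transform(cm, design, tmm_factors(cm))
        fits = fit_and_moderate(voom, design)
        with pytest.raises(ValueError, match="zero"):
            apply_contrast(fits, np.zeros(len(design.labels)))

    def test_standard_contrast_set_names(self):
        cm, _ = simulate_counts(n_genes=20, n_rep=2, seed=2)
        names = set(standard_contrasts(group_means_design(cm.samples)))
        assert names == {"A_d7_vs_d0", "A_d14_vs_d0", "B_d7_vs_d0", "B_d14_vs_d0",
                         "interaction_d7_vs_d0", "interaction_d14_vs_d0"}


class TestBH:
    def test_hand_computed_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestDETable:
    def test_signed_fold_change_convention(self):
        cm, _ = simulate_counts(n_genes=50, n_rep=2, seed=3)
        results, fits, _ = run_de(cm)
        res = results["interaction_d7_vs_d0"]
        df = de_table(res)
        pos = df[df.logFC > 0]
        neg = df[df.logFC < 0]
        assert np.allclose(pos.FC, 2.0 ** pos.logFC)
        assert np.allclose(neg.FC, -(2.0 ** (-neg.logFC)))
        assert (df.P.diff().dropna() >= 0).all()

    def test_roundtrip_preserves_six_significant_digits(self, tmp_path):
        cm, _ = simulate_counts(n_genes=50, n_rep=2, seed=4)
        results, _, _ = run_de(cm)
        df = de_table(results["A_d7_vs_d0"])
        p = tmp_path / "de.tsv"
        df.to_csv(p, sep="\t", float_format="%.6g")
        again = pd.read_csv(p, sep="\t", index_col=0)
        for col in ("logFC", "t", "P", "FDR"):
            assert np.allclose(again[col], df[col], rtol=1e-5)
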