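"""Window densities, the density GLM and the tandem-proportion correlation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_gene
from tandemdup.context import (CollinearTermsError, compute_windows,
                               fit_density_glm, merge_intervals,
                               tandem_proportion_correlation,
                               windows_to_frame)
from tandemdup.core_io import SubgenomeBlock, TEFeature


def _window_frame(rng, n, betas, sigma=0.0):
    """Simulate windows directly from the linear model with known betas."""
    df = pd.DataFrame({
        "gene_density": rng.uniform(0.0, 0.6, n),
        "rna_te_density": rng.uniform(0.0, 0.5, n),
        "dna_te_density": rng.uniform(0.0, 0.3, n),
        "subgenome": pd.Categorical(
            rng.choice(["maize1", "maize2", "nonsyntenic"], n),
            categories=["maize1", "maize2", "nonsyntenic"]),
    })
    b0, bg, br, bd, bm2, bns = betas
    df["tandem_density"] = (
        b0 + bg * df.gene_density + br * df.rna_te_density + bd * df.dna_te_density
        + np.where(df.subgenome == "maize2", bm2, 0.0)
        + np.where(df.subgenome == "nonsyntenic", bns, 0.0)
        + rng.normal(0.0, sigma, n)
    )
    return df


class TestDensities:
    def test_single_gene_density(self):
        genes = {"chr1": [make_gene("g1", start=100_000, end=300_000)]}
        w = compute_windows(genes, [], set(), [], chrom_lengths={"chr1": 1_000_000})
        assert len(w) == 1
        assert w[0].gene_density == pytest.approx(0.2)

    def test_union_of_overlapping_genes(self):
        genes = {"chr1": [make_gene("g1", start=0, end=150_000),
                          make_gene("g2", start=100_000, end=300_000, rank=1)]}
        w = compute_windows(genes, [], set(), [], chrom_lengths={"chr1": 1_000_000})
        assert w[0].gene_density == pytest.approx(0.3)

    def test_majority_subgenome_label(self):
        blocks = [SubgenomeBlock("chr1", 0, 600_000, "maize1"),
                  SubgenomeBlock("chr1", 600_000, 900_000, "maize2")]
        w = compute_windows({}, [], set(), blocks, chrom_lengths={"chr1": 1_000_000})
        assert w[0].subgenome == "maize1"

    def test_no_block_coverage_is_nonsyntenic(self):
        genes = {"chr1": [make_gene("g1", start=0, end=1000)]}
        w = compute_windows(genes, [], set(), [], chrom_lengths={"chr1": 500_000})
        assert w[0].subgenome == "nonsyntenic"

    def test_trailing_partial_window_normalized_by_width(self):
        genes = {"chr1": [make_gene("g1", start=1_000_000, end=1_100_000)]}
        w = compute_windows(genes, [], set(), [], chrom_lengths={"chr1": 1_200_000})
        assert len(w) == 2
        assert w[1].width == 200_000
        assert w[1].gene_density == pytest.approx(0.5)

    def test_rna_vs_dna_te_classes(self):
        tes = [TEFeature("t1", "chr1", 0, 100_000, "LTR"),
               TEFeature("t2", "chr1", 200_000, 250_000, "SINE"),
               TEFeature("t3", "chr1", 300_000, 400_000, "TIR")]
        w = compute_windows({}, tes, set(), [], chrom_lengths={"chr1": 1_000_000})
        assert w[0].rna_te_density == pytest.approx(0.15)
        assert w[0].dna_te_density == pytest.approx(0.10)

    def test_density_conservation(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.integers(0, 90_000, 40))
        genes = {"chr1": [make_gene(f"g{i}", start=int(s), end=int(s) + int(l), rank=i)
                          for i, (s, l) in enumerate(zip(starts, rng.integers(100, 5000, 40)))]}
        length = 100_000
        w = compute_windows(genes, [], set(), [], window_size=7000,
                            chrom_lengths={"chr1": length})
        total = sum(round(win.width * win.gene_density) for win in w)
        covered = np.zeros(length, dtype=bool)
        for g in genes["chr1"]:
            covered[g.start:g.end] = True
        assert total == covered.sum()

    def test_merge_intervals_union(self):
        assert merge_intervals([(0, 10), (5, 20), (30, 40)]) == [(0, 20), (30, 40)]


class TestDensityGLM:
    BETAS = (0.01, 0.4, 0.05, -0.03, -0.02, 0.015)

    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        df = _window_frame(rng, 200, self.BETAS, sigma=0.0)
        fit = fit_density_glm(df)
        coef = fit.coefficients
        assert coef["Intercept"] == pytest.approx(self.BETAS[0], abs=1e-10)
        assert coef["gene_density"] == pytest.approx(self.BETAS[1], abs=1e-10)
        assert coef["rna_te_density"] == pytest.approx(self.BETAS[2], abs=1e-10)
        assert coef["dna_te_density"] == pytest.approx(self.BETAS[3], abs=1e-10)
        assert fit.variance_explained == pytest.approx(1.0)

    def test_fitted_plus_residual_reproduces_response(self):
        rng = np.random.default_rng(1)
        df = _window_frame(rng, 100, self.BETAS, sigma=0.01)
        fit = fit_density_glm(df)
        np.testing.assert_allclose(fit.fitted + fit.residuals, df.tandem_density)

    def test_full_model_r2_at_least_nested(self):
        rng = np.random.default_rng(2)
        df = _window_frame(rng, 150, self.BETAS, sigma=0.02)
        full = fit_density_glm(df, include_interaction=True)
        base = fit_density_glm(df, include_interaction=False)
        assert full.variance_explained >= base.variance_explained - 1e-12

    def test_anova_has_all_terms(self):
        rng = np.random.default_rng(3)
        fit = fit_density_glm(_window_frame(rng, 100, self.BETAS, sigma=0.01))
        assert set(fit.anova.index) == {"gene_density", "rna_te_density",
                                        "dna_te_density", "subgenome"}
        assert (fit.anova.p_value <= 1).all()

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(4)
        df = _window_frame(rng, 100, self.BETAS, sigma=0.01)
        df["rna_te_density"] = 2.0 * df["gene_density"]
        with pytest.raises(CollinearTermsError):
            fit_density_glm(df)


class TestTandemProportionCorrelation:
    def _windows(self, gene_density, tandem_density):
        genes = {}
        from tandemdup.context import GenomeWindow
        return [GenomeWindow("chr1", i, i + 1, td, gd, 0, 0, "maize1")
                for i, (gd, td) in enumerate(zip(gene_density, tandem_density))]

    def test_constant_tandem_proportion_is_undefined(self):
        gd = [0.2, 0.4, 0.6, 0.8]
        td = [0.5 * g for g in gd]
        res = tandem_proportion_correlation(self._windows(gd, td))
        assert res.undefined
        assert np.isnan(res.r)

    def test_perfect_linear_relation(self):
        gd = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        td = gd * (0.1 + 0.5 * gd)  # proportion = 0.1 + 0.5 * gene_density
        res = tandem_proportion_correlation(self._windows(gd, td))
        assert res.r == pytest.approx(1.0)

    def test_zero_gene_density_windows_excluded(self):
        gd = [0.0, 0.2, 0.4, 0.6]
        td = [0.0, 0.02, 0.08, 0.18]
        res = tandem_proportion_correlation(self._windows(gd, td))
        assert res.n == 3

    def test_too_few_windows_raise(self):
        with pytest.raises(ValueError):
            tandem_proportion_correlation(self._windows([0.1, 0.2], [0.0, 0.0]))
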