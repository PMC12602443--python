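"""Floor-binned histogram, peak fitting and threshold classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ieireprog.fc_classifier import (
    DistributionFit,
    FCHistogram,
    _gaussian,
    _lorentzian,
    build_histogram,
    classify_genes,
    fit_distribution,
    select_model,
)
from ieireprog.io_formats import DETable


def make_de(log2fc, padj, base_mean=None):
    n = len(log2fc)
    return DETable(
        pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "base_mean": base_mean if base_mean is not None else np.full(n, 10.0),
                "log2fc": np.asarray(log2fc, dtype=float),
                "se": np.full(n, 0.1),
                "p": np.asarray(padj, dtype=float),
                "padj": np.asarray(padj, dtype=float),
                "padj_imputed": False,
            }
        )
    )


class TestBuildHistogram:
    def test_values_in_same_decade_share_a_bin(self):
        h = build_histogram([0.00, 0.04, 0.09])
        assert list(h.bin_left) == [0.0]
        assert list(h.count) == [3]

    def test_floor_is_toward_minus_infinity(self):
        h = build_histogram([-0.01])
        assert list(h.bin_left) == [-0.1]
        assert list(h.count) == [1]

    def test_grid_edge_values_stay_in_their_own_bin(self):
        # 0.7 / 0.1 is 6.999... in floats; the guard keeps it in bin 0.7
        h = build_histogram([0.7, 0.1, -0.3])
        assert list(h.bin_left) == [-0.3, 0.1, 0.7]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no finite"):
            build_histogram([np.nan, np.inf])

    @given(
        xs=st.lists(
            st.floats(allow_nan=True, allow_infinity=True, width=64),
            min_size=1,
            max_size=200,
        )
    )
    def test_mass_conservation(self, xs):
        xs = np.asarray(xs)
        n_finite = int(np.isfinite(xs).sum())
        if n_finite == 0:
            with pytest.raises(ValueError):
                build_histogram(xs)
            return
        h = build_histogram(xs)
        assert h.total == n_finite
        assert h.n_dropped == len(xs) - n_finite
        assert (np.diff(h.bin_left) > 0).all()

    def test_normal_draws_total_and_mode(self):
        rng = np.random.default_rng(0)
        h = build_histogram(rng.normal(0.0, 0.5, 10_000))
        assert h.total == 10_000
        modal = h.bin_left[np.argmax(h.count)]
        assert -0.1 <= modal <= 0.0


class TestFitDistribution:
    def grid(self, lo=-3.0, hi=3.0):
        return np.round(np.arange(lo, hi, 0.1), 10)

    def test_noiseless_gaussian_self_consistency(self):
        bins = self.grid()
        a, mu, sigma = 200.0, 0.15, 0.6
        counts = _gaussian(bins + 0.05, a, mu, sigma)
        h = FCHistogram(bin_left=bins, count=counts)
        fit = fit_distribution(h, "gaussian")
        assert fit.converged
        assert fit.amplitude == pytest.approx(a, rel=1e-6)
        assert fit.center == pytest.approx(mu, rel=1e-6)
        assert fit.width == pytest.approx(sigma, rel=1e-6)

    def test_noiseless_lorentzian_self_consistency(self):
        bins = self.grid()
        a, mu, gamma = 150.0, -0.2, 0.4
        counts = _lorentzian(bins + 0.05, a, mu, gamma)
        h = FCHistogram(bin_left=bins, count=counts)
        fit = fit_distribution(h, "lorentzian")
        assert fit.converged
        assert fit.center == pytest.approx(mu, rel=1e-6)
        assert fit.width == pytest.approx(gamma, rel=1e-6)

    def test_symmetric_histogram_centers_at_zero(self):
        bins = np.round(np.arange(-1.1, 1.1, 0.1), 10)  # centers symmetric about 0
        counts = _gaussian(bins + 0.05, 100.0, 0.0, 0.5)
        fit = fit_distribution(FCHistogram(bin_left=bins, count=counts), "gaussian")
        assert abs(fit.center) < 1e-9

    def test_simulated_normal_recovery(self):
        rng = np.random.default_rng(77)
        h = build_histogram(rng.normal(0.2, 0.6, 15_000))
        fit = fit_distribution(h, "gaussian")
        assert fit.converged
        assert fit.center == pytest.approx(0.2, abs=0.05)
        assert fit.width == pytest.approx(0.6, rel=0.10)

    def test_too_few_bins_rejected(self):
        h = FCHistogram(bin_left=np.array([0.0, 0.1]), count=np.array([3, 4]))
        with pytest.raises(ValueError, match="at least 5"):
            fit_distribution(h, "gaussian")

    def test_unknown_model_rejected(self):
        h = FCHistogram(bin_left=np.arange(5) * 0.1, count=np.ones(5))
        with pytest.raises(ValueError, match="unknown model"):
            fit_distribution(h, "voigt")


class TestSelectModel:
    def test_pure_gaussian_histogram_selects_gaussian(self):
        bins = np.round(np.arange(-3.0, 3.0, 0.1), 10)
        counts = _gaussian(bins + 0.05, 300.0, 0.1, 0.5)
        assert select_model(FCHistogram(bin_left=bins, count=counts)).model == "gaussian"

    def test_pure_lorentzian_histogram_selects_lorentzian(self):
        bins = np.round(np.arange(-3.0, 3.0, 0.1), 10)
        counts = _lorentzian(bins + 0.05, 300.0, 0.1, 0.5)
        assert select_model(FCHistogram(bin_left=bins, count=counts)).model == "lorentzian"

    def test_explicit_model_bypasses_selection(self):
        bins = np.round(np.arange(-3.0, 3.0, 0.1), 10)
        counts = _lorentzian(bins + 0.05, 300.0, 0.1, 0.5)
        fit = fit_distribution(FCHistogram(bin_left=bins, count=counts), "gaussian")
        assert fit.model == "gaussian"


class TestClassifyGenes:
    fit = DistributionFit(
        model="gaussian", center=0.0, width=0.5, amplitude=1.0, sse=0.0, converged=True
    )

    def test_strong_induction_is_increased(self):
        de = make_de([np.log2(170.0)], [1e-8])
        assert classify_genes(de, self.fit)["category"].iloc[0] == "increased"

    def test_within_band_is_unchanged_even_if_significant(self):
        de = make_de([0.3], [0.001])
        assert classify_genes(de, self.fit)["category"].iloc[0] == "unchanged"

    def test_non_significant_gene_gated_out(self):
        de = make_de([5.0], [0.2])
        assert classify_genes(de, self.fit)["category"].iloc[0] == "not_significant"

    def test_boundary_equality_is_unchanged(self):
        de = make_de([0.5, -0.5], [0.001, 0.001])
        assert list(classify_genes(de, self.fit)["category"]) == ["unchanged", "unchanged"]

    def test_partition_covers_table(self):
        rng = np.random.default_rng(11)
        de = make_de(rng.normal(0, 1, 500), rng.uniform(0, 1, 500))
        classes = classify_genes(de, self.fit)
        assert len(classes) == 500
        assert classes["category"].isin(
            ["increased", "decreased", "unchanged", "not_significant"]
        ).all()

    def test_non_converged_fit_refused(self):
        bad = DistributionFit("gaussian", 0.0, 0.5, 1.0, 0.0, converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            classify_genes(make_de([0.0], [0.5]), bad)


class TestShiftInvariance:
    def test_shifting_lfc_shifts_center_and_preserves_categories(self):
        rng = np.random.default_rng(21)
        lfc = rng.normal(0.0, 0.5, 12_000)
        padj = rng.uniform(0, 1, 12_000)
        shift = 0.8

        fit0 = fit_distribution(build_histogram(lfc), "gaussian")
        fit1 = fit_distribution(build_histogram(lfc + shift), "gaussian")
        assert fit1.center - fit0.center == pytest.approx(shift, abs=0.02)

        c0 = classify_genes(make_de(lfc, padj), fit0)["category"]
        c1 = classify_genes(make_de(lfc + shift, padj), fit1)["category"]
        assert (c0 == c1).mean() > 0.99  # only bin-resolution boundary flips allowed
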