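"""Normalization, dispersion, the NB Wald test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from ieireprog.de_core import (
    ALPHA_MIN,
    bh_adjust,
    de_test,
    estimate_dispersion,
    size_factors,
)

from conftest import make_counts, make_sheet


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Independent median-of-ratios: per sample, median over genes positive in
    every sample of count / geometric mean, then rescale to geomean 1."""
    keep = [g for g in range(counts.shape[0]) if all(counts[g] > 0)]
    factors = []
    for j in range(counts.shape[1]):
        ratios = sorted(
            counts[g, j] / float(np.prod([float(c) for c in counts[g]])) ** (1.0 / counts.shape[1])
            for g in keep
        )
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        factors.append(med)
    factors = np.asarray(factors)
    return factors / np.prod(factors) ** (1.0 / len(factors))


def brute_force_bh(p):
    """BH from the definition: adj_i = min over j with p_j >= p_i of p_j * m / rank_j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        adj[i] = min(best, 1.0)
    return np.asarray(adj)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_counts([[5, 5, 5], [9, 9, 9], [2, 2, 2]])
        np.testing.assert_allclose(size_factors(cm).to_numpy(), 1.0, atol=1e-12)

    def test_doubled_sample_closed_form(self):
        cm = make_counts([[10, 20], [3, 6], [50, 100]])
        sf = size_factors(cm).to_numpy()
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)
        assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-12)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            counts = rng.integers(0, 500, size=(50, rng.integers(2, 6)))
            counts[:10] += 1  # guarantee some all-positive genes
            got = size_factors(make_counts(counts)).to_numpy()
            want = brute_force_size_factors(counts)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_invariant_to_gene_reordering(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 300, size=(40, 4))
        cm = make_counts(counts)
        perm = rng.permutation(40)
        cm_perm = make_counts(counts[perm])
        np.testing.assert_allclose(
            size_factors(cm).to_numpy(), size_factors(cm_perm).to_numpy(), rtol=1e-12
        )

    def test_equivariant_to_scaling_one_sample(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 300, size=(41, 3))
        sf0 = size_factors(make_counts(counts)).to_numpy()
        scaled = counts.copy()
        scaled[:, 1] *= 4
        sf1 = size_factors(make_counts(scaled)).to_numpy()
        # the scaled sample's factor quadruples relative to the others
        np.testing.assert_allclose(
            (sf1[1] / sf1[0]) / (sf0[1] / sf0[0]), 4.0, rtol=1e-12
        )

    def test_all_zero_gene_only_matrix_errors(self):
        with pytest.raises(ValueError, match="filter"):
            size_factors(make_counts([[0, 1], [1, 0]]))

    def test_agrees_with_pydeseq2_on_ratios(self):
        pydeseq2_pp = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 1000, size=(101, 4))  # odd gene count: unambiguous median
        ours = size_factors(make_counts(counts)).to_numpy()
        _, theirs = pydeseq2_pp.deseq2_norm(pd.DataFrame(counts.T))
        theirs = np.asarray(theirs)
        np.testing.assert_allclose(ours / ours[0], theirs / theirs[0], rtol=1e-8)


class TestDispersion:
    def test_constant_gene_hits_floor(self):
        cm = make_counts([[7, 7, 7, 7]])
        sf = pd.Series(1.0, index=cm.sample_ids)
        groups = pd.Series(["a", "a", "b", "b"], index=cm.sample_ids)
        assert estimate_dispersion(cm, sf, groups).iloc[0] == ALPHA_MIN

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(5.0, 1.0, 400)
        counts = rng.poisson(np.repeat(base[:, None], 40, axis=1))
        cm = make_counts(counts)
        sf = pd.Series(1.0, index=cm.sample_ids)
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=cm.sample_ids)
        alpha = estimate_dispersion(cm, sf, groups)
        assert (alpha <= 0.01).mean() >= 0.95

    def test_nb_dispersion_recovered_within_factor_two(self):
        rng = np.random.default_rng(6)
        base = rng.lognormal(5.0, 1.0, 300)
        r = 1 / 0.1
        mu = np.repeat(base[:, None], 100, axis=1)
        counts = rng.negative_binomial(r, r / (r + mu))
        cm = make_counts(counts)
        sf = pd.Series(1.0, index=cm.sample_ids)
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=cm.sample_ids)
        alpha = estimate_dispersion(cm, sf, groups)
        assert 0.05 <= np.median(alpha) <= 0.2

    def test_single_sample_group_rejected(self):
        cm = make_counts([[1, 2, 3]])
        sf = pd.Series(1.0, index=cm.sample_ids)
        groups = pd.Series(["a", "a", "b"], index=cm.sample_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(cm, sf, groups)


def _run_de(counts, conditions, contrast=("cm", "sham")):
    cm = make_counts(counts)
    sheet = make_sheet(conditions)
    sf = size_factors(cm)
    groups = sheet.conditions()
    disp = estimate_dispersion(cm, sf, groups)
    return de_test(cm, sf, disp, groups, contrast)


class TestDETest:
    def test_identical_groups_give_zero_lfc_unit_p(self):
        counts = np.array([[10, 20, 30, 10, 20, 30], [5, 5, 5, 5, 5, 5]])
        de = _run_de(counts, ["sham"] * 3 + ["cm"] * 3)
        np.testing.assert_allclose(de.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(de.table["p"], 1.0, atol=1e-12)

    def test_swapped_contrast_negates_log2fc_exactly(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 400, size=(60, 6))
        cond = ["sham"] * 3 + ["cm"] * 3
        fwd = _run_de(counts, cond, ("cm", "sham"))
        rev = _run_de(counts, cond, ("sham", "cm"))
        np.testing.assert_allclose(
            fwd.table["log2fc"].to_numpy(), -rev.table["log2fc"].to_numpy(), rtol=0, atol=0
        )

    def test_spiked_gene_recovered(self):
        rng = np.random.default_rng(9)
        n, ratio, base = 6, 8.0, 500.0
        means = rng.lognormal(4.0, 1.0, 300)
        mu = np.repeat(means[:, None], 2 * n, axis=1).copy()
        mu[0, :] = base  # spiked gene
        mu[0, n:] = base / ratio
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu))
        de = _run_de(counts, ["cm"] * n + ["sham"] * n)
        assert de.table.loc[0, "log2fc"] == pytest.approx(3.0, abs=0.3)
        assert de.table.loc[0, "padj"] < 0.05

    def test_empty_contrast_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            _run_de(np.ones((3, 4), dtype=int), ["sham"] * 2 + ["cm"] * 2, ("cm_ntci", "sham"))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_staircase(self):
        # each p_(i) * 4 / i is (0.04, 0.04, 0.04, 0.04): the step-up min is 0.04 everywhere
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            got = bh_adjust(p)
            np.testing.assert_allclose(got, brute_force_bh(p), rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(
                got, multipletests(p, method="fdr_bh")[1], rtol=1e-10, atol=1e-12
            )

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_monotone_and_never_decreasing(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.5])
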