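"""Housekeeping normalization, fold-change medians, Wilcoxon and motif tests."""

import numpy as np
import pytest
from scipy import stats

from crossbear.xcu import (adjust_pvalues, ggach_frequency,
                           housekeeping_normalize, motif_shift_test,
                           per_gene_median_log2fc, xcu_test)

from _reference import enumeration_signed_rank_pvalue


class TestHousekeepingNormalize:
    HK = np.array([True, True, False, False, False])

    def test_divides_by_housekeeping_mass(self):
        cell = np.array([[0.5, 1.5, 4.0, 1.0, 3.0]])
        out = housekeeping_normalize(cell, self.HK)
        np.testing.assert_allclose(out, cell / 2.0)

    def test_global_scalar_invariance_and_idempotence(self):
        rng = np.random.default_rng(0)
        cells = rng.uniform(0.1, 2, size=(4, 5))
        a = housekeeping_normalize(cells, self.HK)
        b = housekeeping_normalize(cells * 37.0, self.HK)
        np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(housekeeping_normalize(a, self.HK), a)

    def test_zero_mass_cell_excluded_with_warning(self):
        cells = np.array([[0.0, 0.0, 1.0, 1.0, 1.0],
                          [1.0, 1.0, 1.0, 1.0, 1.0]])
        with pytest.warns(UserWarning):
            out = housekeeping_normalize(cells, self.HK)
        assert out.shape[0] == 1

    def test_hand_computed_two_hk_genes(self):
        cell = np.array([[2.0, 3.0, 1.0, 7.0, 0.5]])
        out = housekeeping_normalize(cell, self.HK)
        np.testing.assert_allclose(out[0], cell[0] / 5.0)


class TestMedianLog2FC:
    def test_identity_gives_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.01, 1, size=(6, 4))
        np.testing.assert_allclose(per_gene_median_log2fc(x, x), 0.0)

    def test_antisymmetric_under_species_swap(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(0.01, 1, size=(5, 4))
        l = rng.uniform(0.01, 1, size=(5, 4))
        np.testing.assert_allclose(per_gene_median_log2fc(u, l),
                                   -per_gene_median_log2fc(l, u))

    def test_hand_computed_three_cell_median(self):
        eps = 1e-2
        upper = np.array([[0.1], [0.4], [0.2]])
        lower = np.array([[0.2], [0.1], [0.2]])
        expected = np.median(np.log2((upper + eps) / (lower + eps)), axis=0)
        np.testing.assert_allclose(
            per_gene_median_log2fc(upper, lower), expected)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            per_gene_median_log2fc(np.ones((2, 3)), np.ones((3, 3)))

    def test_transitive_across_three_species_on_noiseless_data(self):
        rng = np.random.default_rng(3)
        mouse = rng.uniform(0.05, 1, size=(4, 6))
        ratio1 = rng.uniform(0.5, 2, size=6)
        ratio2 = rng.uniform(0.5, 2, size=6)
        opossum = mouse * ratio1
        chicken = opossum * ratio2
        eps = 0.0  # exact transitivity holds without the pseudocount floor
        fc_mc = per_gene_median_log2fc(mouse, chicken, pseudocount=eps)
        fc_mo = per_gene_median_log2fc(mouse, opossum, pseudocount=eps)
        fc_oc = per_gene_median_log2fc(opossum, chicken, pseudocount=eps)
        np.testing.assert_allclose(fc_mc, fc_mo + fc_oc, atol=1e-10)


class TestWilcoxon:
    def test_all_positive_unit_shift_n20(self):
        p = xcu_test(np.full(20, -1.0 + 1.0), null_median=-1.0,
                     alternative="greater")
        assert p == pytest.approx(2.0 ** -20, rel=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exact_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        vals = np.round(rng.normal(size=n), 1)  # rounding induces ties
        alt = "greater" if seed % 2 else "less"
        got = xcu_test(vals, null_median=0.0, alternative=alt)
        expected = enumeration_signed_rank_pvalue(vals, 0.0, alt)
        if np.isnan(got):
            assert len(vals[vals != 0]) == 0
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_normal_approximation_large_n(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(loc=0.2, size=200)
        for alt in ("greater", "less"):
            got = xcu_test(vals, null_median=0.0, alternative=alt)
            ref = stats.wilcoxon(vals, alternative=alt, correction=True,
                                 method="approx").pvalue
            assert got == pytest.approx(ref, abs=1e-8)

    def test_symmetric_values_give_half(self):
        rng = np.random.default_rng(8)
        mags = rng.uniform(0.1, 1, size=100)
        vals = np.concatenate([mags, -mags])
        assert xcu_test(vals, 0.0, "greater") == pytest.approx(0.5, abs=0.05)

    def test_one_sided_complementarity(self):
        rng = np.random.default_rng(9)
        vals = np.round(rng.normal(size=10), 1)
        pg = xcu_test(vals, 0.0, "greater")
        pl = xcu_test(vals, 0.0, "less")
        assert pg + pl >= 1.0 - 1e-12  # overlap at the observed point mass

    def test_degenerate_all_at_null_is_missing(self):
        assert np.isnan(xcu_test(np.full(5, -1.0), null_median=-1.0))

    def test_upregulation_hypotheses_on_shifted_group(self):
        rng = np.random.default_rng(10)
        fc = rng.normal(loc=-0.4, scale=0.3, size=80)
        # upregulated relative to full halving (-1), not fully compensated (0)
        assert xcu_test(fc, -1.0, "greater") < 1e-6
        assert xcu_test(fc, 0.0, "less") < 1e-6


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03]), [0.03])

    def test_hand_applied_bh(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_ties_and_bounds(self):
        out = adjust_pvalues([0.2, 0.2, 0.2, 0.9])
        assert len(set(np.round(out[:3], 12))) == 1
        assert np.all(out <= 1.0)
        with pytest.raises(ValueError):
            adjust_pvalues([1.5])


class TestGGACH:
    @pytest.mark.parametrize("seq,count", [
        ("GGACT", 1), ("GGACG", 0), ("GGACAGGACC", 2), ("GGACU", 1),
        ("ggaca", 1), ("AAAAA", 0), ("GGACGGACT", 1),
    ])
    def test_known_sequences(self, seq, count):
        got, rate = ggach_frequency(seq)
        assert got == count
        assert rate == pytest.approx(count * 1000 / len(seq))

    def test_matches_sliding_window_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            expected = sum(seq[i:i + 5] in
                           {"GGACA", "GGACC", "GGACT"}
                           for i in range(len(seq) - 4))
            assert ggach_frequency(seq)[0] == expected

    def test_rejects_empty_and_invalid(self):
        with pytest.raises(ValueError):
            ggach_frequency("")
        with pytest.raises(ValueError):
            ggach_frequency("GGAXZ")


class TestMotifShift:
    def test_identical_distributions_pvalues_uniform_on_average(self):
        rng = np.random.default_rng(12)
        ps = [motif_shift_test(rng.normal(size=60), rng.normal(size=60))
              for _ in range(200)]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.08)

    def test_downward_shift_detected(self):
        rng = np.random.default_rng(13)
        auto = rng.normal(size=300)
        assert motif_shift_test(auto - 1.0, auto) < 1e-10

    def test_swapping_groups_flips_the_tail(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=50) - 0.5
        b = rng.normal(size=50)
        assert motif_shift_test(a, b) < 0.5 < motif_shift_test(b, a)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            motif_shift_test([], [1.0])
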