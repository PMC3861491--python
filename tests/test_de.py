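import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from crossde.counts_io import CountMatrix
from crossde.de_test import (
    ALPHA_FLOOR,
    DEParams,
    adjust_bh,
    detect_expressed,
    estimate_dispersion,
    estimate_size_factors,
    nb_exact_test,
    run_de,
)
from crossde.synthetic_data import SynthConfig, generate_counts

from conftest import make_cell_line


def oracle_nb_exact(counts_a, counts_b, sa, sb, alpha):
    """Independent linear-space enumeration of the conditional exact test."""
    sa = np.asarray(sa, float)
    sb = np.asarray(sb, float)
    ca = np.asarray(counts_a)
    cb = np.asarray(counts_b)
    q0 = (np.sum(ca / sa) + np.sum(cb / sb)) / (sa.size + sb.size)
    total = int(ca.sum() + cb.sum())
    if total == 0:
        return 1.0

    def pmf(k, s_arr):
        mu = q0 * s_arr.sum()
        var = float(np.sum(s_arr * q0 + alpha * (s_arr * q0) ** 2))
        if mu <= 0:
            return 1.0 if k == 0 else 0.0
        if var <= mu:
            return stats.poisson.pmf(k, mu)
        p = mu / var
        r = mu * mu / (var - mu)
        return stats.nbinom.pmf(k, r, p)

    probs = np.array([pmf(a, sa) * pmf(total - a, sb) for a in range(total + 1)])
    obs = probs[int(ca.sum())]
    return float(probs[probs <= obs * (1 + 1e-9)].sum() / probs.sum())


class TestDetectExpressed:
    def test_exactly_three_nonzero_replicates_is_expressed(self):
        counts = np.zeros((1, 9), dtype=int)
        counts[0, :3] = 1
        matrix, design = make_cell_line(counts, n_treated=6, n_control=3)
        assert "g0" in detect_expressed(matrix, design, "A")

    def test_one_big_replicate_is_not_expressed(self):
        counts = np.zeros((1, 9), dtype=int)
        counts[0, 0] = 50
        matrix, design = make_cell_line(counts, n_treated=6, n_control=3)
        assert "g0" not in detect_expressed(matrix, design, "A")

    def test_all_zero_gene_not_expressed(self):
        matrix, design = make_cell_line(np.zeros((1, 9), dtype=int), n_treated=6, n_control=3)
        assert len(detect_expressed(matrix, design, "A")) == 0

    def test_unknown_cell_line_raises(self):
        matrix, design = make_cell_line(np.ones((1, 9), dtype=int), n_treated=6, n_control=3)
        with pytest.raises(KeyError):
            detect_expressed(matrix, design, "Z")


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = CountMatrix(pd.DataFrame({"s1": [4, 7], "s2": [4, 7]}, index=["a", "b"]))
        assert np.allclose(estimate_size_factors(m), 1.0)

    def test_doubled_sample_gives_sqrt2_split(self):
        m = CountMatrix(pd.DataFrame({"sA": [4, 10], "sB": [8, 20]}, index=["a", "b"]))
        f = estimate_size_factors(m)
        assert f["sA"] == pytest.approx(1 / np.sqrt(2))
        assert f["sB"] == pytest.approx(np.sqrt(2))

    def test_matches_brute_force_median_of_ratios(self):
        arr = np.array([[21, 10, 7], [29, 6, 10], [19, 23, 19], [26, 2, 12], [17, 13, 12]])
        m = CountMatrix(pd.DataFrame(arr, index=list("abcde"), columns=["s1", "s2", "s3"]))
        f = estimate_size_factors(m)
        expected = [1.8469147504478327, 0.879483214498968, 0.8669420587837955]
        assert np.allclose(f.to_numpy(), expected, rtol=1e-12)

    def test_scale_equivariance_of_factor_ratios(self):
        # the geometric-mean reference changes too, so equivariance holds for
        # factors relative to an unscaled sample, not in absolute terms
        rng = np.random.default_rng(3)
        arr = rng.integers(1, 100, size=(20, 4))
        m = CountMatrix(pd.DataFrame(arr, columns=list("wxyz")))
        f = estimate_size_factors(m)
        scaled = arr.copy()
        scaled[:, 1] *= 3
        f2 = estimate_size_factors(CountMatrix(pd.DataFrame(scaled, columns=list("wxyz"))))
        assert f2["x"] / f2["w"] == pytest.approx(3 * f["x"] / f["w"])
        # and the scaled sample's factor moves by c^((n-1)/n)
        assert f2["x"] == pytest.approx(3 ** (3 / 4) * f["x"])

    def test_no_usable_gene_raises(self):
        m = CountMatrix(pd.DataFrame({"s1": [0, 5], "s2": [3, 0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="median-of-ratios"):
            estimate_size_factors(m)


class TestDispersion:
    def test_poisson_like_data_hits_floor(self):
        # within-condition variance == mean: moment estimator <= 0, floored
        counts = np.array([[10, 10, 10, 10, 4, 4, 4]])
        matrix, design = make_cell_line(counts, n_treated=4, n_control=3)
        f = pd.Series(1.0, index=matrix.sample_ids)
        alpha = estimate_dispersion(matrix, design, f, "A")
        assert alpha["g0"] == ALPHA_FLOOR

    def test_hand_computed_moment_value(self):
        counts = np.array([[30, 10, 20, 5, 25, 15]])
        matrix, design = make_cell_line(counts, n_treated=3, n_control=3)
        f = pd.Series(1.0, index=matrix.sample_ids)
        alpha = estimate_dispersion(matrix, design, f, "A")
        # by hand: m = 17.5, pooled within-condition v = 400/4 = 100,
        # shot noise z = m (unit factors), alpha = (100 - 17.5) / 17.5^2
        assert alpha["g0"] == pytest.approx((100 - 17.5) / 17.5**2, rel=1e-12)

    def test_all_zero_gene_gets_floor(self):
        counts = np.zeros((1, 6), dtype=int)
        matrix, design = make_cell_line(counts, n_treated=3, n_control=3)
        f = pd.Series(1.0, index=matrix.sample_ids)
        assert estimate_dispersion(matrix, design, f, "A")["g0"] == ALPHA_FLOOR

    def test_single_replicate_condition_rejected(self):
        counts = np.ones((1, 3), dtype=int)
        matrix, design = make_cell_line(counts, n_treated=2, n_control=1)
        f = pd.Series(1.0, index=matrix.sample_ids)
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersion(matrix, design, f, "A")


class TestNBExactTest:
    def test_all_zero_groups_give_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], [1, 1], [1, 1], 0.1) == 1.0

    def test_symmetric_under_group_swap(self):
        p1 = nb_exact_test([9, 4, 6], [1, 0], [1, 1, 1], [1, 1], 0.2)
        p2 = nb_exact_test([1, 0], [9, 4, 6], [1, 1], [1, 1, 1], 0.2)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_frozen_small_enumeration(self):
        # K = 6 split 5|1 between equal-size groups, unit factors, alpha 0.1
        p = nb_exact_test([3, 1, 1], [1, 0, 0], [1, 1, 1], [1, 1, 1], 0.1)
        assert p == pytest.approx(0.24142797093616755, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([-1, 2], [1, 1], [1, 1], [1, 1], 0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([], [1, 1], [], [1, 1], 0.1)

    def test_matches_enumeration_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            na, nb = rng.integers(2, 5, size=2)
            while True:
                ca = rng.integers(0, 8, size=na)
                cb = rng.integers(0, 8, size=nb)
                if ca.sum() + cb.sum() <= 60:
                    break
            sa = rng.uniform(0.5, 2.0, size=na)
            sb = rng.uniform(0.5, 2.0, size=nb)
            alpha = float(rng.uniform(0, 0.5))
            p = nb_exact_test(ca, cb, sa, sb, alpha)
            expected = oracle_nb_exact(ca, cb, sa, sb, alpha)
            assert p == pytest.approx(expected, abs=1e-10)


class TestAdjustBH:
    def test_closed_form_triple(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.4]) == pytest.approx([0.4])

    def test_matches_statsmodels_with_ties(self):
        p = [0.01, 0.04, 0.04, 0.2, 1.0]
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjust_bh(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.0, 0.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_monotone_and_permutation_invariant(self, p):
        p = np.asarray(p)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        rng = np.random.default_rng(0)
        perm = rng.permutation(p.size)
        assert np.allclose(adjust_bh(p[perm]), adj[perm])


class TestRunDE:
    def test_unexpressed_gene_absent_from_results(self):
        counts = np.zeros((2, 9), dtype=int)
        counts[0] = [5, 6, 7, 8, 9, 10, 5, 6, 7]
        counts[1, 0] = 100  # detected in only one replicate
        matrix, design = make_cell_line(counts, n_treated=6, n_control=3)
        res, de = run_de(matrix, design, "A")
        assert list(res["gene_id"]) == ["g0"]

    def test_overwhelming_effect_is_called_de(self):
        rng = np.random.default_rng(5)
        n_bg = 200
        counts = rng.poisson(50, size=(n_bg, 9))
        hit = np.concatenate([rng.poisson(500 * 16, size=6), rng.poisson(500, size=3)])
        counts = np.vstack([counts, hit])
        matrix, design = make_cell_line(counts, n_treated=6, n_control=3)
        res, de = run_de(matrix, design, "A")
        assert f"g{n_bg}" in de
        row = res.set_index("gene_id").loc[f"g{n_bg}"]
        assert row["direction"] == 1.0
        assert row["log2_fold_change"] > 2

    def test_null_type_one_error_calibrated(self):
        cfg = SynthConfig(n_genes=3000, n_cell_lines=1, n_effect_genes=0, seed=23)
        ds = generate_counts(cfg)
        res, de = run_de(ds.matrices["CL01"], ds.designs["CL01"], "CL01")
        frac = (res["p_raw"] < 0.01).mean()
        assert 0.002 <= frac <= 0.02
        assert len(de) == 0

    def test_planted_genes_recovered(self, small_synth):
        ds = small_synth
        res, de = run_de(ds.matrices["CL01"], ds.designs["CL01"], "CL01")
        planted = set(ds.truth.loc[ds.truth.cell_line == "CL01", "gene_id"])
        sens = len(de & planted) / len(planted)
        assert sens >= 0.8

    def test_padj_at_least_praw_and_direction_consistency(self, small_synth):
        ds = small_synth
        res, _ = run_de(ds.matrices["CL01"], ds.designs["CL01"], "CL01")
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
        assert res["p_raw"].between(0, 1, inclusive="right").all()
        up = res["mean_treated"] > res["mean_control"]
        assert (res.loc[up, "direction"] == 1.0).all()
        down = res["mean_treated"] < res["mean_control"]
        assert (res.loc[down, "direction"] == 0.0).all()
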