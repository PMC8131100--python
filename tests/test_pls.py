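"""Stability filtering, behavioural PLS, permutation and bootstrap inference."""

import numpy as np
import pytest

from gemcm.pls import (BehavioralPLS, bootstrap_ratios,
                       permutation_component_test, rank_genes,
                       stability_filter, svd_pls)


class TestStabilityFilter:
    def test_constant_nonzero_parameter_kept(self, rng):
        params = rng.standard_normal((20, 3))
        params[:, 1] = 1.0
        assert 1 in stability_filter(params)

    def test_exactly_zero_parameter_dropped(self, rng):
        params = rng.standard_normal((20, 3))
        params[:, 2] = 0.0
        assert 2 not in stability_filter(params)

    def test_null_retention_rate_calibrated(self, rng):
        # i.i.d. N(0,1) parameters: a 99% CI excludes 0 about 1% of the time
        params = rng.standard_normal((100, 5000))
        kept = stability_filter(params, ci_level=0.99)
        frac = kept.size / 5000
        sd = np.sqrt(0.01 * 0.99 / 5000)
        assert abs(frac - 0.01) < 3 * sd

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            stability_filter(rng.standard_normal((2, 4)))


def _planted(rng, n=200, noise_cols=2):
    driver = rng.standard_normal(n)
    params = np.c_[driver, rng.standard_normal((n, noise_cols))]
    slopes = driver[:, None].copy()
    return params, slopes


class TestSvdPls:
    def test_planted_driver_dominates_first_component(self, rng):
        params, slopes = _planted(rng)
        res = svd_pls(params, slopes)
        assert res.explained_variance[0] > 0.95
        assert np.argmax(np.abs(res.saliences[:, 0])) == 0

    def test_explained_variance_sums_to_one(self, rng):
        res = svd_pls(rng.standard_normal((50, 7)), rng.standard_normal((50, 4)))
        assert res.explained_variance.sum() == pytest.approx(1.0)
        assert res.explained_variance[0] < 1.0

    def test_component_count_bounded_by_smaller_block(self, rng):
        res = svd_pls(rng.standard_normal((40, 9)), rng.standard_normal((40, 5)))
        assert res.n_components == 5

    def test_zero_variance_column_excluded_with_warning(self, rng):
        params = rng.standard_normal((30, 4))
        params[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = svd_pls(params, rng.standard_normal((30, 2)))
        assert res.saliences.shape[0] == 3
        assert 2 not in res.param_indices

    def test_sign_convention_largest_score_loading_positive(self, rng):
        res = svd_pls(rng.standard_normal((60, 6)), rng.standard_normal((60, 3)))
        for c in range(res.n_components):
            j = np.argmax(np.abs(res.score_loadings[:, c]))
            assert res.score_loadings[j, c] > 0


class TestPermutation:
    def test_perfect_association_attains_minimum_pvalue(self, rng):
        params, slopes = _planted(rng)
        p = permutation_component_test(params, slopes, n_perm=999, seed=1)
        assert p[0] == pytest.approx(1.0 / 1000.0)

    def test_pvalues_bounded(self, rng):
        p = permutation_component_test(rng.standard_normal((30, 4)),
                                       rng.standard_normal((30, 2)),
                                       n_perm=99, seed=2)
        assert np.all(p >= 1 / 100) and np.all(p <= 1.0)

    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_component_test(rng.standard_normal((10, 2)),
                                       rng.standard_normal((10, 2)), n_perm=0)

    def test_deterministic_under_seed(self, rng):
        params = rng.standard_normal((25, 3))
        slopes = rng.standard_normal((25, 2))
        a = permutation_component_test(params, slopes, n_perm=200, seed=9)
        b = permutation_component_test(params, slopes, n_perm=200, seed=9)
        assert np.array_equal(a, b)


class TestBootstrap:
    def test_planted_driver_selected(self, rng):
        params, slopes = _planted(rng)
        ratios, selected, _ = bootstrap_ratios(params, slopes, component=0,
                                               n_boot=2000, seed=3)
        assert abs(ratios[0]) > 2.58
        assert 0 in selected

    def test_noise_columns_rarely_selected(self, rng):
        params, slopes = _planted(rng, noise_cols=200)
        _, selected, _ = bootstrap_ratios(params, slopes, component=0,
                                          n_boot=1000, seed=4)
        noise_selected = [j for j in selected if j != 0]
        assert len(noise_selected) / 200 < 0.05

    def test_infinite_threshold_selects_nothing(self, rng):
        params, slopes = _planted(rng)
        _, selected, _ = bootstrap_ratios(params, slopes, component=0,
                                          n_boot=200, seed=5,
                                          threshold=np.inf)
        assert selected.size == 0

    def test_sign_alignment_mode_agrees_on_strong_signal(self, rng):
        params, slopes = _planted(rng)
        r1, _, _ = bootstrap_ratios(params, slopes, n_boot=500, seed=6,
                                    procrustes=True)
        r2, _, _ = bootstrap_ratios(params, slopes, n_boot=500, seed=6,
                                    procrustes=False)
        assert np.sign(r1[0]) == np.sign(r2[0])
        assert abs(r1[0]) > 2.58 and abs(r2[0]) > 2.58


class TestRankGenes:
    _labels = [("gA", "tau", "abeta"), ("gB", "cbf", "tau"),
               ("gC", "tau", "tau")]

    def test_single_selection_single_row(self):
        df = rank_genes(self._labels, np.array([0.1, 0.9, 0.2]),
                        np.array([1.0, 3.5, 1.2]), np.array([1]))
        assert len(df) == 1 and df.loc[0, "gene"] == "gB"

    def test_empty_selection_gives_empty_table(self):
        df = rank_genes(self._labels, np.zeros(3), np.zeros(3),
                        np.array([], dtype=int))
        assert len(df) == 0
        assert list(df.columns) == ["gene", "source_factor", "target_factor",
                                    "salience", "bootstrap_ratio"]

    def test_sorted_by_abs_salience_with_label_tiebreak(self):
        df = rank_genes(self._labels, np.array([-0.5, 0.5, 0.9]),
                        np.array([3.0, 3.0, 4.0]), np.array([0, 1, 2]))
        assert list(df["gene"]) == ["gC", "gA", "gB"]  # tie |0.5| -> gA first


class TestBehavioralPLS:
    def test_end_to_end_planted_driver(self, rng):
        params, slopes = _planted(rng, n=100, noise_cols=5)
        res = BehavioralPLS(params, slopes).fit(n_perm=199, n_boot=500, seed=1)
        assert res.component_pvalues[0] < 0.05
        assert res.tested_component == 0
        assert 0 in res.selected_params

    def test_null_data_usually_skips_bootstrap(self, rng):
        params = rng.standard_normal((40, 4))
        slopes = rng.standard_normal((40, 3))
        res = BehavioralPLS(params, slopes).fit(n_perm=199, n_boot=100, seed=2)
        if res.component_pvalues.min() >= 0.05:
            assert res.bootstrap_ratio is None
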