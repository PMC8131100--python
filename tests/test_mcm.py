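"""Forward model, finite differences and design-matrix construction."""

import numpy as np
import pytest

from gemcm.datatypes import (AlignmentError, Connectome, FactorParameterSet,
                             GeneExpressionTemplate, SimulationUnstableError,
                             SubjectTimeseries, parameter_labels)
from gemcm.mcm import (build_design_matrix, finite_difference_derivatives,
                       r2_score, simulate_forward)


def _make_ts(values, times, n_factors, n_rois):
    return SubjectTimeseries(values, times,
                             [f"f{m}" for m in range(n_factors)],
                             [f"roi{i:03d}" for i in range(n_rois)])


class TestFiniteDifferences:
    def test_vector_length_matches_rois_times_intervals(self, rng):
        # 138 regions, 4 visits -> 414 stacked derivative values
        ts = _make_ts(rng.standard_normal((2, 138, 4)), np.arange(4.0), 2, 138)
        d, left = finite_difference_derivatives(ts, 0)
        assert d.size == 138 * 3 == 414
        assert left.size == d.size and left.max() == 2

    def test_constant_trajectory_gives_zero(self):
        ts = _make_ts(np.ones((2, 5, 3)), np.array([0.0, 1.0, 3.0]), 2, 5)
        d, _ = finite_difference_derivatives(ts, 1)
        assert np.all(d == 0)

    def test_linear_trajectory_gives_slope(self, rng):
        times = np.array([0.0, 0.5, 2.0, 3.5])
        b = rng.standard_normal(6)
        vals = np.empty((1, 6, 4))
        vals[0] = 1.0 + b[:, None] * times[None, :]
        ts = _make_ts(vals, times, 1, 6)
        d, _ = finite_difference_derivatives(ts, 0)
        assert np.allclose(d, np.tile(b, 3))

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            _make_ts(np.ones((1, 2, 3)), np.array([0.0, 1.0, 1.0]), 1, 2)


def _toy_inputs(rng, n_genes=2, n_factors=2, n_rois=3, n_times=3):
    region_ids = [f"roi{i:03d}" for i in range(n_rois)]
    G = rng.standard_normal((n_genes, n_rois))
    G = (G - G.mean(1, keepdims=True)) / G.std(1, keepdims=True)
    template = GeneExpressionTemplate(G, [f"g{k}" for k in range(n_genes)],
                                      region_ids)
    C = np.abs(rng.standard_normal((n_rois, n_rois)))
    C = (C + C.T) / 2
    np.fill_diagonal(C, 0.0)
    conn = Connectome(C, region_ids)
    ts = _make_ts(rng.uniform(0.5, 1.5, (n_factors, n_rois, n_times)),
                  np.arange(float(n_times)), n_factors, n_rois)
    return ts, template, conn


class TestDesignMatrix:
    def test_column_count_at_full_scale_geometry(self, rng):
        # 976 genes x 6 factors -> 5863 columns, 5856 of them gene terms
        ts, template, conn = _toy_inputs(rng, n_genes=976, n_factors=6,
                                         n_rois=4, n_times=2)
        X = build_design_matrix(ts, template, conn, 0)
        assert X.shape == (4, 6 + 976 * 6 + 1)
        assert X.shape[1] == 5863
        assert X.shape[1] - ts.n_factors - 1 == 5856
        labels = parameter_labels(template.gene_ids, ts.factor_names, "f0")
        assert len(labels) == 5863

    def test_empty_gene_block(self, rng):
        ts, _, conn = _toy_inputs(rng, n_genes=1, n_factors=6, n_rois=3)
        template = GeneExpressionTemplate(np.empty((0, 3)), [], ts.region_ids)
        X = build_design_matrix(ts, template, conn, 2)
        assert X.shape[1] == 7

    def test_entries_match_explicit_loop_evaluation(self, rng):
        """Element-by-element oracle: every design entry equals the direct
        evaluation of the model terms by explicit loops."""
        ts, template, conn = _toy_inputs(rng)
        m = 1
        X = build_design_matrix(ts, template, conn, m)
        F, R, T, K = 2, 3, 3, 2
        G, C, S = template.matrix, conn.matrix, ts.values
        for t in range(T - 1):
            for i in range(R):
                row = X[t * R + i]
                for n in range(F):
                    assert row[n] == pytest.approx(S[n, i, t], abs=0)
                for k in range(K):
                    for n in range(F):
                        assert row[F + k * F + n] == pytest.approx(
                            G[k, i] * S[n, i, t], rel=1e-15)
                spread = sum(C[j, i] * (S[m, j, t] - S[m, i, t])
                             for j in range(R) if j != i)
                assert row[-1] == pytest.approx(spread, rel=1e-12)

    def test_region_mismatch_raises_alignment_error(self, rng):
        ts, template, conn = _toy_inputs(rng)
        bad = GeneExpressionTemplate(template.matrix, template.gene_ids,
                                     ["a", "b", "c"])
        with pytest.raises(AlignmentError):
            build_design_matrix(ts, bad, conn, 0)

    def test_deterministic_construction(self, rng):
        ts, template, conn = _toy_inputs(rng)
        X1 = build_design_matrix(ts, template, conn, 0)
        X2 = build_design_matrix(ts, template, conn, 0)
        assert np.array_equal(X1, X2)


class TestSimulateForward:
    def _params(self, rng, F, K, scale=0.1):
        return [FactorParameterSet(scale * rng.standard_normal(F),
                                   scale * rng.standard_normal((K, F)),
                                   scale * abs(rng.standard_normal()),
                                   f"f{m}") for m in range(F)]

    def test_zero_parameters_freeze_state(self, rng):
        ts, template, conn = _toy_inputs(rng)
        params = [FactorParameterSet(np.zeros(2), np.zeros((2, 2)), 0.0, f"f{m}")
                  for m in range(2)]
        s0 = rng.uniform(0.5, 1.5, (2, 3))
        out = simulate_forward(params, s0, np.arange(4.0), template, conn)
        assert np.allclose(out.values, s0[:, :, None])

    def test_symmetric_spreading_conserves_total_signal(self, rng):
        ts, template, conn = _toy_inputs(rng, n_rois=6)
        params = [FactorParameterSet(np.zeros(2), np.zeros((2, 2)), 0.05, f"f{m}")
                  for m in range(2)]
        s0 = rng.uniform(0.5, 1.5, (2, 6))
        out = simulate_forward(params, s0, np.arange(5.0), template, conn)
        totals = out.values.sum(axis=1)  # per factor, per time
        assert np.allclose(totals, totals[:, [0]], atol=1e-10)

    def test_roundtrip_identity_design_times_truth_equals_derivatives(self, rng):
        """Forward-Euler trajectories satisfy derivs = X @ theta exactly."""
        ts, template, conn = _toy_inputs(rng, n_rois=5, n_times=4)
        params = self._params(rng, 2, 2)
        s0 = rng.uniform(0.5, 1.5, (2, 5))
        sim = simulate_forward(params, s0, ts.times, template, conn)
        for m in range(2):
            y, _ = finite_difference_derivatives(sim, m)
            X = build_design_matrix(sim, template, conn, m)
            assert np.abs(X @ params[m].flatten() - y).max() < 1e-8

    def test_parameter_scaling_scales_first_step_derivative(self, rng):
        ts, template, conn = _toy_inputs(rng, n_rois=4, n_times=2)
        params = self._params(rng, 2, 2, scale=0.05)
        s0 = rng.uniform(0.5, 1.5, (2, 4))
        times = np.array([0.0, 1.0])
        base = simulate_forward(params, s0, times, template, conn)
        scaled_params = [FactorParameterSet(3 * p.alpha0, 3 * p.alpha_gene,
                                            3 * p.beta_spread, p.target_factor)
                         for p in params]
        scaled = simulate_forward(scaled_params, s0, times, template, conn)
        d0, _ = finite_difference_derivatives(base, 0)
        d1, _ = finite_difference_derivatives(scaled, 0)
        assert np.allclose(d1, 3 * d0, rtol=1e-12)

    def test_divergence_raises_with_step_index(self, rng):
        ts, template, conn = _toy_inputs(rng)
        params = [FactorParameterSet(50.0 * np.ones(2), np.zeros((2, 2)), 0.0,
                                     f"f{m}") for m in range(2)]
        s0 = np.ones((2, 3))
        with pytest.raises(SimulationUnstableError) as exc:
            simulate_forward(params, s0, np.arange(20.0), template, conn,
                             magnitude_bound=1e3, subject_id="s1")
        assert exc.value.step is not None
        assert exc.value.subject == "s1"


class TestR2:
    def test_perfect_prediction_is_one(self, rng):
        y = rng.standard_normal(50)
        assert r2_score(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self, rng):
        y = rng.standard_normal(50)
        assert r2_score(y, np.full(50, y.mean())) == pytest.approx(0.0)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(r2_score(np.ones(5), np.ones(5)))

    def test_matches_snr_theory_in_monte_carlo(self, rng):
        # R2 -> SNR/(SNR+1) for y = signal + noise at known SNR
        snr = 4.0
        r2s = []
        for _ in range(200):
            signal = rng.standard_normal(300) * np.sqrt(snr)
            y = signal + rng.standard_normal(300)
            r2s.append(r2_score(y, signal))
        assert np.mean(r2s) == pytest.approx(snr / (snr + 1), abs=0.02)
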