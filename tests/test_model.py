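"""Emission densities, mixture CDF, forward-backward and Viterbi against
naive and enumeration oracles."""

import numpy as np
import pytest

from segmix.genome import GenomicInterval
from segmix.model import (
    MixtureEmission,
    ModelParams,
    TransitionModel,
    chunk_log_likelihood,
    emission_log_density,
    emission_log_matrix,
    forward_backward,
    load_params,
    mixture_cdf,
    mixture_quantile,
    save_params,
    viterbi,
)
from segmix.signal_io import ObservationChunk

import helpers


def _chunk_from(values, missing=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if missing is None:
        missing = np.zeros_like(values, dtype=bool)
    return ObservationChunk(
        chunk_id=0,
        interval=GenomicInterval("chr1", 0, values.shape[0]),
        values=values,
        missing=np.asarray(missing, dtype=bool),
    )


class TestEmissionDensity:
    def test_peak_density_one_gives_log_zero(self):
        # Normal with sigma^2 = 1/(2 pi) has peak density exactly 1
        em = MixtureEmission(
            weights=np.ones((1, 1, 1)),
            means=np.array([[[1.7]]]),
            variances=np.array([[1.0 / (2 * np.pi)]]),
        )
        val = emission_log_density(em, 0, [1.7], [False])
        assert val == pytest.approx(0.0, abs=1e-14)

    def test_duplicate_components_collapse_to_single(self):
        em2 = MixtureEmission(
            weights=np.full((1, 1, 2), 0.5),
            means=np.full((1, 1, 2), 0.3),
            variances=np.full((1, 2), 1.2),
        )
        em1 = MixtureEmission(
            weights=np.ones((1, 1, 1)),
            means=np.array([[[0.3]]]),
            variances=np.array([[1.2]]),
        )
        x = [0.9]
        assert emission_log_density(em2, 0, x, [False]) == pytest.approx(
            emission_log_density(em1, 0, x, [False]), abs=1e-13
        )

    def test_all_tracks_missing_contribute_zero(self, rng):
        em = MixtureEmission(
            weights=rng.dirichlet(np.ones(2), size=(2, 3)),
            means=rng.normal(size=(2, 3, 2)),
            variances=rng.uniform(0.5, 1.5, size=(3, 2)),
        )
        assert emission_log_density(em, 1, [np.nan] * 3, [True] * 3) == 0.0

    def test_matches_direct_summation_oracle(self, rng):
        em = MixtureEmission(
            weights=rng.dirichlet(np.ones(3), size=(2, 2)),
            means=rng.normal(0, 2, size=(2, 2, 3)),
            variances=rng.uniform(0.5, 2.0, size=(2, 3)),
        )
        for _ in range(20):
            row = rng.normal(0, 2, size=2)
            miss = rng.random(2) < 0.3
            for label in range(2):
                naive = helpers.naive_emission_density(em, label, row, miss)
                ours = emission_log_density(em, label, np.where(miss, np.nan, row), miss)
                assert ours == pytest.approx(np.log(naive), abs=1e-12)

    def test_non_finite_observed_value_is_an_error(self):
        em = MixtureEmission(np.ones((1, 1, 1)), np.zeros((1, 1, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError, match="non-finite"):
            emission_log_matrix(np.array([[np.inf]]), np.array([[False]]), em)


class TestMixtureCdf:
    @staticmethod
    def _em(rng):
        return MixtureEmission(
            weights=rng.dirichlet(np.ones(3), size=(1, 1)),
            means=rng.normal(0, 2, size=(1, 1, 3)),
            variances=rng.uniform(0.3, 1.5, size=(1, 3)),
        )

    def test_symmetry_at_single_component_mean(self):
        em = MixtureEmission(np.ones((1, 1, 1)), np.array([[[2.0]]]), np.array([[0.7]]))
        assert mixture_cdf(em, 0, 0, 2.0) == pytest.approx(0.5, abs=1e-14)

    def test_limits(self, rng):
        em = self._em(rng)
        assert mixture_cdf(em, 0, 0, -1e6) == pytest.approx(0.0, abs=1e-12)
        assert mixture_cdf(em, 0, 0, 1e6) == pytest.approx(1.0, abs=1e-12)

    def test_against_quadrature_oracle(self, rng):
        em = self._em(rng)
        lo, hi = -25.0, 25.0
        grid = np.linspace(lo, hi, 200_001)
        from scipy.stats import norm

        dens = sum(
            em.weights[0, 0, c]
            * norm.pdf(grid, em.means[0, 0, c], np.sqrt(em.variances[0, c]))
            for c in range(3)
        )
        cdf_grid = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        for x in rng.uniform(-6, 6, size=10):
            expected = np.interp(x, grid, cdf_grid)
            assert mixture_cdf(em, 0, 0, float(x)) == pytest.approx(expected, abs=1e-6)

    def test_quantile_inverts_cdf(self, rng):
        em = self._em(rng)
        for p in (0.01, 0.25, 0.5, 0.9, 0.999):
            x = mixture_quantile(em, 0, 0, p)
            assert mixture_cdf(em, 0, 0, x) == pytest.approx(p, abs=1e-10)

    def test_non_decreasing(self, rng):
        em = self._em(rng)
        xs = np.linspace(-8, 8, 500)
        vals = mixture_cdf(em, 0, 0, xs)
        assert np.all(np.diff(vals) >= 0)


class TestForwardBackward:
    def test_single_label_reduces_to_emission_sum(self, rng):
        params = helpers.random_model(rng, K=1, T=2, C=2)
        chunk = helpers.random_chunk(rng, n=7, T=2, missing_rate=0.2)
        post = forward_backward(chunk, params)
        expected = emission_log_matrix(chunk.values, chunk.missing, params.emission).sum()
        assert post.log_likelihood == pytest.approx(expected, abs=1e-10)
        assert np.allclose(post.gamma, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        params = helpers.random_model(rng, K=2, T=1, C=1, m=1)
        chunk = helpers.random_chunk(rng, n=5, T=1)
        post = forward_backward(chunk, params)
        total, _, _ = helpers.enumerate_chunk(chunk, params)
        assert post.log_likelihood == pytest.approx(total, abs=1e-10)

    def test_symmetric_model_has_uniform_posteriors(self, rng):
        K = 2
        em = MixtureEmission(
            weights=np.ones((K, 1, 1)),
            means=np.zeros((K, 1, 1)),
            variances=np.ones((1, 1)),
        )
        params = ModelParams(
            emission=em,
            transitions=TransitionModel(np.full(K, 0.5), np.full((K, K), 0.5)),
        )
        chunk = helpers.random_chunk(rng, n=6, T=1)
        post = forward_backward(chunk, params)
        assert np.allclose(post.gamma, 0.5, atol=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_posterior_invariants(self, rng, m):
        params = helpers.random_model(rng, K=3, T=2, C=2, m=m)
        chunk = helpers.random_chunk(rng, n=12, T=2, missing_rate=0.15)
        post = forward_backward(chunk, params)
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)
        assert post.xi.sum() == pytest.approx(chunk.n_bins - 1, abs=1e-9)
        assert np.all(post.xi >= -1e-12)
        obs = ~chunk.missing
        sums = post.resp.sum(axis=3)
        for t in range(2):
            assert np.allclose(sums[obs[:, t], :, t], 1.0, atol=1e-9)

    def test_forward_and_backward_likelihoods_agree(self, rng):
        from scipy.special import logsumexp
        from segmix.model import _expand

        params = helpers.random_model(rng, K=3, T=1, C=2, m=2)
        chunk = helpers.random_chunk(rng, n=15, T=1)
        log_pi, log_A, state_label = _expand(params.transitions)
        logB = emission_log_matrix(chunk.values, chunk.missing, params.emission)[:, state_label]
        n, S = logB.shape
        beta = np.zeros(S)
        for i in range(n - 2, -1, -1):
            beta = logsumexp(log_A + (logB[i + 1] + beta)[None, :], axis=1)
        ll_backward = logsumexp(log_pi + logB[0] + beta)
        assert chunk_log_likelihood(chunk, params) == pytest.approx(ll_backward, abs=1e-9)

    def test_matches_reference_gaussian_hmm(self, rng):
        hmm = pytest.importorskip("hmmlearn.hmm")
        K, T = 3, 2
        params = helpers.random_model(rng, K=K, T=T, C=1, m=1)
        chunk = helpers.random_chunk(rng, n=40, T=T)
        ref = hmm.GaussianHMM(n_components=K, covariance_type="diag", init_params="")
        ref.startprob_ = params.transitions.initial
        ref.transmat_ = params.transitions.matrix
        ref.means_ = params.emission.means[:, :, 0]
        ref.covars_ = np.tile(params.emission.variances[:, 0], (K, 1))
        assert chunk_log_likelihood(chunk, params) == pytest.approx(
            ref.score(chunk.values), abs=1e-8
        )


class TestViterbi:
    def test_single_label_constant_path(self, rng):
        params = helpers.random_model(rng, K=1)
        chunk = helpers.random_chunk(rng, n=8)
        path, score = viterbi(chunk, params)
        assert np.all(path == 0)
        assert score <= chunk_log_likelihood(chunk, params) + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_argmax(self, seed):
        rng = np.random.default_rng(100 + seed)
        params = helpers.random_model(rng, K=2, T=1, C=1, m=1)
        chunk = helpers.random_chunk(rng, n=5, T=1)
        path, score = viterbi(chunk, params)
        _, best_score, best_path = helpers.enumerate_chunk(chunk, params)
        assert score == pytest.approx(best_score, abs=1e-10)
        assert np.array_equal(path, best_path)

    @pytest.mark.parametrize("seed", range(10))
    def test_min_length_constraint_holds_in_interior(self, seed):
        rng = np.random.default_rng(200 + seed)
        m = 3
        params = helpers.random_model(rng, K=2, T=1, C=1, m=m)
        chunk = helpers.random_chunk(rng, n=9, T=1)
        path, _ = viterbi(chunk, params)
        runs = helpers._runs(path)
        # interior runs obey the hard minimum; chunk-terminal runs may truncate
        for label, length in runs[1:-1]:
            assert length >= m

    def test_score_never_exceeds_total_likelihood(self, rng):
        for _ in range(5):
            params = helpers.random_model(rng, K=3, T=2, C=2, m=2)
            chunk = helpers.random_chunk(rng, n=20, T=2, missing_rate=0.1)
            _, score = viterbi(chunk, params)
            assert score <= chunk_log_likelihood(chunk, params) + 1e-9


class TestParamsSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        params = helpers.random_model(rng, K=4, T=3, C=2, m=2, L=33.5)
        path = tmp_path / "params.json"
        save_params(params, path)
        back = load_params(path)
        assert np.array_equal(back.emission.weights, params.emission.weights)
        assert np.array_equal(back.emission.means, params.emission.means)
        assert np.array_equal(back.emission.variances, params.emission.variances)
        assert np.array_equal(back.transitions.matrix, params.transitions.matrix)
        assert np.array_equal(back.transitions.initial, params.transitions.initial)
        assert back.transitions.min_length == 2
        assert back.transitions.expected_length == 33.5
        assert back.resolution == params.resolution

    def test_schema_mismatch_is_an_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "something-else/9"}')
        with pytest.raises(ValueError, match="schema"):
            load_params(path)
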