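"""Independent oracles used by the test suite.

Everything here is deliberately naive — per-base expansion, exhaustive
path enumeration, probability-domain (non-log) recursions — so the fast
implementations in segmix are checked against code that shares none of
their numerical machinery.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm

from segmix.genome import GenomicInterval
from segmix.model import MixtureEmission, ModelParams, TransitionModel
from segmix.signal_io import ObservationChunk


# ---------------------------------------------------------------------------
# binning oracle
# ---------------------------------------------------------------------------

def bin_by_base_expansion(intervals, chrom_length: int, resolution: int):
    """Expand (start, end, value) intervals to per-base arrays, then average
    per bin. Returns (values, missing) with NaN for missing bins."""
    base_vals = np.full(chrom_length, np.nan)
    for start, end, value in intervals:
        base_vals[start:end] = value
    n_bins = math.ceil(chrom_length / resolution)
    out = np.full(n_bins, np.nan)
    missing = np.ones(n_bins, dtype=bool)
    for b in range(n_bins):
        window = base_vals[b * resolution:(b + 1) * resolution]
        covered = window[~np.isnan(window)]
        if covered.size:
            out[b] = covered.mean()
            missing[b] = False
    return out, missing


# ---------------------------------------------------------------------------
# emission oracle (naive, probability domain)
# ---------------------------------------------------------------------------

def naive_emission_density(em: MixtureEmission, label: int, row, miss) -> float:
    """Direct product-of-mixture-sums density for one observation row."""
    dens = 1.0
    for t in range(em.n_tracks):
        if miss[t]:
            continue
        mix = 0.0
        for c in range(em.n_components):
            mix += em.weights[label, t, c] * norm.pdf(
                row[t], em.means[label, t, c], np.sqrt(em.variances[t, c])
            )
        dens *= mix
    return dens


def emission_matrix_naive(chunk: ObservationChunk, em: MixtureEmission) -> np.ndarray:
    n = chunk.n_bins
    out = np.empty((n, em.n_labels))
    for i in range(n):
        for l in range(em.n_labels):
            out[i, l] = naive_emission_density(em, l, chunk.values[i], chunk.missing[i])
    return out


# ---------------------------------------------------------------------------
# path enumeration oracle
# ---------------------------------------------------------------------------

def _runs(seq):
    runs = []
    for label in seq:
        if runs and runs[-1][0] == label:
            runs[-1][1] += 1
        else:
            runs.append([label, 1])
    return runs


def path_log_prior(seq, trans: TransitionModel) -> float:
    """Log prior of a label sequence under the duration-phase semantics.

    The first run is entered in its final phase (chunk-start relaxation);
    every later run enters at phase 0, spends its first min(d-1, m-1)
    steps in deterministic advances, then dwells. A run followed by
    another must have completed its m phases, so interior runs shorter
    than m are impossible (log prior -inf); the last run may be truncated
    by the chunk end.
    """
    pi, A, m = trans.initial, trans.matrix, trans.min_length
    runs = _runs(seq)
    lp = math.log(pi[runs[0][0]]) if pi[runs[0][0]] > 0 else -math.inf
    for ri, (label, d) in enumerate(runs):
        entered_final = ri == 0
        dwell_steps = d - 1 if entered_final else max(d - 1 - (m - 1), 0)
        if dwell_steps:
            lp += dwell_steps * (math.log(A[label, label]) if A[label, label] > 0 else -math.inf)
        if ri < len(runs) - 1:
            if not entered_final and d < m:
                return -math.inf
            nxt = runs[ri + 1][0]
            lp += math.log(A[label, nxt]) if A[label, nxt] > 0 else -math.inf
    return lp


def enumerate_chunk(chunk: ObservationChunk, params: ModelParams):
    """Brute-force marginal log-likelihood, best path and best score."""
    K = params.n_labels
    n = chunk.n_bins
    dens = emission_matrix_naive(chunk, params.emission)
    with np.errstate(divide="ignore"):
        log_dens = np.log(dens)
    total = -math.inf
    best_score = -math.inf
    best_path = None
    for seq in itertools.product(range(K), repeat=n):
        lp = path_log_prior(seq, params.transitions)
        if lp == -math.inf:
            continue
        score = lp + sum(log_dens[i, seq[i]] for i in range(n))
        total = np.logaddexp(total, score)
        if score > best_score:
            best_score = score
            best_path = np.array(seq)
    return total, best_score, best_path


# ---------------------------------------------------------------------------
# naive forward-backward (probability domain, m=1 only)
# ---------------------------------------------------------------------------

def naive_posteriors(chunk: ObservationChunk, params: ModelParams):
    """Plain-chain forward-backward without scaling or logs (small chunks).

    Returns (log_likelihood, gamma, component responsibilities r) where
    r[i, l, t, c] is the posterior component probability for an observed
    cell given the label.
    """
    assert params.transitions.min_length == 1
    em, trans = params.emission, params.transitions
    K = params.n_labels
    n = chunk.n_bins
    B = emission_matrix_naive(chunk, em)
    alpha = np.zeros((n, K))
    alpha[0] = trans.initial * B[0]
    for i in range(1, n):
        alpha[i] = (alpha[i - 1] @ trans.matrix) * B[i]
    beta = np.zeros((n, K))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta[i] = trans.matrix @ (B[i + 1] * beta[i + 1])
    lik = alpha[-1].sum()
    gamma = alpha * beta / lik
    T, C = em.n_tracks, em.n_components
    r = np.zeros((n, K, T, C))
    for i in range(n):
        for l in range(K):
            for t in range(T):
                if chunk.missing[i, t]:
                    r[i, l, t] = em.weights[l, t]
                    continue
                comp = em.weights[l, t] * norm.pdf(
                    chunk.values[i, t], em.means[l, t], np.sqrt(em.variances[t])
                )
                r[i, l, t] = comp / comp.sum()
    return math.log(lik), gamma, r


# ---------------------------------------------------------------------------
# TSS overlap oracle
# ---------------------------------------------------------------------------

def tss_overlap_bruteforce(annotation, positions):
    """Label overlapping each single-base position, by scanning every
    segment; None when no segment covers it."""
    out = []
    for iv in positions:
        hit = None
        for seg, label in annotation.segments:
            if seg.chrom == iv.chrom and seg.start <= iv.start < seg.end:
                hit = label
                break
        out.append(hit)
    return out


# ---------------------------------------------------------------------------
# random model/chunk factories
# ---------------------------------------------------------------------------

def random_model(rng, K=2, T=1, C=1, m=1, L=10.0) -> ModelParams:
    means = rng.normal(0.0, 3.0, size=(K, T, C))
    variances = rng.uniform(0.4, 2.0, size=(T, C))
    weights = rng.dirichlet(np.ones(C) * 2.0, size=(K, T))
    pi = rng.dirichlet(np.ones(K) * 2.0)
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    return ModelParams(
        emission=MixtureEmission(weights, means, variances),
        transitions=TransitionModel(pi, A, expected_length=L, min_length=m),
        resolution=1,
    )


def random_chunk(rng, n=5, T=1, missing_rate=0.0, chunk_id=0) -> ObservationChunk:
    values = rng.normal(0.0, 2.0, size=(n, T))
    missing = rng.random((n, T)) < missing_rate
    values = values.copy()
    values[missing] = np.nan
    return ObservationChunk(
        chunk_id=chunk_id,
        interval=GenomicInterval("chr1", 0, n),
        values=values,
        missing=missing,
    )
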