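"""The segmentation model and exact chunk-level inference.

Each hidden label ``l`` emits, independently per track ``t``, a value from
a Gaussian mixture with ``C`` components: weights ``w[l,t,c]`` and means
``mu[l,t,c]`` are free per (label, track) pair, while the variances
``sigma2[t,c]`` are tied across labels — there are C mean parameters per
track-label pair and C variances per track. Missing cells are marginalized
out (they contribute nothing to the emission density), so tracks with
uneven coverage are handled without imputation.

Segment lengths are geometric with two extra constraints layered on top:

* a *hard* minimum length ``m`` (bins), enforced structurally by expanding
  each label into ``m`` duration phases — entry at phase 0, deterministic
  advance to phase ``m-1``, and only the final phase may switch label;
* a *soft* expected length ``L`` (bins), expressed as the self-transition
  probability ``1 - 1/L`` of the final phase at initialization (and
  optionally as a prior during training).

The hard constraint is relaxed at chunk boundaries: the chain starts in
the final phase (so the first segment of a chunk may be truncated) and may
end mid-phase, so chunked inference composes over the genome.

All inference is in the natural-log domain; densities use log-sum-exp and
no intermediate can underflow to a hard zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .signal_io import ObservationChunk

__all__ = [
    "MixtureEmission",
    "TransitionModel",
    "ModelParams",
    "ChunkPosteriors",
    "emission_log_density",
    "emission_log_matrix",
    "mixture_cdf",
    "mixture_quantile",
    "forward_backward",
    "viterbi",
    "save_params",
    "load_params",
]

PARAMS_SCHEMA = "segmix-params/1"

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MixtureEmission:
    """Per-label Gaussian-mixture emissions with label-tied variances.

    weights : (K, T, C), rows over components sum to 1
    means   : (K, T, C) in signal units
    variances : (T, C), shared across labels, all >= some positive floor
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if self.weights.shape != self.means.shape:
            raise ValueError("weights and means shapes differ")
        if self.variances.shape != self.weights.shape[1:]:
            raise ValueError("variances must be (T, C)")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if not np.allclose(self.weights.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("mixture weights must sum to 1 per (label, track)")

    @property
    def n_labels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.weights.shape[1]

    @property
    def n_components(self) -> int:
        return self.weights.shape[2]

    def copy(self) -> "MixtureEmission":
        return MixtureEmission(self.weights.copy(), self.means.copy(), self.variances.copy())


@dataclass
class TransitionModel:
    """Label-level Markov dynamics plus length-constraint settings.

    ``matrix[l, l']`` is the probability, when label ``l`` is free to move
    (its hard minimum satisfied), of the next bin carrying ``l'``; the
    diagonal is the geometric dwell probability. ``expected_length`` is the
    soft constraint L (dwell initialized to 1 - 1/L) and ``min_length`` the
    hard minimum m in bins.
    """

    initial: np.ndarray      # (K,)
    matrix: np.ndarray       # (K, K)
    expected_length: float = 100.0
    min_length: int = 1

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        K = self.initial.shape[0]
        if self.matrix.shape != (K, K):
            raise ValueError("transition matrix must be K x K")
        if abs(self.initial.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.expected_length < 1:
            raise ValueError("expected_length must be >= 1")

    @property
    def n_labels(self) -> int:
        return self.initial.shape[0]

    def copy(self) -> "TransitionModel":
        return TransitionModel(
            self.initial.copy(), self.matrix.copy(), self.expected_length, self.min_length
        )


@dataclass
class ModelParams:
    """Full model: emissions, transitions, and the genomic resolution."""

    emission: MixtureEmission
    transitions: TransitionModel
    resolution: int = 1
    track_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.emission.n_labels != self.transitions.n_labels:
            raise ValueError("emission and transition label counts differ")
        if self.track_names is not None and len(self.track_names) != self.emission.n_tracks:
            raise ValueError("track_names length does not match emission tracks")

    @property
    def n_labels(self) -> int:
        return self.emission.n_labels

    @property
    def n_tracks(self) -> int:
        return self.emission.n_tracks

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.emission.copy(), self.transitions.copy(), self.resolution, self.track_names
        )


@dataclass
class ChunkPosteriors:
    """E-step sufficient statistics for one chunk.

    log_likelihood : exact marginal log-probability of the chunk (nats)
    gamma : (n, K) per-bin label posteriors, rows sum to 1
    xi : (K, K) expected label-transition counts over all n-1 steps
    trans_counts : (K, K) expected counts of *free* transitions only
        (final-phase dwell on the diagonal, switches off it) — the
        statistics the transition M-step uses; deterministic phase
        advances are excluded
    resp : (n, K, T, C) component responsibilities conditional on the
        label, summing to 1 over components for observed cells (prior
        weights are substituted for missing cells)
    """

    log_likelihood: float
    gamma: np.ndarray
    xi: np.ndarray
    trans_counts: np.ndarray
    resp: np.ndarray


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------

def _component_logpdf(values: np.ndarray, em: MixtureEmission) -> np.ndarray:
    """(n, K, T, C) log N(x_it ; mu[l,t,c], sigma2[t,c]) with NaN where x is NaN."""
    x = values[:, None, :, None]                   # (n, 1, T, 1)
    mu = em.means[None, :, :, :]                   # (1, K, T, C)
    var = em.variances[None, None, :, :]           # (1, 1, T, C)
    return -0.5 * (_LOG2PI + np.log(var) + (x - mu) ** 2 / var)


def emission_log_matrix(
    values: np.ndarray, missing: np.ndarray, em: MixtureEmission
) -> np.ndarray:
    """Per-bin per-label emission log density, (n, K).

    Sum over observed tracks of ``log sum_c w[l,t,c] N(x_t; mu, sigma2)``;
    missing tracks contribute 0 (marginalized under conditional
    independence across tracks).
    """
    values = np.asarray(values, dtype=np.float64)
    missing = np.asarray(missing, dtype=bool)
    if values.ndim != 2 or values.shape != missing.shape:
        raise ValueError("values and missing must be matching (bins, T) matrices")
    if values.shape[1] != em.n_tracks:
        raise ValueError("track count mismatch")
    if np.any(~np.isfinite(values) & ~missing):
        raise ValueError("non-finite observed value in chunk")
    safe = np.where(missing, 0.0, values)
    lp = _component_logpdf(safe, em) + np.log(em.weights)[None]   # (n,K,T,C)
    per_track = logsumexp(lp, axis=3)                             # (n,K,T)
    per_track = np.where(missing[:, None, :], 0.0, per_track)
    return per_track.sum(axis=2)


def emission_log_density(
    em: MixtureEmission, label: int, values: np.ndarray, missing: np.ndarray
) -> float:
    """Log emission density of one observation row under one label."""
    if not (0 <= label < em.n_labels):
        raise IndexError(f"label {label} out of range")
    mat = emission_log_matrix(
        np.atleast_2d(np.asarray(values, dtype=np.float64)),
        np.atleast_2d(np.asarray(missing, dtype=bool)),
        em,
    )
    return float(mat[0, label])


def mixture_cdf(em: MixtureEmission, label: int, track: int, x) -> np.ndarray | float:
    """CDF of the label's mixture on one track: sum_c w_c Phi((x-mu_c)/sigma_c)."""
    if not (0 <= label < em.n_labels):
        raise IndexError(f"label {label} out of range")
    if not (0 <= track < em.n_tracks):
        raise IndexError(f"track {track} out of range")
    xs = np.asarray(x, dtype=np.float64)
    w = em.weights[label, track]
    mu = em.means[label, track]
    sd = np.sqrt(em.variances[track])
    out = (w * norm.cdf((xs[..., None] - mu) / sd)).sum(axis=-1)
    return float(out) if np.isscalar(x) else out


def mixture_quantile(em: MixtureEmission, label: int, track: int, p: float) -> float:
    """Inverse of :func:`mixture_cdf` by bracketed root finding."""
    from scipy.optimize import brentq

    if not (0.0 < p < 1.0):
        raise ValueError("quantile probability must lie in (0, 1)")
    mu = em.means[label, track]
    sd = np.sqrt(em.variances[track])
    lo = float((mu - 10 * sd).min())
    hi = float((mu + 10 * sd).max())
    while mixture_cdf(em, label, track, lo) > p:
        lo -= 10 * float(sd.max())
    while mixture_cdf(em, label, track, hi) < p:
        hi += 10 * float(sd.max())
    return float(brentq(lambda v: mixture_cdf(em, label, track, v) - p, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# phase expansion
# ---------------------------------------------------------------------------

def _expand(trans: TransitionModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand label dynamics into the phase state space.

    Returns (log_pi, log_A, state_label): state ``l*m + p`` is label ``l``
    in duration phase ``p``. Initial mass sits on final phases so a chunk's
    first segment may be shorter than the hard minimum.
    """
    K, m = trans.n_labels, trans.min_length
    S = K * m
    log_A = np.full((S, S), -np.inf)
    with np.errstate(divide="ignore"):
        logM = np.log(trans.matrix)
        log_pi_label = np.log(trans.initial)
    entry_phase = 0 if m > 1 else m - 1
    for l in range(K):
        for p in range(m - 1):
            log_A[l * m + p, l * m + p + 1] = 0.0     # deterministic advance
        final = l * m + (m - 1)
        log_A[final, final] = logM[l, l]
        for l2 in range(K):
            if l2 != l:
                log_A[final, l2 * m + entry_phase] = logM[l, l2]
    log_pi = np.full(S, -np.inf)
    log_pi[(np.arange(K) * m) + (m - 1)] = log_pi_label
    state_label = np.repeat(np.arange(K), m)
    return log_pi, log_A, state_label


def _check_chunk(chunk: ObservationChunk, params: ModelParams) -> None:
    if chunk.values.shape[1] != params.n_tracks:
        raise ValueError("chunk track count does not match model")


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------

def _log_matvec(u_log: np.ndarray, A: np.ndarray) -> np.ndarray:
    """logsumexp_j(u_log[j] + log A[j, s]) via one exp/matvec/log round.

    Exact log-domain recursion step: states more than ~700 nats below the
    running maximum underflow to -inf, exactly as plain log-sum-exp would
    treat them.
    """
    m = u_log.max()
    if m == -np.inf:
        return np.full(A.shape[1], -np.inf)
    with np.errstate(divide="ignore"):
        return np.log(np.exp(u_log - m) @ A) + m


def forward_backward(chunk: ObservationChunk, params: ModelParams) -> ChunkPosteriors:
    """Exact E-step for one chunk: marginal likelihood, label posteriors,
    expected transition counts, and component responsibilities."""
    _check_chunk(chunk, params)
    em, trans = params.emission, params.transitions
    K, m = em.n_labels, trans.min_length
    logB_label = emission_log_matrix(chunk.values, chunk.missing, em)  # (n, K)
    n = logB_label.shape[0]
    log_pi, log_A, state_label = _expand(trans)
    S = log_A.shape[0]
    logB = logB_label[:, state_label]                                  # (n, S)
    with np.errstate(divide="ignore"):
        A = np.exp(log_A)
        A_T = A.T.copy()

    alpha = np.empty((n, S))
    alpha[0] = log_pi + logB[0]
    for i in range(1, n):
        alpha[i] = _log_matvec(alpha[i - 1], A) + logB[i]
    log_lik = float(logsumexp(alpha[-1]))
    if not np.isfinite(log_lik):
        raise FloatingPointError("non-finite chunk log-likelihood")

    beta = np.empty((n, S))
    beta[-1] = 0.0
    # accumulate expected phase-state transition counts during the
    # backward sweep: xi_s[j, s] = sum_i exp(alpha_i + logA + v_{i+1} - ll)
    xi_s = np.zeros((S, S))
    for i in range(n - 2, -1, -1):
        v = logB[i + 1] + beta[i + 1]
        beta[i] = _log_matvec(v, A_T)
        am, vm = alpha[i].max(), v.max()
        scale = np.exp(am + vm - log_lik)
        xi_s += np.outer(np.exp(alpha[i] - am), np.exp(v - vm)) * A * scale

    log_gamma_s = alpha + beta - log_lik
    gamma_s = np.exp(log_gamma_s)
    gamma = np.zeros((n, K))
    for l in range(K):
        gamma[:, l] = gamma_s[:, l * m:(l + 1) * m].sum(axis=1)

    xi = np.zeros((K, K))
    trans_counts = np.zeros((K, K))
    finals = (np.arange(K) * m) + (m - 1)
    for l in range(K):
        block_l = slice(l * m, (l + 1) * m)
        for l2 in range(K):
            block_l2 = slice(l2 * m, (l2 + 1) * m)
            xi[l, l2] = xi_s[block_l, block_l2].sum()
            if l2 != l:
                trans_counts[l, l2] = xi_s[finals[l], block_l2].sum()
        trans_counts[l, l] = xi_s[finals[l], finals[l]]

    # component responsibilities conditional on the label (prior for missing)
    safe = np.where(chunk.missing, 0.0, chunk.values)
    lp = _component_logpdf(safe, em) + np.log(em.weights)[None]        # (n,K,T,C)
    lp -= logsumexp(lp, axis=3, keepdims=True)
    resp = np.exp(lp)
    resp = np.where(chunk.missing[:, None, :, None], em.weights[None], resp)

    return ChunkPosteriors(
        log_likelihood=log_lik, gamma=gamma, xi=xi, trans_counts=trans_counts, resp=resp
    )


def chunk_log_likelihood(chunk: ObservationChunk, params: ModelParams) -> float:
    """Forward-pass marginal log-likelihood of one chunk (nats)."""
    _check_chunk(chunk, params)
    em, trans = params.emission, params.transitions
    logB_label = emission_log_matrix(chunk.values, chunk.missing, em)
    log_pi, log_A, state_label = _expand(trans)
    logB = logB_label[:, state_label]
    with np.errstate(divide="ignore"):
        A = np.exp(log_A)
    alpha = log_pi + logB[0]
    for i in range(1, logB.shape[0]):
        alpha = _log_matvec(alpha, A) + logB[i]
    ll = float(logsumexp(alpha))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite chunk log-likelihood")
    return ll


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def viterbi(chunk: ObservationChunk, params: ModelParams) -> tuple[np.ndarray, float]:
    """Most probable label path for one chunk and its log-score.

    The hard minimum-length constraint holds in the interior of the chunk
    and is relaxed at both edges. Ties are broken toward the lowest state
    (hence lowest label) index.
    """
    _check_chunk(chunk, params)
    em, trans = params.emission, params.transitions
    m = trans.min_length
    logB_label = emission_log_matrix(chunk.values, chunk.missing, em)
    n = logB_label.shape[0]
    log_pi, log_A, state_label = _expand(trans)
    S = log_A.shape[0]
    logB = logB_label[:, state_label]

    delta = log_pi + logB[0]
    back = np.zeros((n, S), dtype=np.int64)
    for i in range(1, n):
        scores = delta[:, None] + log_A
        back[i] = np.argmax(scores, axis=0)
        delta = scores[back[i], np.arange(S)] + logB[i]
    last = int(np.argmax(delta))
    score = float(delta[last])
    states = np.empty(n, dtype=np.int64)
    states[-1] = last
    for i in range(n - 1, 0, -1):
        states[i - 1] = back[i, states[i]]
    path = state_label[states]
    return path, score


# ---------------------------------------------------------------------------
# parameter serialization
# ---------------------------------------------------------------------------

def save_params(params: ModelParams, path) -> None:
    """Serialize to a human-readable versioned JSON document (lossless)."""
    doc = {
        "schema": PARAMS_SCHEMA,
        "num_labels": params.n_labels,
        "num_tracks": params.n_tracks,
        "num_components": params.emission.n_components,
        "resolution": params.resolution,
        "track_names": list(params.track_names) if params.track_names else None,
        "emission": {
            "weights": params.emission.weights.tolist(),
            "means": params.emission.means.tolist(),
            "variances": params.emission.variances.tolist(),
        },
        "transitions": {
            "initial": params.transitions.initial.tolist(),
            "matrix": params.transitions.matrix.tolist(),
            "expected_length": params.transitions.expected_length,
            "min_length": params.transitions.min_length,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_params(path) -> ModelParams:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != PARAMS_SCHEMA:
        raise ValueError(
            f"{path}: unsupported parameter schema {doc.get('schema')!r} "
            f"(expected {PARAMS_SCHEMA})"
        )
    em = MixtureEmission(
        weights=np.array(doc["emission"]["weights"]),
        means=np.array(doc["emission"]["means"]),
        variances=np.array(doc["emission"]["variances"]),
    )
    tr = TransitionModel(
        initial=np.array(doc["transitions"]["initial"]),
        matrix=np.array(doc["transitions"]["matrix"]),
        expected_length=doc["transitions"]["expected_length"],
        min_length=doc["transitions"]["min_length"],
    )
    names = doc.get("track_names")
    return ModelParams(
        emission=em,
        transitions=tr,
        resolution=doc["resolution"],
        track_names=tuple(names) if names else None,
    )
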