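"""EM training with fixed-region or minibatch regimes.

Fixed-region training runs EM on one region set per instance, so its
training likelihood increases monotonically but the parameters can
overfit that region. Minibatch training draws a fresh random region set
every round; convergence is no longer guaranteed, so after every round
the likelihood of the updated parameters is evaluated on a held-out
validation set of whole chunks, and the final parameters are taken from
the (instance, round) pair with the highest validation likelihood — not
necessarily the last round.

Likelihoods are reported per bin (nats/bin) so rounds with differently
sized region sets and the validation set are directly comparable.

The M-step is exact maximum likelihood by default: means are
responsibility-weighted averages per (label, track, component), variances
are pooled across labels per (track, component) and floored, weights come
from responsibilities, and transitions from expected free-transition
counts. Optional Dirichlet pseudocounts on weights and a prior pulling
the dwell probability toward ``1 - 1/L`` are available (both default to
zero, keeping fixed-regime EM monotone in the data likelihood; labels or
components that lose all responsibility are instead revived by a
deterministic re-seeding perturbation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    MixtureEmission,
    ModelParams,
    TransitionModel,
    forward_backward,
    chunk_log_likelihood,
)
from .rng import child_rng
from .signal_io import ObservationChunk, ObservationStore, split_validation

__all__ = [
    "TrainingConfig",
    "TraceRow",
    "TrainingTrace",
    "sample_minibatch",
    "em_round",
    "validation_loglik",
    "initialize_params",
    "train",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR_FACTOR = 1e-4   # times the global per-track data variance


@dataclass
class TrainingConfig:
    """Everything a training run needs besides the data.

    ``training_fraction`` is the fraction of genome bins used per round
    (minibatch) or per instance (fixed); ``validation_fraction`` is held
    out from training entirely. ``convergence_tol`` stops a fixed-regime
    instance early once the relative training-likelihood change stays
    below it for two consecutive rounds. ``em_iterations`` is the number
    of E-M sweeps a round spends on its region set (exact EM either way;
    more sweeps converge small-fraction training in fewer rounds).
    """

    num_labels: int = 10
    num_components: int = 1
    regime: str = "minibatch"          # "minibatch" | "fixed"
    training_fraction: float = 0.01
    validation_fraction: float = 0.015
    max_rounds: int = 100
    num_instances: int = 1
    seed: int = 0
    min_length: int = 1
    expected_length: float = 100.0
    convergence_tol: float = 1e-5
    em_iterations: int = 5
    weight_pseudocount: float = 0.0
    transition_prior: float = 0.0
    freeze_variance: bool = False

    def __post_init__(self) -> None:
        if self.regime not in ("minibatch", "fixed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        for frac in (self.training_fraction, self.validation_fraction):
            if not (0.0 < frac < 1.0):
                raise ValueError("fractions must lie in (0, 1)")
        if self.max_rounds < 1 or self.num_instances < 1:
            raise ValueError("max_rounds and num_instances must be >= 1")
        if self.em_iterations < 1:
            raise ValueError("em_iterations must be >= 1")
        if self.freeze_variance and self.num_components != 1:
            raise ValueError("freeze_variance applies to single-component emissions only")


@dataclass
class TraceRow:
    instance: int
    round: int
    train_ll_per_bin: float
    validation_ll_per_bin: float
    region_ids: tuple[int, ...]


@dataclass
class TrainingTrace:
    """Per-instance, per-round likelihood record plus the selected winner."""

    rows: list[TraceRow] = field(default_factory=list)
    winner: tuple[int, int] | None = None      # (instance, round)
    winner_validation_ll: float = -np.inf
    aborted_instances: dict[int, str] = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "instance": [r.instance for r in self.rows],
                "round": [r.round for r in self.rows],
                "train_ll_per_bin": [r.train_ll_per_bin for r in self.rows],
                "validation_ll_per_bin": [r.validation_ll_per_bin for r in self.rows],
                "winner": [
                    (r.instance, r.round) == self.winner for r in self.rows
                ],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def instance_rows(self, instance: int) -> list[TraceRow]:
        return [r for r in self.rows if r.instance == instance]


# ---------------------------------------------------------------------------
# region sampling
# ---------------------------------------------------------------------------

def sample_minibatch(
    pool_ids, bin_counts: np.ndarray, fraction: float, total_bins: int,
    rng: np.random.Generator,
) -> tuple[int, ...]:
    """Draw chunks uniformly without replacement until their bin total
    first reaches ``fraction`` of the genome.

    ``pool_ids`` must already exclude every validation chunk. Draws are
    independent across rounds (sampling with replacement across rounds).
    """
    pool_ids = np.asarray(list(pool_ids), dtype=np.int64)
    if pool_ids.size == 0:
        raise ValueError("empty training pool")
    target = fraction * total_bins
    order = rng.permutation(pool_ids.size)
    chosen: list[int] = []
    total = 0
    for j in order:
        if total >= target:
            break
        chosen.append(int(pool_ids[j]))
        total += int(bin_counts[pool_ids[j]])
    return tuple(sorted(chosen))


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _observed_mask(chunk: ObservationChunk) -> np.ndarray:
    return ~chunk.missing


def em_round(
    params: ModelParams,
    regions: list[ObservationChunk],
    *,
    variance_floor: np.ndarray | None = None,
    weight_pseudocount: float = 0.0,
    transition_prior: float = 0.0,
    freeze_variance: bool = False,
    reseed_rng: np.random.Generator | None = None,
) -> tuple[ModelParams, float]:
    """One EM round on a region set.

    Returns the updated parameters and the per-bin training log-likelihood
    of the *input* parameters on these regions (the quantity whose
    monotone increase certifies fixed-regime EM).
    """
    if not regions:
        raise ValueError("em_round needs at least one region chunk")
    em = params.emission
    K, T, C = em.n_labels, em.n_tracks, em.n_components
    if variance_floor is None:
        variance_floor = np.full(T, 1e-12)
    variance_floor = np.asarray(variance_floor, dtype=np.float64)

    s0 = np.zeros((K, T, C))       # sum of gamma * resp
    s1 = np.zeros((K, T, C))       # ... * x
    s2 = np.zeros((K, T, C))       # ... * x^2
    trans_counts = np.zeros((K, K))
    init_counts = np.zeros(K)
    total_ll = 0.0
    total_bins = 0

    for chunk in regions:
        post = forward_backward(chunk, params)
        total_ll += post.log_likelihood
        total_bins += chunk.n_bins
        obs = _observed_mask(chunk)                      # (n, T)
        w = post.gamma[:, :, None, None] * post.resp     # (n,K,T,C)
        w = w * obs[:, None, :, None]
        x = np.where(obs, chunk.values, 0.0)
        s0 += w.sum(axis=0)
        s1 += (w * x[:, None, :, None]).sum(axis=0)
        s2 += (w * (x ** 2)[:, None, :, None]).sum(axis=0)
        trans_counts += post.trans_counts
        init_counts += post.gamma[0]

    train_ll_per_bin = total_ll / total_bins

    # ---- emissions ------------------------------------------------------
    new_means = em.means.copy()
    dead = s0 <= 1e-10
    safe_s0 = np.where(dead, 1.0, s0)
    new_means = np.where(dead, em.means, s1 / safe_s0)

    if freeze_variance:
        new_vars = em.variances.copy()
    else:
        num = s2 - 2.0 * new_means * s1 + (new_means ** 2) * s0   # (K,T,C)
        pooled_num = num.sum(axis=0)                              # (T,C)
        pooled_den = s0.sum(axis=0)
        new_vars = np.where(
            pooled_den > 1e-10, pooled_num / np.maximum(pooled_den, 1e-10), em.variances
        )
        new_vars = np.maximum(new_vars, variance_floor[:, None])

    wc = s0 + weight_pseudocount
    wc_sum = wc.sum(axis=2, keepdims=True)
    new_weights = np.where(wc_sum > 0, wc / np.maximum(wc_sum, 1e-300), em.weights)
    new_weights /= new_weights.sum(axis=2, keepdims=True)

    # revive labels/components that received (almost) no responsibility
    label_mass = s0.sum(axis=(1, 2))
    dead_labels = np.flatnonzero(label_mass <= 1e-8 * max(total_bins, 1))
    if dead_labels.size and reseed_rng is not None:
        live = label_mass > 0
        center = em.means[live].mean(axis=0) if live.any() else em.means.mean(axis=0)
        spread = np.sqrt(np.maximum(new_vars, variance_floor[:, None]))
        for l in dead_labels:
            new_means[l] = center + reseed_rng.normal(0.0, 2.0 * spread)
            new_weights[l] = 1.0 / C
            logger.info("re-seeded label %d after zero responsibility", l)

    # ---- transitions ----------------------------------------------------
    trans = params.transitions
    prior = np.zeros((K, K))
    if transition_prior > 0 and K > 1:
        dwell = 1.0 - 1.0 / trans.expected_length
        prior = np.full((K, K), transition_prior * (1.0 - dwell) / (K - 1))
        np.fill_diagonal(prior, transition_prior * dwell)
    counts = trans_counts + prior
    row = counts.sum(axis=1, keepdims=True)
    new_matrix = np.where(row > 0, counts / np.maximum(row, 1e-300), trans.matrix)
    new_matrix /= new_matrix.sum(axis=1, keepdims=True)
    new_initial = init_counts + 1e-12
    new_initial /= new_initial.sum()

    new_params = ModelParams(
        emission=MixtureEmission(new_weights, new_means, new_vars),
        transitions=TransitionModel(
            new_initial, new_matrix, trans.expected_length, trans.min_length
        ),
        resolution=params.resolution,
        track_names=params.track_names,
    )
    return new_params, float(train_ll_per_bin)


def validation_loglik(params: ModelParams, chunks: list[ObservationChunk]) -> float:
    """Held-out data log-likelihood per bin (nats/bin); a pure function of
    the parameters and the chunk set."""
    total = 0.0
    bins = 0
    for chunk in chunks:
        total += chunk_log_likelihood(chunk, params)
        bins += chunk.n_bins
    if bins == 0:
        raise ValueError("no validation bins")
    return float(total / bins)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _data_summary(store: ObservationStore, pool_ids, cap: int = 200_000):
    """Per-track observed-value sample, variance, and variance floor."""
    T = store.n_tracks
    samples: list[np.ndarray] = []
    for t in range(T):
        vals = []
        n = 0
        for cid in pool_ids:
            chunk = store.chunks[cid]
            obs = chunk.values[~chunk.missing[:, t], t]
            vals.append(obs)
            n += obs.size
            if n >= cap:
                break
        samples.append(np.concatenate(vals) if vals else np.zeros(1))
    variances = np.array([max(float(np.var(s)), 1e-12) for s in samples])
    return samples, variances, VARIANCE_FLOOR_FACTOR * variances


def initialize_params(
    store: ObservationStore, config: TrainingConfig, instance: int,
    samples: list[np.ndarray], track_variances: np.ndarray,
) -> ModelParams:
    """Random-start parameters: component means at jittered data quantiles,
    variances at the per-track data variance, uniform weights, dwell
    probability ``1 - 1/L``."""
    rng = child_rng(config.seed, "init", instance)
    K, C = config.num_labels, config.num_components
    T = store.n_tracks
    means = np.empty((K, T, C))
    for t in range(T):
        q = rng.uniform(0.02, 0.98, size=(K, C))
        jitter = 0.1 * np.sqrt(track_variances[t]) * rng.standard_normal((K, C))
        means[:, t, :] = np.quantile(samples[t], q) + jitter
    variances = np.tile(track_variances[:, None], (1, C))
    weights = np.full((K, T, C), 1.0 / C)
    dwell = 1.0 - 1.0 / config.expected_length
    if K == 1:
        matrix = np.ones((1, 1))
    else:
        matrix = np.full((K, K), (1.0 - dwell) / (K - 1))
        np.fill_diagonal(matrix, dwell)
    return ModelParams(
        emission=MixtureEmission(weights, means, variances),
        transitions=TransitionModel(
            np.full(K, 1.0 / K), matrix, config.expected_length, config.min_length
        ),
        resolution=store.layout.resolution,
        track_names=store.track_names,
    )


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

class InstanceFailure(RuntimeError):
    pass


def train(store: ObservationStore, config: TrainingConfig) -> tuple[ModelParams, TrainingTrace]:
    """Run multi-instance EM training and return the validation winner.

    The validation set is split off once per run; each instance is an
    independent random start. Minibatch instances resample their region
    set every round and always run ``max_rounds``; fixed instances keep
    the region set sampled at round 0 and may stop early on convergence.
    The returned parameters are those of the (instance, round) pair with
    the highest validation log-likelihood across the whole run.
    """
    split = split_validation(store, config.validation_fraction, config.seed)
    val_chunks = store.subset(split.validation_ids)
    pool = np.asarray(split.training_ids, dtype=np.int64)
    bin_counts = store.bin_counts()
    total_bins = int(bin_counts.sum())
    samples, track_vars, floor = _data_summary(store, pool)

    trace = TrainingTrace()
    best_params: ModelParams | None = None

    for instance in range(config.num_instances):
        params = initialize_params(store, config, instance, samples, track_vars)
        fixed_ids: tuple[int, ...] | None = None
        if config.regime == "fixed":
            fixed_ids = sample_minibatch(
                pool, bin_counts, config.training_fraction, total_bins,
                child_rng(config.seed, "fixed", instance),
            )
        prev_ll: float | None = None
        below_tol = 0
        try:
            for rnd in range(1, config.max_rounds + 1):
                if config.regime == "minibatch":
                    region_ids = sample_minibatch(
                        pool, bin_counts, config.training_fraction, total_bins,
                        child_rng(config.seed, "batch", instance, rnd),
                    )
                else:
                    region_ids = fixed_ids  # type: ignore[assignment]
                regions = store.subset(region_ids)
                # a round fits its region set with em_iterations E-M sweeps
                # (still exact EM: monotone in the region-set likelihood);
                # the recorded training likelihood is that of the round's
                # input parameters, as for a single sweep
                params_new, train_ll = em_round(
                    params, regions,
                    variance_floor=floor,
                    weight_pseudocount=config.weight_pseudocount,
                    transition_prior=config.transition_prior,
                    freeze_variance=config.freeze_variance,
                    reseed_rng=child_rng(config.seed, "reseed", instance, rnd),
                )
                for _ in range(config.em_iterations - 1):
                    params_new, _ = em_round(
                        params_new, regions,
                        variance_floor=floor,
                        weight_pseudocount=config.weight_pseudocount,
                        transition_prior=config.transition_prior,
                        freeze_variance=config.freeze_variance,
                        reseed_rng=child_rng(config.seed, "reseed", instance, rnd),
                    )
                val_ll = validation_loglik(params_new, val_chunks)
                if not (np.isfinite(train_ll) and np.isfinite(val_ll)):
                    raise InstanceFailure(
                        f"non-finite likelihood at instance {instance} round {rnd}"
                    )
                trace.rows.append(
                    TraceRow(instance, rnd, train_ll, val_ll, tuple(region_ids))
                )
                if val_ll > trace.winner_validation_ll:
                    trace.winner_validation_ll = val_ll
                    trace.winner = (instance, rnd)
                    best_params = params_new.copy()
                logger.info(
                    "instance %d round %d train %.6f val %.6f",
                    instance, rnd, train_ll, val_ll,
                )
                if config.regime == "fixed" and prev_ll is not None:
                    rel = abs(train_ll - prev_ll) / max(abs(prev_ll), 1e-12)
                    below_tol = below_tol + 1 if rel < config.convergence_tol else 0
                    if below_tol >= 2:
                        params = params_new
                        break
                prev_ll = train_ll
                params = params_new
        except InstanceFailure as exc:
            logger.warning("instance %d aborted: %s", instance, exc)
            trace.aborted_instances[instance] = str(exc)
            continue

    if best_params is None:
        raise RuntimeError("no training instance produced a finite validation likelihood")
    return best_params, trace


def resolve_split(store: ObservationStore, config: TrainingConfig):
    """The validation split a run with this config uses (for callers that
    need to score or annotate on the same partition)."""
    return split_validation(store, config.validation_fraction, config.seed)
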