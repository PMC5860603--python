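"""Ground-truth models and synthetic multi-track genomes.

Everything downstream (training, decoding, evaluation) is exercised on
genomes drawn from a known model: a label path sampled from the
length-constrained Markov dynamics, per-bin track values drawn from the
label's Gaussian mixture, and missing cells injected completely at
random. The generator writes the same text formats the tool consumes
(bedGraph per track, chromosome-sizes TSV, truth BED, parameter JSON), so
round trips through the parsers are part of what the tests cover.

Two named presets mirror experimental designs the model is meant to
expose:

* ``bimodal_params`` — one track whose per-label emission is a
  well-separated two-component mixture, the situation where a
  single-Gaussian emission model is misspecified;
* ``simulate_heterogeneous`` — a block-heterogeneous genome in which each
  chromosome uses only a subset of the labels, so any single fixed
  training region is unrepresentative of held-out regions and minibatch
  sampling has an advantage.

What this emulates and what it does not: bins are conditionally
independent given the label, missingness is uniform, and signal is
stationary within a label — real ChIP-seq/DNase-seq signal has spatial
autocorrelation within segments, mappability structure, and heavy right
tails that these genomes deliberately lack.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .genome import Annotation, GenomeLayout, GenomicInterval
from .model import MixtureEmission, ModelParams, TransitionModel, save_params
from .rng import child_rng
from .signal_io import BinnedGenome, ObservationStore, build_chunks

__all__ = [
    "SimulationSpec",
    "random_params",
    "bimodal_params",
    "simulate_genome",
    "simulate_store",
    "simulate_heterogeneous",
    "write_genome_files",
]


@dataclass
class SimulationSpec:
    """Conditions of a synthetic genome.

    mean_separation is in units of the largest component standard
    deviation: every pair of component means on a track is at least that
    many SDs apart, which makes labels identifiable when >= ~2.
    """

    num_labels: int = 3
    num_tracks: int = 2
    num_components: int = 1
    chrom_lengths: tuple[int, ...] = (1_000_000,)
    resolution: int = 10
    chunk_size: int = 500
    expected_length: float = 50.0
    min_length: int = 1
    mean_separation: float = 3.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.num_labels, self.num_tracks, self.num_components) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mean_separation <= 0:
            raise ValueError("mean_separation must be positive")

    @property
    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))
        return GenomeLayout(
            names, tuple(self.chrom_lengths),
            resolution=self.resolution, chunk_size=self.chunk_size,
        )

    @property
    def track_names(self) -> tuple[str, ...]:
        return tuple(f"track{t}" for t in range(self.num_tracks))


def random_params(spec: SimulationSpec) -> ModelParams:
    """Draw a ground-truth model with well-separated component means.

    Per track, the K*C component means occupy a randomly permuted grid
    with spacing ``mean_separation`` times the largest component SD, so
    pairwise separation meets the spec exactly. Dwell probability is
    1 - 1/L; off-diagonal transitions are uniform.
    """
    rng = child_rng(spec.seed, "truth")
    K, T, C = spec.num_labels, spec.num_tracks, spec.num_components
    variances = rng.uniform(0.5, 1.5, size=(T, C))
    sd_max = float(np.sqrt(variances.max()))
    means = np.empty((K, T, C))
    for t in range(T):
        grid = spec.mean_separation * sd_max * np.arange(K * C, dtype=np.float64)
        grid = grid - grid.mean()
        # components are intensity tiers: within each label, component c=0
        # is the lowest mode, so the label-tied variance sigma2[t,c] always
        # belongs to the same tier of signal
        means[:, t, :] = np.sort(rng.permutation(grid).reshape(K, C), axis=1)
    weights = rng.dirichlet(np.full(C, 5.0), size=(K, T))
    dwell = 1.0 - 1.0 / spec.expected_length
    if K == 1:
        matrix = np.ones((1, 1))
    else:
        matrix = np.full((K, K), (1.0 - dwell) / (K - 1))
        np.fill_diagonal(matrix, dwell)
    emission = MixtureEmission(weights=weights, means=means, variances=variances)
    trans = TransitionModel(
        initial=np.full(K, 1.0 / K),
        matrix=matrix,
        expected_length=spec.expected_length,
        min_length=spec.min_length,
    )
    return ModelParams(
        emission=emission, transitions=trans,
        resolution=spec.resolution, track_names=spec.track_names,
    )


def bimodal_params(spec: SimulationSpec) -> ModelParams:
    """Single-track ground truth with two well-separated modes per label.

    Each of the K labels emits from a balanced two-component mixture whose
    modes interleave with the other labels', giving 2K distinct modes in
    total on one track. With K kept moderate relative to the mode count a
    single-Gaussian emission model cannot devote one label per mode, so
    its per-label fit is visibly worse than a two-component fit.
    """
    rng = child_rng(spec.seed, "truth-bimodal")
    K = spec.num_labels
    variances = np.full((1, 2), 0.5)
    sd_max = float(np.sqrt(variances.max()))
    grid = spec.mean_separation * sd_max * np.arange(2 * K, dtype=np.float64)
    grid = grid - grid.mean()
    means = rng.permutation(grid).reshape(K, 1, 2)
    weights = np.full((K, 1, 2), 0.5)
    weights += rng.uniform(-0.1, 0.1, size=(K, 1, 1))
    weights[..., 1] = 1.0 - weights[..., 0]
    dwell = 1.0 - 1.0 / spec.expected_length
    matrix = np.full((K, K), (1.0 - dwell) / max(K - 1, 1))
    np.fill_diagonal(matrix, dwell)
    if K == 1:
        matrix = np.ones((1, 1))
    emission = MixtureEmission(weights=weights, means=means, variances=variances)
    trans = TransitionModel(
        initial=np.full(K, 1.0 / K), matrix=matrix,
        expected_length=spec.expected_length, min_length=spec.min_length,
    )
    return ModelParams(emission=emission, transitions=trans,
                       resolution=spec.resolution, track_names=("track0",))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_label_path(
    n_bins: int, trans: TransitionModel, rng: np.random.Generator,
    allowed: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a label path of length ``n_bins`` as alternating runs.

    A run entered mid-sequence lasts at least ``min_length`` bins (hard
    constraint) plus a geometric number of extra dwells; the first run is
    entered in its final phase, so only the geometric part applies.
    ``allowed`` optionally restricts the label alphabet (transition rows
    are renormalized on it).
    """
    K = trans.n_labels
    labels = np.arange(K)
    if allowed is None:
        allowed = labels
    allowed = np.asarray(allowed)
    init = trans.initial[allowed]
    init = init / init.sum()
    path = np.empty(n_bins, dtype=np.int64)
    pos = 0
    current = int(allowed[rng.choice(len(allowed), p=init)])
    first = True
    while pos < n_bins:
        dwell = trans.matrix[current, current]
        if dwell >= 1.0:
            path[pos:] = current
            break
        extra = rng.geometric(1.0 - dwell) - 1 if dwell > 0 else 0
        run = (1 if first else trans.min_length) + int(extra)
        run = min(run, n_bins - pos)
        path[pos:pos + run] = current
        pos += run
        first = False
        if pos >= n_bins:
            break
        others = allowed[allowed != current]
        if len(others) == 0:
            run = n_bins - pos
            path[pos:] = current
            break
        probs = trans.matrix[current, others]
        probs = probs / probs.sum()
        current = int(others[rng.choice(len(others), p=probs)])
    return path


def _emit(
    path: np.ndarray, em: MixtureEmission, missing_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw track values for a label path; inject missing cells."""
    n = path.shape[0]
    T, C = em.n_tracks, em.n_components
    values = np.empty((n, T))
    for t in range(T):
        comp = np.empty(n, dtype=np.int64)
        for l in range(em.n_labels):
            idx = np.flatnonzero(path == l)
            if idx.size:
                comp[idx] = rng.choice(C, size=idx.size, p=em.weights[l, t])
        mu = em.means[path, t, comp]
        sd = np.sqrt(em.variances[t, comp])
        values[:, t] = rng.normal(mu, sd)
    missing = rng.random((n, T)) < missing_rate
    values = values.copy()
    values[missing] = np.nan
    return values, missing


def _paths_to_annotation(layout: GenomeLayout, paths: dict[str, np.ndarray]) -> Annotation:
    segments: list[tuple[GenomicInterval, int]] = []
    r = layout.resolution
    for chrom in layout.chrom_names:
        path = paths[chrom]
        length = layout.chrom_length(chrom)
        boundaries = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [path.shape[0]]])
        for b0, b1 in zip(starts, ends):
            segments.append(
                (GenomicInterval(chrom, int(b0) * r, min(int(b1) * r, length)), int(path[b0]))
            )
    return Annotation(segments=segments)


def simulate_genome(
    params: ModelParams, spec: SimulationSpec, *, label_subsets: dict[str, np.ndarray] | None = None
) -> tuple[BinnedGenome, Annotation]:
    """Sample a binned genome and its ground-truth annotation.

    ``label_subsets`` optionally restricts, per chromosome, which labels
    may occur (used by the block-heterogeneous preset).
    """
    layout = spec.layout
    rng = child_rng(spec.seed, "simulate")
    values: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    paths: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        allowed = None if label_subsets is None else label_subsets[chrom]
        path = _sample_label_path(n, params.transitions, rng, allowed=allowed)
        vals, miss = _emit(path, params.emission, spec.missing_rate, rng)
        values[chrom], missing[chrom], paths[chrom] = vals, miss, path
    binned = BinnedGenome(
        layout=layout,
        track_names=params.track_names or spec.track_names,
        values=values, missing=missing,
    )
    return binned, _paths_to_annotation(layout, paths)


def simulate_store(
    params: ModelParams, spec: SimulationSpec, **kw
) -> tuple[ObservationStore, Annotation]:
    """Simulate and chunk in one step (the common in-memory path)."""
    binned, truth = simulate_genome(params, spec, **kw)
    return build_chunks(binned), truth


def simulate_heterogeneous(
    spec: SimulationSpec, blocks: int = 4
) -> tuple[ModelParams, ObservationStore, Annotation]:
    """Block-heterogeneous synthetic genome (one block per chromosome).

    The genome is split into ``blocks`` equal chromosomes; chromosome ``b``
    uses only labels ``{b mod K, (b+1) mod K}``. A fixed training region
    drawn from a few chunks therefore never observes the full label
    repertoire, while held-out chunks span all blocks — the regime
    contrast between minibatch and fixed-region training.
    """
    total = sum(spec.chrom_lengths)
    per = total // blocks
    spec = SimulationSpec(
        num_labels=spec.num_labels, num_tracks=spec.num_tracks,
        num_components=spec.num_components,
        chrom_lengths=tuple([per] * blocks),
        resolution=spec.resolution, chunk_size=spec.chunk_size,
        expected_length=spec.expected_length, min_length=spec.min_length,
        mean_separation=spec.mean_separation, missing_rate=spec.missing_rate,
        seed=spec.seed,
    )
    params = random_params(spec)
    K = spec.num_labels
    subsets = {
        chrom: np.unique(np.array([b % K, (b + 1) % K]))
        for b, chrom in enumerate(spec.layout.chrom_names)
    }
    store, truth = simulate_store(params, spec, label_subsets=subsets)
    return params, store, truth


# ---------------------------------------------------------------------------
# fixture bundle on disk
# ---------------------------------------------------------------------------

def write_genome_files(
    binned: BinnedGenome, truth: Annotation, params: ModelParams, out_dir
) -> dict[str, object]:
    """Write bedGraph per track, chromosome sizes, truth BED and params JSON.

    Missing bins are simply omitted from the bedGraph, which is how real
    coverage gaps present; the files re-read bit-exactly at the same
    resolution.
    """
    from .signal_io import write_bed

    os.makedirs(out_dir, exist_ok=True)
    layout = binned.layout
    r = layout.resolution
    track_paths = []
    for t, name in enumerate(binned.track_names):
        path = os.path.join(out_dir, f"{name}.bedgraph")
        with open(path, "w") as fh:
            for chrom in layout.chrom_names:
                vals = binned.values[chrom][:, t]
                miss = binned.missing[chrom][:, t]
                length = layout.chrom_length(chrom)
                for i in np.flatnonzero(~miss):
                    start = int(i) * r
                    fh.write(f"{chrom}\t{start}\t{min(start + r, length)}\t{float(vals[i])!r}\n")
        track_paths.append(path)
    sizes_path = os.path.join(out_dir, "chrom.sizes")
    with open(sizes_path, "w") as fh:
        for chrom, length in zip(layout.chrom_names, layout.chrom_lengths):
            fh.write(f"{chrom}\t{length}\n")
    truth_path = os.path.join(out_dir, "truth.bed")
    write_bed(truth, truth_path)
    params_path = os.path.join(out_dir, "params.json")
    save_params(params, params_path)
    return {
        "tracks": track_paths, "sizes": sizes_path,
        "truth": truth_path, "params": params_path,
    }
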