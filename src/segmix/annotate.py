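"""Genome-wide Viterbi annotation.

Every chunk is decoded independently with the winning parameters; the
per-bin label paths are concatenated in genome order and runs of equal
labels are merged into maximal segments, including across chunk joins
within a chromosome. The merge is cosmetic — inference is still chunked,
so segment boundaries that coincide with chunk joins are approximate.
"""

from __future__ import annotations

import numpy as np

from .genome import Annotation, GenomicInterval
from .model import ModelParams, viterbi
from .signal_io import BinnedGenome, ObservationStore

__all__ = ["annotate_genome", "label_signal_sample", "paths_from_annotation"]


def annotate_genome(store: ObservationStore, params: ModelParams) -> Annotation:
    """Viterbi-decode every chunk and stitch the paths into segments.

    Every annotatable bin is covered exactly once; consecutive same-label
    runs merge across chunk boundaries within a chromosome.
    """
    if store.layout.resolution != params.resolution:
        raise ValueError("store and model disagree on resolution")
    if params.track_names is not None and tuple(store.track_names) != tuple(params.track_names):
        raise ValueError("store and model disagree on track set")
    layout = store.layout
    expected = layout.chunk_intervals()
    if len(expected) != len(store.chunks):
        raise ValueError("store does not tile its layout (missing chunk)")

    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in layout.chrom_names}
    for chunk, interval in zip(store.chunks, expected):
        if chunk.interval != interval:
            raise ValueError(f"missing or out-of-order chunk at {interval}")
        path, _ = viterbi(chunk, params)
        per_chrom[chunk.interval.chrom].append(path)

    segments: list[tuple[GenomicInterval, int]] = []
    r = layout.resolution
    for chrom in layout.chrom_names:
        path = np.concatenate(per_chrom[chrom])
        length = layout.chrom_length(chrom)
        boundaries = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [path.shape[0]]])
        for b0, b1 in zip(starts, ends):
            segments.append(
                (
                    GenomicInterval(chrom, int(b0) * r, min(int(b1) * r, length)),
                    int(path[b0]),
                )
            )
    ann = Annotation(
        segments=segments,
        label_names={l: str(l) for l in range(params.n_labels)},
    )
    ann.validate()
    return ann


def paths_from_annotation(annotation: Annotation, layout) -> dict[str, np.ndarray]:
    """Inverse of the stitching: per-chromosome per-bin label arrays."""
    r = layout.resolution
    paths = {
        chrom: np.full(layout.n_bins(chrom), -1, dtype=np.int64)
        for chrom in layout.chrom_names
    }
    for interval, label in annotation.segments:
        b0 = interval.start // r
        b1 = b0 + int(np.ceil(len(interval) / r))
        paths[interval.chrom][b0:b1] = label
    return paths


def label_signal_sample(
    annotation: Annotation, binned: BinnedGenome, track: int, label: int
) -> np.ndarray:
    """All non-missing bin values of one track inside segments of ``label``.

    A label with no segments yields an empty sample (not an error) — the
    empirical distribution the per-label goodness-of-fit runs on.
    """
    layout = binned.layout
    r = layout.resolution
    out: list[np.ndarray] = []
    for interval, seg_label in annotation.segments:
        if seg_label != label:
            continue
        b0 = interval.start // r
        b1 = b0 + int(np.ceil(len(interval) / r))
        vals = binned.values[interval.chrom][b0:b1, track]
        miss = binned.missing[interval.chrom][b0:b1, track]
        out.append(vals[~miss])
    if not out:
        return np.empty(0)
    return np.concatenate(out)
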