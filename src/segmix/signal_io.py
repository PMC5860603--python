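"""Signal-track input, binning, chunking, and BED exchange.

Tracks arrive as bedGraph (4 columns) or wiggle (fixedStep/variableStep)
text. Each track is binned onto a :class:`~segmix.genome.GenomeLayout`:
a bin's value is the mean of the base values covering it, and a bin none
of whose bases are covered is missing. Binned tracks are cut into
fixed-size chunks — the unit of all downstream inference — and chunks are
split into a training pool and a held-out validation set by whole chunks,
so training and validation likelihoods use the same inference unit.

The binary observation store (HDF5, one group per chunk, versioned header)
lets a genome be binned once and reused across training runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Annotation, GenomeLayout, GenomicInterval
from .rng import child_rng

__all__ = [
    "BinnedTrack",
    "BinnedGenome",
    "ObservationChunk",
    "ObservationStore",
    "ChunkSplit",
    "read_signal_track",
    "read_tracks",
    "build_chunks",
    "split_validation",
    "read_bed",
    "write_bed",
]

STORE_FORMAT = "segmix-observations"
STORE_VERSION = 1


# ---------------------------------------------------------------------------
# binned containers
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """One track binned on a layout: per-chromosome values and missing mask."""

    layout: GenomeLayout
    values: dict[str, np.ndarray]   # chrom -> (n_bins,) float64
    missing: dict[str, np.ndarray]  # chrom -> (n_bins,) bool


@dataclass
class BinnedGenome:
    """Several tracks binned on a shared layout, stacked bins x tracks."""

    layout: GenomeLayout
    track_names: tuple[str, ...]
    values: dict[str, np.ndarray]   # chrom -> (n_bins, T) float64
    missing: dict[str, np.ndarray]  # chrom -> (n_bins, T) bool


@dataclass
class ObservationChunk:
    """A contiguous run of binned positions x tracks; the unit of inference."""

    chunk_id: int
    interval: GenomicInterval
    values: np.ndarray   # (bins, T) float64; finite wherever not missing
    missing: np.ndarray  # (bins, T) bool

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class ObservationStore:
    """Ordered chunk collection tiling the genome, plus its layout."""

    layout: GenomeLayout
    track_names: tuple[str, ...]
    chunks: list[ObservationChunk] = field(default_factory=list)

    @property
    def n_tracks(self) -> int:
        return len(self.track_names)

    @property
    def total_bins(self) -> int:
        return sum(c.n_bins for c in self.chunks)

    def bin_counts(self) -> np.ndarray:
        return np.array([c.n_bins for c in self.chunks], dtype=np.int64)

    def subset(self, chunk_ids) -> list[ObservationChunk]:
        return [self.chunks[i] for i in chunk_ids]

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as fh:
            fh.attrs["format"] = STORE_FORMAT
            fh.attrs["version"] = STORE_VERSION
            fh.attrs["layout"] = json.dumps(
                {
                    "chrom_names": list(self.layout.chrom_names),
                    "chrom_lengths": list(self.layout.chrom_lengths),
                    "resolution": self.layout.resolution,
                    "chunk_size": self.layout.chunk_size,
                }
            )
            fh.attrs["track_names"] = json.dumps(list(self.track_names))
            grp = fh.create_group("chunks")
            for chunk in self.chunks:
                g = grp.create_group(str(chunk.chunk_id))
                g.attrs["chrom"] = chunk.interval.chrom
                g.attrs["start"] = chunk.interval.start
                g.attrs["end"] = chunk.interval.end
                g.create_dataset("values", data=chunk.values, compression="gzip")
                g.create_dataset("missing", data=chunk.missing, compression="gzip")

    @classmethod
    def load(cls, path) -> "ObservationStore":
        import h5py
        import json

        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != STORE_FORMAT:
                raise ValueError(f"{path}: not a {STORE_FORMAT} file")
            if int(fh.attrs["version"]) != STORE_VERSION:
                raise ValueError(
                    f"{path}: store version {fh.attrs['version']} unsupported "
                    f"(expected {STORE_VERSION})"
                )
            lay = json.loads(fh.attrs["layout"])
            layout = GenomeLayout(
                tuple(lay["chrom_names"]),
                tuple(lay["chrom_lengths"]),
                resolution=lay["resolution"],
                chunk_size=lay["chunk_size"],
            )
            names = tuple(json.loads(fh.attrs["track_names"]))
            chunks = []
            for key in sorted(fh["chunks"], key=int):
                g = fh["chunks"][key]
                chunks.append(
                    ObservationChunk(
                        chunk_id=int(key),
                        interval=GenomicInterval(
                            str(g.attrs["chrom"]), int(g.attrs["start"]), int(g.attrs["end"])
                        ),
                        values=np.asarray(g["values"], dtype=np.float64),
                        missing=np.asarray(g["missing"], dtype=bool),
                    )
                )
        return cls(layout=layout, track_names=names, chunks=chunks)


@dataclass
class ChunkSplit:
    """Disjoint partition of chunk ids into training pool and validation set."""

    training_ids: tuple[int, ...]
    validation_ids: tuple[int, ...]
    validation_fraction: float

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.validation_ids):
            raise ValueError("training and validation chunk sets overlap")


# ---------------------------------------------------------------------------
# track parsing and binning
# ---------------------------------------------------------------------------

def _iter_bedgraph(path):
    """Yield (lineno, chrom, start, end, value) from a bedGraph file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from None
            yield lineno, fields[0], start, end, value


def _iter_wiggle(path):
    """Yield (lineno, chrom, start, end, value) from a wiggle file.

    Wiggle coordinates are 1-based; emitted intervals are 0-based half-open.
    """
    chrom = None
    pos = None      # next 0-based start for fixedStep
    step = span = 1
    mode = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                mode = "fixed" if line.startswith("fixedStep") else "variable"
                kv = dict(f.split("=", 1) for f in line.split()[1:])
                if "chrom" not in kv:
                    raise ValueError(f"{path}:{lineno}: declaration missing chrom=")
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                if mode == "fixed":
                    if "start" not in kv:
                        raise ValueError(f"{path}:{lineno}: fixedStep missing start=")
                    pos = int(kv["start"]) - 1
                    step = int(kv.get("step", 1))
                continue
            if mode is None:
                raise ValueError(f"{path}:{lineno}: data before any step declaration")
            fields = line.split()
            if mode == "fixed":
                if len(fields) != 1:
                    raise ValueError(f"{path}:{lineno}: fixedStep lines hold one value")
                yield lineno, chrom, pos, pos + span, float(fields[0])
                pos += step
            else:
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: variableStep lines hold start value")
                start = int(fields[0]) - 1
                yield lineno, chrom, start, start + span, float(fields[1])


def read_signal_track(path, layout: GenomeLayout) -> BinnedTrack:
    """Read and bin one bedGraph or wiggle track onto ``layout``.

    Each bin's value is the mean of the base values covering it; bases not
    covered by any interval are missing, and a bin all of whose bases are
    missing is missing. Overlapping input intervals are a hard error (they
    would silently change results), as is an interval on an undeclared
    chromosome or beyond its end.
    """
    name = str(path)
    iterator = _iter_wiggle(path) if name.endswith((".wig", ".wiggle")) else _iter_bedgraph(path)

    per_chrom: dict[str, list[tuple[int, int, int, float]]] = {}
    for lineno, chrom, start, end, value in iterator:
        if chrom not in layout.lengths:
            raise ValueError(f"{name}:{lineno}: unknown chromosome {chrom!r}")
        if not (0 <= start < end <= layout.chrom_length(chrom)):
            raise ValueError(
                f"{name}:{lineno}: interval {start}-{end} outside {chrom} bounds"
            )
        if not np.isfinite(value):
            raise ValueError(f"{name}:{lineno}: non-finite signal value")
        per_chrom.setdefault(chrom, []).append((start, end, lineno, value))

    r = layout.resolution
    values: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        n = layout.n_bins(chrom)
        sums = np.zeros(n)
        covered = np.zeros(n, dtype=np.int64)
        n_iv = np.zeros(n, dtype=np.int64)     # intervals touching each bin
        last_val = np.zeros(n)
        prev_end, prev_line = -1, -1
        for start, end, lineno, value in sorted(per_chrom.get(chrom, [])):
            if start < prev_end:
                raise ValueError(
                    f"{name}:{lineno}: interval overlaps line {prev_line} on {chrom}"
                )
            prev_end, prev_line = end, lineno
            b0, b1 = start // r, (end - 1) // r
            if b0 == b1:
                sums[b0] += (end - start) * value
                covered[b0] += end - start
            else:
                head = (b0 + 1) * r - start
                tail = end - b1 * r
                sums[b0] += head * value
                covered[b0] += head
                sums[b1] += tail * value
                covered[b1] += tail
                if b1 - b0 > 1:
                    sums[b0 + 1:b1] += r * value
                    covered[b0 + 1:b1] += r
            n_iv[b0:b1 + 1] += 1
            last_val[b0:b1 + 1] = value
        miss = covered == 0
        vals = np.zeros(n)
        np.divide(sums, covered, out=vals, where=~miss)
        # a bin covered by exactly one interval has mean exactly that value;
        # assign it directly so constant coverage round-trips bit-exactly
        single = n_iv == 1
        vals[single] = last_val[single]
        vals[miss] = np.nan
        values[chrom] = vals
        missing[chrom] = miss
    return BinnedTrack(layout=layout, values=values, missing=missing)


def read_tracks(paths, names, layout: GenomeLayout) -> BinnedGenome:
    """Read several tracks and stack them bins x tracks per chromosome."""
    if len(paths) != len(names):
        raise ValueError("paths and names differ in length")
    tracks = [read_signal_track(p, layout) for p in paths]
    values, missing = {}, {}
    for chrom in layout.chrom_names:
        values[chrom] = np.column_stack([t.values[chrom] for t in tracks])
        missing[chrom] = np.column_stack([t.missing[chrom] for t in tracks])
    return BinnedGenome(layout=layout, track_names=tuple(names), values=values, missing=missing)


# ---------------------------------------------------------------------------
# chunking and splitting
# ---------------------------------------------------------------------------

def build_chunks(binned: BinnedGenome) -> ObservationStore:
    """Cut a binned genome into fixed-size chunks tiling every chromosome.

    Concatenating chunk values in order reproduces the binned matrices
    exactly; no chunk spans a chromosome boundary.
    """
    layout = binned.layout
    chunks: list[ObservationChunk] = []
    for interval in layout.chunk_intervals():
        r = layout.resolution
        b0 = interval.start // r
        b1 = b0 + int(np.ceil(len(interval) / r))
        vals = binned.values[interval.chrom][b0:b1]
        miss = binned.missing[interval.chrom][b0:b1]
        if vals.shape[0] != b1 - b0:
            raise ValueError("track and layout disagree on bin counts")
        chunks.append(
            ObservationChunk(
                chunk_id=len(chunks), interval=interval, values=vals, missing=miss
            )
        )
    return ObservationStore(layout=layout, track_names=binned.track_names, chunks=chunks)


def split_validation(store: ObservationStore, fraction: float, seed: int) -> ChunkSplit:
    """Hold out whole chunks, drawn uniformly without replacement, until
    their bin total first reaches ``fraction`` of the genome.

    Deterministic given ``seed``; the held-out set is excluded from all
    training so per-round likelihoods on it are comparable across regimes.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("validation fraction must lie in (0, 1)")
    n_chunks = len(store.chunks)
    bins = store.bin_counts()
    target = fraction * bins.sum()
    order = child_rng(seed, "split").permutation(n_chunks)
    chosen: list[int] = []
    total = 0
    for idx in order:
        if total >= target:
            break
        chosen.append(int(idx))
        total += int(bins[idx])
    if len(chosen) >= n_chunks:
        raise ValueError("validation fraction leaves no training chunks")
    chosen_set = set(chosen)
    training = tuple(i for i in range(n_chunks) if i not in chosen_set)
    return ChunkSplit(
        training_ids=training,
        validation_ids=tuple(sorted(chosen)),
        validation_fraction=fraction,
    )


# ---------------------------------------------------------------------------
# BED exchange
# ---------------------------------------------------------------------------

def write_bed(annotation: Annotation, path) -> None:
    """Write an annotation as BED4 (chrom, start, end, label name)."""
    annotation.validate()
    with open(path, "w") as fh:
        for interval, label in annotation.segments:
            fh.write(f"{interval.chrom}\t{interval.start}\t{interval.end}\t{annotation.name_of(label)}\n")


def read_bed(path) -> Annotation:
    """Read a BED4 file back into an annotation.

    Numeric label names map to their integer indices; otherwise labels are
    indexed by sorted name. ``read_bed(write_bed(a)) == a`` for any valid
    annotation with default names.
    """
    rows: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 BED columns")
            try:
                interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed BED interval") from None
            rows.append((interval, fields[3]))
    names = [name for _, name in rows]
    if all(name.lstrip("-").isdigit() for name in names):
        index = {name: int(name) for name in names}
    else:
        index = {name: i for i, name in enumerate(sorted(set(names)))}
    ann = Annotation(
        segments=[(iv, index[name]) for iv, name in rows],
        label_names={index[name]: name for name in names},
    )
    ann.validate()
    return ann
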