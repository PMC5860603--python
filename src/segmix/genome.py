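"""Genome coordinate plumbing: layout, intervals, segment annotations.

All coordinates are 0-based half-open (BED convention). A genome is binned
at a fixed resolution ``r``; bin ``i`` of a chromosome covers bases
``[i*r, (i+1)*r)``, the last bin possibly truncated at the chromosome end.
Chromosomes are tiled by consecutive fixed-size chunks of ``chunk_size``
bins each (the unit of inference), the last chunk possibly shorter. No
chunk ever spans a chromosome boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "Annotation",
    "read_chrom_sizes",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus the working resolution and chunking.

    Parameters
    ----------
    chrom_names, chrom_lengths
        Parallel tuples of chromosome names and lengths in base pairs.
    resolution
        Base pairs per bin (>= 1).
    chunk_size
        Bins per inference chunk (>= 2).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    resolution: int = 1
    chunk_size: int = 500

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if self.chunk_size < 2:
            raise ValueError("chunk_size must be >= 2")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_length(chrom) / self.resolution)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def chunk_intervals(self) -> list[GenomicInterval]:
        """Tile every chromosome, in layout order, with chunk intervals."""
        out: list[GenomicInterval] = []
        span = self.chunk_size * self.resolution
        for chrom, length in zip(self.chrom_names, self.chrom_lengths):
            start = 0
            while start < length:
                out.append(GenomicInterval(chrom, start, min(start + span, length)))
                start += span
        return out


def read_chrom_sizes(path, *, resolution: int = 1, chunk_size: int = 500) -> GenomeLayout:
    """Read a two-column (name, length) TSV into a :class:`GenomeLayout`."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
            names.append(fields[0])
            try:
                lengths.append(int(fields[1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: length {fields[1]!r} is not an integer") from None
    return GenomeLayout(tuple(names), tuple(lengths), resolution=resolution, chunk_size=chunk_size)


@dataclass
class Annotation:
    """Ordered, non-overlapping labelled segments in genome coordinates.

    ``segments`` is a list of ``(GenomicInterval, label_index)`` sorted by
    (chromosome, start); within a chromosome consecutive segments are
    adjacent and carry different labels. ``label_names`` maps label index to
    the name written to BED (defaults to the decimal index).
    """

    segments: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    label_names: dict[int, str] = field(default_factory=dict)

    def name_of(self, label: int) -> str:
        return self.label_names.get(label, str(label))

    def validate(self) -> None:
        prev: GenomicInterval | None = None
        prev_label: int | None = None
        for interval, label in self.segments:
            if prev is not None and prev.chrom == interval.chrom:
                if interval.start < prev.end:
                    raise ValueError(
                        f"overlapping segments at {interval.chrom}:{interval.start}"
                    )
                if interval.start == prev.end and label == prev_label:
                    raise ValueError(
                        f"unmerged adjacent segments with equal label at "
                        f"{interval.chrom}:{interval.start}"
                    )
            prev, prev_label = interval, label

    def labels_present(self) -> list[int]:
        return sorted({label for _, label in self.segments})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self.segments == other.segments and all(
            self.name_of(lab) == other.name_of(lab)
            for _, lab in self.segments
        )
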