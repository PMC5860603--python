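"""Track parsing, binning, chunking, validation splits and BED round trips."""

import numpy as np
import pytest

from segmix.genome import Annotation, GenomeLayout, GenomicInterval
from segmix.signal_io import (
    ObservationStore,
    build_chunks,
    read_bed,
    read_signal_track,
    read_tracks,
    split_validation,
    write_bed,
)

import helpers


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


def _layout(lengths=(100,), resolution=10, chunk_size=5):
    names = tuple(f"chr{i+1}" for i in range(len(lengths)))
    return GenomeLayout(names, tuple(lengths), resolution=resolution, chunk_size=chunk_size)


class TestBedGraphBinning:
    def test_empty_file_every_bin_missing(self, tmp_path):
        track = read_signal_track(_write(tmp_path, "t.bedgraph", ""), _layout())
        assert track.missing["chr1"].all()

    def test_constant_coverage_fills_bins(self, tmp_path):
        track = read_signal_track(
            _write(tmp_path, "t.bedgraph", "chr1\t0\t20\t2.0\n"), _layout()
        )
        assert track.values["chr1"][0] == 2.0
        assert track.values["chr1"][1] == 2.0
        assert not track.missing["chr1"][:2].any()
        assert track.missing["chr1"][2:].all()

    def test_sub_bin_intervals_average_per_base(self, tmp_path):
        # 5 bases at 1.0 and 5 bases at 3.0 inside one 10 bp bin -> mean 2.0
        track = read_signal_track(
            _write(tmp_path, "t.bedgraph", "chr1\t0\t5\t1.0\nchr1\t5\t10\t3.0\n"),
            _layout(),
        )
        assert track.values["chr1"][0] == pytest.approx(2.0, abs=1e-12)

    def test_unknown_chromosome_names_line(self, tmp_path):
        path = _write(tmp_path, "t.bedgraph", "chr1\t0\t5\t1.0\nchrX\t0\t5\t1.0\n")
        with pytest.raises(ValueError, match=r":2.*chrX"):
            read_signal_track(path, _layout())

    def test_overlapping_intervals_are_an_error(self, tmp_path):
        path = _write(tmp_path, "t.bedgraph", "chr1\t0\t10\t1.0\nchr1\t5\t15\t1.0\n")
        with pytest.raises(ValueError, match="overlap"):
            read_signal_track(path, _layout())

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_base_expansion_oracle(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(30, 120))
        resolution = int(rng.integers(1, 13))
        layout = _layout((length,), resolution=resolution)
        # random non-overlapping intervals
        cuts = np.sort(rng.choice(np.arange(1, length), size=6, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        intervals = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if rng.random() < 0.6:
                intervals.append((int(lo), int(hi), float(rng.normal())))
        text = "".join(f"chr1\t{s}\t{e}\t{v!r}\n" for s, e, v in intervals)
        track = read_signal_track(_write(tmp_path, "t.bedgraph", text), layout)
        expected, missing = helpers.bin_by_base_expansion(intervals, length, resolution)
        assert np.array_equal(track.missing["chr1"], missing)
        obs = ~missing
        assert np.allclose(track.values["chr1"][obs], expected[obs], rtol=1e-9)
        # conservation: sum(bin value * covered bases) == sum over bases
        covered_base_sum = sum((e - s) * v for s, e, v in intervals)
        per_bin_cover = [
            np.sum([min(e, (b + 1) * resolution) - max(s, b * resolution)
                    for s, e, _ in intervals
                    if s < (b + 1) * resolution and e > b * resolution])
            for b in range(layout.n_bins("chr1"))
        ]
        total = sum(
            track.values["chr1"][b] * per_bin_cover[b]
            for b in range(len(per_bin_cover)) if obs[b]
        )
        assert total == pytest.approx(covered_base_sum, rel=1e-9, abs=1e-9)


class TestWiggle:
    def test_fixed_step_equals_bedgraph(self, tmp_path):
        layout = _layout((40,), resolution=10)
        wig = "fixedStep chrom=chr1 start=1 step=10 span=10\n1.0\n2.0\n3.0\n4.0\n"
        bg = "chr1\t0\t10\t1.0\nchr1\t10\t20\t2.0\nchr1\t20\t30\t3.0\nchr1\t30\t40\t4.0\n"
        t_wig = read_signal_track(_write(tmp_path, "t.wig", wig), layout)
        t_bg = read_signal_track(_write(tmp_path, "t.bedgraph", bg), layout)
        assert np.array_equal(t_wig.values["chr1"], t_bg.values["chr1"])

    def test_variable_step(self, tmp_path):
        layout = _layout((30,), resolution=10)
        wig = "variableStep chrom=chr1 span=10\n1\t5.0\n21\t7.0\n"
        track = read_signal_track(_write(tmp_path, "t.wig", wig), layout)
        assert track.values["chr1"][0] == 5.0
        assert track.missing["chr1"][1]
        assert track.values["chr1"][2] == 7.0

    def test_data_before_declaration_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="declaration"):
            read_signal_track(_write(tmp_path, "t.wig", "1.0\n"), _layout())


class TestChunking:
    def test_tiling_arithmetic(self, tmp_path):
        # 25 bins, chunk_size 10 -> chunks of 10, 10, 5 bins
        layout = _layout((250,), resolution=10, chunk_size=10)
        binned = read_tracks(
            [_write(tmp_path, "t.bedgraph", "chr1\t0\t250\t1.0\n")], ["t"], layout
        )
        store = build_chunks(binned)
        assert [c.n_bins for c in store.chunks] == [10, 10, 5]

    def test_round_trip_concatenation_is_bit_identical(self, tmp_path, small_layout):
        rng = np.random.default_rng(0)
        text = "".join(
            f"{chrom}\t{s}\t{s+10}\t{float(rng.normal())!r}\n"
            for chrom, length in zip(small_layout.chrom_names, small_layout.chrom_lengths)
            for s in range(0, length - 9, 10)
            if rng.random() < 0.8
        )
        binned = read_tracks([_write(tmp_path, "t.bedgraph", text)], ["t"], small_layout)
        store = build_chunks(binned)
        for chrom in small_layout.chrom_names:
            chunks = [c for c in store.chunks if c.interval.chrom == chrom]
            rebuilt = np.concatenate([c.values for c in chunks])
            obs = ~np.concatenate([c.missing for c in chunks])
            assert np.array_equal(rebuilt[obs], binned.values[chrom][obs])

    def test_no_chunk_spans_a_chromosome_boundary(self, small_layout):
        for iv in small_layout.chunk_intervals():
            assert iv.end <= small_layout.chrom_length(iv.chrom)
            assert len(iv) <= small_layout.chunk_size * small_layout.resolution


class TestValidationSplit:
    @staticmethod
    def _store(n_chunks=1000, bins=10):
        layout = GenomeLayout(("chr1",), (n_chunks * bins,), resolution=1, chunk_size=bins)
        rng = np.random.default_rng(1)
        from segmix.signal_io import BinnedGenome

        binned = BinnedGenome(
            layout=layout, track_names=("t",),
            values={"chr1": rng.normal(size=(n_chunks * bins, 1))},
            missing={"chr1": np.zeros((n_chunks * bins, 1), dtype=bool)},
        )
        return build_chunks(binned)

    def test_held_out_fraction_chunk_count(self):
        # 1.5% of a 1000-chunk equal-size genome -> exactly 15 chunks
        store = self._store()
        split = split_validation(store, 0.015, seed=3)
        assert len(split.validation_ids) == 15

    def test_same_seed_identical_split(self):
        store = self._store(100)
        assert split_validation(store, 0.1, 7) == split_validation(store, 0.1, 7)

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_split_is_a_partition(self, seed):
        store = self._store(50)
        split = split_validation(store, 0.13, seed)
        tr, va = set(split.training_ids), set(split.validation_ids)
        assert not (tr & va)
        assert tr | va == set(range(50))
        # realized fraction within one chunk of requested
        bins = store.bin_counts()
        realized = bins[list(va)].sum() / bins.sum()
        assert abs(realized - 0.13) <= bins.max() / bins.sum()

    def test_fraction_leaving_no_training_chunks_is_an_error(self):
        store = self._store(4)
        with pytest.raises(ValueError, match="training"):
            split_validation(store, 0.999, 0)


class TestBed:
    def test_empty_round_trip(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed(Annotation(), path)
        assert path.read_text() == ""
        assert read_bed(path).segments == []

    def test_single_segment_format(self, tmp_path):
        ann = Annotation(segments=[(GenomicInterval("chr1", 0, 100), 3)])
        path = tmp_path / "one.bed"
        write_bed(ann, path)
        assert path.read_text() == "chr1\t0\t100\t3\n"

    def test_overlapping_segments_refuse_to_write(self, tmp_path):
        ann = Annotation(
            segments=[
                (GenomicInterval("chr1", 0, 100), 0),
                (GenomicInterval("chr1", 50, 150), 1),
            ]
        )
        with pytest.raises(ValueError, match="overlap"):
            write_bed(ann, tmp_path / "bad.bed")

    def test_malformed_bed_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\t0\nchr1\tx\ty\t1\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(path)

    @pytest.mark.parametrize("seed", range(50))
    def test_random_annotations_round_trip_byte_stably(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        segments = []
        for chrom in ("chr1", "chr2"):
            pos = 0
            prev = -1
            for _ in range(int(rng.integers(1, 6))):
                length = int(rng.integers(1, 50))
                label = int(rng.integers(0, 4))
                if label == prev:
                    label = (label + 1) % 4
                segments.append((GenomicInterval(chrom, pos, pos + length), label))
                pos += length
                prev = label
        ann = Annotation(segments=segments)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(ann, p1)
        back = read_bed(p1)
        assert back == ann
        write_bed(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestObservationStore:
    def test_hdf5_round_trip(self, tmp_path, small_layout):
        rng = np.random.default_rng(5)
        from segmix.signal_io import BinnedGenome

        values = {
            c: rng.normal(size=(small_layout.n_bins(c), 2))
            for c in small_layout.chrom_names
        }
        missing = {
            c: rng.random((small_layout.n_bins(c), 2)) < 0.1
            for c in small_layout.chrom_names
        }
        for c in missing:
            values[c][missing[c]] = np.nan
        store = build_chunks(
            BinnedGenome(layout=small_layout, track_names=("a", "b"),
                         values=values, missing=missing)
        )
        path = tmp_path / "obs.h5"
        store.save(path)
        back = ObservationStore.load(path)
        assert back.layout == store.layout
        assert back.track_names == store.track_names
        for c1, c2 in zip(store.chunks, back.chunks):
            assert c1.interval == c2.interval
            assert np.array_equal(c1.missing, c2.missing)
            assert np.array_equal(c1.values[~c1.missing], c2.values[~c2.missing])
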