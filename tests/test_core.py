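"""Interval arithmetic, BED I/O and the brute-force oracle equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cooccupy.core import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    intersect_sets,
    nearest_flanks,
    overlaps,
    percent,
    read_bed,
    read_genome,
    stitch,
    write_bed,
    write_genome,
)
from cooccupy.errors import ParseError, ValidationError

from conftest import random_peakset


class TestBedIO:
    def test_bed5_line_maps_fields(self, tmp_path, genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpk1\t5\n")
        ps = read_bed(p, genome)
        (iv,) = ps
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.score) == ("chr1", 100, 200, "pk1", 5.0)

    def test_narrowpeak_signal_value_becomes_score(self, tmp_path, genome):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tpk1\t850\t.\t7.25\t12.0\t10.1\t50\n")
        (iv,) = read_bed(p, genome)
        assert iv.score == 7.25  # signalValue, not the display score column

    @pytest.mark.parametrize(
        "line",
        ["chr1\t200\t100", "chr1\t100", "chr1\tx\t200", "chr1\t-5\t10"],
    )
    def test_malformed_line_raises_with_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(ParseError, match="line 2"):
            read_bed(p)

    def test_out_of_bounds_and_unknown_chrom_rejected(self, tmp_path, genome):
        p = tmp_path / "a.bed"
        p.write_text("chrX\t0\t10\n")
        with pytest.raises(ValidationError):
            read_bed(p, genome)
        p.write_text("chr2\t0\t600000\n")  # chr2 is 500 kb
        with pytest.raises(ValidationError):
            read_bed(p, genome)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        raw=st.lists(
            st.tuples(
                st.integers(0, 9000), st.integers(1, 500), st.integers(0, 999)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_bed6_round_trip_is_byte_identical(self, raw, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        ivs = [
            GenomicInterval("chr1", s, s + l, f"pk{i}", float(sc), "+")
            for i, (s, l, sc) in enumerate(raw)
        ]
        ps = PeakSet("x", None, ivs)
        f1, f2 = tmp / "a.bed", tmp / "b.bed"
        write_bed(ps, f1)
        write_bed(read_bed(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_genome_round_trip(self, tmp_path, genome):
        p = tmp_path / "g.sizes"
        write_genome(genome, p)
        assert read_genome(p) == genome


class TestOverlaps:
    def test_one_bp_overlap_boundary(self):
        assert overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 199, 300))

    def test_half_open_adjacency_is_not_overlap(self):
        assert not overlaps(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.tuples(st.integers(0, 100), st.integers(1, 40)),
        b=st.tuples(st.integers(0, 100), st.integers(1, 40)),
        min_bp=st.integers(1, 5),
    )
    def test_matches_base_by_base_enumeration(self, a, b, min_bp):
        ia = GenomicInterval("chr1", a[0], a[0] + a[1])
        ib = GenomicInterval("chr1", b[0], b[0] + b[1])
        shared_bases = len(
            set(range(ia.start, ia.end)) & set(range(ib.start, ib.end))
        )
        assert overlaps(ia, ib, min_bp) == (shared_bases >= min_bp)


def _oracle_hits(query, subject, min_bp=1):
    out = []
    for q in query:
        for s in subject:
            if q.chrom == s.chrom and min(q.end, s.end) - max(q.start, s.start) >= min_bp:
                out.append(q)
                break
    return out


class TestIntersectSets:
    def test_simple_hit(self, genome):
        q = PeakSet("q", genome, [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)])
        s = PeakSet("s", genome, [GenomicInterval("chr1", 5, 6)])
        hits, summary = intersect_sets(q, s)
        assert [iv.start for iv in hits] == [0]
        assert (summary.n_hit, summary.n_query) == (1, 2)

    def test_identity(self, genome, rng):
        q = random_peakset(rng, genome, 100)
        _, summary = intersect_sets(q, q)
        assert summary.n_hit == summary.n_query == 100

    def test_genome_mismatch_rejected(self, genome):
        other = GenomeLayout.from_lengths([100])
        q = PeakSet("q", genome, [GenomicInterval("chr1", 0, 10)])
        s = PeakSet("s", other, [GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValidationError):
            intersect_sets(q, s)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_loop_oracle(self, genome, seed):
        rng = np.random.default_rng(seed)
        q = random_peakset(rng, genome, 500, "q")
        s = random_peakset(rng, genome, 500, "s")
        min_bp = int(rng.integers(1, 10))
        hits, _ = intersect_sets(q, s, min_bp)
        oracle = _oracle_hits(q, s, min_bp)
        assert [(h.chrom, h.start, h.end) for h in hits] == sorted(
            (o.chrom, o.start, o.end) for o in oracle
        )


def _oracle_flanks(x, ivs):
    if any(
        iv.chrom == x.chrom and min(iv.end, x.end) - max(iv.start, x.start) >= 1
        for iv in ivs
    ):
        return (0, 0)
    lefts = [x.start - iv.end for iv in ivs if iv.chrom == x.chrom and iv.end <= x.start]
    rights = [iv.start - x.end for iv in ivs if iv.chrom == x.chrom and iv.start >= x.end]
    return (min(lefts) if lefts else None, min(rights) if rights else None)


class TestNearestFlanks:
    def test_arithmetic_example(self, genome):
        s = PeakSet("s", genome, [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 300, 400)])
        assert nearest_flanks(GenomicInterval("chr1", 100, 200), s) == (50, 100)

    def test_overlap_reports_zero_both_sides(self, genome):
        s = PeakSet("s", genome, [GenomicInterval("chr1", 150, 160)])
        assert nearest_flanks(GenomicInterval("chr1", 100, 200), s) == (0, 0)

    def test_absent_chromosome_gives_none(self, genome):
        s = PeakSet("s", genome, [GenomicInterval("chr1", 0, 50)])
        assert nearest_flanks(GenomicInterval("chr2", 100, 200), s) == (None, None)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_scan_oracle(self, genome, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_peakset(rng, genome, 200, "s")
        for _ in range(50):
            start = int(rng.integers(0, 900_000))
            x = GenomicInterval("chr1", start, start + int(rng.integers(1, 400)))
            assert nearest_flanks(x, s) == _oracle_flanks(x, s.intervals)


class TestStitch:
    def test_gap_within_threshold_merges_and_sums(self, genome):
        s = PeakSet("s", genome, [
            GenomicInterval("chr1", 0, 100, score=2),
            GenomicInterval("chr1", 200, 300, score=3),
        ])
        out = stitch(s, 150)
        (iv,) = out
        assert (iv.start, iv.end, iv.score) == (0, 300, 5)
        assert out.merged

    def test_gap_beyond_threshold_keeps_separate(self, genome):
        s = PeakSet("s", genome, [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)])
        assert len(stitch(s, 50)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_disjointness_idempotence(self, genome, seed):
        rng = np.random.default_rng(200 + seed)
        s = random_peakset(rng, genome, 300, scored=True)
        gap = int(rng.integers(0, 2000))
        out = stitch(s, gap)
        # score conservation
        assert sum(iv.score for iv in out) == pytest.approx(
            sum(iv.score for iv in s)
        )
        # coverage superset: every input base is covered by some output span
        for iv in s:
            assert any(
                o.chrom == iv.chrom and o.start <= iv.start and iv.end <= o.end
                for o in out
            )
        # pairwise disjoint with gaps > gap, per chromosome
        by_chrom = {}
        for o in out:
            by_chrom.setdefault(o.chrom, []).append(o)
        for ivs in by_chrom.values():
            for a, b in zip(ivs, ivs[1:]):
                assert b.start - a.end > gap
        # idempotent
        again = stitch(out, gap)
        assert [(o.chrom, o.start, o.end, o.score) for o in again] == [
            (o.chrom, o.start, o.end, o.score) for o in out
        ]


class TestPercentConvention:
    @pytest.mark.parametrize(
        "n_hit,n_query,expected",
        [(1752, 2489, 70), (5367, 13690, 39), (530, 652, 81), (409, 652, 63)],
    )
    def test_reporting_pairs(self, n_hit, n_query, expected):
        assert percent(n_hit, n_query) == expected

    def test_half_rounds_away_from_zero(self):
        assert percent(1, 200) == 1  # 0.5% -> 1
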