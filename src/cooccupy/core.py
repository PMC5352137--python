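"""Genomic intervals, peak sets and BED-family I/O.

Everything downstream — activity classification, super-enhancer calling,
gene association, co-occupancy arithmetic — consumes the types defined
here. Coordinates are 0-based, half-open throughout (BED native), so the
interval [a, b) covers bases a .. b-1 and [100, 200) is adjacent to, not
overlapping, [200, 300). Strand is carried on intervals but deliberately
ignored by all overlap tests; only gene-association logic is strand-aware.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

from .errors import ParseError, ValidationError

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "OverlapSummary",
    "read_genome",
    "write_genome",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "overlaps",
    "overlap_length",
    "intersect_sets",
    "nearest_flanks",
    "flank_gaps",
    "stitch",
    "percent",
]


def percent(n_hit: int, n_query: int) -> int:
    """Integer percent, rounding half away from zero.

    This is the reporting convention used for every fraction the package
    prints; it reproduces e.g. 1752/2489 -> 70 and 409/652 -> 63.
    """
    if n_query <= 0:
        raise ValidationError("percent undefined for n_query <= 0")
    import math

    return int(math.floor(100.0 * n_hit / n_query + 0.5))


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (chrom.sizes dialect)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome layout")
        for name, length in self.chromosomes:
            if not name:
                raise ValidationError("empty chromosome name")
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @classmethod
    def from_lengths(cls, lengths: Sequence[int], prefix: str = "chr") -> "GenomeLayout":
        return cls(tuple((f"{prefix}{i + 1}", int(l)) for i, l in enumerate(lengths)))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} not in genome layout") from None

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]


@dataclass(frozen=True)
class GenomicInterval:
    """A located, optionally named/scored/stranded half-open interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.score is not None and self.score < 0:
            raise ValidationError("negative score")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the single reference point the analyses need: its TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    expression: float | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS")


@dataclass(frozen=True)
class OverlapSummary:
    """Counts for a query-vs-subject overlap, with the fixed percent convention."""

    n_query: int
    n_hit: int

    def __post_init__(self):
        if not (0 <= self.n_hit <= self.n_query):
            raise ValidationError("need 0 <= n_hit <= n_query")

    @property
    def percent(self) -> int:
        return percent(self.n_hit, self.n_query)


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


class PeakSet:
    """A labelled, sorted collection of intervals on one genome.

    Intervals within a set may overlap each other unless produced by a
    merge; ``merged`` records whether a stitch has been applied. Subject-
    side overlap queries are served from per-chromosome interval trees and
    sorted coordinate arrays, built lazily and cached.
    """

    def __init__(
        self,
        label: str,
        genome: GenomeLayout | None,
        intervals: Iterable[GenomicInterval],
        merged: bool = False,
    ):
        self.label = label
        self.genome = genome
        self.intervals: list[GenomicInterval] = sorted(intervals, key=_sort_key)
        self.merged = merged
        if genome is not None:
            for iv in self.intervals:
                if iv.chrom not in genome:
                    raise ValidationError(
                        f"{label}: chromosome {iv.chrom!r} not in genome layout"
                    )
                if iv.end > genome.length(iv.chrom):
                    raise ValidationError(
                        f"{label}: interval {iv.chrom}:{iv.start}-{iv.end} "
                        "exceeds chromosome length"
                    )
        self._trees: dict[str, IntervalTree] | None = None
        self._starts: dict[str, list[int]] | None = None
        self._ends: dict[str, list[int]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def replace_intervals(self, intervals, merged=None) -> "PeakSet":
        return PeakSet(
            self.label,
            self.genome,
            intervals,
            self.merged if merged is None else merged,
        )

    # -- cached per-chromosome indexes ------------------------------------

    def _ensure_index(self):
        if self._trees is not None:
            return
        trees: dict[str, IntervalTree] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for iv in self.intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        for c in ends:
            ends[c].sort()  # starts are already sorted by construction
        self._trees, self._starts, self._ends = trees, starts, ends

    def overlapping(self, x: GenomicInterval, min_bp: int = 1) -> list[GenomicInterval]:
        """All intervals in this set overlapping ``x`` by at least ``min_bp``."""
        if min_bp < 1:
            raise ValidationError("min_bp must be >= 1")
        self._ensure_index()
        tree = self._trees.get(x.chrom)
        if tree is None:
            return []
        hits = [
            h.data
            for h in tree.overlap(x.start, x.end)
            if overlap_length(h.data, x) >= min_bp
        ]
        return sorted(hits, key=_sort_key)

    def has_overlap(self, x: GenomicInterval, min_bp: int = 1) -> bool:
        return bool(self.overlapping(x, min_bp))


# ---------------------------------------------------------------------------
# interval arithmetic


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of [a.start,a.end) ∩ [b.start,b.end); 0 off-chromosome."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff the two intervals share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValidationError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


def intersect_sets(
    query: PeakSet, subject: PeakSet, min_bp: int = 1
) -> tuple[PeakSet, OverlapSummary]:
    """Query peaks overlapping >=1 subject peak by >= min_bp, each counted once."""
    if query.genome is not None and subject.genome is not None:
        if query.genome != subject.genome:
            raise ValidationError("query and subject are on different genomes")
    hits = [iv for iv in query if subject.has_overlap(iv, min_bp)]
    summary = OverlapSummary(n_query=len(query), n_hit=len(hits))
    return query.replace_intervals(hits), summary


def nearest_flanks(
    x: GenomicInterval, s: PeakSet
) -> tuple[int | None, int | None]:
    """Gaps to the nearest s-intervals entirely left/right of ``x``.

    An s-interval overlapping ``x`` short-circuits to (0, 0); a side with
    no interval reports None. Abutting intervals have gap 0.
    """
    if s.has_overlap(x):
        return (0, 0)
    return flank_gaps(x, s)


def flank_gaps(x: GenomicInterval, s: PeakSet) -> tuple[int | None, int | None]:
    """Gaps to nearest non-overlapping s-intervals strictly left and right of x.

    Unlike :func:`nearest_flanks` this ignores any s-interval overlapping x,
    which is what flank-evidence rules need (evidence must be distinct from
    an overlap).
    """
    s._ensure_index()
    ends = s._ends.get(x.chrom)
    starts = s._starts.get(x.chrom)
    left = right = None
    if ends:
        i = bisect.bisect_right(ends, x.start)  # ends[:i] are <= x.start
        if i > 0:
            left = x.start - ends[i - 1]
    if starts:
        j = bisect.bisect_left(starts, x.end)  # starts[j:] are >= x.end
        if j < len(starts):
            right = starts[j] - x.end
    return (left, right)


def _stitch_groups(
    s: PeakSet, gap: int
) -> list[tuple[GenomicInterval, list[GenomicInterval]]]:
    if gap < 0:
        raise ValidationError("stitch gap must be >= 0")
    out: list[tuple[GenomicInterval, list[GenomicInterval]]] = []
    members: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    scores_seen = False

    def flush():
        nonlocal members
        if not members:
            return
        total = sum(iv.score for iv in members if iv.score is not None)
        any_score = any(iv.score is not None for iv in members)
        name = ",".join(iv.name for iv in members if iv.name) or None
        span = GenomicInterval(
            cur_chrom, cur_start, cur_end, name=name, score=total if any_score else None
        )
        out.append((span, members))
        members = []

    for iv in s:  # already sorted
        if iv.chrom != cur_chrom or iv.start - cur_end > gap:
            flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            members = [iv]
        else:
            cur_end = max(cur_end, iv.end)
            members.append(iv)
    flush()
    return out


def stitch(s: PeakSet, gap: int) -> PeakSet:
    """Merge intervals separated by <= ``gap`` bp; scores sum, output disjoint.

    Idempotent: every remaining inter-interval gap exceeds ``gap``.
    """
    spans = [span for span, _ in _stitch_groups(s, gap)]
    return s.replace_intervals(spans, merged=True)


# ---------------------------------------------------------------------------
# I/O — BED3/BED6/narrowPeak, chrom.sizes, gene tables


def read_genome(path) -> GenomeLayout:
    """Read a two-column 'chrom<TAB>length' file (UCSC chrom.sizes)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError("expected 'chrom\\tlength'", ln)
        try:
            rows.append((parts[0], int(parts[1])))
        except ValueError:
            raise ParseError(f"bad length {parts[1]!r}", ln) from None
    return GenomeLayout(tuple(rows))


def write_genome(layout: GenomeLayout, path) -> None:
    Path(path).write_text(
        "".join(f"{n}\t{l}\n" for n, l in layout.chromosomes)
    )


def _fmt_score(score: float) -> str:
    return f"{score:g}"


def read_bed(path, genome: GenomeLayout | None = None, label: str | None = None) -> PeakSet:
    """Read BED3/BED6 or ENCODE narrowPeak into a sorted PeakSet.

    narrowPeak (10 columns) maps signalValue (col 7) to the interval score;
    BED6 maps the score column. Out-of-bounds records and malformed lines
    raise with their line number.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    intervals = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ParseError("fewer than 3 BED fields", ln)
        chrom = f[0]
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise ParseError(f"non-integer coordinates {f[1]!r}, {f[2]!r}", ln) from None
        if start >= end or start < 0:
            raise ParseError(f"invalid interval [{start}, {end})", ln)
        name = f[3] if len(f) > 3 and f[3] not in (".", "") else None
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        score: float | None = None
        if len(f) >= 10:  # narrowPeak: signalValue is authoritative
            try:
                score = float(f[6])
            except ValueError:
                raise ParseError(f"bad narrowPeak signalValue {f[6]!r}", ln) from None
        elif len(f) > 4 and f[4] not in (".", ""):
            try:
                score = float(f[4])
            except ValueError:
                raise ParseError(f"bad score {f[4]!r}", ln) from None
        if score is not None and score < 0:
            raise ParseError(f"negative score {score}", ln)
        if genome is not None:
            if chrom not in genome:
                raise ValidationError(
                    f"line {ln}: chromosome {chrom!r} not in genome layout"
                )
            if end > genome.length(chrom):
                raise ValidationError(
                    f"line {ln}: interval end {end} exceeds {chrom} length"
                )
        intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
    return PeakSet(label, genome, intervals)


def write_bed(s: PeakSet | Sequence[GenomicInterval], path, header: str | None = None) -> None:
    """Write BED (6 columns when name/score/strand are present, else BED3)."""
    ivs = list(s)
    six = any(iv.name is not None or iv.score is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for iv in ivs:
            if six:
                score = _fmt_score(iv.score) if iv.score is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_table(path, genome: GenomeLayout | None = None) -> list[GeneModel]:
    """Read a gene table TSV: gene_id, chrom, strand, tss[, expression]."""
    genes = []
    seen = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if f[0] == "gene_id":  # optional header
            continue
        if len(f) < 4:
            raise ParseError("expected gene_id, chrom, strand, tss[, expression]", ln)
        gid, chrom, strand = f[0], f[1], f[2]
        if gid in seen:
            raise ValidationError(f"line {ln}: duplicate gene id {gid!r}")
        seen.add(gid)
        try:
            tss = int(f[3])
        except ValueError:
            raise ParseError(f"bad TSS {f[3]!r}", ln) from None
        expr = None
        if len(f) > 4 and f[4] not in (".", ""):
            try:
                expr = float(f[4])
            except ValueError:
                raise ParseError(f"bad expression {f[4]!r}", ln) from None
        if genome is not None and (chrom not in genome or tss >= genome.length(chrom)):
            raise ValidationError(f"line {ln}: TSS outside genome layout")
        genes.append(GeneModel(gid, chrom, strand, tss, expr))
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texpression\n")
        for g in genes:
            expr = "" if g.expression is None else f"{g.expression:g}"
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{expr}\n")
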