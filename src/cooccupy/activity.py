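"""Active-element classification of TF peaks and enhancer-signature calling.

A TF peak is *active* when it overlaps an H3K27ac peak (>=1 bp) or lies
between two distinct H3K27ac peaks, one on each side, each within
``flank_max`` bp. An *enhancer signature* is a p300 peak flanked by
H3K4me1 peaks; a TF peak is *fully* marked when it overlaps such a full
signature span, and *partially* marked when it merely overlaps p300 or is
flanked by at least one H3K4me1 peak. The two flanking rules are
deliberately asymmetric — activity needs both sides, the partial enhancer
grade needs only one — and flank evidence always comes from peaks that do
not themselves overlap the query.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomicInterval, PeakSet, flank_gaps
from .errors import ValidationError

__all__ = [
    "ActivityCall",
    "SignatureCall",
    "DEFAULT_FLANK_MAX",
    "classify_activity",
    "call_enhancer_signatures",
    "grade_peaks_vs_signature",
]

#: Default maximum flanking distance in bp. The classification rule needs a
#: bound to be computable; 10 kb is of the order of typical enhancer spacing
#: and is always echoed into output headers so runs are self-describing.
DEFAULT_FLANK_MAX = 10_000


@dataclass(frozen=True)
class ActivityCall:
    peak: GenomicInterval
    status: str  # active_overlap | active_flanked | inactive
    left_gap: int | None
    right_gap: int | None

    @property
    def active(self) -> bool:
        return self.status != "inactive"


@dataclass(frozen=True)
class SignatureCall:
    peak: GenomicInterval
    grade: str  # full | partial | none
    evidence: frozenset[str]  # subset of {p300_overlap, left_k4me1, right_k4me1}


def _check_genomes(a: PeakSet, b: PeakSet):
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValidationError("peak sets are on different genomes")


def classify_activity(
    peaks: PeakSet, k27ac: PeakSet, flank_max: int = DEFAULT_FLANK_MAX
) -> list[ActivityCall]:
    """Label each peak active_overlap, active_flanked or inactive."""
    _check_genomes(peaks, k27ac)
    if flank_max <= 0:
        raise ValidationError("flank_max must be > 0")
    calls = []
    for p in peaks:
        if k27ac.has_overlap(p):
            calls.append(ActivityCall(p, "active_overlap", 0, 0))
            continue
        left, right = flank_gaps(p, k27ac)
        if left is not None and right is not None and left <= flank_max and right <= flank_max:
            calls.append(ActivityCall(p, "active_flanked", left, right))
        else:
            calls.append(ActivityCall(p, "inactive", left, right))
    return calls


def call_enhancer_signatures(
    p300: PeakSet, k4me1: PeakSet, flank_max: int = DEFAULT_FLANK_MAX
) -> tuple[list[SignatureCall], PeakSet]:
    """Grade each p300 peak by its H3K4me1 flanks; return full-signature spans.

    full = a non-overlapping H3K4me1 peak within flank_max on each side; the
    full-signature span runs from the left flank's start to the right
    flank's end. partial = exactly one side flanked.
    """
    _check_genomes(p300, k4me1)
    calls: list[SignatureCall] = []
    spans: list[GenomicInterval] = []
    k4me1._ensure_index()
    # map each flank coordinate back to an interval so spans can be built
    by_end: dict[tuple[str, int], GenomicInterval] = {}
    by_start: dict[tuple[str, int], GenomicInterval] = {}
    for iv in k4me1:
        k = (iv.chrom, iv.end)
        if k not in by_end or iv.start < by_end[k].start:
            by_end[k] = iv
        k = (iv.chrom, iv.start)
        if k not in by_start or iv.end < by_start[k].end:
            by_start[k] = iv
    import bisect as _b

    for p in p300:
        left, right = flank_gaps(p, k4me1)
        ev = set()
        if left is not None and left <= flank_max:
            ev.add("left_k4me1")
        if right is not None and right <= flank_max:
            ev.add("right_k4me1")
        if ev == {"left_k4me1", "right_k4me1"}:
            grade = "full"
            ends = k4me1._ends[p.chrom]
            starts = k4me1._starts[p.chrom]
            left_iv = by_end[(p.chrom, ends[_b.bisect_right(ends, p.start) - 1])]
            right_iv = by_start[(p.chrom, starts[_b.bisect_left(starts, p.end)])]
            # span: start of the left flank to end of the right flank
            spans.append(
                GenomicInterval(p.chrom, left_iv.start, right_iv.end, name=p.name)
            )
        elif ev:
            grade = "partial"
        else:
            grade = "none"
        calls.append(SignatureCall(p, grade, frozenset(ev)))
    span_set = PeakSet("full_enhancer_signature", p300.genome, spans)
    return calls, span_set


def grade_peaks_vs_signature(
    tf_peaks: PeakSet,
    p300: PeakSet,
    k4me1: PeakSet,
    flank_max: int = DEFAULT_FLANK_MAX,
) -> tuple[dict[str, float], list[SignatureCall]]:
    """Fraction of TF peaks fully / partially / not marked as enhancers.

    full: the TF peak overlaps a full p300+H3K4me1 signature span.
    partial: it overlaps p300, or has >=1 H3K4me1 peak within flank_max on
    either side. Fractions are over len(tf_peaks) and sum to 1.
    """
    _check_genomes(tf_peaks, p300)
    _check_genomes(tf_peaks, k4me1)
    _, full_spans = call_enhancer_signatures(p300, k4me1, flank_max)
    calls: list[SignatureCall] = []
    counts = {"full": 0, "partial": 0, "none": 0}
    for p in tf_peaks:
        ev = set()
        if p300.has_overlap(p):
            ev.add("p300_overlap")
        left, right = flank_gaps(p, k4me1)
        if left is not None and left <= flank_max:
            ev.add("left_k4me1")
        if right is not None and right <= flank_max:
            ev.add("right_k4me1")
        if full_spans.has_overlap(p):
            grade = "full"
        elif ev:
            grade = "partial"
        else:
            grade = "none"
        counts[grade] += 1
        calls.append(SignatureCall(p, grade, frozenset(ev)))
    n = max(len(tf_peaks), 1)
    fractions = {k: v / n for k, v in counts.items()}
    return fractions, calls
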