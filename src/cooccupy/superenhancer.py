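"""Super-enhancer calling by the tangent-slope cutoff on the ranked tag curve.

Enhancer peaks are stitched (neighbours within a gap merged, tag counts
summed), ranked by total tag count, and both axes scaled to [0, 1]:
x = rank / (n - 1) with enhancers in ascending order, y = tag count / max
tag count. On this hockey-stick curve the super-enhancer cutoff is the
point where a line of slope 1 is tangent to the curve — computed exactly
and deterministically as argmax(x - y). Everything with a tag count
strictly above the cutoff signal is a super-enhancer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GenomicInterval, PeakSet, _stitch_groups
from .errors import ValidationError

__all__ = [
    "StitchedEnhancer",
    "SECurve",
    "SECallResult",
    "DEFAULT_STITCH_GAP",
    "build_stitched",
    "call_superenhancers",
    "export_curve",
]

#: Default stitching gap in bp (the customary distance within which
#: neighbouring enhancer peaks are considered one regulatory cluster).
DEFAULT_STITCH_GAP = 12_500


@dataclass(frozen=True)
class StitchedEnhancer:
    span: GenomicInterval
    members: tuple[str, ...]
    tag_count: float


@dataclass(frozen=True)
class SECurve:
    points: tuple[tuple[float, float], ...]  # (scaled rank, scaled signal), ascending
    cutoff_index: int
    cutoff_signal: float  # raw tag count at the cutoff point


@dataclass(frozen=True)
class SECallResult:
    super: tuple[StitchedEnhancer, ...]
    typical: tuple[StitchedEnhancer, ...]
    curve: SECurve

    @property
    def ranked(self) -> tuple[StitchedEnhancer, ...]:
        """All stitched enhancers in ascending tag-count order."""
        return self.typical + self.super


def build_stitched(
    enhancer_peaks: PeakSet, gap: int = DEFAULT_STITCH_GAP
) -> list[StitchedEnhancer]:
    """Stitch scored enhancer peaks; constituent names and summed tags kept."""
    for iv in enhancer_peaks:
        if iv.score is None:
            raise ValidationError(
                f"enhancer peak {iv.chrom}:{iv.start}-{iv.end} has no tag-count score"
            )
    out = []
    for i, (span, members) in enumerate(_stitch_groups(enhancer_peaks, gap)):
        names = tuple(
            m.name if m.name else f"{m.chrom}:{m.start}-{m.end}" for m in members
        )
        out.append(StitchedEnhancer(span, names, float(span.score)))
    return out


def _rank_key(e: StitchedEnhancer):
    # ties in tag count broken by coordinate so the curve is deterministic
    return (e.tag_count, e.span.chrom, e.span.start, e.span.end)


def call_superenhancers(stitched: list[StitchedEnhancer]) -> SECallResult:
    """Partition stitched enhancers into super and typical at the slope-1 point.

    With enhancers sorted ascending, x_i = i/(n-1) and y_i = tag_i/max_tag;
    the cutoff is argmax(x - y), the rank at which the discrete slope of
    the scaled curve passes 1 for good. Super-enhancers are those with tag
    count strictly greater than the cutoff signal (ties stay typical). A
    flat curve (all tags equal) yields zero super-enhancers.
    """
    n = len(stitched)
    if n < 2:
        raise ValidationError("need at least 2 stitched enhancers")
    ranked = sorted(stitched, key=_rank_key)
    max_tag = ranked[-1].tag_count
    if max_tag <= 0:
        raise ValidationError("max tag count must be > 0")
    points = tuple(
        (i / (n - 1), e.tag_count / max_tag) for i, e in enumerate(ranked)
    )
    cutoff_index = max(range(n), key=lambda i: points[i][0] - points[i][1])
    cutoff_signal = ranked[cutoff_index].tag_count
    super_ = tuple(e for e in ranked if e.tag_count > cutoff_signal)
    typical = tuple(e for e in ranked if e.tag_count <= cutoff_signal)
    return SECallResult(super=super_, typical=typical, curve=SECurve(points, cutoff_index, cutoff_signal))


def export_curve(result: SECallResult) -> list[tuple[float, float]]:
    """(normalized rank, normalized SE score) rows — the hockey-stick curve."""
    return [(x, y) for x, y in result.curve.points]
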