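"""TF-TF peak sharing, SE binding classes and gene-level co-association.

Sharing between two factors means their peaks overlap by at least one
base pair; each query peak is counted once however many subject peaks it
touches. All percentages use the package-wide convention of rounding
half away from zero to the nearest integer percent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import OverlapSummary, PeakSet, intersect_sets, percent
from .errors import ValidationError
from .superenhancer import StitchedEnhancer

__all__ = [
    "SEBindingClass",
    "GeneCategory",
    "share_peaks",
    "gene_venn",
    "classify_se_binding",
    "categorize_gene_list",
    "three_way_sharing",
    "crossspecies_concordance",
]


@dataclass(frozen=True)
class SEBindingClass:
    se: StitchedEnhancer
    binding: str  # neither | a_only | b_only | both
    shared_peak_bound: bool

    def __post_init__(self):
        if self.shared_peak_bound and self.binding != "both":
            raise ValidationError("shared_peak_bound implies binding == 'both'")


@dataclass(frozen=True)
class GeneCategory:
    gene_id: str
    category: str  # a_only | both | b_only | none
    shared_peak_flag: bool


def share_peaks(a: PeakSet, b: PeakSet, min_bp: int = 1) -> tuple[PeakSet, OverlapSummary]:
    """Peaks of ``a`` shared with ``b`` (>= min_bp overlap), counted once each."""
    return intersect_sets(a, b, min_bp=min_bp)


def gene_venn(genes_a: set[str], genes_b: set[str]) -> dict:
    """Three-way partition of two gene-id sets with the A-in-B fraction."""
    a_only = genes_a - genes_b
    both = genes_a & genes_b
    b_only = genes_b - genes_a
    return {
        "a_only": len(a_only),
        "both": len(both),
        "b_only": len(b_only),
        "percent_a_in_b": percent(len(both), len(genes_a)) if genes_a else None,
        "percent_b_in_a": percent(len(both), len(genes_b)) if genes_b else None,
    }


def classify_se_binding(
    ses: list[StitchedEnhancer], a: PeakSet, b: PeakSet
) -> tuple[list[SEBindingClass], dict]:
    """Classify each stitched enhancer span by >=1 bp overlap with each TF set.

    ``shared_peak_bound`` is true when some a-peak overlapping the span
    itself overlaps a b-peak — co-occupancy at the same element, not just
    both factors somewhere on the span.
    """
    calls = []
    counts = {"neither": 0, "a_only": 0, "b_only": 0, "both": 0}
    n_shared = 0
    for se in ses:
        a_hits = a.overlapping(se.span)
        hit_a = bool(a_hits)
        hit_b = b.has_overlap(se.span)
        binding = (
            "both" if hit_a and hit_b
            else "a_only" if hit_a
            else "b_only" if hit_b
            else "neither"
        )
        shared = binding == "both" and any(b.has_overlap(p) for p in a_hits)
        n_shared += shared
        counts[binding] += 1
        calls.append(SEBindingClass(se, binding, shared))
    n = len(ses)
    summary = {
        "n": n,
        **counts,
        "shared_peak_bound": n_shared,
        "percent_both": percent(counts["both"], n) if n else None,
        "percent_shared_peak_bound": percent(n_shared, n) if n else None,
    }
    return calls, summary


def categorize_gene_list(
    gene_list: list[str],
    active_a_genes: set[str],
    active_b_genes: set[str],
    shared_peak_genes: set[str],
) -> tuple[list[GeneCategory], dict]:
    """Partition a curated gene list by active-peak association of two factors."""
    cats = []
    counts = {"a_only": 0, "both": 0, "b_only": 0, "none": 0}
    n_flagged = 0
    for gid in gene_list:
        in_a, in_b = gid in active_a_genes, gid in active_b_genes
        category = (
            "both" if in_a and in_b
            else "a_only" if in_a
            else "b_only" if in_b
            else "none"
        )
        flag = category == "both" and gid in shared_peak_genes
        n_flagged += flag
        counts[category] += 1
        cats.append(GeneCategory(gid, category, flag))
    return cats, {"n": len(gene_list), **counts, "shared_peak_flagged": n_flagged}


def three_way_sharing(a: PeakSet, b: PeakSet, c: PeakSet) -> dict:
    """Partition a's peaks by overlap pattern against two other cell types.

    Returns fractions (unique, shared with exactly one of b/c, shared with
    both); the fractions sum to 1 over a's peaks.
    """
    n = len(a)
    if n == 0:
        raise ValidationError("empty query peak set")
    counts = {"a_unique": 0, "exactly_one": 0, "all_three": 0}
    for p in a:
        k = int(b.has_overlap(p)) + int(c.has_overlap(p))
        if k == 0:
            counts["a_unique"] += 1
        elif k == 1:
            counts["exactly_one"] += 1
        else:
            counts["all_three"] += 1
    return {
        "n": n,
        **counts,
        "fractions": {k: v / n for k, v in counts.items()},
        "percents": {k: percent(v, n) for k, v in counts.items()},
    }


def crossspecies_concordance(native: PeakSet, lifted: PeakSet) -> OverlapSummary:
    """Fraction of native-genome peaks hit by peaks lifted over from another species."""
    _, summary = intersect_sets(native, lifted, min_bp=1)
    return summary
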