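"""Regulatory-domain construction and peak-to-gene association.

Each gene gets a strand-aware *basal* domain around its TSS (default 5 kb
upstream, 1 kb downstream) which is then *extended* in both directions up
to a maximum (default 100 kb) but never across another gene's basal
domain. A peak is associated with every gene whose extended domain
contains the peak midpoint. Distance profiles stratify genes by
expression (highest / median-centred / lowest strata) and measure the
distance from each TSS to the nearest peak edge, 0 when a peak covers the
TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ActivityCall
from .core import GeneModel, GenomicInterval, PeakSet
from .errors import ValidationError

__all__ = [
    "RegulatoryDomain",
    "AssociationRow",
    "build_domains",
    "associate",
    "associated_gene_ids",
    "tss_distance_profile",
    "restrict_to_active",
]

DISTANCE_BINS = (0, 1_000, 5_000, 10_000, 50_000, 100_000, 500_000)


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self):
        b, e = self.basal, self.extended
        if not (e.start <= b.start and b.end <= e.end and b.chrom == e.chrom):
            raise ValidationError(f"{self.gene_id}: basal not contained in extended")


@dataclass(frozen=True)
class AssociationRow:
    peak_name: str
    gene_id: str | None  # None marks an unassigned peak
    distance: int | None  # signed TSS -> peak-midpoint distance, + downstream


def _basal_bounds(g: GeneModel, up: int, down: int, chrom_len: int | None):
    if g.strand == "+":
        lo, hi = g.tss - up, g.tss + down
    else:
        lo, hi = g.tss - down, g.tss + up
    lo = max(0, lo)
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    if lo >= hi:
        raise ValidationError(f"gene {g.gene_id}: degenerate basal domain")
    return lo, hi


def build_domains(
    genes: list[GeneModel],
    genome=None,
    basal_up: int = 5_000,
    basal_down: int = 1_000,
    max_ext: int = 100_000,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains, one per gene.

    The extension on each side reaches to the nearer of (basal edge +
    max_ext) and the nearest other gene's basal boundary, clipped to the
    chromosome; extensions never intrude into another basal domain, while
    basal domains themselves may overlap each other.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene ids")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: dict[str, RegulatoryDomain] = {}
    for chrom, gs in by_chrom.items():
        chrom_len = genome.length(chrom) if genome is not None else None
        bounds = [_basal_bounds(g, basal_up, basal_down, chrom_len) for g in gs]
        bs = np.array([b[0] for b in bounds], dtype=np.int64)
        be = np.array([b[1] for b in bounds], dtype=np.int64)
        n = len(gs)
        # vectorized pairwise scan: fine at the few-thousand-genes-per-
        # chromosome scale this package targets
        bs_j, be_j = bs[None, :], be[None, :]
        bs_i, be_i = bs[:, None], be[:, None]
        # left extension is blocked by any other basal intersecting (ext, bs_i)
        left_block = np.where(bs_j < bs_i, np.minimum(be_j, bs_i), -1)
        np.fill_diagonal(left_block, -1)
        left_limit = left_block.max(axis=1)
        ext_left = np.maximum(np.maximum(bs - max_ext, left_limit), 0)
        # right extension blocked by any other basal intersecting (be_i, ext)
        right_block = np.where(be_j > be_i, np.maximum(bs_j, be_i), np.iinfo(np.int64).max)
        np.fill_diagonal(right_block, np.iinfo(np.int64).max)
        right_limit = right_block.min(axis=1)
        ext_right = np.minimum(np.minimum(be + max_ext, right_limit),
                               chrom_len if chrom_len is not None else np.iinfo(np.int64).max)
        ext_right = np.maximum(ext_right, be)
        ext_left = np.minimum(ext_left, bs)
        for i, g in enumerate(gs):
            out[g.gene_id] = RegulatoryDomain(
                g.gene_id,
                basal=GenomicInterval(chrom, int(bs[i]), int(be[i]), name=g.gene_id),
                extended=GenomicInterval(chrom, int(ext_left[i]), int(ext_right[i]), name=g.gene_id),
            )
    # emit in input order: domain construction is order-independent
    return [out[g.gene_id] for g in genes]


def associate(
    peaks: PeakSet,
    domains: list[RegulatoryDomain],
    genes: list[GeneModel] | None = None,
) -> list[AssociationRow]:
    """Peak -> gene rows wherever the peak midpoint falls in an extended domain.

    A peak may associate with several genes; peaks hitting no domain are
    reported once with gene_id None. When the gene table is supplied the
    signed TSS-to-midpoint distance is strand-aware (positive downstream).
    """
    tss = {g.gene_id: (g.tss, g.strand) for g in genes} if genes else {}
    dom_set = PeakSet(
        "extended_domains",
        None,
        [d.extended for d in domains],
    )
    rows: list[AssociationRow] = []
    for p in peaks:
        mid = p.midpoint
        point = GenomicInterval(p.chrom, mid, mid + 1)
        hits = [d for d in dom_set.overlapping(point)]
        pname = p.name if p.name else f"{p.chrom}:{p.start}-{p.end}"
        if not hits:
            rows.append(AssociationRow(pname, None, None))
            continue
        for d in hits:
            dist = None
            if d.name in tss:
                t, strand = tss[d.name]
                dist = mid - t if strand == "+" else t - mid
            rows.append(AssociationRow(pname, d.name, dist))
    return rows


def associated_gene_ids(rows: list[AssociationRow]) -> set[str]:
    return {r.gene_id for r in rows if r.gene_id is not None}


def _nearest_peak_distance(tss: int, chrom: str, peaks: PeakSet) -> int | None:
    """Distance in bp from a TSS to the nearest covered base of any peak."""
    peaks._ensure_index()
    point = GenomicInterval(chrom, tss, tss + 1)
    if peaks.has_overlap(point):
        return 0
    from .core import flank_gaps

    left, right = flank_gaps(point, peaks)
    cands = []
    if left is not None:
        cands.append(left + 1)  # gap to last covered base
    if right is not None:
        cands.append(right + 1)
    return min(cands) if cands else None


def tss_distance_profile(
    genes: list[GeneModel], peaks: PeakSet, stratum_size: int = 1000
) -> dict[str, dict]:
    """TSS-to-nearest-peak distance distributions for expression strata.

    Genes are ranked by expression (descending, ties by gene id); the
    ``highest`` and ``lowest`` strata are the extremes, the ``median``
    stratum is the stratum_size genes whose ranks straddle n/2. Each
    stratum reports binned counts, quantiles of defined distances, and the
    number of genes with no peak on their chromosome.
    """
    expressed = [g for g in genes if g.expression is not None]
    if len(expressed) < 3 * stratum_size:
        raise ValidationError(
            f"need >= {3 * stratum_size} genes with expression, got {len(expressed)}"
        )
    ranked = sorted(expressed, key=lambda g: (-g.expression, g.gene_id))
    n = len(ranked)
    mid_start = n // 2 - stratum_size // 2
    strata = {
        "highest": ranked[:stratum_size],
        "median": ranked[mid_start : mid_start + stratum_size],
        "lowest": ranked[-stratum_size:],
    }
    out = {}
    edges = list(DISTANCE_BINS) + [float("inf")]
    for label, gs in strata.items():
        dists = [_nearest_peak_distance(g.tss, g.chrom, peaks) for g in gs]
        defined = np.array([d for d in dists if d is not None], dtype=float)
        counts = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            counts.append(int(((defined >= lo) & (defined < hi)).sum()))
        q = (
            {
                "q25": float(np.percentile(defined, 25)),
                "median": float(np.percentile(defined, 50)),
                "q75": float(np.percentile(defined, 75)),
            }
            if defined.size
            else {"q25": None, "median": None, "q75": None}
        )
        out[label] = {
            "n": len(gs),
            "no_peak": sum(1 for d in dists if d is None),
            "bin_edges": edges[:-1],
            "bin_counts": counts,
            **q,
        }
    return out


def restrict_to_active(peaks: PeakSet, activity: list[ActivityCall]) -> PeakSet:
    """Subset of peaks whose activity status is not inactive."""
    if len(activity) != len(peaks):
        raise ValidationError("activity call list does not match peak set")
    keep = []
    for p, call in zip(peaks, activity):
        if (call.peak.chrom, call.peak.start, call.peak.end) != (p.chrom, p.start, p.end):
            raise ValidationError("activity calls are not aligned with peaks")
        if call.active:
            keep.append(p)
    return peaks.replace_intervals(keep)
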