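"""Basal-plus-extension domains, peak-to-gene association and TSS profiles."""

import numpy as np
import pytest

from cooccupy.activity import ActivityCall
from cooccupy.core import GeneModel, GenomeLayout, GenomicInterval, PeakSet
from cooccupy.errors import ValidationError
from cooccupy.gene_association import (
    associate,
    associated_gene_ids,
    build_domains,
    restrict_to_active,
    tss_distance_profile,
)


@pytest.fixture
def two_genes():
    return [
        GeneModel("A", "chr1", "+", 10_000),
        GeneModel("B", "chr1", "+", 50_000),
    ]


@pytest.fixture
def mb_genome():
    return GenomeLayout.from_lengths([1_000_000])


class TestBuildDomains:
    def test_two_gene_worked_example(self, two_genes, mb_genome):
        da, db = build_domains(two_genes, mb_genome)
        assert (da.basal.start, da.basal.end) == (5_000, 11_000)
        assert (db.basal.start, db.basal.end) == (45_000, 51_000)
        assert (da.extended.start, da.extended.end) == (0, 45_000)
        assert (db.extended.start, db.extended.end) == (11_000, 151_000)

    def test_single_gene_extends_full_max(self, mb_genome):
        (d,) = build_domains([GeneModel("A", "chr1", "+", 500_000)], mb_genome)
        assert (d.extended.start, d.extended.end) == (
            d.basal.start - 100_000,
            d.basal.end + 100_000,
        )

    def test_minus_strand_basal_mirrored(self, mb_genome):
        (d,) = build_domains([GeneModel("A", "chr1", "-", 500_000)], mb_genome)
        assert (d.basal.start, d.basal.end) == (499_000, 505_000)

    def test_duplicate_gene_ids_rejected(self, mb_genome):
        genes = [GeneModel("A", "chr1", "+", 1000), GeneModel("A", "chr1", "+", 2000)]
        with pytest.raises(ValidationError):
            build_domains(genes, mb_genome)

    def test_order_independence(self, mb_genome, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+" if rng.integers(2) else "-",
                      int(rng.integers(10_000, 990_000)))
            for i in range(50)
        ]
        d1 = {d.gene_id: d for d in build_domains(genes, mb_genome)}
        shuffled = list(genes)
        rng.shuffle(shuffled)
        d2 = {d.gene_id: d for d in build_domains(shuffled, mb_genome)}
        assert d1 == d2

    @pytest.mark.parametrize("seed", range(5))
    def test_extensions_never_cross_neighbor_basal(self, mb_genome, seed):
        rng = np.random.default_rng(400 + seed)
        genes = [
            GeneModel(f"g{i}", "chr1", "+" if rng.integers(2) else "-",
                      int(rng.integers(10_000, 990_000)))
            for i in range(60)
        ]
        domains = build_domains(genes, mb_genome)
        for d in domains:
            for other in domains:
                if other.gene_id == d.gene_id:
                    continue
                b = other.basal
                # the extension regions flanking the basal must not intersect
                # any other gene's basal domain
                assert min(b.end, d.basal.start) <= max(b.start, d.extended.start)
                assert min(b.end, d.extended.end) <= max(b.start, d.basal.end)
            assert d.extended.start <= d.basal.start <= d.basal.end <= d.extended.end


class TestAssociate:
    def test_worked_example_midpoint_containment(self, two_genes, mb_genome):
        # midpoint 20,250 sits in A's extension and in B's (extensions of
        # neighbouring genes overlap in the shared intergenic space)
        domains = build_domains(two_genes, mb_genome)
        peaks = PeakSet("p", mb_genome, [GenomicInterval("chr1", 20_000, 20_500, "pk")])
        rows = associate(peaks, domains, two_genes)
        assert {(r.peak_name, r.gene_id) for r in rows} == {("pk", "A"), ("pk", "B")}
        by_gene = {r.gene_id: r for r in rows}
        assert by_gene["A"].distance == 10_250  # downstream of A's TSS 10,000
        assert by_gene["B"].distance == -29_750  # upstream of B's TSS 50,000

    def test_far_peak_unassigned(self, two_genes, mb_genome):
        domains = build_domains(two_genes, mb_genome)
        peaks = PeakSet("p", mb_genome, [GenomicInterval("chr1", 900_000, 900_500, "pk")])
        (row,) = associate(peaks, domains, two_genes)
        assert row.gene_id is None

    def test_peak_order_permutation_stable(self, two_genes, mb_genome, rng):
        domains = build_domains(two_genes, mb_genome)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 200, f"p{i}")
            for i, s in enumerate(rng.integers(0, 900_000, size=50))
        ]
        a = associate(PeakSet("p", mb_genome, ivs), domains, two_genes)
        rng.shuffle(ivs)
        b = associate(PeakSet("p", mb_genome, ivs), domains, two_genes)
        assert a == b

    def test_midpoint_containment_audit(self, mb_genome, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", int(t))
            for i, t in enumerate(sorted(rng.integers(10_000, 990_000, size=30)))
        ]
        domains = build_domains(genes, mb_genome)
        dmap = {d.gene_id: d for d in domains}
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 300, f"p{i}")
            for i, s in enumerate(rng.integers(0, 990_000, size=200))
        ]
        peaks = PeakSet("p", mb_genome, ivs)
        pmap = {iv.name: iv for iv in ivs}
        for r in associate(peaks, domains, genes):
            if r.gene_id is None:
                continue
            d = dmap[r.gene_id]
            mid = pmap[r.peak_name].midpoint
            assert d.extended.start <= mid < d.extended.end


class TestTssProfile:
    def _genes(self, n, chrom="chr1", spacing=3000):
        return [
            GeneModel(f"g{i:04d}", chrom, "+", 10_000 + i * spacing, expression=float(n - i))
            for i in range(n)
        ]

    def test_peak_on_tss_gives_zero(self, mb_genome):
        genes = self._genes(30)
        peaks = PeakSet("p", mb_genome, [GenomicInterval("chr1", g.tss - 50, g.tss + 50) for g in genes])
        prof = tss_distance_profile(genes, peaks, stratum_size=10)
        assert prof["highest"]["median"] == 0

    def test_planted_promoter_peaks_separate_strata(self, mb_genome):
        genes = self._genes(300)
        # peaks only at the TSSs of the 100 most-expressed genes
        top = sorted(genes, key=lambda g: -g.expression)[:100]
        peaks = PeakSet("p", mb_genome, [GenomicInterval("chr1", g.tss, g.tss + 100) for g in top])
        prof = tss_distance_profile(genes, peaks, stratum_size=100)
        assert prof["highest"]["median"] == 0
        assert prof["lowest"]["median"] > 100 * prof["highest"]["median"] + 100

    def test_matches_linear_scan_oracle(self, mb_genome, rng):
        genes = self._genes(30)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 500)))
            for s in rng.integers(0, 900_000, size=80)
        ]
        peaks = PeakSet("p", mb_genome, ivs)
        from cooccupy.gene_association import _nearest_peak_distance

        for g in genes:
            dists = []
            for iv in ivs:
                if iv.start <= g.tss < iv.end:
                    dists.append(0)
                elif g.tss < iv.start:
                    dists.append(iv.start - g.tss)
                else:
                    dists.append(g.tss - (iv.end - 1))
            assert _nearest_peak_distance(g.tss, "chr1", peaks) == min(dists)

    def test_too_few_genes_rejected(self, mb_genome):
        with pytest.raises(ValidationError):
            tss_distance_profile(self._genes(20), PeakSet("p", mb_genome, []), stratum_size=10)


class TestRestrictToActive:
    def test_bookkeeping(self, mb_genome, rng):
        ivs = [GenomicInterval("chr1", i * 1000, i * 1000 + 200, f"p{i}") for i in range(20)]
        peaks = PeakSet("p", mb_genome, ivs)
        statuses = ["active_overlap" if i % 3 == 0 else "inactive" for i in range(20)]
        calls = [
            ActivityCall(iv, st, 0 if st != "inactive" else None, None)
            for iv, st in zip(peaks, statuses)
        ]
        active = restrict_to_active(peaks, calls)
        assert len(active) == sum(1 for s in statuses if s != "inactive")

    def test_misaligned_calls_rejected(self, mb_genome):
        peaks = PeakSet("p", mb_genome, [GenomicInterval("chr1", 0, 100)])
        wrong = [ActivityCall(GenomicInterval("chr1", 500, 600), "inactive", None, None)]
        with pytest.raises(ValidationError):
            restrict_to_active(peaks, wrong)
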