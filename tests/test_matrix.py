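"""Site-gene assignment, counting semantics and the denoising filter cascade."""

import numpy as np
import pysam
import pytest

from apadiff.discovery import PolyASite, SiteLibrary
from apadiff.intervals import GenomicInterval, GeneModel
from apadiff.matrix import (
    APAMatrix,
    assign_sites_to_genes,
    count_reads,
    expression_filter,
    normalize_proportions,
    pover_a_filter,
    proportion_filter,
    site_order_key,
)
from tests.conftest import write_bam


def site(start, end, strand="+", sid=None, chrom="c1"):
    return PolyASite(site_id=sid or f"{chrom}:{start}-{end}:{strand}",
                     interval=GenomicInterval(chrom, start, end, strand))


def gene(gene_id, start, end, strand="+", chrom="c1"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


def make_matrix(counts, strand="+", groups=("control",) * 3 + ("treated",) * 3):
    counts = np.asarray(counts)
    n = counts.shape[0]
    sites = [site(1000 * (i + 1), 1000 * (i + 1) + 50, strand) for i in range(n)]
    if strand == "-":
        sites = sites[::-1]
    return APAMatrix(
        gene_id="g", sites=sites, counts=counts,
        sample_ids=[f"r{j}" for j in range(counts.shape[1])],
        group_labels=list(groups),
    )


class TestAssignment:
    def test_extension_zone_within_16kb_assigned(self):
        g = gene("A", 100, 1000, "+")
        lib = SiteLibrary([site(11_000, 11_050, "+")], md=25)
        assign_sites_to_genes(lib, [g])
        assert lib.sites[0].gene_id == "A"

    def test_beyond_16kb_unassigned(self):
        g = gene("A", 100, 1000, "+")
        lib = SiteLibrary([site(18_000, 18_050, "+")], md=25)
        assign_sites_to_genes(lib, [g])
        assert lib.sites[0].gene_id is None
        assert "unassigned" in lib.sites[0].filter_flags

    def test_body_overlap_beats_extension_zone(self):
        a = gene("A", 100, 1000, "+")
        b = gene("B", 5000, 9000, "+")
        lib = SiteLibrary([site(6000, 6050, "+")], md=25)  # in A's zone, in B's body
        assign_sites_to_genes(lib, [a, b])
        assert lib.sites[0].gene_id == "B"

    def test_other_gene_body_blocks_extension_assignment(self):
        a = gene("A", 100, 1000, "+")
        b = gene("B", 5000, 9000, "-")  # opposite strand body at the site
        lib = SiteLibrary([site(6000, 6050, "+")], md=25)
        assign_sites_to_genes(lib, [a, b])
        assert lib.sites[0].gene_id is None

    def test_two_extension_zones_resolved_by_nearer_tes_and_tie_unassigned(self):
        a = gene("A", 100, 1000, "+")
        b = gene("B", 100, 3000, "+", chrom="c1")
        lib = SiteLibrary([site(4000, 4050, "+")], md=25)
        assign_sites_to_genes(lib, [a, b])
        assert lib.sites[0].gene_id == "B"  # TES 3000 nearer than 1000
        # exact tie: two genes sharing the same TES
        c = gene("C", 100, 1000, "+")
        d = gene("D", 500, 1000, "+")
        tie = SiteLibrary([site(4000, 4050, "+")], md=25)
        assign_sites_to_genes(tie, [c, d])
        assert tie.sites[0].gene_id is None

    def test_minus_strand_downstream_is_leftward(self):
        g = gene("A", 10_000, 12_000, "-")
        lib = SiteLibrary([site(4000, 4050, "-"), site(12_500, 12_550, "-")], md=25)
        assign_sites_to_genes(lib, [g])
        by_start = {s.interval.start: s for s in lib.sites}
        assert by_start[4000].gene_id == "A"          # 6 kb downstream of TES
        assert by_start[12_500].gene_id is None       # upstream of the gene

    def test_matches_exhaustive_overlap_oracle(self):
        rng = np.random.default_rng(2)
        genes = []
        for i in range(8):
            start = int(rng.integers(0, 200_000))
            genes.append(gene(f"g{i}", start, start + int(rng.integers(500, 5000)),
                              "+" if i % 2 == 0 else "-"))
        sites = [site(int(s), int(s) + 50, "+" if rng.random() < 0.5 else "-")
                 for s in rng.integers(0, 220_000, size=120)]
        lib = SiteLibrary(list(sites), md=25)
        assign_sites_to_genes(lib, genes, max_extension=16_000)
        for s in lib.sites:
            iv = s.interval
            body = [g for g in genes
                    if g.strand == iv.strand and g.body.overlaps(iv)]
            if body:
                body.sort(key=lambda g: abs(
                    (iv.three_prime - g.tes) if g.strand == "+" else (g.tes - iv.three_prime)))
                assert s.gene_id == body[0].gene_id
                continue
            if any(g.body.start < iv.end and iv.start < g.body.end for g in genes):
                assert s.gene_id is None
                continue
            cands = []
            for g in genes:
                if g.strand != iv.strand:
                    continue
                d = (iv.three_prime - g.tes) if g.strand == "+" else (g.tes - iv.three_prime)
                if 0 <= d <= 16_000:
                    cands.append((d, g.gene_id))
            cands.sort()
            if not cands or (len(cands) > 1 and cands[0][0] == cands[1][0]):
                assert s.gene_id is None
            else:
                assert s.gene_id == cands[0][1]


class TestCounting:
    def test_overlap_semantics(self, tmp_path):
        # 5 reads inside site1, 1 read spanning site1+site2, 1 read in neither
        reads = [("c1", 100, 20, "+")] * 5 + [("c1", 130, 30, "+"), ("c1", 700, 20, "+")]
        bam_a = write_bam(tmp_path / "a.bam", {"c1": 2000}, reads)
        bam_b = write_bam(tmp_path / "b.bam", {"c1": 2000}, reads[:2])
        g = gene("A", 50, 400, "+")
        s1, s2 = site(100, 140, "+"), site(150, 200, "+")
        s1.gene_id = s2.gene_id = "A"
        lib = SiteLibrary([s1, s2], md=25)
        handles = {sid: pysam.AlignmentFile(p)
                   for sid, p in (("a", bam_a), ("b", bam_b),
                                  ("a2", bam_a), ("b2", bam_b))}
        mats = count_reads(handles, lib, [g],
                           {"a": "control", "b": "control",
                            "a2": "treated", "b2": "treated"})
        m = mats["A"]
        col = m.sample_ids.index("a")
        assert m.counts[0, col] == 6  # 5 contained + 1 spanning
        assert m.counts[1, col] == 1  # the spanning read counts here too
        for h in handles.values():
            h.close()

    def test_strand_mismatch_not_counted(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", {"c1": 2000}, [("c1", 100, 20, "-")] * 3)
        g = gene("A", 50, 400, "+")
        s1, s2 = site(100, 140, "+"), site(150, 200, "+")
        s1.gene_id = s2.gene_id = "A"
        lib = SiteLibrary([s1, s2], md=25)
        handles = {x: pysam.AlignmentFile(bam) for x in ("a", "b", "c", "d")}
        mats = count_reads(handles, lib, [g],
                           dict(a="control", b="control", c="treated", d="treated"))
        assert mats["A"].counts.sum() == 0
        for h in handles.values():
            h.close()


class TestFilters:
    def test_povera_passes_on_one_good_group(self):
        m = make_matrix([[10, 12, 0, 0, 0, 0], [20, 20, 20, 20, 20, 20]])
        pover_a_filter(m, p=0.6, A=5, M=10)
        assert "povera_fail" not in m.sites[0].filter_flags

    def test_povera_all_zero_fails(self):
        m = make_matrix([[0, 0, 0, 0, 0, 0], [20, 20, 20, 20, 20, 20]])
        pover_a_filter(m, p=0.6, A=5, M=10)
        assert "povera_fail" in m.sites[0].filter_flags

    def test_povera_group_max_clause_binds(self):
        m = make_matrix([[6, 6, 6, 6, 6, 6], [20, 20, 20, 20, 20, 20]])
        pover_a_filter(m, p=1.0, A=5, M=10)
        assert "povera_fail" in m.sites[0].filter_flags

    def test_proportion_fails_only_when_low_in_both_groups(self):
        m = make_matrix([[2, 2, 2, 2, 2, 2], [98, 98, 98, 98, 98, 98]])
        proportion_filter(m, mp=0.05)
        assert "proportion_fail" in m.sites[0].filter_flags
        m2 = make_matrix([[2, 2, 2, 30, 30, 30], [98, 98, 98, 70, 70, 70]])
        proportion_filter(m2, mp=0.05)
        assert "proportion_fail" not in m2.sites[0].filter_flags

    def test_proportion_mp_zero_is_vacuous(self):
        m = make_matrix([[0, 0, 0, 0, 0, 0], [98, 98, 98, 98, 98, 98]])
        proportion_filter(m, mp=0.0)
        assert all("proportion_fail" not in s.filter_flags for s in m.sites)

    def test_expression_drops_gene_weak_in_either_condition(self):
        m = make_matrix([[100, 100, 100, 1, 1, 1], [150, 100, 150, 1, 2, 1]])
        assert expression_filter(m, me=10) is False
        assert m.exclusion_reason == "gene_unexpressed"
        m2 = make_matrix([[10, 10, 10, 10, 10, 10], [10, 10, 10, 10, 10, 10]])
        assert expression_filter(m2, me=10) is True

    def test_normalize_columns_sum_to_one(self):
        m = make_matrix([[30, 3, 1, 5, 5, 5], [10, 1, 3, 5, 5, 5]])
        normalize_proportions(m)
        np.testing.assert_allclose(m.proportions.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(m.proportions[:, 0], [0.75, 0.25])

    def test_normalize_zero_column_left_zero_with_warning(self):
        m = make_matrix([[30, 0, 1, 5, 5, 5], [10, 0, 3, 5, 5, 5]])
        with pytest.warns(UserWarning):
            normalize_proportions(m)
        assert m.proportions[:, 1].sum() == 0

    def test_single_retained_site_excludes_gene(self):
        m = make_matrix([[30, 3, 1, 5, 5, 5], [0, 0, 0, 0, 0, 0]])
        pover_a_filter(m)
        normalize_proportions(m)
        assert m.exclusion_reason == "fewer_than_2_sites"
        assert not m.testable


class TestSiteOrdering:
    def test_proximal_to_distal_reverses_with_strand(self):
        gp = gene("P", 100, 1000, "+")
        gm = gene("M", 5000, 9000, "-")
        sites = [site(2000, 2050, "+"), site(3000, 3050, "+")]
        keys = [site_order_key(s, gp) for s in sites]
        assert keys[0] < keys[1]
        msites = [site(4000, 4050, "-"), site(3000, 3050, "-")]
        mkeys = [site_order_key(s, gm) for s in msites]
        assert mkeys[0] < mkeys[1]  # larger coordinate = more proximal on '-'
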