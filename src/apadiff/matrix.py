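"""Per-gene APA matrices: site-gene assignment, counting and denoising.

Each gene is abstracted as a matrix with polyA sites as rows (ordered
proximal -> distal by strand-aware distance from the gene's 3' end) and
sample replicates as columns.  Counting is followed by a fixed filter
cascade — pOverA replicate-consistency, minimum within-gene proportion,
minimum gene expression — and column normalization to within-gene site
usage proportions.  The three filters deliberately use different
quantifiers: pOverA passes if consistent in at least ONE group, the
proportion filter drops a site only when low in BOTH groups, and the
expression filter drops a gene when weak in EITHER group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from apadiff.discovery import PolyASite, SiteLibrary, _read_strand, _usable
from apadiff.intervals import GeneModel

GROUPS = ("control", "treated")

DEFAULT_MAX_EXTENSION = 16_000  # longest known 3'UTR, in bp


@dataclass
class APAMatrix:
    """Site x replicate count matrix for one gene, plus derived proportions.

    ``sites`` are ordered proximal -> distal; ``counts[i, j]`` is the read
    count of site i in replicate j.  ``proportions`` (after
    :func:`normalize_proportions`) covers only the retained sites, each
    column normalized to the within-gene total.
    """

    gene_id: str
    sites: list[PolyASite]
    counts: np.ndarray
    sample_ids: list[str]
    group_labels: list[str]
    proportions: np.ndarray | None = None
    retained_sites: list[PolyASite] = field(default_factory=list)
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sites), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_sites, n_replicates)")
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label per replicate required")
        if any(g not in GROUPS for g in self.group_labels):
            raise ValueError(f"group labels must be in {GROUPS}")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([j for j, g in enumerate(self.group_labels) if g == group])

    def retained_row_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.sites) if not s.filter_flags]

    @property
    def testable(self) -> bool:
        return self.exclusion_reason is None and self.proportions is not None


def site_order_key(site: PolyASite, gene: GeneModel) -> int:
    """Strand-aware proximal->distal sort key: 3'UTR length implied by the
    site, i.e. distance of its cleavage point from the gene's 5' side."""
    if gene.strand == "+":
        return site.cleavage_pos
    return -site.cleavage_pos


def _tes_distance(site: PolyASite, gene: GeneModel) -> int:
    """Signed downstream distance from the gene TES to the site's cleavage
    point (positive = downstream of the TES)."""
    if gene.strand == "+":
        return site.cleavage_pos - gene.tes
    return gene.tes - site.cleavage_pos


def assign_sites_to_genes(
    library: SiteLibrary,
    genes: list[GeneModel],
    max_extension: int = DEFAULT_MAX_EXTENSION,
) -> SiteLibrary:
    """Map each site to a gene, honoring the 16 kb TES-extension rule.

    A site is assigned to gene G if it overlaps G's body on the same
    strand, or lies within ``max_extension`` bp downstream of G's TES and
    does not overlap any other gene's body.  A site falling in two genes'
    extension zones goes to the gene with the nearer TES; an exact tie is
    left unassigned.  Unassignable sites are flagged ``unassigned``.
    """
    if max_extension < 0:
        raise ValueError("max_extension must be >= 0")
    for site in library:
        iv = site.interval
        body_hits = [
            g for g in genes
            if g.chrom == iv.chrom and g.strand == iv.strand and g.body.overlaps(iv)
        ]
        if body_hits:
            body_hits.sort(key=lambda g: abs(_tes_distance(site, g)))
            site.gene_id = body_hits[0].gene_id
            continue
        overlaps_any_body = any(
            g.chrom == iv.chrom and g.body.start < iv.end and iv.start < g.body.end
            for g in genes
        )
        candidates = []
        if not overlaps_any_body:
            for g in genes:
                if g.chrom != iv.chrom or g.strand != iv.strand:
                    continue
                d = _tes_distance(site, g)
                if 0 <= d <= max_extension:
                    candidates.append((d, g))
        if not candidates:
            site.flag("unassigned")
            continue
        candidates.sort(key=lambda t: t[0])
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            site.flag("unassigned")  # ambiguous extension-zone tie
            continue
        site.gene_id = candidates[0][1].gene_id
    return library


def count_reads(
    alignments: dict[str, pysam.AlignmentFile],
    library: SiteLibrary,
    genes: list[GeneModel],
    group_labels: dict[str, str],
    strandness: str = "forward",
) -> dict[str, APAMatrix]:
    """Count reads per site per replicate and build per-gene matrices.

    A read is counted for every site its aligned span overlaps (strand
    matched), once per site.  Replicates with zero mapped reads yield an
    all-zero column with a warning.
    """
    sample_ids = list(alignments)
    gene_by_id = {g.gene_id: g for g in genes}
    assigned = [s for s in library if s.gene_id is not None and not s.filter_flags]

    counts = {s.site_id: np.zeros(len(sample_ids), dtype=np.int64) for s in assigned}
    for j, sid in enumerate(sample_ids):
        bam = alignments[sid]
        if bam.mapped == 0:
            warnings.warn(f"replicate {sid!r} has zero mapped reads")
        for site in assigned:
            iv = site.interval
            n = 0
            for read in bam.fetch(iv.chrom, iv.start, iv.end):
                if _usable(read) and _read_strand(read, strandness) == iv.strand:
                    n += 1
            counts[site.site_id][j] = n

    by_gene: dict[str, list[PolyASite]] = {}
    for site in assigned:
        by_gene.setdefault(site.gene_id, []).append(site)

    matrices: dict[str, APAMatrix] = {}
    for gene_id, sites in sorted(by_gene.items()):
        gene = gene_by_id[gene_id]
        sites.sort(key=lambda s: site_order_key(s, gene))
        matrices[gene_id] = APAMatrix(
            gene_id=gene_id,
            sites=sites,
            counts=np.vstack([counts[s.site_id] for s in sites]),
            sample_ids=sample_ids,
            group_labels=[group_labels[sid] for sid in sample_ids],
        )
    return matrices


def pover_a_filter(
    matrix: APAMatrix, p: float = 0.6, A: int = 5, M: int = 10
) -> APAMatrix:
    """Replicate-consistency filter.

    A site passes iff, in at least one group, the fraction of replicates
    with count > A is >= p and the group maximum count is >= M; failing
    sites are flagged ``povera_fail``.
    """
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    for i, site in enumerate(matrix.sites):
        if site.filter_flags:
            continue
        passes = False
        for group in GROUPS:
            cols = matrix.group_columns(group)
            if cols.size == 0:
                continue
            vals = matrix.counts[i, cols]
            if (vals > A).mean() >= p and vals.max() >= M:
                passes = True
                break
        if not passes:
            site.flag("povera_fail")
    return matrix


def proportion_filter(matrix: APAMatrix, mp: float = 0.05) -> APAMatrix:
    """Drop sites carrying less than ``mp`` of the gene's reads in BOTH groups.

    Shares are computed per group over the sites still in play; a group
    with zero gene-level reads contributes share 0.
    """
    if not (0 <= mp < 1):
        raise ValueError("mp must be in [0, 1)")
    rows = matrix.retained_row_indices()
    if not rows:
        return matrix
    for group in GROUPS:
        cols = matrix.group_columns(group)
        sub = matrix.counts[np.ix_(rows, cols)]
        total = sub.sum()
        shares = sub.sum(axis=1) / total if total > 0 else np.zeros(len(rows))
        for i, share in zip(rows, shares):
            if share < mp:
                matrix.sites[i].filter_flags.add(f"_lowshare_{group}")
    for i in rows:
        site = matrix.sites[i]
        low = {f for f in site.filter_flags if f.startswith("_lowshare_")}
        site.filter_flags -= low
        if len(low) == len(GROUPS):
            site.flag("proportion_fail")
    return matrix


def expression_filter(matrix: APAMatrix, me: int = 10) -> bool:
    """Gene-level expression gate.

    Returns True if the gene is kept; a gene whose retained-site read
    total is below ``me`` in EITHER group is dropped (remaining sites
    flagged ``gene_unexpressed``).
    """
    if me < 0:
        raise ValueError("me must be >= 0")
    rows = matrix.retained_row_indices()
    keep = True
    for group in GROUPS:
        cols = matrix.group_columns(group)
        if matrix.counts[np.ix_(rows, cols)].sum() < me:
            keep = False
            break
    if not keep:
        for i in rows:
            matrix.sites[i].flag("gene_unexpressed")
        matrix.exclusion_reason = "gene_unexpressed"
    return keep


def normalize_proportions(matrix: APAMatrix) -> APAMatrix:
    """Column-normalize retained-site counts to within-gene proportions.

    Genes with fewer than two retained sites cannot show APA and are
    excluded from testing (reason recorded).  All-zero replicate columns
    are left as zeros with a warning.
    """
    rows = matrix.retained_row_indices()
    if len(rows) < 2:
        matrix.exclusion_reason = matrix.exclusion_reason or "fewer_than_2_sites"
        matrix.proportions = None
        matrix.retained_sites = [matrix.sites[i] for i in rows]
        return matrix
    sub = matrix.counts[rows, :].astype(float)
    totals = sub.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"gene {matrix.gene_id}: {int(zero.sum())} replicate column(s) with "
            "zero retained-site reads left unnormalized"
        )
    safe = np.where(zero, 1.0, totals)
    matrix.proportions = sub / safe
    matrix.retained_sites = [matrix.sites[i] for i in rows]
    return matrix
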