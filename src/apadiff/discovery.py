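"""De novo polyA-site discovery from 3'Seq alignments.

Candidate sites are maximal runs of per-base read coverage per sample
(split by read strand), pooled over all samples and merged whenever two
features on the same chrom/strand overlap or lie within a merge distance
``md`` of each other.  ``md`` absorbs the cleavage-position wobble of the
sequencing protocol; merging is transitive, so chains of nearby features
collapse into a single site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from apadiff.intervals import GenomicInterval

FILTER_FLAGS = frozenset(
    {"misprimed", "povera_fail", "proportion_fail", "gene_unexpressed", "unassigned"}
)


@dataclass
class PolyASite:
    """A candidate cleavage site in the pooled library.

    A site contributes to differential testing iff ``filter_flags`` is
    empty and ``gene_id`` is set.  ``cleavage_pos`` is the strand-aware
    3'-most base of the interval — the best point estimate of the actual
    cleavage position.
    """

    site_id: str
    interval: GenomicInterval
    annotated: bool = False
    gene_id: str | None = None
    filter_flags: set[str] = field(default_factory=set)
    peak_depth: int = 0

    @property
    def cleavage_pos(self) -> int:
        return self.interval.three_prime

    @property
    def testable(self) -> bool:
        return not self.filter_flags and self.gene_id is not None

    def flag(self, name: str) -> None:
        if name not in FILTER_FLAGS:
            raise ValueError(f"unknown filter flag {name!r}")
        self.filter_flags.add(name)


@dataclass
class SiteLibrary:
    """Pooled, merged polyA-site library, sorted by (chrom, start).

    Invariant: no two retained sites on the same chrom+strand overlap or
    lie within ``md`` bp of each other.
    """

    sites: list[PolyASite]
    md: int

    def __post_init__(self) -> None:
        self.sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.strand))

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def retained(self) -> list[PolyASite]:
        return [s for s in self.sites if "misprimed" not in s.filter_flags]


@dataclass(frozen=True)
class CoverageFeature:
    """A maximal contiguous run of per-base depth >= min_depth in one sample."""

    interval: GenomicInterval
    sample_id: str
    peak_depth: int

    def __post_init__(self) -> None:
        if self.peak_depth < 1:
            raise ValueError("peak_depth must be >= 1")


def _read_strand(read: pysam.AlignedSegment, strandness: str) -> str:
    strand = "-" if read.is_reverse else "+"
    if strandness == "reverse":
        strand = "-" if strand == "+" else "+"
    return strand


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary)


def extract_coverage_features(
    alignment: pysam.AlignmentFile,
    sample_id: str,
    min_depth: int = 1,
    strandness: str = "forward",
) -> list[CoverageFeature]:
    """Per-base coverage features from a sorted, indexed alignment.

    Depth is computed from the full aligned span of each read and
    accumulated separately per strand; each maximal run with depth >=
    ``min_depth`` becomes one feature whose ``peak_depth`` is the maximum
    per-base depth inside the run.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not alignment.has_index():
        raise ValueError(f"alignment {alignment.filename!r} is not indexed")
    features: list[CoverageFeature] = []
    for chrom, chrom_len in zip(alignment.references, alignment.lengths):
        depth = {s: None for s in "+-"}
        for read in alignment.fetch(chrom):
            if not _usable(read):
                continue
            strand = _read_strand(read, strandness)
            if depth[strand] is None:
                depth[strand] = np.zeros(chrom_len, dtype=np.int32)
            depth[strand][read.reference_start:read.reference_end] += 1
        for strand in "+-":
            cov = depth[strand]
            if cov is None:
                continue
            above = np.flatnonzero(cov >= min_depth)
            if above.size == 0:
                continue
            # split into maximal contiguous runs
            breaks = np.flatnonzero(np.diff(above) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [above.size - 1]))
            for a, b in zip(starts, ends):
                lo, hi = int(above[a]), int(above[b]) + 1
                features.append(
                    CoverageFeature(
                        GenomicInterval(chrom, lo, hi, strand),
                        sample_id,
                        int(cov[lo:hi].max()),
                    )
                )
    return features


def pool_and_merge(
    features: Iterable[Sequence[CoverageFeature]] | Sequence[CoverageFeature],
    md: int = 25,
) -> SiteLibrary:
    """Pool per-sample features and merge into a unified site library.

    Features on the same chrom and strand whose intervals overlap or whose
    gap is <= ``md`` bp are merged transitively into one site spanning
    their union.  Accepts either a flat feature list or per-sample lists;
    the result is independent of sample order.
    """
    if md < 0:
        raise ValueError("md must be >= 0")
    flat: list[CoverageFeature] = []
    for item in features:
        if isinstance(item, CoverageFeature):
            flat.append(item)
        else:
            flat.extend(item)

    by_key: dict[tuple[str, str], list[CoverageFeature]] = {}
    for f in flat:
        by_key.setdefault((f.interval.chrom, f.interval.strand), []).append(f)

    sites: list[PolyASite] = []
    for (chrom, strand), group in by_key.items():
        group.sort(key=lambda f: (f.interval.start, f.interval.end))
        cur_start, cur_end, cur_peak = None, None, 0
        merged: list[tuple[int, int, int]] = []
        for f in group:
            if cur_start is None:
                cur_start, cur_end, cur_peak = f.interval.start, f.interval.end, f.peak_depth
            elif f.interval.start - cur_end <= md:
                cur_end = max(cur_end, f.interval.end)
                cur_peak = max(cur_peak, f.peak_depth)
            else:
                merged.append((cur_start, cur_end, cur_peak))
                cur_start, cur_end, cur_peak = f.interval.start, f.interval.end, f.peak_depth
        if cur_start is not None:
            merged.append((cur_start, cur_end, cur_peak))
        for start, end, peak in merged:
            sites.append(
                PolyASite(
                    site_id=f"{chrom}:{start}-{end}:{strand}",
                    interval=GenomicInterval(chrom, start, end, strand),
                    peak_depth=peak,
                )
            )
    return SiteLibrary(sites, md=md)
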