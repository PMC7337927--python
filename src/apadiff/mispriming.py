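"""Internal-priming ("mispriming") filter.

Oligo(dT) primers intended for the poly(A) tail can anneal to genomic
adenine stretches inside the transcript body, creating false polyA sites
whose reads pile up immediately upstream of the A-stretch.  Each candidate
site is therefore extended from its strand-aware 3'-most base downstream
by a mispriming distance ``mpd`` and the extension scanned for adenine
content in mRNA sense (A on the plus strand, T on the minus-strand
reference, handled by reverse complement).  Sites whose best 20 bp window
exceeds 65% adenine are flagged as misprimed and removed — unless they lie
within ``rescue_bp`` (50 bp) of an annotated cleavage site on the same
strand, in which case they are considered accurate regardless.
"""

from __future__ import annotations

from dataclasses import dataclass

from apadiff.discovery import PolyASite, SiteLibrary
from apadiff.intervals import AnnotatedSiteDB, GenomeAccessor

DEFAULT_THRESHOLD = 0.65
DEFAULT_WINDOW = 20
DEFAULT_MPD = 20
DEFAULT_RESCUE_BP = 50


@dataclass(frozen=True)
class MisprimeVerdict:
    site_id: str
    misprimed: bool
    max_a_fraction: float
    rescued: bool
    annotated_distance: float


def max_adenine_window_fraction(seq: str, window: int = DEFAULT_WINDOW) -> float:
    """Maximum A fraction over all ``window``-length substrings of ``seq``.

    Sequences shorter than ``window`` are scored over the single
    full-length window; an empty sequence scores 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not seq:
        return 0.0
    if len(seq) <= window:
        return seq.count("A") / len(seq)
    is_a = [1 if c == "A" else 0 for c in seq]
    count = sum(is_a[:window])
    best = count
    for i in range(window, len(seq)):
        count += is_a[i] - is_a[i - window]
        if count > best:
            best = count
    return best / window


def downstream_sequence(site: PolyASite, genome: GenomeAccessor, mpd: int) -> str:
    """mRNA-sense genomic sequence of the ``mpd`` bases 3' of the site's
    cleavage point, truncated at the chromosome boundary."""
    iv = site.interval
    if iv.strand == "+":
        return genome.fetch_clipped(iv.chrom, iv.end, iv.end + mpd, "+")
    return genome.fetch_clipped(iv.chrom, iv.start - mpd, iv.start, "-")


def is_misprimed(
    site: PolyASite,
    genome: GenomeAccessor,
    mpd: int = DEFAULT_MPD,
    threshold: float = DEFAULT_THRESHOLD,
    window: int = DEFAULT_WINDOW,
) -> MisprimeVerdict:
    """Verdict for one site from downstream adenine content alone.

    ``misprimed`` is True iff the maximum sliding-window A fraction is
    strictly greater than ``threshold`` (a window at exactly the threshold
    is not filtered).  Rescue is decided separately by
    :func:`apply_mispriming_filter`.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    seq = downstream_sequence(site, genome, mpd)
    frac = max_adenine_window_fraction(seq, window)
    return MisprimeVerdict(
        site_id=site.site_id,
        misprimed=frac > threshold,
        max_a_fraction=frac,
        rescued=False,
        annotated_distance=float("inf"),
    )


def apply_mispriming_filter(
    library: SiteLibrary,
    genome: GenomeAccessor,
    annot: AnnotatedSiteDB,
    mpd: int = DEFAULT_MPD,
    threshold: float = DEFAULT_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    rescue_bp: int = DEFAULT_RESCUE_BP,
) -> tuple[SiteLibrary, list[MisprimeVerdict]]:
    """Remove misprimed sites with annotation rescue.

    A site flagged by the adenine scan is retained anyway when its
    cleavage point lies within ``rescue_bp`` of an annotated cleavage site
    on the same chrom and strand.  All sites within ``rescue_bp`` of an
    annotated site are marked ``annotated=True`` (novel otherwise).  The
    full verdict list is returned for attrition reporting.
    """
    if rescue_bp < 0:
        raise ValueError("rescue_bp must be >= 0")
    verdicts: list[MisprimeVerdict] = []
    retained: list[PolyASite] = []
    for site in library:
        base = is_misprimed(site, genome, mpd=mpd, threshold=threshold, window=window)
        iv = site.interval
        dist = annot.nearest_distance(iv.chrom, site.cleavage_pos, iv.strand)
        site.annotated = dist <= rescue_bp
        rescued = base.misprimed and site.annotated
        verdicts.append(
            MisprimeVerdict(
                site_id=site.site_id,
                misprimed=base.misprimed and not rescued,
                max_a_fraction=base.max_a_fraction,
                rescued=rescued,
                annotated_distance=dist,
            )
        )
        if base.misprimed and not rescued:
            site.flag("misprimed")
        else:
            retained.append(site)
    return SiteLibrary(retained, md=library.md), verdicts
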