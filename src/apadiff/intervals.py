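"""Reference input/output and the coordinate conventions the package obeys.

Every coordinate in the package is 0-based, half-open, BED-native.
1-based coordinates appear only in human-readable report columns that are
explicitly labelled as such.  Strand is always ``+`` or ``-`` and strand
matching is required wherever two genomic features are compared (site-gene
assignment, annotation rescue): 3'Seq libraries are stranded and an
adenine stretch on one strand is a thymine stretch on the other.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strand-aware half-open interval: [start, end) on ``chrom``.

    ``start`` is 0-based inclusive, ``end`` exclusive; the unit of all
    site arithmetic in the package.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def three_prime(self) -> int:
        """0-based coordinate of the strand-aware 3'-most base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its annotated body and transcriptional end site (TES).

    The TES is the strand-aware 3' boundary of the body: the BED end for a
    plus-strand gene, the BED start for a minus-strand gene.
    """

    gene_id: str
    body: GenomicInterval

    @property
    def tes(self) -> int:
        return self.body.end if self.body.strand == "+" else self.body.start

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def chrom(self) -> str:
        return self.body.chrom


class GenomeAccessor:
    """Uppercase sequence access to an indexed FASTA, by GenomicInterval.

    Minus-strand queries return the reverse complement so the caller always
    sees mRNA-sense sequence.
    """

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        self._fasta = Fasta(str(path), sequence_always_upper=True,
                            duplicate_action="stop")
        self.chrom_lengths = {name: len(rec) for name, rec in self._fasta.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval`` in mRNA sense (revcomp for minus strand)."""
        length = self.chrom_lengths.get(interval.chrom)
        if length is None:
            raise KeyError(f"unknown sequence {interval.chrom!r}")
        if interval.end > length:
            raise IndexError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds sequence length {length}"
            )
        seq = str(self._fasta[interval.chrom][interval.start:interval.end])
        return reverse_complement(seq) if interval.strand == "-" else seq

    def fetch_clipped(self, chrom: str, start: int, end: int, strand: str) -> str:
        """Like :meth:`fetch` but truncating at chromosome boundaries."""
        length = self.chrom_lengths[chrom]
        start = max(0, start)
        end = min(length, end)
        if start >= end:
            return ""
        return self.fetch(GenomicInterval(chrom, start, end, strand))


def read_genome(path: str | Path) -> GenomeAccessor:
    """Open an (indexable) FASTA genome for interval queries."""
    return GenomeAccessor(path)


def _parse_bed6(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            if strand not in STRANDS:
                raise ValueError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}"
                )
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            yield lineno, chrom, start_i, end_i, name, score, strand


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 or GTF (gene features).

    GTF ``gene`` records are mapped to the BED convention: the 1-based
    inclusive GTF span [start, end] becomes the half-open [start-1, end),
    and the gene_id attribute becomes the identifier.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gene_models_gtf(path)
    genes = []
    for lineno, chrom, start, end, name, _score, strand in _parse_bed6(path):
        genes.append(GeneModel(name, GenomicInterval(chrom, start, end, strand)))
    return genes


def _read_gene_models_gtf(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-'")
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: gene feature without gene_id")
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, int(start) - 1, int(end), strand))
            )
    return genes


@dataclass
class AnnotatedSiteDB:
    """Sorted single-base annotated cleavage positions, per (chrom, strand).

    BED records are reduced to their strand-aware 3'-most base, since an
    annotated cleavage site is a position, not an interval.  Supports
    nearest-distance queries used by the annotation rescue of the
    internal-priming filter.
    """

    positions: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    @classmethod
    def from_positions(cls, entries) -> "AnnotatedSiteDB":
        """Build from an iterable of (chrom, position, strand)."""
        db: dict[tuple[str, str], list[int]] = {}
        for chrom, pos, strand in entries:
            db.setdefault((chrom, strand), []).append(int(pos))
        for key in db:
            db[key].sort()
        return cls(db)

    def __len__(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def nearest_distance(self, chrom: str, pos: int, strand: str) -> float:
        """Minimum base distance from ``pos`` to any annotated site on the
        same chrom and strand; ``inf`` when none exist."""
        sites = self.positions.get((chrom, strand))
        if not sites:
            return float("inf")
        i = bisect.bisect_left(sites, pos)
        best = float("inf")
        if i < len(sites):
            best = min(best, abs(sites[i] - pos))
        if i > 0:
            best = min(best, abs(sites[i - 1] - pos))
        return best


def read_annotated_sites(path: str | Path) -> AnnotatedSiteDB:
    """Read an annotated cleavage-site database from BED.

    Each record is collapsed to its strand-aware 3'-most base.  An empty
    file yields an empty DB (annotation rescue simply never fires).
    """
    entries = []
    for _lineno, chrom, start, end, _name, _score, strand in _parse_bed6(path):
        three_prime = end - 1 if strand == "+" else start
        entries.append((chrom, three_prime, strand))
    return AnnotatedSiteDB.from_positions(entries)
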