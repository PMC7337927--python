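"""Synthetic 3'Seq study generator with known ground truth.

Builds a random genome, strand-alternating gene models with 2-5 cleavage
sites spaced 200-2000 bp within/beyond the 3'UTR, an annotated-site BED
covering a configurable subset of the true sites, and per-replicate
sorted/indexed BAMs of single-end 60 bp reads whose 3' ends pile up at
the cleavage points.  Known APA effects (a fixed usage mass moved from
the most distal to the most proximal site in "treated") and internal
priming artifacts (reads ending just upstream of a planted genomic
A-stretch) are programmed in, so every pipeline stage can be checked
against the truth table.

Replicate-level usage proportions are jittered around the condition truth
with a symmetric-concentration Dirichlet, which keeps them on the simplex
with tunable dispersion.  The generator emulates clean, ungapped 3'Seq
alignments only: no sequencing errors, quality variation or fragment-length
modeling, and cleavage-position wobble is a small uniform jitter rather
than a protocol-specific profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimSpec:
    """Study conditions for the synthetic fixture.

    Defaults describe a small two-condition 3'Seq experiment: 50 genes of
    which 10 carry a programmed distal-to-proximal usage shift of 0.4,
    3 vs 3 replicates, ~1000 reads per gene per replicate, one internal
    priming decoy per gene attracting 20% of its reads, and half of the
    true sites present in the annotated database.
    """

    n_genes: int = 50
    n_shifted: int = 10
    min_sites: int = 2
    max_sites: int = 5
    min_spacing: int = 200
    max_spacing: int = 2000
    reads_per_gene: int = 1000
    replicates_per_group: int = 3
    effect: float = 0.4
    mispriming_rate: float = 0.2
    annotated_fraction: float = 0.5
    dirichlet_concentration: float = 200.0
    read_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.min_sites <= self.max_sites):
            raise ValueError("need 2 <= min_sites <= max_sites")
        if self.n_shifted > self.n_genes:
            raise ValueError("n_shifted cannot exceed n_genes")
        if not (0 <= self.effect <= 0.6):
            raise ValueError("effect must be in [0, 0.6]")
        if self.min_spacing < 2 * self.read_length:
            raise ValueError("min_spacing must exceed twice the read length")


@dataclass
class SimReference:
    fasta: Path
    genes_bed: Path
    polyadb_bed: Path
    truth_tsv: Path
    truth: pd.DataFrame
    chrom_sequences: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


_GENE_PITCH = 25_000
_MARGIN = 2_000
_SANITIZE_LEN = 50  # bp downstream of each true cleavage kept A-poor
_STRETCH_LEN = 20   # planted decoy adenine stretch


def _write_clean_downstream(seq: np.ndarray, cleavage: int, strand: str,
                            rng: np.random.Generator) -> None:
    """Resample the region 3' of a true cleavage point with low adenine
    content (in mRNA sense) so no true site trips the mispriming scan."""
    clean = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8),
        size=_SANITIZE_LEN,
        p=[0.10, 0.30, 0.30, 0.30],
    )
    if strand == "+":
        seq[cleavage + 1:cleavage + 1 + _SANITIZE_LEN] = clean
    else:
        # sense A is reference T on the minus strand; reverse-complement
        comp = np.frombuffer(b"TGCA", dtype=np.uint8)[
            np.searchsorted(_BASES, clean)
        ][::-1]
        seq[cleavage - _SANITIZE_LEN:cleavage] = comp


def _plant_a_stretch(seq: np.ndarray, decoy: int, strand: str) -> None:
    if strand == "+":
        seq[decoy + 1:decoy + 1 + _STRETCH_LEN] = ord("A")
    else:
        seq[decoy - _STRETCH_LEN:decoy] = ord("T")


def generate_reference(spec: SimSpec, outdir: str | Path) -> SimReference:
    """Generate FASTA genome, gene BED, annotated-site BED and truth table.

    Genes alternate strands across two chromosomes; each gene's most
    proximal cleavage point sits at the annotated TES, remaining sites lie
    downstream of the TES (exercising the TES-extension assignment rule).
    The same seed always produces byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    per_chrom = (spec.n_genes + 1) // 2
    chrom_of = lambda g: "chr1" if g < per_chrom else "chr2"
    idx_on_chrom = lambda g: g if g < per_chrom else g - per_chrom

    shifted = set(range(spec.n_shifted))  # deterministic: first genes shifted
    records = []
    for g in range(spec.n_genes):
        chrom = chrom_of(g)
        base = _MARGIN + idx_on_chrom(g) * _GENE_PITCH
        strand = "+" if g % 2 == 0 else "-"
        n_sites = int(rng.integers(spec.min_sites, spec.max_sites + 1))
        spacings = rng.integers(spec.min_spacing, spec.max_spacing + 1,
                                size=n_sites - 1)
        if strand == "+":
            proximal = base + 1500
            cleavages = proximal + np.concatenate(([0], np.cumsum(spacings)))
            body = (base + 500, proximal + 1)
            decoy = int(proximal + spacings[0] // 2)
        else:
            proximal = base + 12_000
            cleavages = proximal - np.concatenate(([0], np.cumsum(spacings)))
            body = (proximal, base + 13_000)
            decoy = int(proximal - spacings[0] // 2)

        # condition truth: control distal-heavy; shifted genes move
        # `effect` usage mass from the most distal to the most proximal site
        raw = rng.dirichlet(np.full(n_sites, 5.0))
        control = raw * 0.4
        control[-1] += 0.6
        treated = control.copy()
        if g in shifted:
            treated[-1] -= spec.effect
            treated[0] += spec.effect
        annotated = rng.random(n_sites) < spec.annotated_fraction

        for i, c in enumerate(cleavages):
            records.append(dict(
                gene_id=f"gene{g:03d}", chrom=chrom, strand=strand,
                body_start=body[0], body_end=body[1],
                site_index=i, cleavage=int(c), is_decoy=False,
                annotated=bool(annotated[i]),
                control_usage=float(control[i]), treated_usage=float(treated[i]),
                shifted=g in shifted,
            ))
        if spec.mispriming_rate > 0:
            records.append(dict(
                gene_id=f"gene{g:03d}", chrom=chrom, strand=strand,
                body_start=body[0], body_end=body[1],
                site_index=-1, cleavage=decoy, is_decoy=True,
                annotated=False, control_usage=0.0, treated_usage=0.0,
                shifted=g in shifted,
            ))

    truth = pd.DataFrame.from_records(records)

    chrom_lengths = {
        "chr1": _MARGIN * 2 + per_chrom * _GENE_PITCH,
        "chr2": _MARGIN * 2 + (spec.n_genes - per_chrom) * _GENE_PITCH,
    }
    sequences = {
        chrom: rng.choice(_BASES, size=length)
        for chrom, length in chrom_lengths.items()
    }
    for rec in records:
        seq = sequences[rec["chrom"]]
        if rec["is_decoy"]:
            _plant_a_stretch(seq, rec["cleavage"], rec["strand"])
        else:
            _write_clean_downstream(seq, rec["cleavage"], rec["strand"], rng)

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), 80):
                fh.write(raw[i:i + 80] + "\n")

    genes_bed = outdir / "genes.bed"
    with open(genes_bed, "w") as fh:
        for gene_id, grp in truth.groupby("gene_id", sort=True):
            r = grp.iloc[0]
            fh.write(f"{r.chrom}\t{r.body_start}\t{r.body_end}\t{gene_id}\t0\t{r.strand}\n")

    polyadb_bed = outdir / "polyadb.bed"
    with open(polyadb_bed, "w") as fh:
        ann = truth[truth.annotated & ~truth.is_decoy]
        for _, r in ann.iterrows():
            fh.write(f"{r.chrom}\t{r.cleavage}\t{r.cleavage + 1}\t"
                     f"{r.gene_id}.PA{r.site_index}\t0\t{r.strand}\n")

    truth_tsv = outdir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)

    return SimReference(
        fasta=fasta, genes_bed=genes_bed, polyadb_bed=polyadb_bed,
        truth_tsv=truth_tsv, truth=truth, chrom_sequences=sequences,
    )


def generate_alignments(
    spec: SimSpec, reference: SimReference, outdir: str | Path
) -> tuple[dict[str, Path], dict[str, str]]:
    """Simulate per-replicate sorted, indexed BAMs.

    Per replicate and gene, a Poisson read total around ``reads_per_gene``
    is split across true sites by a Dirichlet-jittered copy of the
    condition truth, with ``mispriming_rate`` of reads diverted to the
    planted decoy.  Reads are ungapped, MAPQ 60, and end (strand-aware)
    within 5 bp of the assigned cleavage point.

    Returns (sample_id -> BAM path, sample_id -> group label).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    L = spec.read_length

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, seq in reference.chrom_sequences.items():
        header_lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
    header = "\n".join(header_lines) + "\n"

    genes = reference.truth.groupby("gene_id", sort=True)
    bam_paths: dict[str, Path] = {}
    groups: dict[str, str] = {}
    qual = "I" * L

    for group, usage_col in (("control", "control_usage"), ("treated", "treated_usage")):
        for rep in range(spec.replicates_per_group):
            sample = f"{group}{rep + 1}"
            lines = []
            serial = 0
            for gene_id, grp in genes:
                sites = grp[~grp.is_decoy].sort_values("site_index")
                decoys = grp[grp.is_decoy]
                strand = sites.iloc[0].strand
                chrom = sites.iloc[0].chrom
                seq_arr = reference.chrom_sequences[chrom]
                n_reads = int(rng.poisson(spec.reads_per_gene))
                if n_reads == 0:
                    continue
                truth_props = sites[usage_col].to_numpy()
                props = rng.dirichlet(spec.dirichlet_concentration * truth_props)
                positions = sites.cleavage.to_numpy()
                if len(decoys) and spec.mispriming_rate > 0:
                    props = np.append(props * (1 - spec.mispriming_rate),
                                      spec.mispriming_rate)
                    positions = np.append(positions, decoys.iloc[0].cleavage)
                alloc = rng.multinomial(n_reads, props)
                for cleavage, count in zip(positions, alloc):
                    if count == 0:
                        continue
                    jitter = rng.integers(0, 6, size=count)
                    for j in jitter:
                        if strand == "+":
                            end = int(cleavage) + 1 - int(j)
                            start = end - L
                            flag = 0
                        else:
                            start = int(cleavage) + int(j)
                            flag = 16
                        seq = seq_arr[start:start + L].tobytes().decode()
                        serial += 1
                        lines.append(
                            f"r{sample}.{serial}\t{flag}\t{chrom}\t{start + 1}\t60\t"
                            f"{L}M\t*\t0\t0\t{seq}\t{qual}"
                        )
            sam_path = outdir / f"{sample}.sam"
            with open(sam_path, "w") as fh:
                fh.write(header)
                if lines:
                    fh.write("\n".join(lines) + "\n")
            bam_path = outdir / f"{sample}.bam"
            pysam.sort("-o", str(bam_path), str(sam_path))
            pysam.index(str(bam_path))
            sam_path.unlink()
            bam_paths[sample] = bam_path
            groups[sample] = group
    return bam_paths, groups
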