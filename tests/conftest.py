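"""Shared fixtures: tiny hand-built references/BAMs and the synthetic study."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from apadiff.simulate import SimSpec, generate_alignments, generate_reference


def write_fasta(path: Path, sequences: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_bam(path: Path, chrom_lengths: dict[str, int],
              reads: list[tuple[str, int, int, str]]) -> Path:
    """Build a sorted+indexed BAM from (chrom, start, length, strand) reads."""
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{c}\tLN:{n}" for c, n in chrom_lengths.items()]
    lines = []
    for i, (chrom, start, length, strand) in enumerate(reads):
        flag = 16 if strand == "-" else 0
        lines.append(
            f"r{i}\t{flag}\t{chrom}\t{start + 1}\t60\t{length}M\t*\t0\t0\t"
            f"{'A' * length}\t{'I' * length}"
        )
    sam = path.with_suffix(".sam")
    sam.write_text("\n".join(header + lines) + "\n")
    pysam.sort("-o", str(path), str(sam))
    pysam.index(str(path))
    sam.unlink()
    return path


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 12-gene synthetic study (4 shifted), small enough for fast tests."""
    root = tmp_path_factory.mktemp("small_study")
    spec = SimSpec(n_genes=12, n_shifted=4, reads_per_gene=500, seed=11)
    ref = generate_reference(spec, root / "ref")
    bams, groups = generate_alignments(spec, ref, root / "aln")
    return spec, ref, bams, groups
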