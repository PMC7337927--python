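"""Simulate a two-condition 3'Seq study and run the full pipeline.

Builds a 20-gene synthetic study (5 genes carry a programmed 0.4
distal-to-proximal usage shift, every gene has an internal-priming decoy),
runs discovery -> mispriming filter -> denoising -> consensus NMF ->
beta LRT -> projection scoring, and prints the gene-level results table.
"""

import tempfile
from pathlib import Path

from apadiff.pipeline import RunConfig, run_pipeline
from apadiff.simulate import SimSpec, generate_alignments, generate_reference

workdir = Path(tempfile.mkdtemp(prefix="apadiff_example_"))
spec = SimSpec(n_genes=20, n_shifted=5, reads_per_gene=800, seed=42)
ref = generate_reference(spec, workdir / "ref")
bams, groups = generate_alignments(spec, ref, workdir / "aln")

config = RunConfig(
    control_bams=[str(p) for s, p in bams.items() if groups[s] == "control"],
    treated_bams=[str(p) for s, p in bams.items() if groups[s] == "treated"],
    genome=str(ref.fasta),
    genes=str(ref.genes_bed),
    polyadb=str(ref.polyadb_bed),
    ni=50,
    base_seed=7,
)
result = run_pipeline(config, workdir / "out")

print("Site attrition per filter stage:")
for stage, n in result.attrition.items():
    print(f"  {stage:18s} {n}")
print()
print(result.results.to_string(index=False))
print()
print(
    "Genes with q <= 0.05 AND a directional call are the detected APA\n"
    "changes; negative scores mean 3'UTR shortening (usage moved toward\n"
    "proximal polyA sites), and |score| reflects how much usage moved and\n"
    "how far along the 3'UTR.  The five programmed genes (gene000-gene004)\n"
    "should top the table with scores near -0.4."
)
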