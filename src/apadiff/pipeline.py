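"""End-to-end orchestration: discovery -> filters -> per-gene testing.

``run_pipeline`` executes the full analysis on two labelled groups of
replicate BAMs and writes four artifacts to the output directory:

* ``results.tsv``   — gene-level table sorted by q then |score|
* ``sites.bed``     — retained polyA sites (novel/annotated in the name)
* ``attrition.tsv`` — sites removed per filter stage
* ``run.log``       — machine-readable JSON of config, seeds and versions

Runs are deterministic: per-gene NMF seeds are derived from the base seed
and the sorted gene order, so identical inputs and configuration yield
byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

import apadiff
from apadiff.betalrt import adjust_fdr, lrt_test
from apadiff.discovery import SiteLibrary, extract_coverage_features, pool_and_merge
from apadiff.intervals import (
    AnnotatedSiteDB,
    GenomicInterval,
    read_annotated_sites,
    read_gene_models,
    read_genome,
)
from apadiff.matrix import (
    assign_sites_to_genes,
    count_reads,
    expression_filter,
    normalize_proportions,
    pover_a_filter,
    proportion_filter,
)
from apadiff.mispriming import apply_mispriming_filter
from apadiff.nmf import consensus_matrix, stability_score
from apadiff.projection import apa_score
from apadiff.discovery import PolyASite

RESULT_COLUMNS = [
    "gene_id", "n_sites_tested", "lrt_stat", "p_value", "q_value",
    "stability", "score", "direction",
]

ATTRITION_STAGES = [
    "misprimed", "unassigned", "povera_fail", "proportion_fail",
    "gene_unexpressed",
]


@dataclass
class RunConfig:
    """Full configuration of one run; serialized verbatim into run.log."""

    control_bams: list[str]
    treated_bams: list[str]
    genome: str
    genes: str
    polyadb: str | None = None
    md: int = 25
    mpd: int = 20
    window: int = 20
    a_threshold: float = 0.65
    rescue_bp: int = 50
    min_depth: int = 1
    max_extension: int = 16_000
    p: float = 0.6
    A: int = 5
    M: int = 10
    mp: float = 0.05
    me: int = 10
    ni: int = 100
    base_seed: int = 7
    fdr_cutoff: float = 0.05
    nochange_delta: float = 0.05
    strandness: str = "forward"

    def __post_init__(self) -> None:
        if len(self.control_bams) < 2 or len(self.treated_bams) < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.strandness not in ("forward", "reverse"):
            raise ValueError("strandness must be 'forward' or 'reverse'")


@dataclass
class PipelineResult:
    results: pd.DataFrame
    library: SiteLibrary
    attrition: dict[str, int]
    verdicts: list
    matrices: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)


def _sample_ids(config: RunConfig) -> tuple[dict[str, str], dict[str, str]]:
    """Map unique sample ids to paths and group labels."""
    paths: dict[str, str] = {}
    groups: dict[str, str] = {}
    for group, files in (("control", config.control_bams),
                         ("treated", config.treated_bams)):
        for i, f in enumerate(files):
            sid = Path(f).stem
            if sid in paths:
                sid = f"{sid}.{group}{i}"
            paths[sid] = f
            groups[sid] = group
    return paths, groups


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Run the full differential-APA analysis and write all outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_genome(config.genome)
    genes = read_gene_models(config.genes)
    annot = (read_annotated_sites(config.polyadb)
             if config.polyadb else AnnotatedSiteDB())

    paths, groups = _sample_ids(config)
    handles = {sid: pysam.AlignmentFile(p, "rb") for sid, p in paths.items()}

    per_sample = [
        extract_coverage_features(h, sid, min_depth=config.min_depth,
                                  strandness=config.strandness)
        for sid, h in handles.items()
    ]
    library = pool_and_merge(per_sample, md=config.md)
    n_discovered = len(library)

    library, verdicts = apply_mispriming_filter(
        library, genome, annot,
        mpd=config.mpd, threshold=config.a_threshold,
        window=config.window, rescue_bp=config.rescue_bp,
    )
    library = assign_sites_to_genes(library, genes,
                                    max_extension=config.max_extension)
    matrices = count_reads(handles, library, genes, groups,
                           strandness=config.strandness)

    excluded: dict[str, str] = {}
    testable = {}
    for gene_id, m in matrices.items():
        pover_a_filter(m, p=config.p, A=config.A, M=config.M)
        proportion_filter(m, mp=config.mp)
        if not expression_filter(m, me=config.me):
            excluded[gene_id] = "gene_unexpressed"
            continue
        normalize_proportions(m)
        if not m.testable:
            excluded[gene_id] = m.exclusion_reason
            continue
        testable[gene_id] = m

    prior_cache: dict[str, np.ndarray] = {}
    rows = []
    consensus = {}
    for idx, (gene_id, m) in enumerate(sorted(testable.items())):
        prior = np.array([0 if g == "control" else 1 for g in m.group_labels])
        seed = config.base_seed + idx * config.ni
        cm = consensus_matrix(m.proportions, prior, ni=config.ni, base_seed=seed)
        consensus[gene_id] = cm
        test = lrt_test(cm, gene_id=gene_id)
        if test is None:
            excluded[gene_id] = "untestable_pair_counts"
            continue
        score = apa_score(m, delta=config.nochange_delta)
        if score is None:
            excluded[gene_id] = "degenerate_group"
            continue
        rows.append(dict(
            gene_id=gene_id,
            n_sites_tested=len(m.retained_sites),
            lrt_stat=test.lrt_stat,
            p_value=test.p_value,
            q_value=np.nan,
            stability=stability_score(cm),
            score=score.score,
            direction=score.direction,
        ))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(results):
        results["q_value"] = adjust_fdr(results["p_value"].to_numpy())
        # ascending q, then descending |score|
        results = results.assign(_abs=results["score"].abs()).sort_values(
            ["q_value", "_abs"], ascending=[True, False]
        ).drop(columns="_abs").reset_index(drop=True)
    else:
        warnings.warn("no testable genes; writing empty results table")

    attrition = _attrition(library, verdicts, n_discovered)

    results.to_csv(outdir / "results.tsv", sep="\t", index=False,
                   float_format="%.6g")
    write_site_bed(library, outdir / "sites.bed")
    pd.Series(attrition, name="n_sites").rename_axis("stage").to_frame() \
        .to_csv(outdir / "attrition.tsv", sep="\t")
    _write_run_log(config, outdir / "run.log", n_discovered, len(results))

    for h in handles.values():
        h.close()
    return PipelineResult(
        results=results, library=library, attrition=attrition,
        verdicts=verdicts, matrices=matrices, consensus=consensus,
        excluded=excluded,
    )


def _attrition(library: SiteLibrary, verdicts, n_discovered: int) -> dict[str, int]:
    counts = {stage: 0 for stage in ATTRITION_STAGES}
    counts["misprimed"] = sum(1 for v in verdicts if v.misprimed)
    for site in library:
        for stage in ATTRITION_STAGES[1:]:
            if stage in site.filter_flags:
                counts[stage] += 1
                break
    counts["discovered"] = n_discovered
    counts["retained"] = n_discovered - sum(
        counts[s] for s in ATTRITION_STAGES
    )
    return counts


def _write_run_log(config: RunConfig, path: Path, n_discovered: int,
                   n_tested: int) -> None:
    log = dict(
        config=asdict(config),
        versions=dict(
            apadiff=apadiff.__version__,
            numpy=np.__version__,
            pandas=pd.__version__,
            pysam=pysam.__version__,
        ),
        n_sites_discovered=n_discovered,
        n_genes_tested=n_tested,
    )
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")


def write_site_bed(library: SiteLibrary, path: str | Path) -> None:
    """Emit retained (non-misprimed) sites as BED6.

    Name encodes ``gene|chrom:start-end:strand|status`` with status
    ``annotated`` or ``novel``; score is the pooled peak depth.  Records
    are sorted by (chrom, start) and the file round-trips through
    :func:`read_site_bed`.
    """
    with open(path, "w") as fh:
        for site in sorted(library.retained(),
                           key=lambda s: (s.interval.chrom, s.interval.start)):
            iv = site.interval
            status = "annotated" if site.annotated else "novel"
            name = f"{site.gene_id or 'NA'}|{site.site_id}|{status}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                     f"{site.peak_depth}\t{iv.strand}\n")


def read_site_bed(path: str | Path, md: int = 25) -> SiteLibrary:
    """Inverse of :func:`write_site_bed` (filter flags are not persisted)."""
    sites = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            gene_id, site_id, status = name.split("|")
            sites.append(PolyASite(
                site_id=site_id,
                interval=GenomicInterval(chrom, int(start), int(end), strand),
                annotated=status == "annotated",
                gene_id=None if gene_id == "NA" else gene_id,
                peak_depth=int(score),
            ))
    return SiteLibrary(sites, md=md)
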