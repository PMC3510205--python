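"""End-to-end orchestration: datasets on disk -> stage tables -> report.

A run consumes three aligned libraries (nucRNA-Seq, RNAPII ChIP-Seq,
genomic input), a gene annotation, and optionally a conservation track and
TF peak BEDs; it emits one TSV per stage plus a JSON summary carrying the
config hash and seed, and re-running the same config reproduces the tables
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import coverage as cov
from . import expression_classes as xc
from . import io_formats as iof
from . import lncrna as lnc
from . import regulatory as reg
from . import stalling as st
from .coverage import TagCollection
from .genome import GeneModel, GenomicInterval
from .synthetic_data import (
    SimConfig,
    SyntheticDataset,
    simulate_library_arrays,
    simulate_tracks,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Stage parameters; defaults follow the study's stated values."""

    window_size: int = 10_000
    pseudocount: float = 1.0
    window_stat: str = "max"
    min_gene_length: int = 300
    trim: float = 0.05
    stall_flank: int = 300
    stall_percentile: float = 95.0
    peak_window: int = 20
    peak_p: float = 0.001
    peak_halfwidth: int = 100
    nucrna_max_gap: int = 100
    nucrna_min_size: int = 1000
    tss_flank: int = 500
    near_distance: int = 10_000
    conservation_cut: float = 0.8
    conservation_span: int = 1000
    tf_bin: int = 1000
    strict_gap: int = 2000
    strict_min: int = 4500
    sensitive_gap: int = 1000
    sensitive_min: int = 2500
    sensitive_merge: int = 5000
    selection_rule: str = "boxplot"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    params: PipelineParams
    thresholds: xc.ClassThresholds
    gene_classes: list[xc.ClassifiedRegion]
    window_classes: list[xc.ClassifiedRegion]
    efficiency: dict[str, float]
    stalling_records: list[st.StallingRecord]
    stall_cutoffs: tuple[float, float]
    stall_kw: Optional[tuple[float, float]]
    peaks: list[reg.PeakRegion]
    nucrna_regions: list[GenomicInterval]
    candidates: list[reg.CandidateRegion]
    positional_fractions: dict[str, float]
    conservation: Optional[object]
    tf_per: dict
    tf_combined: Optional[object]
    erythroid_subset: list
    contigs: list[lnc.ContigCandidate]
    contig_counts: dict
    selection: dict


def analyze(
    genes: list[GeneModel],
    nuc_tags: TagCollection,
    pol_tags: TagCollection,
    input_tags: TagCollection,
    conservation: Optional[dict[str, np.ndarray]] = None,
    tf_peaks: Optional[dict[str, list[GenomicInterval]]] = None,
    params: Optional[PipelineParams] = None,
) -> PipelineResult:
    """Run every analysis stage in dependency order on in-memory inputs."""
    p = params or PipelineParams()
    nuc_cov = nuc_tags.coverage()
    pol_cov = pol_tags.coverage()
    inp_cov = input_tags.coverage()

    # expression classes on windows and genes
    wscores = cov.window_scores(
        nuc_cov, pol_cov, inp_cov, p.window_size, p.window_stat, p.pseudocount, genes
    )
    _, window_classes = xc.classify(wscores, min_gene_length=0)
    gscores = cov.gene_scores(genes, nuc_cov, pol_cov, inp_cov, p.window_stat, p.pseudocount)
    thresholds, gene_classes = xc.classify(gscores, p.min_gene_length)
    efficiency = xc.efficiency_ratio(gene_classes, p.trim)

    # stalling
    records = st.compute_records(
        genes, pol_cov, nuc_cov, inp_cov, p.stall_flank, p.min_gene_length, p.pseudocount
    )
    try:
        pr_cut, tp_cut, records = st.categorize(records, p.stall_percentile)
    except ValueError:
        pr_cut = tp_cut = float("nan")
    try:
        _, kw_h, kw_p = st.body_ratio_by_category(records)
        stall_kw = (kw_h, kw_p)
    except ValueError:
        stall_kw = None

    # regulatory candidates
    try:
        peaks = reg.call_peaks(pol_tags, p.peak_window, p.peak_p, p.peak_halfwidth)
    except ValueError:
        logger.warning("peak calling skipped (unstranded tags)")
        peaks = []
    regions = reg.nucrna_regions(nuc_tags, p.nucrna_max_gap, p.nucrna_min_size)
    survivors = reg.subtract_transcribed(peaks, regions)
    candidates = reg.positional_classify(survivors, genes, p.tss_flank, p.near_distance)
    fractions = reg.positional_fractions(candidates)
    cons_result = None
    if conservation is not None and candidates:
        cons_result = reg.conservation_enrichment(
            candidates, conservation, nuc_tags.chrom_sizes,
            p.conservation_cut, p.conservation_span, p.seed,
        )
    elif conservation is None:
        logger.warning("no conservation track: conservation enrichment skipped")
    tf_per, tf_combined, subset = {}, None, []
    if tf_peaks and candidates:
        tf_per, tf_combined, subset = reg.tf_overlap_enrichment(
            candidates, tf_peaks, nuc_tags.chrom_sizes, p.tf_bin
        )

    # lncRNA discovery
    exclusion = [g.span for g in genes]
    contigs, counts = lnc.discover(
        nuc_tags, exclusion,
        strict=(p.strict_gap, p.strict_min),
        sensitive=(p.sensitive_gap, p.sensitive_min, p.sensitive_merge),
    )
    lnc.quantify(contigs, nuc_cov, pol_cov, p.pseudocount)
    selection = (
        lnc.select_stable(contigs, rule=p.selection_rule) if contigs else {"rule": p.selection_rule}
    )

    return PipelineResult(
        params=p, thresholds=thresholds,
        gene_classes=gene_classes, window_classes=window_classes,
        efficiency=efficiency, stalling_records=records,
        stall_cutoffs=(pr_cut, tp_cut), stall_kw=stall_kw,
        peaks=peaks, nucrna_regions=regions, candidates=candidates,
        positional_fractions=fractions, conservation=cons_result,
        tf_per=tf_per, tf_combined=tf_combined, erythroid_subset=subset,
        contigs=contigs, contig_counts=counts, selection=selection,
    )


# ---------------------------------------------------------------------------
# Dataset persistence (synthetic datasets round-trip through standard formats)
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: SyntheticDataset, outdir, format: str = "bed"
) -> dict[str, Path]:
    """Simulate all three libraries and tracks and write them to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    with open(outdir / "chrom.sizes", "w") as fh:
        for c, s in sorted(dataset.chrom_sizes.items()):
            fh.write(f"{c}\t{s}\n")
    paths["chrom_sizes"] = outdir / "chrom.sizes"

    iof.write_annotation(dataset.genes, outdir / "annotation.gtf")
    paths["annotation"] = outdir / "annotation.gtf"

    for lib in ("nucRNA", "RNAPII", "input"):
        tags = simulate_library_arrays(dataset, lib)
        path = outdir / f"{lib}.{format}"
        if format == "bed":
            iof.write_bed(
                [t.interval for t in tags.iter_tags()], path,
            )
        else:
            iof.write_sam(tags.iter_tags(), path, dataset.chrom_sizes)
        paths[lib] = path

    conservation, tf_peaks = simulate_tracks(dataset)
    iof.write_bedgraph(conservation, outdir / "conservation.bedgraph")
    paths["conservation"] = outdir / "conservation.bedgraph"
    for name, peaks in tf_peaks.items():
        iof.write_bed(peaks, outdir / f"tf_{name}.bed")
        paths[f"tf_{name}"] = outdir / f"tf_{name}.bed"

    truth_rows = []
    for t in dataset.truth:
        truth_rows.append({
            "feature_id": t.feature_id, "feature_kind": t.feature_kind,
            "chrom": t.interval.chrom, "start": t.interval.start,
            "end": t.interval.end, "strand": t.interval.strand,
            "planted_class": t.planted_class, "planted_stall": t.planted_stall,
            "nucRNA_rate": t.nucRNA_rate, "RNAPII_rate": t.RNAPII_rate,
            "splicing_fraction": t.splicing_fraction,
        })
    iof.write_table(truth_rows, outdir / "truth.tsv")
    paths["truth"] = outdir / "truth.tsv"
    return paths


def load_dataset_dir(directory) -> dict:
    """Load a dataset directory written by :func:`write_dataset`."""
    d = Path(directory)
    chrom_sizes = iof.read_chrom_sizes(d / "chrom.sizes")
    genes = iof.read_annotation(d / "annotation.gtf")
    libs = {}
    for lib in ("nucRNA", "RNAPII", "input"):
        for ext in ("bed", "sam"):
            path = d / f"{lib}.{ext}"
            if path.exists():
                libs[lib] = TagCollection.from_tags(
                    iof.read_alignments(path, library_id=lib, chrom_sizes=chrom_sizes),
                    chrom_sizes, lib,
                )
                break
        else:
            raise FileNotFoundError(f"missing {lib} library in {d}")
    conservation = None
    cons_path = d / "conservation.bedgraph"
    if cons_path.exists():
        conservation = iof.read_wiggle(cons_path, chrom_sizes)
    tf_peaks = {
        p.stem[3:]: iof.read_bed(p) for p in sorted(d.glob("tf_*.bed"))
    } or None
    return {
        "chrom_sizes": chrom_sizes, "genes": genes, "libs": libs,
        "conservation": conservation, "tf_peaks": tf_peaks,
    }


def write_report(result: PipelineResult, outdir) -> None:
    """Serialize all stage outputs as TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.params.config_hash()

    def _region_rows(classified):
        return [{
            "name": c.score.name or f"{c.score.region.chrom}:{c.score.region.start}",
            "chrom": c.score.region.chrom, "start": c.score.region.start,
            "end": c.score.region.end,
            "nucRNA_score": c.score.nucRNA_score, "RNAPII_score": c.score.RNAPII_score,
            "has_gene": c.score.has_gene, "label": c.label,
            "efficiency_ratio": c.efficiency_ratio,
        } for c in classified]

    iof.write_table(_region_rows(result.gene_classes), outdir / "gene_classes.tsv")
    iof.write_table(_region_rows(result.window_classes), outdir / "window_classes.tsv")
    iof.write_table([{
        "gene_id": r.gene_id, "promoter_index": r.promoter_index,
        "three_prime_index": r.three_prime_index,
        "body_mean_RNAPII": r.body_mean_RNAPII, "body_mean_nucRNA": r.body_mean_nucRNA,
        "body_ratio": r.body_ratio, "category": r.category,
        "excluded": r.exclusion_reason,
    } for r in result.stalling_records], outdir / "stalling.tsv")
    iof.write_bed(
        [c.peak.interval for c in result.candidates], outdir / "candidates.bed",
        names=[c.positional_class for c in result.candidates],
        scores=[f"{c.peak.p_value:.3g}" for c in result.candidates],
    )
    iof.write_table([{
        "chrom": c.interval.chrom, "start": c.interval.start, "end": c.interval.end,
        "pass": c.pass_, "tag_count": c.tag_count,
        "nucRNA_depth_norm": c.nucRNA_depth_norm,
        "RNAPII_depth_norm": c.RNAPII_depth_norm,
        "ratio": c.ratio, "selected": c.selected,
    } for c in result.contigs], outdir / "lncrna_candidates.tsv")

    summary = {
        "config_hash": h,
        "seed": result.params.seed,
        "params": asdict(result.params),
        "class_counts": xc.class_counts(result.gene_classes),
        "thresholds": {
            "nucRNA": result.thresholds.nucRNA_threshold,
            "RNAPII": result.thresholds.RNAPII_threshold,
        },
        "efficiency_ratio": result.efficiency,
        "stall_cutoffs": list(result.stall_cutoffs),
        "stall_kruskal_wallis": list(result.stall_kw) if result.stall_kw else None,
        "n_peaks": len(result.peaks),
        "n_nucrna_regions": len(result.nucrna_regions),
        "n_candidates": len(result.candidates),
        "positional_fractions": result.positional_fractions,
        "conservation_log_odds": (
            result.conservation.log_odds if result.conservation else None
        ),
        "tf_combined_log_odds": (
            result.tf_combined.log_odds if result.tf_combined else None
        ),
        "n_erythroid_subset": len(result.erythroid_subset),
        "contig_counts": result.contig_counts,
        "n_selected_lncrna": sum(c.selected for c in result.contigs),
        "selection": {
            k: (v if np.isfinite(v) else str(v)) if isinstance(v, float) else v
            for k, v in result.selection.items()
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)


def run_all(dataset_dir, outdir, params: Optional[PipelineParams] = None) -> PipelineResult:
    """Load a dataset directory, run every stage, write the report."""
    data = load_dataset_dir(dataset_dir)
    result = analyze(
        data["genes"], data["libs"]["nucRNA"], data["libs"]["RNAPII"],
        data["libs"]["input"], data["conservation"], data["tf_peaks"], params,
    )
    write_report(result, outdir)
    return result
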