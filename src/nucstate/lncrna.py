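"""Contig-based discovery of stable nuclear-retained lncRNA candidates.

Semi-contiguous runs of nucRNA tags are merged under two parameter sets —
a strict pass (2 kb gap, 4.5 kb minimum) that captures well-expressed units
and a sensitive pass (1 kb gap, 2.5 kb minimum, merging survivors closer
than 5 kb) for weaker ones.  Candidates overlapping annotated genes or
other excluded features (pseudogenes, rRNA, miRNA) by even 1 bp are
removed; the survivors are scored by the ratio of length- and
library-normalized nucRNA to RNAPII average depth, high ratios marking
transcripts that accumulate in the nucleus relative to ongoing polymerase
engagement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .coverage import CoverageTrack, TagCollection
from .expression_classes import boxplot_threshold
from .genome import GenomicInterval, merge_intervals


@dataclass
class ContigCandidate:
    interval: GenomicInterval
    tag_count: int = 0
    nucRNA_depth_norm: float = float("nan")
    RNAPII_depth_norm: float = float("nan")
    ratio: float = float("nan")
    pass_: str = ""  # which parameter set produced it: strict | sensitive
    selected: bool = False
    overlaps: dict = field(default_factory=dict)
    consolidates: dict = field(default_factory=dict)


def contig_pass(
    tags: TagCollection,
    max_gap: int,
    min_size: int,
    merge_within: Optional[int] = None,
) -> list[GenomicInterval]:
    """One contig-building pass over the nucRNA tag stream.

    Reads merge when their gap is <= ``max_gap``; if ``merge_within`` is
    set, contigs separated by less than that many bp are merged next; only
    then is the ``min_size`` filter applied.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    raw: list[GenomicInterval] = []
    for chrom in sorted(tags.chrom_sizes):
        starts, ends, _ = tags.chrom_arrays(chrom)
        if starts.size == 0:
            continue
        cummax_end = np.maximum.accumulate(ends)
        breaks = np.flatnonzero(starts[1:] - cummax_end[:-1] > max_gap) + 1
        bounds = np.concatenate(([0], breaks, [starts.size]))
        for i in range(bounds.size - 1):
            raw.append(
                GenomicInterval(
                    chrom, int(starts[bounds[i]]), int(cummax_end[bounds[i + 1] - 1])
                )
            )
    if merge_within is not None and raw:
        raw = merge_intervals(raw, max_gap=merge_within - 1)
    return [iv for iv in raw if len(iv) >= min_size]


def _coverage_fraction(iv: GenomicInterval, trees: dict[str, IntervalTree]) -> float:
    tree = trees.get(iv.chrom)
    if tree is None:
        return 0.0
    covered = 0
    for hit in tree.overlap(iv.start, iv.end):
        covered += min(hit.end, iv.end) - max(hit.begin, iv.start)
    return covered / len(iv)


def _trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    out: dict[str, IntervalTree] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return out


def discover(
    nuc_tags: TagCollection,
    exclusion: Sequence[GenomicInterval],
    strict: tuple[int, int] = (2000, 4500),
    sensitive: tuple[int, int, int] = (1000, 2500, 5000),
    containment: float = 0.5,
) -> tuple[list[ContigCandidate], dict]:
    """Run both contig passes, union them, and drop excluded overlaps.

    ``exclusion`` is the union of annotated gene spans and any other
    excluded feature sets.  Sensitive-pass contigs are added only when less
    than ``containment`` of their length is already covered by a strict
    contig.  Any candidate touching an exclusion interval by >= 1 bp is
    removed.  Returns (candidates, counts) where counts reports the
    pre-/post-exclusion sizes of both passes.
    """
    strict_ivs = contig_pass(nuc_tags, strict[0], strict[1])
    sens_ivs = contig_pass(nuc_tags, sensitive[0], sensitive[1], merge_within=sensitive[2])

    strict_trees = _trees(strict_ivs)
    added = [iv for iv in sens_ivs if _coverage_fraction(iv, strict_trees) < containment]

    excl_trees = _trees(exclusion)

    def _keep(iv: GenomicInterval) -> bool:
        tree = excl_trees.get(iv.chrom)
        return tree is None or not tree.overlaps(iv.start, iv.end)

    candidates = [
        ContigCandidate(iv, pass_="strict") for iv in strict_ivs if _keep(iv)
    ] + [ContigCandidate(iv, pass_="sensitive") for iv in added if _keep(iv)]
    candidates.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    for c in candidates:
        c.tag_count = nuc_tags.count_overlapping(c.interval)
    counts = {
        "strict_initial": len(strict_ivs),
        "sensitive_added": len(added),
        "initial_total": len(strict_ivs) + len(added),
        "after_exclusion": len(candidates),
    }
    return candidates, counts


def quantify(
    candidates: Sequence[ContigCandidate],
    nucrna: CoverageTrack,
    rnapii: CoverageTrack,
    pseudocount: float = 0.0,
) -> None:
    """Fill normalized average depths and their ratio for each candidate.

    Average per-base depth over the candidate, scaled to tags-per-million
    (normalizing for candidate length and total reads).  With a positive
    ``pseudocount`` (the pipeline uses the same value as fold enrichment)
    the ratio of weakly covered candidates is pulled toward 1 instead of
    exploding when RNAPII depth is near zero; at pseudocount 0 a candidate
    with RNA but no polymerase gets an infinite ratio.
    """
    for c in candidates:
        c.nucRNA_depth_norm = nucrna.scaled_stat(c.interval, "mean")
        c.RNAPII_depth_norm = rnapii.scaled_stat(c.interval, "mean")
        denom = c.RNAPII_depth_norm + pseudocount
        num = c.nucRNA_depth_norm + pseudocount
        if denom > 0:
            c.ratio = num / denom
        else:
            c.ratio = float("inf") if num > 0 else float("nan")


def select_stable(
    candidates: Sequence[ContigCandidate],
    rule: str = "boxplot",
    top_n: Optional[int] = None,
    min_ratio: Optional[float] = None,
) -> dict:
    """Flag candidates with outlying nucRNA:RNAPII ratios as stable.

    Rules: ``boxplot`` (fence on the finite ratio distribution, mirroring
    the T-class logic; infinite ratios always pass), ``top_n``, or
    ``min_ratio``.  Returns a record of the rule and threshold used.
    """
    ratios = np.array([c.ratio for c in candidates], dtype=np.float64)
    finite = ratios[np.isfinite(ratios)]
    if rule == "boxplot":
        threshold = boxplot_threshold(finite) if finite.size >= 4 else float("inf")
        for c in candidates:
            c.selected = c.ratio > threshold
        return {"rule": rule, "threshold": threshold}
    if rule == "top_n":
        if not top_n:
            raise ValueError("top_n rule needs top_n")
        order = np.argsort(-ratios)
        chosen = set(order[:top_n].tolist())
        for i, c in enumerate(candidates):
            c.selected = i in chosen
        threshold = float(ratios[order[top_n - 1]]) if len(candidates) >= top_n else float("nan")
        return {"rule": rule, "threshold": threshold, "n": top_n}
    if rule == "min_ratio":
        if min_ratio is None:
            raise ValueError("min_ratio rule needs min_ratio")
        for c in candidates:
            c.selected = c.ratio >= min_ratio
        return {"rule": rule, "threshold": min_ratio}
    raise ValueError(f"unknown selection rule {rule!r}")


def annotate_overlaps(
    candidates: Sequence[ContigCandidate],
    named_sets: dict[str, Sequence[GenomicInterval]],
) -> dict:
    """Count overlaps of candidates with named reference interval sets.

    Per set: how many candidates hit >= 1 interval, the fraction of
    candidates, and how many candidates *consolidate* >= 2 reference
    intervals (one discovered unit covering a previously fragmented
    cluster).  Per candidate, ``overlaps[set]`` records the hit count.
    """
    report: dict = {}
    n = len(candidates)
    for name, ivs in named_sets.items():
        trees = _trees(list(ivs))
        n_hit = n_consolidate = 0
        for c in candidates:
            tree = trees.get(c.interval.chrom)
            k = len(tree.overlap(c.interval.start, c.interval.end)) if tree else 0
            c.overlaps[name] = k
            c.consolidates[name] = k >= 2
            if k:
                n_hit += 1
            if k >= 2:
                n_consolidate += 1
        report[name] = {
            "n_candidates_overlapping": n_hit,
            "fraction": n_hit / n if n else 0.0,
            "n_consolidating": n_consolidate,
        }
    return report
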