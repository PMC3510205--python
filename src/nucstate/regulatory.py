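"""RNAPII+/nucRNA- regulatory-region nomination.

A minimal strand-imbalance peak caller (the SISSRs idea: transcription-factor
-style binding puts forward tags upstream and reverse tags downstream of the
bound point, so the forward-minus-reverse count changes sign at the summit)
yields RNAPII peaks; peaks overlapping merged nucRNA-covered regions are
removed; survivors are positionally classified against the annotation and
tested for conservation and TF-peak overlap enrichment via 2x2 log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps

from .coverage import TagCollection
from .genome import GeneModel, GenomicInterval
from .stats import ContingencyTable, LogOddsResult, log_odds

POSITIONAL_CLASSES = ("TSS", "gene_body", "upstream_10kb", "downstream_10kb", "intergenic")


@dataclass
class PeakRegion:
    interval: GenomicInterval
    summit: int
    score: float  # net (forward - reverse) tag count at the summit transition
    p_value: float

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie inside the peak interval")


@dataclass
class CandidateRegion:
    peak: PeakRegion
    positional_class: str = ""
    conserved_fraction: float = float("nan")
    tf_hits: list = field(default_factory=list)
    erythroid_subset_flag: bool = False


def call_peaks(
    tags: TagCollection,
    window: int = 20,
    p_cut: float = 0.001,
    halfwidth: int = 100,
) -> list[PeakRegion]:
    """Call strand-imbalance peaks from stranded RNAPII tags.

    Forward-tag 5' ends and reverse-tag 5' ends (the tag *end* coordinate)
    are binned at ``window`` bp; a candidate summit sits at each + -> - sign
    change of the net count.  Summits closer than ``2 x window`` are merged.
    A summit is kept when the tag-start count in ``summit +/- halfwidth``
    beats a Poisson background at the genome-average rate with p < p_cut.
    """
    peaks: list[PeakRegion] = []
    genome = sum(tags.chrom_sizes.values())
    n_total = tags.library_size
    if n_total == 0:
        return peaks
    rate = n_total / genome  # tag starts per bp

    for chrom in sorted(tags.chrom_sizes):
        starts, ends, strands = tags.chrom_arrays(chrom)
        if starts.size == 0:
            continue
        if np.all(strands == 0):
            raise ValueError(
                "unstranded tags: the caller needs strand information "
                "(import externally-called peaks instead)"
            )
        size = tags.chrom_sizes[chrom]
        nbins = size // window + 1
        fwd = np.bincount(starts[strands > 0] // window, minlength=nbins)
        rev = np.bincount(
            np.minimum(ends[strands < 0] - 1, size - 1) // window, minlength=nbins
        )
        net = fwd.astype(np.int64) - rev.astype(np.int64)
        # sign change between consecutive non-empty bins (forward cluster and
        # reverse cluster may be separated by empty bins)
        nz = np.flatnonzero(net)
        if nz.size < 2:
            continue
        sign_flip = (net[nz[:-1]] > 0) & (net[nz[1:]] < 0)
        left, right = nz[:-1][sign_flip], nz[1:][sign_flip]
        if left.size == 0:
            continue
        summits = ((left + 1) * window + right * window) // 2
        scores = net[left]

        # merge summits closer than 2*window into one (mean position)
        merged: list[tuple[int, float]] = []
        group = [0]
        for i in range(1, summits.size):
            if summits[i] - summits[group[-1]] < 2 * window:
                group.append(i)
            else:
                merged.append((int(np.mean(summits[group])), float(scores[group].max())))
                group = [i]
        merged.append((int(np.mean(summits[group])), float(scores[group].max())))

        for summit, score in merged:
            lo = max(0, summit - halfwidth)
            hi = min(size, summit + halfwidth)
            n_in = int(
                np.searchsorted(starts, hi, side="left")
                - np.searchsorted(starts, lo, side="left")
            )
            lam = rate * (hi - lo)
            p = float(sps.poisson.sf(n_in - 1, lam))
            if p < p_cut:
                summit = min(max(summit, lo), hi - 1)
                peaks.append(
                    PeakRegion(GenomicInterval(chrom, lo, hi), summit, score, p)
                )
    return peaks


def nucrna_regions(
    tags: TagCollection, max_gap: int = 100, min_size: int = 1000
) -> list[GenomicInterval]:
    """Merge nucRNA tags (gap <= max_gap) and keep regions >= min_size bp.

    These are the "transcribed" footprints used to subtract expressed
    sequence from the RNAPII peak list.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom in sorted(tags.chrom_sizes):
        starts, ends, _ = tags.chrom_arrays(chrom)
        if starts.size == 0:
            continue
        cummax_end = np.maximum.accumulate(ends)
        breaks = np.flatnonzero(starts[1:] - cummax_end[:-1] > max_gap) + 1
        bounds = np.concatenate(([0], breaks, [starts.size]))
        for i in range(bounds.size - 1):
            s = int(starts[bounds[i]])
            e = int(cummax_end[bounds[i + 1] - 1])
            if e - s >= min_size:
                out.append(GenomicInterval(chrom, s, e))
    return out


def _build_trees(regions: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def subtract_transcribed(
    peaks: Sequence[PeakRegion], regions: Sequence[GenomicInterval]
) -> list[PeakRegion]:
    """Retain peaks whose interval overlaps no nucRNA region by >= 1 bp."""
    trees = _build_trees(regions)
    out = []
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        if tree is None or not tree.overlaps(p.interval.start, p.interval.end):
            out.append(p)
    return out


def positional_classify(
    peaks: Sequence[PeakRegion],
    genes: Sequence[GeneModel],
    tss_flank: int = 500,
    near: int = 10_000,
) -> list[CandidateRegion]:
    """Classify peak midpoints against the annotation.

    Precedence: TSS (+/- tss_flank of any TSS) > gene_body > upstream_10kb >
    downstream_10kb > intergenic.  Up/downstream are strand-aware relative
    to the nearest gene; "intergenic" means > ``near`` bp from any gene.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out = []
    for p in peaks:
        mid = p.interval.midpoint
        chrom_genes = by_chrom.get(p.interval.chrom, [])
        cls = "intergenic"
        if any(abs(mid - g.tss) <= tss_flank for g in chrom_genes):
            cls = "TSS"
        elif any(g.span.start <= mid < g.span.end for g in chrom_genes):
            cls = "gene_body"
        else:
            nearest = None
            best = None
            for g in chrom_genes:
                d = max(g.span.start - mid, mid - (g.span.end - 1), 0)
                if best is None or d < best:
                    best, nearest = d, g
            if nearest is not None and best <= near:
                if nearest.strand == "+":
                    upstream = mid < nearest.span.start
                else:
                    upstream = mid >= nearest.span.end
                cls = "upstream_10kb" if upstream else "downstream_10kb"
        out.append(CandidateRegion(p, positional_class=cls))
    return out


def positional_fractions(candidates: Sequence[CandidateRegion]) -> dict[str, float]:
    n = len(candidates)
    return {
        cls: (sum(c.positional_class == cls for c in candidates) / n if n else 0.0)
        for cls in POSITIONAL_CLASSES
    }


def sample_random_regions(
    n: int,
    span: int,
    chrom_sizes: dict[str, int],
    exclude: Sequence[GenomicInterval],
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Uniformly sample ``n`` regions of width ``span`` avoiding ``exclude``."""
    trees = _build_trees(exclude)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place random regions outside exclusions")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        size = chrom_sizes[chrom]
        if size <= span:
            continue
        start = int(rng.integers(0, size - span))
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(start, start + span):
            continue
        out.append(GenomicInterval(chrom, start, start + span))
    return out


def conservation_enrichment(
    candidates: Sequence[CandidateRegion],
    conservation: dict[str, np.ndarray],
    chrom_sizes: dict[str, int],
    cut: float = 0.8,
    span: int = 1000,
    seed: int = 0,
    random_regions: Optional[Sequence[GenomicInterval]] = None,
) -> LogOddsResult:
    """Base-level conservation enrichment of candidates vs random regions.

    Counts bases with conservation score > ``cut`` within ``span`` bp around
    each candidate midpoint against the same count in matched random regions
    (same number and width, sampled outside candidate footprints), and
    returns the natural-log odds with a chi-square-equivalent Wald p.
    Candidate ``conserved_fraction`` fields are filled in as a side effect.
    """
    half = span // 2
    cand_spans = []
    for c in candidates:
        mid = c.peak.interval.midpoint
        size = chrom_sizes[c.peak.interval.chrom]
        lo, hi = max(0, mid - half), min(size, mid + half)
        cand_spans.append(GenomicInterval(c.peak.interval.chrom, lo, hi))
    if random_regions is None:
        rng = np.random.default_rng(seed)
        random_regions = sample_random_regions(
            len(cand_spans), span, chrom_sizes,
            [c.peak.interval for c in candidates], rng,
        )

    def _count(regions):
        conserved = total = 0
        fracs = []
        for r in regions:
            seg = conservation[r.chrom][r.start:r.end]
            k = int((seg > cut).sum())
            conserved += k
            total += seg.size
            fracs.append(k / seg.size if seg.size else float("nan"))
        return conserved, total, fracs

    a, n_cand, fracs = _count(cand_spans)
    c_cons, n_rand, _ = _count(random_regions)
    for cand, f in zip(candidates, fracs):
        cand.conserved_fraction = f
    table = ContingencyTable(a, n_cand - a, c_cons, n_rand - c_cons)
    return log_odds(table)


def _mark_bins(
    intervals: Sequence[GenomicInterval], chrom_sizes: dict[str, int], bin_size: int
) -> dict[str, np.ndarray]:
    marks = {
        c: np.zeros(-(-size // bin_size), dtype=bool) for c, size in chrom_sizes.items()
    }
    for iv in intervals:
        if iv.chrom not in marks:
            continue
        lo = iv.start // bin_size
        hi = (iv.end - 1) // bin_size + 1
        marks[iv.chrom][lo:hi] = True
    return marks


def tf_overlap_enrichment(
    candidates: Sequence[CandidateRegion],
    tf_peak_sets: dict[str, Sequence[GenomicInterval]],
    chrom_sizes: dict[str, int],
    bin_size: int = 1000,
) -> tuple[dict[str, LogOddsResult], Optional[LogOddsResult], list[CandidateRegion]]:
    """Genome-bin overlap enrichment between candidates and TF peak sets.

    The genome is tiled into ``bin_size`` bins; for each TF (and all TFs
    pooled) a 2x2 table of (bin overlaps candidate) x (bin overlaps TF peak)
    gives a log-odds ratio.  Candidates overlapping >= 1 TF peak form the
    "erythroid subset".  Empty TF sets are skipped.
    """
    cand_ivs = [c.peak.interval for c in candidates]
    cand_bins = _mark_bins(cand_ivs, chrom_sizes, bin_size)

    def _table(tf_bins) -> LogOddsResult:
        a = b = c_ = d = 0
        for chrom in cand_bins:
            cb = cand_bins[chrom]
            tb = tf_bins[chrom]
            a += int((cb & tb).sum())
            b += int((cb & ~tb).sum())
            c_ += int((~cb & tb).sum())
            d += int((~cb & ~tb).sum())
        return log_odds(ContingencyTable(a, b, c_, d))

    per_tf: dict[str, LogOddsResult] = {}
    pooled: list[GenomicInterval] = []
    for name, peaks in tf_peak_sets.items():
        peaks = list(peaks)
        if not peaks:
            continue
        pooled.extend(peaks)
        per_tf[name] = _table(_mark_bins(peaks, chrom_sizes, bin_size))
    combined = _table(_mark_bins(pooled, chrom_sizes, bin_size)) if pooled else None

    tf_trees = {name: _build_trees(list(peaks)) for name, peaks in tf_peak_sets.items()}
    for cand in candidates:
        iv = cand.peak.interval
        hits = [
            name
            for name, trees in tf_trees.items()
            if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)
        ]
        cand.tf_hits = hits
        cand.erythroid_subset_flag = bool(hits)
    return per_tf, combined, [c for c in candidates if c.erythroid_subset_flag]
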