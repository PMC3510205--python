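"""Brute-force oracles and small builders shared by the test suite.

Everything here is deliberately naive (per-base loops, all-pairs scans,
exhaustive permutation) so it stays independent of the vectorised
implementations it checks.
"""

from itertools import permutations

import numpy as np

from nucstate.coverage import CoverageTrack, TagCollection
from nucstate.genome import AlignedTag, GenomicInterval


def make_tags(rows, chrom_sizes, library_id=""):
    """rows: (chrom, start, end, strand) tuples -> TagCollection."""
    tags = [AlignedTag(GenomicInterval(*r), library_id=library_id) for r in rows]
    return TagCollection.from_tags(tags, chrom_sizes, library_id)


def make_track(depths, library_size, library_id=""):
    """depths: {chrom: list/array} -> CoverageTrack."""
    return CoverageTrack(
        {c: np.asarray(a, dtype=np.int64) for c, a in depths.items()},
        library_size, library_id,
    )


def bf_coverage(rows, size):
    """Per-base depth by counting every tag at every base."""
    depth = np.zeros(size, dtype=np.int64)
    for _, start, end, *_ in rows:
        for pos in range(start, end):
            depth[pos] += 1
    return depth


def bf_merge(intervals, max_gap, min_size=0):
    """Merge-then-filter by repeated pairwise scanning."""
    ivs = sorted(intervals)
    out = []
    for s, e in ivs:
        if out and s - out[-1][1] <= max_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out if e - s >= min_size]


def bf_count_overlaps(rows, region):
    """All-pairs overlap counting."""
    chrom, start, end = region.chrom, region.start, region.end
    return sum(
        1 for r in rows if r[0] == chrom and r[1] < end and start < r[2]
    )


def bf_positional(midpoint, chrom, genes, tss_flank=500, near=10_000):
    """Independent re-derivation of the positional precedence rule."""
    cg = [g for g in genes if g.chrom == chrom]
    for g in cg:
        if abs(midpoint - g.tss) <= tss_flank:
            return "TSS"
    for g in cg:
        if g.span.start <= midpoint < g.span.end:
            return "gene_body"
    best, nearest = None, None
    for g in cg:
        d = max(g.span.start - midpoint, midpoint - (g.span.end - 1), 0)
        if best is None or d < best:
            best, nearest = d, g
    if nearest is not None and best <= near:
        if nearest.strand == "+":
            return "upstream_10kb" if midpoint < nearest.span.start else "downstream_10kb"
        return "upstream_10kb" if midpoint >= nearest.span.end else "downstream_10kb"
    return "intergenic"


def jt_statistic(groups):
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    jt += (x < y) + 0.5 * (x == y)
    return jt


def exact_jt_p(groups, alternative="increasing"):
    """Exhaustive-permutation p-value of the JT statistic (<= 8 obs)."""
    sizes = [len(g) for g in groups]
    pooled = [x for g in groups for x in g]
    obs = jt_statistic(groups)
    stats = []
    for perm in set(permutations(pooled)):
        regrouped, k = [], 0
        for n in sizes:
            regrouped.append(perm[k:k + n])
            k += n
        stats.append(jt_statistic(regrouped))
    stats = np.array(stats)
    if alternative == "increasing":
        return float((stats >= obs).mean())
    if alternative == "decreasing":
        return float((stats <= obs).mean())
    lo = min(float((stats >= obs).mean()), float((stats <= obs).mean()))
    return min(1.0, 2 * lo)


def kw_h(groups):
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    n = pooled.size
    h = 0.0
    k = 0
    for g in groups:
        r = ranks[k:k + len(g)]
        k += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    corr = 1 - (t**3 - t).sum() / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def exact_kw_p(groups):
    """Exhaustive-permutation p-value of tie-corrected H (<= 8 obs)."""
    sizes = [len(g) for g in groups]
    pooled = [x for g in groups for x in g]
    obs = kw_h([list(g) for g in groups])
    stats = []
    for perm in set(permutations(pooled)):
        regrouped, k = [], 0
        for n in sizes:
            regrouped.append(list(perm[k:k + n]))
            k += n
        stats.append(kw_h(regrouped))
    stats = np.array(stats)
    return float((stats >= obs - 1e-12).mean())


def reciprocal_overlap(a, b):
    """Overlap length / max(len(a), len(b)); 0 if different chroms."""
    if a.chrom != b.chrom:
        return 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return ov / max(len(a), len(b))
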