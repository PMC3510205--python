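"""Per-base coverage, input normalization, RPKM and window scoring.

The central normalization is *fold enrichment over input*: a region's
library-size-scaled depth statistic divided by the same statistic of the
matched genomic input library, each stabilised by a pseudocount.  This
corrects mappability/repeat artifacts that inflate raw depth in every
library equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np

from .genome import AlignedTag, GeneModel, GenomicInterval

DEFAULT_PSEUDOCOUNT = 1.0


class TagCollection:
    """Aligned tags of one library, held as per-chromosome numpy arrays.

    Arrays are sorted by tag start; a separately sorted end array supports
    O(log n) overlap counting.
    """

    def __init__(self, chrom_sizes: dict[str, int], library_id: str = ""):
        self.chrom_sizes = dict(chrom_sizes)
        self.library_id = library_id
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._strands: dict[str, np.ndarray] = {}  # +1 forward, -1 reverse
        self._ends_sorted: dict[str, np.ndarray] = {}
        for c in self.chrom_sizes:
            self._starts[c] = np.empty(0, dtype=np.int64)
            self._ends[c] = np.empty(0, dtype=np.int64)
            self._strands[c] = np.empty(0, dtype=np.int8)
            self._ends_sorted[c] = np.empty(0, dtype=np.int64)

    @classmethod
    def from_tags(
        cls,
        tags: Iterable[AlignedTag],
        chrom_sizes: dict[str, int],
        library_id: str = "",
    ) -> "TagCollection":
        buf: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_sizes}
        for tag in tags:
            iv = tag.interval
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"tag on unknown chromosome {iv.chrom!r}")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"tag {iv.chrom}:{iv.start}-{iv.end} beyond chromosome end"
                )
            code = {"-": -1, "+": 1}.get(iv.strand, 0)
            buf[iv.chrom].append((iv.start, iv.end, code))
        coll = cls(chrom_sizes, library_id)
        for c, rows in buf.items():
            if rows:
                arr = np.array(rows, dtype=np.int64)
                order = np.argsort(arr[:, 0], kind="stable")
                arr = arr[order]
                coll._starts[c] = arr[:, 0].copy()
                coll._ends[c] = arr[:, 1].copy()
                coll._strands[c] = arr[:, 2].astype(np.int8)
                coll._ends_sorted[c] = np.sort(arr[:, 1])
        return coll

    @classmethod
    def from_arrays(
        cls,
        chrom_sizes: dict[str, int],
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_id: str = "",
    ) -> "TagCollection":
        """Build from ``{chrom: (starts, ends, strands±1)}`` arrays."""
        coll = cls(chrom_sizes, library_id)
        for c, (starts, ends, strands) in per_chrom.items():
            if c not in chrom_sizes:
                raise ValueError(f"unknown chromosome {c!r}")
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            strands = np.asarray(strands, dtype=np.int8)
            if starts.size and ends.max(initial=0) > chrom_sizes[c]:
                raise ValueError(f"tag beyond end of {c}")
            order = np.argsort(starts, kind="stable")
            coll._starts[c] = starts[order]
            coll._ends[c] = ends[order]
            coll._strands[c] = strands[order]
            coll._ends_sorted[c] = np.sort(ends)
        return coll

    @property
    def library_size(self) -> int:
        """Number of aligned tags (each mate counts once)."""
        return int(sum(a.size for a in self._starts.values()))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._starts[chrom], self._ends[chrom], self._strands[chrom]

    def count_overlapping(self, region: GenomicInterval) -> int:
        """Number of tags overlapping ``region`` by >=1 bp."""
        starts = self._starts.get(region.chrom)
        if starts is None or starts.size == 0:
            return 0
        ends_sorted = self._ends_sorted[region.chrom]
        n_start_before_end = np.searchsorted(starts, region.end, side="left")
        n_end_at_or_before_start = np.searchsorted(ends_sorted, region.start, side="right")
        return int(n_start_before_end - n_end_at_or_before_start)

    def iter_tags(self) -> Iterable[AlignedTag]:
        for c in sorted(self._starts):
            s, e, st = self._starts[c], self._ends[c], self._strands[c]
            sym = {-1: "-", 1: "+", 0: "."}
            for i in range(s.size):
                yield AlignedTag(
                    GenomicInterval(c, int(s[i]), int(e[i]), sym[int(st[i])]),
                    library_id=self.library_id,
                )

    def coverage(self) -> "CoverageTrack":
        depth = {}
        for c, size in self.chrom_sizes.items():
            diff = np.zeros(size + 1, dtype=np.int64)
            s, e = self._starts[c], self._ends[c]
            if s.size:
                np.add.at(diff, s, 1)
                np.add.at(diff, e, -1)
            depth[c] = np.cumsum(diff[:-1])
        return CoverageTrack(depth, self.library_size, self.library_id)


@dataclass
class CoverageTrack:
    """Per-base tag depth for one library, plus its size for scaling."""

    depth: dict[str, np.ndarray]
    library_size: int
    library_id: str = ""

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(a.size) for c, a in self.depth.items()}

    def total_mass(self) -> int:
        """Sum of depths == sum of aligned tag lengths."""
        return int(sum(int(a.sum()) for a in self.depth.values()))

    def region_stat(self, region: GenomicInterval, stat: str = "max") -> float:
        """Raw depth statistic (max or mean) over a region."""
        arr = self.depth[region.chrom]
        if region.end > arr.size:
            raise ValueError(f"region beyond end of {region.chrom}")
        seg = arr[region.start:region.end]
        if seg.size == 0:
            raise ValueError("empty region")
        return float(seg.max()) if stat == "max" else float(seg.mean())

    def scaled_stat(self, region: GenomicInterval, stat: str = "max") -> float:
        """Depth statistic scaled to tags-per-million library size."""
        raw = self.region_stat(region, stat)
        return raw * 1e6 / self.library_size if self.library_size else 0.0

    def scaled_profile(self, chrom: str, start: int = 0, end: Optional[int] = None) -> np.ndarray:
        """Per-base depth scaled to tags-per-million, as a float array."""
        arr = self.depth[chrom][start:end]
        scale = 1e6 / self.library_size if self.library_size else 0.0
        return arr.astype(np.float64) * scale


def build_coverage(
    tags: Iterable[AlignedTag], chrom_sizes: dict[str, int], library_id: str = ""
) -> CoverageTrack:
    """Turn a tag stream into a per-base depth track."""
    return TagCollection.from_tags(tags, chrom_sizes, library_id).coverage()


def fold_enrichment(
    sample: CoverageTrack,
    input_track: CoverageTrack,
    region: GenomicInterval,
    stat: Literal["max", "mean"] = "max",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Fold enrichment of ``sample`` over genomic input in a region.

    ``(stat_sample * 1e6 / N_sample + eps) / (stat_input * 1e6 / N_input + eps)``
    with per-million scaling so the ratio is invariant to sequencing depth.
    """
    if region.chrom not in sample.depth or region.chrom not in input_track.depth:
        raise ValueError(f"chromosome {region.chrom!r} missing from a track")
    s = sample.scaled_stat(region, stat)
    i = input_track.scaled_stat(region, stat)
    if i + pseudocount == 0:
        raise ZeroDivisionError("zero input signal and zero pseudocount")
    return (s + pseudocount) / (i + pseudocount)


def fe_profile(
    sample: CoverageTrack,
    input_track: CoverageTrack,
    chrom: str,
    start: int = 0,
    end: Optional[int] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Per-base fold-enrichment-over-input profile for a region."""
    s = sample.scaled_profile(chrom, start, end)
    i = input_track.scaled_profile(chrom, start, end)
    return (s + pseudocount) / (i + pseudocount)


def rpkm(
    gene: GeneModel,
    tags: TagCollection,
    feature: Literal["gene_span", "exon1"] = "gene_span",
) -> float:
    """Reads per kilobase of feature per million mapped reads.

    ``exon1`` is the first exon in transcription order (the last interval on
    the "-" strand).
    """
    if tags.library_size <= 0:
        raise ValueError("library size must be > 0")
    if feature == "gene_span":
        region = gene.span
    elif feature == "exon1":
        region = gene.exons[0] if gene.strand == "+" else gene.exons[-1]
    else:
        raise ValueError(f"unknown feature {feature!r}")
    if len(region) == 0:
        raise ValueError("zero-length feature")
    n = tags.count_overlapping(region)
    return n / (len(region) / 1e3) / (tags.library_size / 1e6)


@dataclass
class RegionScore:
    """Input-normalized nucRNA and RNAPII scores for one region."""

    region: GenomicInterval
    nucRNA_score: float
    RNAPII_score: float
    nucRNA_raw: float
    RNAPII_raw: float
    has_gene: bool = False
    partial: bool = False
    name: str = ""


def window_scores(
    nucrna: CoverageTrack,
    rnapii: CoverageTrack,
    input_track: CoverageTrack,
    window: int = 10_000,
    stat: Literal["max", "mean"] = "max",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    genes: Optional[list[GeneModel]] = None,
) -> list[RegionScore]:
    """Score non-overlapping genome windows (tiled from coordinate 0).

    The trailing partial window is kept and flagged.  ``has_gene`` marks
    windows overlapping any annotated gene.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    gene_ivs: dict[str, list[tuple[int, int]]] = {}
    for g in genes or []:
        gene_ivs.setdefault(g.chrom, []).append((g.span.start, g.span.end))
    out: list[RegionScore] = []
    for chrom in sorted(nucrna.depth):
        size = nucrna.depth[chrom].size
        for start in range(0, size, window):
            end = min(start + window, size)
            region = GenomicInterval(chrom, start, end)
            has_gene = any(
                s < end and start < e for s, e in gene_ivs.get(chrom, ())
            )
            out.append(
                RegionScore(
                    region=region,
                    nucRNA_score=fold_enrichment(nucrna, input_track, region, stat, pseudocount),
                    RNAPII_score=fold_enrichment(rnapii, input_track, region, stat, pseudocount),
                    nucRNA_raw=nucrna.region_stat(region, stat),
                    RNAPII_raw=rnapii.region_stat(region, stat),
                    has_gene=has_gene,
                    partial=(end - start) < window,
                )
            )
    return out


def gene_scores(
    genes: list[GeneModel],
    nucrna: CoverageTrack,
    rnapii: CoverageTrack,
    input_track: CoverageTrack,
    stat: Literal["max", "mean"] = "max",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[RegionScore]:
    """Score annotated gene spans the same way as genome windows."""
    out = []
    for g in genes:
        region = g.span
        out.append(
            RegionScore(
                region=region,
                nucRNA_score=fold_enrichment(nucrna, input_track, region, stat, pseudocount),
                RNAPII_score=fold_enrichment(rnapii, input_track, region, stat, pseudocount),
                nucRNA_raw=nucrna.region_stat(region, stat),
                RNAPII_raw=rnapii.region_stat(region, stat),
                has_gene=True,
                name=g.gene_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exon/intron structure of nuclear RNA coverage
# ---------------------------------------------------------------------------

def _third_bounds(gene: GeneModel) -> list[tuple[int, int]]:
    """Gene-span thirds in transcription order (5' third first)."""
    s, e = gene.span.start, gene.span.end
    L = e - s
    cuts = [s, s + L // 3, s + (2 * L) // 3, e]
    thirds = [(cuts[i], cuts[i + 1]) for i in range(3)]
    if gene.strand == "-":
        thirds = thirds[::-1]
    return thirds


def exon_intron_summary(gene: GeneModel, track: CoverageTrack) -> dict:
    """Mean per-base depth over exonic and intronic bases, per gene third.

    Thirds are equal splits of the gene span in transcription order (the 5'
    third sits at the span end on the "-" strand).  A third with no exonic
    (or intronic) bases reports ``nan`` for that mean, not 0.
    """
    arr = track.depth[gene.chrom]
    mask = np.zeros(len(gene.span), dtype=bool)
    off = gene.span.start
    for ex in gene.exons:
        mask[ex.start - off:ex.end - off] = True
    seg = arr[gene.span.start:gene.span.end]

    def _mean(lo, hi, exonic):
        m = mask[lo - off:hi - off]
        sel = seg[lo - off:hi - off][m if exonic else ~m]
        return float(sel.mean()) if sel.size else float("nan")

    result = {
        "gene_id": gene.gene_id,
        "exonic_mean": _mean(gene.span.start, gene.span.end, True),
        "intronic_mean": _mean(gene.span.start, gene.span.end, False),
        "thirds": [],
    }
    for label, (lo, hi) in zip(("five_prime", "body", "three_prime"), _third_bounds(gene)):
        result["thirds"].append(
            {"third": label, "exonic_mean": _mean(lo, hi, True), "intronic_mean": _mean(lo, hi, False)}
        )
    return result


def exonic_fraction(track: CoverageTrack, genes: list[GeneModel]) -> float:
    """Fraction of aligned bases (depth mass) falling on annotated exons."""
    total = track.total_mass()
    if total == 0:
        return float("nan")
    exonic = 0
    for chrom, arr in track.depth.items():
        mask = np.zeros(arr.size, dtype=bool)
        for g in genes:
            if g.chrom != chrom:
                continue
            for ex in g.exons:
                mask[ex.start:ex.end] = True
        exonic += int(arr[mask].sum())
    return exonic / total
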