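"""Promoter-proximal and 3'-end RNAPII stalling indices.

The stalling index of a gene is the maximum input-normalized RNAPII signal
in a +/-300 bp window around the TSS (or TES for the 3' index) divided by
the mean signal over the gene body; a high ratio indicates polymerase
accumulating at the gene end relative to productive elongation through the
body.  Genes are categorized (promoter / three_prime / double / none) by
exceedance of the 95th percentile of each index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .coverage import CoverageTrack, DEFAULT_PSEUDOCOUNT, fe_profile
from .genome import GeneModel
from .stats import jonckheere, kruskal_wallis

CATEGORIES = ("promoter", "three_prime", "double", "none")


@dataclass
class StallingRecord:
    gene_id: str
    promoter_index: float = float("nan")
    three_prime_index: float = float("nan")
    body_mean_RNAPII: float = float("nan")
    body_mean_nucRNA: float = float("nan")
    body_ratio: float = float("nan")
    category: str = ""
    undefined_flag: bool = False
    exclusion_reason: str = ""

    @property
    def defined(self) -> bool:
        return not self.undefined_flag and np.isfinite(self.promoter_index) and np.isfinite(
            self.three_prime_index
        )


def _anchor_window(anchor: int, flank: int, chrom_size: int) -> tuple[int, int]:
    """Closed +/-flank window around a base, clipped, as half-open coords."""
    return max(0, anchor - flank), min(chrom_size, anchor + flank + 1)


def _body_mask(gene: GeneModel, flank: int, chrom_size: int) -> tuple[int, int, np.ndarray]:
    """Boolean mask (over the gene span) of body bases: span minus both
    anchor windows."""
    s, e = gene.span.start, gene.span.end
    mask = np.ones(e - s, dtype=bool)
    for anchor in (gene.tss, gene.tes):
        lo, hi = _anchor_window(anchor, flank, chrom_size)
        lo, hi = max(lo, s), min(hi, e)
        if hi > lo:
            mask[lo - s:hi - s] = False
    return s, e, mask


def stalling_index(
    gene: GeneModel,
    rnapii: CoverageTrack,
    input_track: CoverageTrack,
    end: Literal["five_prime", "three_prime"] = "five_prime",
    flank: int = 300,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Stalling index at one gene end (strand-aware anchor).

    ``max FE(anchor +/- flank) / mean FE(body)`` where the body is the gene
    span minus *both* anchor windows (so a peak at the opposite end cannot
    inflate this index's denominator).  Raises for genes too short to leave
    a body.
    """
    chrom_size = rnapii.depth[gene.chrom].size
    if gene.length <= 2 * flank + 300:
        raise ValueError(
            f"gene {gene.gene_id} too short ({gene.length} bp) for flank {flank}"
        )
    anchor = gene.tss if end == "five_prime" else gene.tes
    lo, hi = _anchor_window(anchor, flank, chrom_size)
    window_fe = fe_profile(rnapii, input_track, gene.chrom, lo, hi, pseudocount)
    s, e, mask = _body_mask(gene, flank, chrom_size)
    body_fe = fe_profile(rnapii, input_track, gene.chrom, s, e, pseudocount)[mask]
    wmax = float(window_fe.max())
    # flat signal: the ratio is exactly 1 (a constant array's floating-point
    # mean can differ from the constant in the last ulp)
    if body_fe.min() == body_fe.max() == wmax:
        return 1.0
    body_mean = float(body_fe.mean())
    if body_mean == 0:
        return float("nan")
    return wmax / body_mean


def compute_records(
    genes: Sequence[GeneModel],
    rnapii: CoverageTrack,
    nucrna: CoverageTrack,
    input_track: CoverageTrack,
    flank: int = 300,
    min_gene_length: int = 300,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[StallingRecord]:
    """Per-gene stalling indices and body signals.

    Genes at or below ``min_gene_length`` bp, or too short for a non-empty
    body, produce exclusion records (reason-coded) rather than being
    silently dropped.
    """
    out = []
    for g in genes:
        if g.length <= min_gene_length:
            out.append(StallingRecord(g.gene_id, undefined_flag=True,
                                      exclusion_reason="min_gene_length"))
            continue
        if g.length <= 2 * flank + 300:
            out.append(StallingRecord(g.gene_id, undefined_flag=True,
                                      exclusion_reason="body_degenerate"))
            continue
        chrom_size = rnapii.depth[g.chrom].size
        s, e, mask = _body_mask(g, flank, chrom_size)
        pol_body = fe_profile(rnapii, input_track, g.chrom, s, e, pseudocount)[mask]
        nuc_body = fe_profile(nucrna, input_track, g.chrom, s, e, pseudocount)[mask]
        body_pol = float(pol_body.mean())
        body_nuc = float(nuc_body.mean())
        rec = StallingRecord(
            g.gene_id,
            promoter_index=stalling_index(g, rnapii, input_track, "five_prime", flank, pseudocount),
            three_prime_index=stalling_index(g, rnapii, input_track, "three_prime", flank, pseudocount),
            body_mean_RNAPII=body_pol,
            body_mean_nucRNA=body_nuc,
            body_ratio=body_nuc / body_pol if body_pol > 0 else float("nan"),
        )
        if not rec.defined:
            rec.undefined_flag = True
            rec.exclusion_reason = "zero_body_signal"
        out.append(rec)
    return out


def categorize(
    records: Sequence[StallingRecord], percentile: float = 95.0
) -> tuple[float, float, list[StallingRecord]]:
    """Assign promoter/three_prime/double/none categories.

    Cutoffs are the given percentile of each index over *defined* records;
    a gene is in a peak category when it strictly exceeds the cutoff.
    Returns (promoter_cutoff, three_prime_cutoff, records).
    """
    defined = [r for r in records if r.defined]
    if len(defined) < 20:
        raise ValueError("need >= 20 defined records to place percentile cutoffs")
    pr_cut = float(np.percentile([r.promoter_index for r in defined], percentile))
    tp_cut = float(np.percentile([r.three_prime_index for r in defined], percentile))
    for r in records:
        if not r.defined:
            r.category = ""
            continue
        hi_pr = r.promoter_index > pr_cut
        hi_tp = r.three_prime_index > tp_cut
        r.category = ("double" if hi_tp else "promoter") if hi_pr else (
            "three_prime" if hi_tp else "none"
        )
    return pr_cut, tp_cut, list(records)


def body_ratio_by_category(
    records: Sequence[StallingRecord],
) -> tuple[dict[str, np.ndarray], float, float]:
    """nucRNA:RNAPII body-signal ratio distributions per stall category,
    with a Kruskal-Wallis test across the non-empty categories."""
    groups: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        vals = np.array([
            r.body_ratio for r in records
            if r.category == cat and np.isfinite(r.body_ratio)
        ])
        if vals.size:
            groups[cat] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty categories")
    h, p = kruskal_wallis(list(groups.values()))
    return groups, h, p


def trend_test(
    index_values: Sequence[float],
    outcome_values: Sequence[float],
    n_bins: int = 5,
    alternative: str = "decreasing",
):
    """Jonckheere-Terpstra trend of an outcome across ordered index bins.

    Genes are binned into ``n_bins`` quantile groups of the stalling index
    (default quintiles); the default one-sided alternative is that the
    outcome (nucRNA coverage) *decreases* with the index.
    """
    idx = np.asarray(index_values, dtype=np.float64)
    out = np.asarray(outcome_values, dtype=np.float64)
    if idx.shape != out.shape:
        raise ValueError("index and outcome must align")
    ok = np.isfinite(idx) & np.isfinite(out)
    idx, out = idx[ok], out[ok]
    edges = np.quantile(idx, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, idx, side="right") - 1, 0, n_bins - 1)
    groups = [out[bins == b] for b in range(n_bins) if (bins == b).any()]
    return jonckheere(groups, alternative=alternative)
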