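"""BT/B/T/loBT transcriptional-class assignment.

Regions (10 kb genome windows or annotated genes) are placed in a 2-d score
space of input-normalized RNAPII occupancy vs nuclear RNA output.  Highly
enriched outliers on each axis are found with the boxplot rule
``Q3 + 1.5 x IQR``; the two fences partition regions into four classes:

* BT   - above both fences (bound and transcribed)
* B    - above the RNAPII fence only (bound, not highly transcribed)
* T    - above the nucRNA fence only (transcribed, low RNAPII)
* loBT - above neither
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage import RegionScore
from .stats import trimmed_mean

LABELS = ("BT", "B", "T", "loBT")


@dataclass
class ClassThresholds:
    nucRNA_threshold: float
    RNAPII_threshold: float
    nucRNA_quartiles: tuple[float, float]
    RNAPII_quartiles: tuple[float, float]


@dataclass
class ClassifiedRegion:
    score: RegionScore
    label: str
    efficiency_ratio: float


def boxplot_threshold(values: Sequence[float]) -> float:
    """Outlier fence ``Q3 + 1.5 x (Q3 - Q1)`` with linear-interpolation
    (type-7) quantiles.  Requires >= 4 finite values."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        raise ValueError("need >= 4 values for quartiles")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # numpy default is type-7
    return float(q3 + 1.5 * (q3 - q1))


def classify(
    scores: Sequence[RegionScore],
    min_gene_length: int = 300,
) -> tuple[ClassThresholds, list[ClassifiedRegion]]:
    """Assign each scored region a BT/B/T/loBT label.

    Regions no longer than ``min_gene_length`` bp are dropped *before* the
    fences are computed (the annotation contains sub-300 bp entries that are
    mostly artefactual).  A region must strictly exceed a fence to count as
    enriched on that axis; ties at the fence fall to the low side.
    """
    kept = [s for s in scores if len(s.region) > min_gene_length]
    if not kept:
        raise ValueError("no regions left after length filter")
    nuc = np.array([s.nucRNA_score for s in kept])
    pol = np.array([s.RNAPII_score for s in kept])
    if not (np.isfinite(nuc).all() and np.isfinite(pol).all()):
        raise ValueError("scores must be finite")
    thr = ClassThresholds(
        nucRNA_threshold=boxplot_threshold(nuc),
        RNAPII_threshold=boxplot_threshold(pol),
        nucRNA_quartiles=tuple(np.quantile(nuc, [0.25, 0.75])),
        RNAPII_quartiles=tuple(np.quantile(pol, [0.25, 0.75])),
    )
    out = []
    for s in kept:
        hi_nuc = s.nucRNA_score > thr.nucRNA_threshold
        hi_pol = s.RNAPII_score > thr.RNAPII_threshold
        label = ("BT" if hi_nuc else "B") if hi_pol else ("T" if hi_nuc else "loBT")
        ratio = s.nucRNA_score / s.RNAPII_score if s.RNAPII_score > 0 else float("nan")
        out.append(ClassifiedRegion(s, label, ratio))
    return thr, out


def efficiency_ratio(
    classified: Sequence[ClassifiedRegion], trim: float = 0.05
) -> dict[str, float]:
    """Per-class trimmed mean of the nucRNA:RNAPII score ratio.

    The ratio (in fold-enrichment units) measures RNA output per unit of
    polymerase occupancy.  Empty classes report ``nan``.
    """
    out: dict[str, float] = {}
    for label in LABELS:
        ratios = [
            c.efficiency_ratio
            for c in classified
            if c.label == label and np.isfinite(c.efficiency_ratio)
        ]
        if not ratios:
            out[label] = float("nan")
        elif len(ratios) <= 2:  # too few members to trim a tail
            out[label] = float(np.mean(ratios))
        else:
            out[label] = trimmed_mean(ratios, trim)
    return out


def class_counts(classified: Sequence[ClassifiedRegion]) -> dict[str, int]:
    counts = {label: 0 for label in LABELS}
    for c in classified:
        counts[c.label] += 1
    return counts
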