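"""Synthetic genomes and aligned libraries with planted ground truth.

The generator emulates the three-library design — nuclear RNA-Seq, RNAPII
ChIP-Seq and a genomic input — over a toy genome, planting:

* genes of known transcriptional class (BT/B/T/loBT rate combinations,
  with per-gene lognormal expression dispersion),
* promoter / 3'-end / double RNAPII stalling configurations,
* enhancer-like RNAPII-only elements with strand-arranged tags around a
  summit, a conserved core, and TF peak cover,
* intergenic lncRNA units (stable high nucRNA:RNAPII ratio, plus low-ratio
  decoys), and
* a mapping-artifact region that attracts a fixed fraction of *every*
  library's tags, so raw depth is inflated but fold enrichment over input
  stays near 1.

Tag starts are Poisson: the expected number of tags starting in a feature
is ``rate x eligible_starts x depth/1e6`` where ``rate`` is in tags per
base per million nominal library tags and ``eligible_starts`` is the
feature length minus the tag length plus one.  Everything is deterministic
under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Optional

import numpy as np

from .coverage import TagCollection
from .genome import AlignedTag, GeneModel, GenomicInterval

LIBRARIES = ("nucRNA", "RNAPII", "input")
_LIB_STREAM = {"nucRNA": 1, "RNAPII": 2, "input": 3, "tracks": 10, "genome": 0}


@dataclass
class TruthRecord:
    """Ground truth for one planted feature."""

    feature_id: str
    feature_kind: Literal["gene", "enhancer_like", "lncRNA_unit", "background"]
    interval: GenomicInterval
    planted_class: str = "none"  # BT | B | T | loBT | none
    planted_stall: str = "none"  # promoter | three_prime | double | none
    nucRNA_rate: float = 0.0  # tags/bp per million nominal library tags
    RNAPII_rate: float = 0.0
    splicing_fraction: float = 0.0
    summit: Optional[int] = None

    def __post_init__(self):
        if self.nucRNA_rate < 0 or self.RNAPII_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (0 <= self.splicing_fraction <= 1):
            raise ValueError("splicing_fraction must be in [0, 1]")


@dataclass
class SimConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_200_000
    # genes per planted class; outlier classes are minorities because the
    # boxplot fence can only flag a minority as enriched
    n_genes: dict = field(default_factory=lambda: {"BT": 4, "B": 4, "T": 4, "loBT": 28})
    # (nucRNA_rate, RNAPII_rate) per class
    class_rates: dict = field(
        default_factory=lambda: {
            "BT": (4.0, 4.0),
            "B": (0.1, 4.0),
            "T": (4.0, 0.1),
            "loBT": (0.1, 0.15),
        }
    )
    # stall genes must stay a small minority: the 95th-percentile rule can
    # only flag ~5% of the cohort per index
    n_stall: dict = field(
        default_factory=lambda: {"promoter": 1, "three_prime": 1, "double": 1}
    )
    stall_factor: float = 10.0
    stall_flank: int = 300
    n_enhancers: int = 8
    enhancer_rnapii_rate: float = 4.0  # matches a B-class gene
    enhancer_width: int = 300
    enhancer_conserved_core: int = 200
    n_lncrna: int = 4
    n_lncrna_decoys: int = 16
    n_lncrna_in_genes: int = 0  # gene-overlapping units (invisible by design)
    lncrna_rates: tuple = (2.0, 0.05)  # stable units
    lncrna_decoy_rates: tuple = (2.0, 2.0)
    lncrna_length: tuple = (7000, 11000)  # Malat1/Xist-scale stable units
    depth: int = 500_000  # nominal tags per library (scales all rates)
    tag_length: int = 36
    background_rate: float = 0.0001  # sample libraries; sparse intergenic tags
    input_rate: float = 0.3  # uniform genomic input
    splicing_fraction: float = 0.5
    rate_dispersion: float = 0.4  # sigma of per-gene lognormal multiplier
    min_spacing: int = 12_000
    max_spacing: int = 22_000
    input_artifact: bool = True
    artifact_width: int = 5000
    artifact_fraction: float = 0.02  # of each library's tags
    n_tfs: int = 3
    tf_peak_width: int = 300
    tf_background_peaks: int = 30  # random peaks per TF
    tf_on_enhancers: bool = True
    conserved_enhancers: bool = True
    short_gene_fixture: bool = False  # allow genes < 900 bp (not generated by default)

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < 50_000:
            raise ValueError("need >= 1 chromosome of >= 50 kb")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if sum(self.n_stall.values()) > self.n_genes.get("B", 0) + self.n_genes.get("BT", 0):
            raise ValueError("more stall genes requested than B/BT genes available")


@dataclass
class SyntheticDataset:
    config: SimConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    truth: list[TruthRecord]

    def truth_by_kind(self, kind: str) -> list[TruthRecord]:
        return [t for t in self.truth if t.feature_kind == kind]

    @property
    def artifact(self) -> Optional[TruthRecord]:
        for t in self.truth:
            if t.feature_id == "input_artifact":
                return t
        return None


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _LIB_STREAM[stream]])


def _make_gene(rng, chrom, start, strand) -> tuple[list[tuple[int, int]], int]:
    """Random exon layout (3-5 exons of 200-400 bp, introns 300-800 bp)."""
    n_exons = int(rng.integers(3, 6))
    exon_lens = rng.integers(200, 401, n_exons)
    intron_lens = rng.integers(300, 801, n_exons - 1)
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return exons, pos - start


def build_genome(config: SimConfig) -> SyntheticDataset:
    """Lay out genes, enhancer-like elements, lncRNA units and the input
    artifact along the toy genome, >= ``min_spacing`` bp apart."""
    config.validate()
    rng = _rng(config, "genome")
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}

    # feature descriptors before placement
    feats: list[dict] = []
    for label, count in config.n_genes.items():
        for i in range(count):
            feats.append({"kind": "gene", "class": label, "id": f"gene_{label}_{i}"})
    for i in range(config.n_enhancers):
        feats.append({"kind": "enhancer_like", "id": f"enhancer_{i}"})
    for i in range(config.n_lncrna):
        feats.append({"kind": "lncRNA_unit", "id": f"lncRNA_{i}", "decoy": False})
    for i in range(config.n_lncrna_decoys):
        feats.append({"kind": "lncRNA_unit", "id": f"lncRNA_decoy_{i}", "decoy": True})
    if config.input_artifact:
        feats.append({"kind": "background", "id": "input_artifact"})
    rng.shuffle(feats)

    # assign stalling configurations to B/BT genes
    stall_targets = [s for s in feats if s.get("class") in ("B", "BT")]
    rng.shuffle(stall_targets)
    stall_labels = (
        ["promoter"] * config.n_stall.get("promoter", 0)
        + ["three_prime"] * config.n_stall.get("three_prime", 0)
        + ["double"] * config.n_stall.get("double", 0)
    )
    for feat, stall in zip(stall_targets, stall_labels):
        feat["stall"] = stall

    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    chroms = sorted(chrom_sizes)
    ci = 0
    cursor = int(rng.integers(config.min_spacing, config.max_spacing))
    for feat in feats:
        placed = False
        while not placed:
            if ci >= len(chroms):
                raise ValueError("requested features exceed genome capacity")
            chrom = chroms[ci]
            if feat["kind"] == "gene":
                strand = str(rng.choice(["+", "-"]))
                exons, length = _make_gene(rng, chrom, cursor, strand)
            elif feat["kind"] == "enhancer_like":
                length = config.enhancer_width
            elif feat["kind"] == "lncRNA_unit":
                length = int(rng.integers(*config.lncrna_length))
            else:
                length = config.artifact_width
            if cursor + length + config.min_spacing > chrom_sizes[chrom]:
                ci += 1
                cursor = int(rng.integers(config.min_spacing, config.max_spacing))
                continue
            iv = GenomicInterval(chrom, cursor, cursor + length)
            if feat["kind"] == "gene":
                mult = float(np.exp(rng.normal(0.0, config.rate_dispersion)))
                nuc, pol = config.class_rates[feat["class"]]
                stall = feat.get("stall", "none")
                if stall == "double":
                    nuc = nuc * 2  # double-peak genes carry extra body RNA
                span = GenomicInterval(chrom, cursor, cursor + length, strand)
                gene = GeneModel(
                    feat["id"], span,
                    tuple(GenomicInterval(chrom, s, e) for s, e in exons),
                )
                genes.append(gene)
                truth.append(
                    TruthRecord(
                        feat["id"], "gene", span,
                        planted_class=feat["class"], planted_stall=stall,
                        nucRNA_rate=nuc * mult, RNAPII_rate=pol * mult,
                        splicing_fraction=config.splicing_fraction,
                    )
                )
            elif feat["kind"] == "enhancer_like":
                truth.append(
                    TruthRecord(
                        feat["id"], "enhancer_like", iv,
                        RNAPII_rate=config.enhancer_rnapii_rate,
                        summit=iv.midpoint,
                    )
                )
            elif feat["kind"] == "lncRNA_unit":
                nuc, pol = (
                    config.lncrna_decoy_rates if feat["decoy"] else config.lncrna_rates
                )
                truth.append(
                    TruthRecord(
                        feat["id"], "lncRNA_unit",
                        GenomicInterval(chrom, iv.start, iv.end, str(rng.choice(["+", "-"]))),
                        planted_class="BT" if feat["decoy"] else "T",
                        nucRNA_rate=nuc, RNAPII_rate=pol,
                    )
                )
            else:
                truth.append(TruthRecord(feat["id"], "background", iv))
            cursor = iv.end + int(rng.integers(config.min_spacing, config.max_spacing))
            placed = True

    # gene-overlapping lncRNA units (planted to be invisible to discovery)
    gene_pool = [g for g in genes if g.length > 500]
    for i in range(config.n_lncrna_in_genes):
        if not gene_pool:
            raise ValueError("no genes available to overlap")
        g = gene_pool[i % len(gene_pool)]
        length = int(rng.integers(*config.lncrna_length))
        start = g.span.start + 100
        end = min(start + length, chrom_sizes[g.chrom])
        truth.append(
            TruthRecord(
                f"lncRNA_ingene_{i}", "lncRNA_unit",
                GenomicInterval(g.chrom, start, end, g.strand),
                planted_class="T",
                nucRNA_rate=config.lncrna_rates[0],
                RNAPII_rate=config.lncrna_rates[1],
            )
        )

    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return SyntheticDataset(config, chrom_sizes, genes, truth)


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def _poisson_uniform_starts(rng, rate, lo, hi, taglen, scale) -> np.ndarray:
    """Tag starts for a uniform-rate segment [lo, hi); empty if too short."""
    n_pos = hi - lo - taglen + 1
    if n_pos <= 0 or rate <= 0 or scale <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * n_pos * scale)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return rng.integers(lo, lo + n_pos, n)


def simulate_library_arrays(
    dataset: SyntheticDataset, library: str, config: Optional[SimConfig] = None
) -> TagCollection:
    """Simulate one library directly into a :class:`TagCollection`."""
    config = config or dataset.config
    if library not in LIBRARIES:
        raise ValueError(f"unknown library {library!r}; expected one of {LIBRARIES}")
    rng = _rng(config, library)
    scale = config.depth / 1e6
    taglen = config.tag_length
    genes_by_id = {g.gene_id: g for g in dataset.genes}

    starts: dict[str, list[np.ndarray]] = {c: [] for c in dataset.chrom_sizes}
    strands: dict[str, list[np.ndarray]] = {c: [] for c in dataset.chrom_sizes}

    def _add(chrom, s, st):
        if s.size:
            starts[chrom].append(s.astype(np.int64))
            strands[chrom].append(st.astype(np.int8))

    def _balanced(rng, n):
        return rng.choice(np.array([-1, 1], dtype=np.int8), n)

    # background (uniform; the input library has its own deeper rate)
    bg_rate = config.input_rate if library == "input" else config.background_rate
    for chrom, size in dataset.chrom_sizes.items():
        s = _poisson_uniform_starts(rng, bg_rate, 0, size, taglen, scale)
        _add(chrom, s, _balanced(rng, s.size))

    if library != "input":
        for t in dataset.truth:
            if t.feature_kind == "gene":
                gene = genes_by_id[t.feature_id]
                if library == "nucRNA":
                    code = np.int8(-1 if gene.strand == "-" else 1)
                    for ex in gene.exons:
                        s = _poisson_uniform_starts(
                            rng, t.nucRNA_rate, ex.start, ex.end, taglen, scale
                        )
                        _add(gene.chrom, s, np.full(s.size, code))
                    intr_rate = t.nucRNA_rate * (1 - t.splicing_fraction)
                    for intron in gene.introns:
                        s = _poisson_uniform_starts(
                            rng, intr_rate, intron.start, intron.end, taglen, scale
                        )
                        _add(gene.chrom, s, np.full(s.size, code))
                else:  # RNAPII covers the whole transcription unit
                    s = _poisson_uniform_starts(
                        rng, t.RNAPII_rate, gene.span.start, gene.span.end, taglen, scale
                    )
                    _add(gene.chrom, s, _balanced(rng, s.size))
                    if t.planted_stall != "none":
                        anchors = {
                            "promoter": [gene.tss],
                            "three_prime": [gene.tes],
                            "double": [gene.tss, gene.tes],
                        }[t.planted_stall]
                        extra = (config.stall_factor - 1) * t.RNAPII_rate
                        for anchor in anchors:
                            lo = max(0, anchor - config.stall_flank)
                            hi = min(dataset.chrom_sizes[gene.chrom],
                                     anchor + config.stall_flank + 1)
                            s = _poisson_uniform_starts(rng, extra, lo, hi, taglen, scale)
                            _add(gene.chrom, s, _balanced(rng, s.size))
            elif t.feature_kind == "enhancer_like" and library == "RNAPII":
                # TF-binding-style arrangement: forward tags upstream of the
                # summit, reverse tags downstream
                mu = t.RNAPII_rate * len(t.interval) * scale / 2
                n_f, n_r = rng.poisson(mu), rng.poisson(mu)
                summit = t.summit
                f = rng.integers(summit - 120, summit - 40 + 1, n_f)
                r_end = rng.integers(summit + 40, summit + 120 + 1, n_r)
                _add(t.interval.chrom, f, np.full(n_f, 1, dtype=np.int8))
                _add(t.interval.chrom, r_end - taglen, np.full(n_r, -1, dtype=np.int8))
            elif t.feature_kind == "lncRNA_unit":
                rate = t.nucRNA_rate if library == "nucRNA" else t.RNAPII_rate
                s = _poisson_uniform_starts(
                    rng, rate, t.interval.start, t.interval.end, taglen, scale
                )
                if library == "nucRNA":
                    code = np.int8(-1 if t.interval.strand == "-" else 1)
                    _add(t.interval.chrom, s, np.full(s.size, code))
                else:
                    _add(t.interval.chrom, s, _balanced(rng, s.size))

    # mapping artifact: a fixed fraction of every library piles up here
    art = dataset.artifact
    if art is not None and config.artifact_fraction > 0:
        n_so_far = int(sum(sum(a.size for a in v) for v in starts.values()))
        n_art = rng.poisson(config.artifact_fraction * n_so_far)
        s = rng.integers(art.interval.start, art.interval.end - taglen + 1, n_art)
        _add(art.interval.chrom, s, _balanced(rng, n_art))

    per_chrom = {}
    for chrom in dataset.chrom_sizes:
        if starts[chrom]:
            s = np.concatenate(starts[chrom])
            st = np.concatenate(strands[chrom])
        else:
            s = np.empty(0, dtype=np.int64)
            st = np.empty(0, dtype=np.int8)
        per_chrom[chrom] = (s, s + taglen, st)
    return TagCollection.from_arrays(dataset.chrom_sizes, per_chrom, library_id=library)


def simulate_library(
    dataset: SyntheticDataset, library: str, config: Optional[SimConfig] = None
) -> Iterable[AlignedTag]:
    """Spec-level API: the simulated library as a stream of tags."""
    return simulate_library_arrays(dataset, library, config).iter_tags()


# ---------------------------------------------------------------------------
# Conservation and TF tracks
# ---------------------------------------------------------------------------

def simulate_tracks(
    dataset: SyntheticDataset, config: Optional[SimConfig] = None
) -> tuple[dict[str, np.ndarray], dict[str, list[GenomicInterval]]]:
    """Conservation score arrays and TF peak BED sets.

    Background conservation is uniform below 0.8; enhancer cores score in
    (0.85, 1.0).  Each enhancer is covered by 1..n_tfs TF peaks (unless
    ``tf_on_enhancers`` is off, the null configuration); every TF also gets
    ``tf_background_peaks`` uniformly placed peaks.
    """
    config = config or dataset.config
    rng = _rng(config, "tracks")
    conservation = {
        c: rng.uniform(0.0, 0.5, size) for c, size in dataset.chrom_sizes.items()
    }
    enhancers = dataset.truth_by_kind("enhancer_like")
    if config.conserved_enhancers:
        half = config.enhancer_conserved_core // 2
        for t in enhancers:
            mid = t.interval.midpoint
            conservation[t.interval.chrom][mid - half:mid + half] = rng.uniform(
                0.85, 1.0, 2 * half
            )

    tf_names = [f"TF{i + 1}" for i in range(config.n_tfs)]
    tf_peaks: dict[str, list[GenomicInterval]] = {name: [] for name in tf_names}
    w = config.tf_peak_width
    if config.tf_on_enhancers and config.n_tfs > 0:
        for t in enhancers:
            k = int(rng.integers(1, config.n_tfs + 1))
            for ti in rng.choice(config.n_tfs, k, replace=False):
                center = t.interval.midpoint + int(rng.integers(-100, 101))
                lo = max(0, center - w // 2)
                tf_peaks[tf_names[ti]].append(
                    GenomicInterval(t.interval.chrom, lo, lo + w)
                )
    chroms = sorted(dataset.chrom_sizes)
    for name in tf_names:
        for _ in range(config.tf_background_peaks):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            lo = int(rng.integers(0, dataset.chrom_sizes[chrom] - w))
            tf_peaks[name].append(GenomicInterval(chrom, lo, lo + w))
    return conservation, tf_peaks


def fish_frequencies(dataset: SyntheticDataset, c: float = 0.05):
    """Per-gene detection frequencies emulating a single-cell RNA FISH assay.

    The chance of seeing a focus in a cell saturates with expression rate:
    ``1 - exp(-c x nucRNA_rate)``.  Deterministic; used to exercise the
    log-linear correlation of imaging frequency against max coverage depth.
    """
    import pandas as pd

    rows = [
        {"gene_id": t.feature_id,
         "frequency": 1.0 - float(np.exp(-c * t.nucRNA_rate))}
        for t in dataset.truth_by_kind("gene")
    ]
    return pd.DataFrame(rows)
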