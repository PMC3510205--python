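"""Readers and writers for the standard formats the pipeline touches.

Every reader converts to 0-based half-open coordinates at the boundary:
BED and bedGraph are native, SAM and GTF/GFF are 1-based and shifted here,
fixedStep wiggle headers are 1-based.  Nothing downstream ever sees a
1-based coordinate.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
import pysam

from .genome import AlignedTag, GeneModel, GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A record that cannot be parsed as the declared format."""


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC-style ``chrom.sizes`` file (name <tab> length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{i}: expected 'chrom<TAB>size'")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignments(
    path,
    format: Optional[str] = None,
    library_id: str = "",
    chrom_sizes: Optional[dict[str, int]] = None,
    on_unknown_chrom: str = "error",
) -> Iterator[AlignedTag]:
    """Stream aligned tags from a SAM or BED file.

    Parameters
    ----------
    format:
        "sam" or "bed"; inferred from the file suffix when omitted.
    chrom_sizes:
        If given, tags on chromosomes absent from this mapping are either
        skipped (``on_unknown_chrom="skip"``) or raise (``"error"``).

    Unaligned, secondary and supplementary SAM records are skipped; the
    skipped count is logged.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".sam": "sam", ".bam": "sam", ".bed": "bed"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer alignment format from {path.name}")
    format = format.lower()
    if format == "sam":
        yield from _read_sam(path, library_id, chrom_sizes, on_unknown_chrom)
    elif format == "bed":
        yield from _read_bed_tags(path, library_id, chrom_sizes, on_unknown_chrom)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def _known(chrom, chrom_sizes, on_unknown, where) -> bool:
    if chrom_sizes is None or chrom in chrom_sizes:
        return True
    if on_unknown == "skip":
        return False
    raise FormatError(f"{where}: unknown chromosome {chrom!r}")


def _read_sam(path, library_id, chrom_sizes, on_unknown):
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            chrom = rec.reference_name
            if not _known(chrom, chrom_sizes, on_unknown, f"{path}:{rec.query_name}"):
                n_skipped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            yield AlignedTag(
                GenomicInterval(chrom, rec.reference_start, rec.reference_end, strand),
                library_id=library_id,
            )
    if n_skipped:
        logger.info("%s: skipped %d unaligned/secondary/unknown records", path, n_skipped)


def _read_bed_tags(path, library_id, chrom_sizes, on_unknown):
    n_skipped = 0
    for i, iv in enumerate(_iter_bed(path), 1):
        if not _known(iv.chrom, chrom_sizes, on_unknown, f"{path}:{i}"):
            n_skipped += 1
            continue
        yield AlignedTag(iv, library_id=library_id)
    if n_skipped:
        logger.info("%s: skipped %d records on unknown chromosomes", path, n_skipped)


def _iter_bed(path) -> Iterator[GenomicInterval]:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{i}: BED needs >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                yield GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: {exc}") from exc


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file into a list of intervals."""
    return list(_iter_bed(path))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[GeneModel]:
    """Read gene models from a GTF/GFF file.

    One :class:`GeneModel` per ``gene_id``; overlapping exons of a gene are
    merged.  The gene span comes from the ``gene`` feature when present,
    otherwise from the union of the gene's exons.  Output is ordered by
    (chrom, start, gene_id).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )

    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype not in ("gene", "exon"):
            continue
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        if ftype == "gene":
            spans[gid] = iv
        else:
            exons.setdefault(gid, []).append(iv)

    genes: list[GeneModel] = []
    for gid in set(spans) | set(exons):
        exs = exons.get(gid)
        if not exs:
            raise FormatError(f"gene {gid!r} has no exon features")
        strand = spans[gid].strand if gid in spans else exs[0].strand
        merged = merge_intervals(exs, max_gap=0)
        if gid in spans:
            span = spans[gid]
            for ex in merged:
                if ex.start < span.start or ex.end > span.end:
                    raise FormatError(f"gene {gid!r}: exon outside gene span")
        else:
            span = GenomicInterval(
                merged[0].chrom, merged[0].start, merged[-1].end, strand
            )
        span = GenomicInterval(span.chrom, span.start, span.end, strand)
        genes.append(GeneModel(gid, span, tuple(merged)))
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return genes


def write_annotation(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GTF (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tnucstate\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tnucstate\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Per-base score tracks (wiggle / bedGraph)
# ---------------------------------------------------------------------------

def read_wiggle(path, chrom_sizes: Optional[dict[str, int]] = None) -> dict[str, np.ndarray]:
    """Read a fixedStep wiggle or bedGraph file into per-base score arrays.

    Bases not covered by any record score 0.  Overlapping records are an
    error.  Returns ``{chrom: float array}``; array length is the chromosome
    size when provided, else the last covered base.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    state = None  # (chrom, next_start, step, span) for fixedStep
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=", 1) for f in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"]) - 1  # header is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                if span > step:
                    raise FormatError(f"{path}:{i}: span {span} > step {step}")
                state = [chrom, start, step, span]
                continue
            if line.startswith("variableStep"):
                raise FormatError(f"{path}:{i}: variableStep not supported")
            fields = line.split()
            if len(fields) == 1:
                if state is None:
                    raise FormatError(f"{path}:{i}: value outside fixedStep block")
                chrom, start, step, span = state
                spans.setdefault(chrom, []).append((start, start + span, float(fields[0])))
                state[1] = start + step
            elif len(fields) == 4:
                state = None
                start, end = int(fields[1]), int(fields[2])
                spans.setdefault(fields[0], []).append((start, end, float(fields[3])))
            else:
                raise FormatError(f"{path}:{i}: unrecognized wiggle/bedGraph line")

    tracks: dict[str, np.ndarray] = {}
    for chrom, recs in spans.items():
        recs.sort(key=lambda r: r[0])
        for (s0, e0, _), (s1, _, _) in zip(recs, recs[1:]):
            if s1 < e0:
                raise FormatError(f"{path}: overlapping records on {chrom} at {s1}")
        size = chrom_sizes[chrom] if chrom_sizes else recs[-1][1]
        arr = np.zeros(size, dtype=np.float64)
        for s, e, v in recs:
            if e > size:
                raise FormatError(f"{path}: record beyond {chrom} end ({e} > {size})")
            arr[s:e] = v
        tracks[chrom] = arr
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            tracks.setdefault(chrom, np.zeros(size, dtype=np.float64))
    return tracks


def write_bedgraph(tracks: dict[str, np.ndarray], path, precision: int = 4) -> None:
    """Write per-base score arrays as run-length-encoded bedGraph (zeros omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            arr = np.asarray(tracks[chrom], dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{round(float(v), precision)}\n")


# ---------------------------------------------------------------------------
# BED / tables
# ---------------------------------------------------------------------------

def write_bed(regions: Iterable, path, names=None, scores=None) -> None:
    """Write intervals as BED6.

    ``regions`` may be :class:`GenomicInterval` or anything with
    chrom/start/end/strand attributes.  Coordinates round-trip bit-identically
    through :func:`read_bed`.
    """
    regions = list(regions)
    if names is None:
        names = ["." for _ in regions]
    if scores is None:
        scores = [0 for _ in regions]
    with open(path, "w") as fh:
        for iv, name, score in zip(regions, names, scores):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def write_table(records, path, **to_csv_kwargs) -> None:
    """Write records (DataFrame or list of dicts) as a TSV."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, **to_csv_kwargs)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sam(tags: Iterable[AlignedTag], path, chrom_sizes: dict[str, int]) -> None:
    """Write tags as an unsorted SAM file (header from ``chrom_sizes``)."""
    chroms = sorted(chrom_sizes)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for n, tag in enumerate(tags):
            iv = tag.interval
            a = pysam.AlignedSegment(header)
            a.query_name = f"tag{n}"
            a.reference_id = tid[iv.chrom]
            a.reference_start = iv.start
            a.cigarstring = f"{len(iv)}M"
            a.mapping_quality = 255
            a.flag = 16 if iv.strand == "-" else 0
            fh.write(a)
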