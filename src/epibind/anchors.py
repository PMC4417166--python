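"""Anchors and bin geometry.

Gene promoters (TSS), transcription termination sites and enhancer midpoints
are treated uniformly as *anchors*: single genomic positions around which an
8-kb window is tiled with 80 disjoint 100-bp bins, indexed -40..-1 (upstream)
and +1..+40 (downstream) with no bin 0.  All coordinates are 0-based,
half-open internally; 1-based dialects are converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "EnhancerRecord",
    "Anchor",
    "BinScheme",
    "BinWindow",
    "AnnotationParseError",
    "read_gene_annotation",
    "read_chrom_sizes",
    "filter_genes",
    "make_bin_windows",
    "bin_indices",
    "enhancer_midpoint",
    "read_enhancers",
    "anchors_from_genes",
    "anchors_from_enhancers",
    "windows_to_bed",
]

VALID_STRANDS = ("+", "-")


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed; names the line."""


@dataclass(frozen=True)
class GeneRecord:
    """One transcript: TSS/TTS are 5'/3' ends in transcription direction.

    For a minus-strand transcript the TSS is the *end* of the annotated
    interval, so ``tss > tts`` there; ``abs(tts - tss)`` is the gene length.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: empty chrom")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.tss == self.tts:
            raise ValueError(f"{self.gene_id}: zero-length gene (tss == tts)")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return abs(self.tts - self.tss)


@dataclass(frozen=True)
class EnhancerRecord:
    chrom: str
    start: int
    end: int
    enhancer_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.enhancer_id}: start >= end")


@dataclass(frozen=True)
class Anchor:
    """A single anchored position; strand '.' marks an unstranded anchor."""

    anchor_id: str
    chrom: str
    pos: int
    strand: str = "."
    anchor_class: str = "coding"  # coding | noncoding | enhancer


@dataclass(frozen=True)
class BinScheme:
    """Tiling geometry: 2 * n_per_side bins of bin_size bp centered on the anchor."""

    bin_size: int = 100
    n_per_side: int = 40
    strand_aware: bool = True

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_per_side <= 0:
            raise ValueError("n_per_side must be positive")

    @property
    def half_span(self) -> int:
        return self.n_per_side * self.bin_size

    @property
    def n_bins(self) -> int:
        return 2 * self.n_per_side


@dataclass(frozen=True)
class BinWindow:
    bin_index: int  # in {-n..-1, +1..+n}; no 0
    chrom: str
    start: int
    end: int


def bin_indices(scheme: BinScheme) -> list[int]:
    """Bin indices in canonical order -n..-1, +1..+n (no zero)."""
    n = scheme.n_per_side
    return list(range(-n, 0)) + list(range(1, n + 1))


# ---------------------------------------------------------------------------
# readers


def _parse_refflat_line(fields: Sequence[str], lineno: int) -> tuple[str, str, str, int, int]:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd ...
    if len(fields) < 6:
        raise AnnotationParseError(f"line {lineno}: expected >= 6 refFlat columns, got {len(fields)}")
    gene_id, _name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
    try:
        tx_start, tx_end = int(fields[4]), int(fields[5])
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-numeric txStart/txEnd") from exc
    return gene_id, chrom, strand, tx_start, tx_end


def _parse_bed_line(fields: Sequence[str], lineno: int) -> tuple[str, str, str, int, int]:
    # BED6: chrom start end name score strand
    if len(fields) < 6:
        raise AnnotationParseError(f"line {lineno}: expected >= 6 BED columns, got {len(fields)}")
    chrom, name, strand = fields[0], fields[3], fields[5]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: non-numeric coordinates") from exc
    return name, chrom, strand, start, end


def read_gene_annotation(
    path: str | Path,
    dialect: str = "refFlat",
    biotype_column: int | None = None,
    default_biotype: str = "coding",
) -> list[GeneRecord]:
    """Read transcripts from a refFlat or BED6 file.

    The TSS is the 5' end in transcription direction: on '+' the interval
    start, on '-' the interval end.  Records with an unknown strand symbol
    are skipped with a warning; structurally malformed lines raise
    :class:`AnnotationParseError` naming the line number.

    ``biotype_column`` (0-based) optionally names an extra column carrying
    ``coding``/``noncoding``; otherwise ``default_biotype`` applies.
    """
    if dialect not in ("refFlat", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parse = _parse_refflat_line if dialect == "refFlat" else _parse_bed_line

    records: list[GeneRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            gene_id, chrom, strand, start, end = parse(fields, lineno)
            if strand not in VALID_STRANDS:
                logger.warning("line %d: rejected record %s with strand %r", lineno, gene_id, strand)
                n_rejected += 1
                continue
            if start >= end:
                logger.warning("line %d: rejected record %s with start >= end", lineno, gene_id)
                n_rejected += 1
                continue
            biotype = default_biotype
            if biotype_column is not None:
                if biotype_column >= len(fields):
                    raise AnnotationParseError(f"line {lineno}: missing biotype column {biotype_column}")
                biotype = fields[biotype_column]
            tss, tts = (start, end) if strand == "+" else (end, start)
            records.append(GeneRecord(gene_id, chrom, strand, tss, tts, biotype))
    if n_rejected:
        logger.info("rejected %d malformed records from %s", n_rejected, path)
    return records


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column chrom-sizes text (chrom <tab> length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise AnnotationParseError(f"line {lineno}: expected chrom and length")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise AnnotationParseError(f"line {lineno}: non-numeric length") from exc
    return sizes


def read_enhancers(path: str | Path) -> list[EnhancerRecord]:
    """Read enhancer intervals from BED4/BED6; zero-length intervals are skipped."""
    records: list[EnhancerRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationParseError(f"line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationParseError(f"line {lineno}: non-numeric coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"enh{lineno}"
            if start >= end:
                logger.warning("line %d: rejected zero-length enhancer %s", lineno, name)
                continue
            records.append(EnhancerRecord(chrom, start, end, name))
    return records


# ---------------------------------------------------------------------------
# filtering and geometry


def filter_genes(genes: Iterable[GeneRecord], min_length: int = 4000) -> list[GeneRecord]:
    """Keep genes with TSS-to-TTS length >= ``min_length`` (strictly shorter
    genes are dropped, so a gene of exactly ``min_length`` survives).  Order
    is preserved; the operation is idempotent."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return [g for g in genes if g.length >= min_length]


def enhancer_midpoint(e: EnhancerRecord) -> int:
    """Midpoint floor((start + end) / 2); enhancer anchors are unstranded."""
    return (e.start + e.end) // 2


def make_bin_windows(
    anchor_chrom: str,
    anchor_pos: int,
    strand: str = ".",
    scheme: BinScheme = BinScheme(),
) -> list[BinWindow]:
    """Tile the window around an anchor into 2*n_per_side disjoint bins.

    Returned in canonical index order -n..-1, +1..+n.  For '+' or unstranded
    anchors, bin +k = [anchor + (k-1)*B, anchor + k*B) and bin -k mirrors it
    upstream.  For a '-' anchor under ``strand_aware`` the genomic mapping is
    reflected so positive indices extend in transcription direction.
    """
    B = scheme.bin_size
    if anchor_pos - scheme.half_span < 0:
        raise ValueError(
            f"window for anchor {anchor_chrom}:{anchor_pos} extends past chromosome start"
        )
    mirrored = scheme.strand_aware and strand == "-"
    windows = []
    for k in bin_indices(scheme):
        idx = -k if mirrored else k
        if idx > 0:
            start = anchor_pos + (idx - 1) * B
        else:
            start = anchor_pos + idx * B
        windows.append(BinWindow(k, anchor_chrom, start, start + B))
    return windows


def anchors_from_genes(
    genes: Iterable[GeneRecord],
    chrom_sizes: dict[str, int] | None = None,
    scheme: BinScheme = BinScheme(),
    deduplicate: bool = True,
) -> list[Anchor]:
    """TSS anchors from gene records.

    Records sharing (chrom, strand, tss) collapse to a single anchor so the
    design matrix carries no duplicated rows; the number collapsed is logged.
    Anchors whose full window would leave chromosome bounds are excluded
    (not truncated) so every retained anchor has a complete bin profile.
    """
    seen: set[tuple[str, str, int]] = set()
    anchors: list[Anchor] = []
    n_collapsed = 0
    n_out_of_bounds = 0
    half = scheme.half_span
    for g in genes:
        key = (g.chrom, g.strand, g.tss)
        if deduplicate and key in seen:
            n_collapsed += 1
            continue
        seen.add(key)
        if g.tss - half < 0:
            n_out_of_bounds += 1
            continue
        if chrom_sizes is not None:
            size = chrom_sizes.get(g.chrom)
            if size is None or g.tss + half > size:
                n_out_of_bounds += 1
                continue
        anchors.append(Anchor(g.gene_id, g.chrom, g.tss, g.strand, g.biotype))
    if n_collapsed:
        logger.info("collapsed %d duplicate TSS anchors", n_collapsed)
    if n_out_of_bounds:
        logger.info("excluded %d anchors with out-of-bounds windows", n_out_of_bounds)
    return anchors


def anchors_from_enhancers(
    enhancers: Iterable[EnhancerRecord],
    chrom_sizes: dict[str, int] | None = None,
    scheme: BinScheme = BinScheme(),
) -> list[Anchor]:
    """Unstranded midpoint anchors from enhancer intervals (bounds-checked)."""
    anchors: list[Anchor] = []
    half = scheme.half_span
    n_out = 0
    for e in enhancers:
        mid = enhancer_midpoint(e)
        if mid - half < 0:
            n_out += 1
            continue
        if chrom_sizes is not None:
            size = chrom_sizes.get(e.chrom)
            if size is None or mid + half > size:
                n_out += 1
                continue
        anchors.append(Anchor(e.enhancer_id, e.chrom, mid, ".", "enhancer"))
    if n_out:
        logger.info("excluded %d enhancer anchors with out-of-bounds windows", n_out)
    return anchors


def windows_to_bed(anchor: Anchor, windows: Iterable[BinWindow]) -> str:
    """BED text for an anchor's bins, name = "<anchor_id>:<bin_index>"."""
    lines = [
        f"{w.chrom}\t{w.start}\t{w.end}\t{anchor.anchor_id}:{w.bin_index:+d}"
        for w in windows
    ]
    return "\n".join(lines) + "\n"
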