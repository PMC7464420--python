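"""Genomic windows around retained markers and gene-content annotation.

Retained markers are expanded into +/-250 kbp windows (the scale of useful
linkage disequilibrium on SNP-array data in cattle), optionally merged into
non-redundant regions, and intersected with a gene annotation (BED or
GFF3).  All coordinates are 1-based inclusive; overlap means at least one
shared base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genotype_io import LocusInfo
from .multicohort import OccurrenceTable, _chrom_sort_key

DEFAULT_HALF_WIDTH = 250_000


@dataclass
class GenomicWindow:
    chrom: str
    start_bp: int
    end_bp: int
    source_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.start_bp <= self.end_bp):
            raise ValueError(
                f"require 1 <= start <= end, got {self.start_bp}-{self.end_bp}"
            )

    def overlaps(self, other: "GenomicWindow") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start_bp: int
    end_bp: int
    symbol: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.symbol}: start > end")


@dataclass
class AnnotatedRegion:
    window: GenomicWindow
    genes: list[str] = field(default_factory=list)


class AnnotationParseError(ValueError):
    """Malformed BED/GFF3 content (message carries the line number)."""


def snp_window(
    locus: LocusInfo,
    half_width: int = DEFAULT_HALF_WIDTH,
    chrom_length: int | None = None,
) -> GenomicWindow:
    """+/-``half_width`` bp window around a marker, clamped at position 1
    (and at ``chrom_length`` when known)."""
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    start = max(1, locus.position_bp - half_width)
    end = locus.position_bp + half_width
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicWindow(
        chrom=locus.chrom, start_bp=start, end_bp=end, source_snps=[locus.snp_id]
    )


def merge_windows(windows: Iterable[GenomicWindow]) -> list[GenomicWindow]:
    """Merge overlapping or book-ended windows per chromosome.

    Source markers are unioned; output is sorted by chromosome then start.
    """
    by_chrom: dict[str, list[GenomicWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    merged: list[GenomicWindow] = []
    for chrom in sorted(by_chrom, key=_chrom_sort_key):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start_bp, w.end_bp))
        cur = GenomicWindow(
            chrom, ws[0].start_bp, ws[0].end_bp, list(ws[0].source_snps)
        )
        for w in ws[1:]:
            if w.start_bp <= cur.end_bp + 1:  # overlap or book-ended
                cur.end_bp = max(cur.end_bp, w.end_bp)
                cur.source_snps += [s for s in w.source_snps if s not in cur.source_snps]
            else:
                merged.append(cur)
                cur = GenomicWindow(chrom, w.start_bp, w.end_bp, list(w.source_snps))
        merged.append(cur)
    return merged


def delimited_interval(loci: Sequence[LocusInfo]) -> GenomicWindow:
    """Interval spanned by the outermost markers, with no flanks added."""
    if len(loci) < 2:
        raise ValueError("need at least 2 loci")
    chroms = {loc.chrom for loc in loci}
    if len(chroms) != 1:
        raise ValueError(f"loci span multiple chromosomes: {sorted(chroms)}")
    positions = [loc.position_bp for loc in loci]
    lo, hi = min(positions), max(positions)
    return GenomicWindow(
        chrom=loci[0].chrom,
        start_bp=lo,
        end_bp=max(lo, hi),
        source_snps=[loc.snp_id for loc in sorted(loci, key=lambda x: x.position_bp)],
    )


def read_gene_annotation(path: str | Path, format: str | None = None) -> list[GeneRecord]:
    """Read gene records from BED (0-based half-open) or GFF3 (1-based).

    BED coordinates are converted to 1-based inclusive.  In GFF3, only rows
    of type ``gene`` are used; the symbol is the ``Name`` attribute, falling
    back to ``gene`` then ``ID``.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if format not in {"bed", "gff3"}:
        raise ValueError(f"unknown annotation format: {format}")
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if format == "bed":
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: BED needs >= 4 columns"
                    )
                try:
                    start0, end0 = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
                records.append(
                    GeneRecord(fields[0], start0 + 1, end0, fields[3])
                )
            else:
                fields = line.split("\t")
                if len(fields) < 9:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: GFF3 needs 9 columns"
                    )
                if fields[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                symbol = attrs.get("Name") or attrs.get("gene") or attrs.get("ID")
                if symbol is None:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: gene row without Name/gene/ID attribute"
                    )
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
                records.append(GeneRecord(fields[0], start, end, symbol))
    return records


def genes_in_regions(
    regions: Sequence[GenomicWindow], genes: Sequence[GeneRecord]
) -> list[AnnotatedRegion]:
    """Attach to each region the genes sharing at least one base with it,
    ordered by gene start."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open tree coordinates: 1-based inclusive [s, e] -> [s, e+1)
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    out: list[AnnotatedRegion] = []
    for region in regions:
        tree = trees.get(region.chrom)
        hits = (
            sorted(
                (iv.data for iv in tree.overlap(region.start_bp, region.end_bp + 1)),
                key=lambda g: (g.start_bp, g.end_bp, g.symbol),
            )
            if tree is not None
            else []
        )
        out.append(AnnotatedRegion(window=region, genes=[g.symbol for g in hits]))
    return out


def report_table(
    occurrences: OccurrenceTable,
    regions_annotated: Sequence[AnnotatedRegion],
    loci_by_id: dict[str, LocusInfo],
) -> str:
    """Per-marker TSV: CHR, SNP ID, per-reference counts, OVERALL, POSITION,
    CONSIDERED INTERVAL, GENES.  One region per marker (its window), rows
    sorted by chromosome then position."""
    region_by_snp: dict[str, AnnotatedRegion] = {}
    for ar in regions_annotated:
        for s in ar.window.source_snps:
            region_by_snp[s] = ar
    header = (
        ["CHR", "SNP ID"]
        + [r.upper() for r in occurrences.reference_breeds]
        + ["OVERALL", "POSITION", "CONSIDERED INTERVAL", "GENES"]
    )
    rows = []
    for i, snp in enumerate(occurrences.snp_ids):
        if snp not in region_by_snp:
            continue
        loc = loci_by_id[snp]
        ar = region_by_snp[snp]
        rows.append(
            [
                loc.chrom,
                snp,
                *[str(int(c)) for c in occurrences.counts[i]],
                str(int(occurrences.overall[i])),
                str(loc.position_bp),
                f"{ar.window.start_bp}-{ar.window.end_bp}",
                ", ".join(ar.genes),
            ]
        )
    rows.sort(key=lambda r: (_chrom_sort_key(r[0]), int(r[-3])))
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    return "\n".join(lines) + "\n"
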