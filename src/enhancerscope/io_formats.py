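"""Readers and writers for BED, bedGraph, GTF gene records and TSV tables.

Every reader normalizes into the package's single internal convention:
0-based half-open coordinates.  GTF (1-based inclusive) is converted on
read and back on write, so a round trip is a bijection on coordinates.
All writers are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .signal import SignalTrack

if TYPE_CHECKING:  # pragma: no cover
    from .calling import RankedEnhancerTable

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_gtf_genes",
    "write_gtf_genes",
    "read_bedgraph",
    "write_bedgraph",
    "read_expression_table",
    "write_enhancer_table",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


def _fmt(x: float) -> str:
    """Stable float formatting: up to 6 decimal places, no trailing zeros."""
    return f"{x:.6f}".rstrip("0").rstrip(".")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, preserving file order.

    Columns beyond chrom/start/end are optional; column 4 becomes the
    interval name and column 5 its score ('.' means absent).
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name=name, score=score)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(_fmt(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read gene records from a GTF file into strand-aware gene models.

    Uses ``gene`` features, falling back to ``transcript`` when a file has
    no gene lines.  GTF's 1-based inclusive spans become 0-based half-open.
    """
    genes: dict[str, list[GeneModel]] = {"gene": [], "transcript": []}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            feature = fields[2]
            if feature not in genes:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            gene_id = _gtf_attribute(fields[8], "gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            try:
                genes[feature].append(
                    GeneModel(gene_id, fields[0], strand, start1 - 1, end1)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes["gene"] if genes["gene"] else genes["transcript"]


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        item = item.strip()
        if item.startswith(key + " "):
            return item[len(key):].strip().strip('"')
    return None


def write_gtf_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "enhancerscope",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f'gene_id "{g.gene_id}";',
                    ]
                )
                + "\n"
            )


def read_bedgraph(path: str | Path, total_mass: float | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a sorted signal track.

    Zero-value gaps are implicit; overlapping intervals on one chromosome
    are an error.  ``total_mass`` (e.g. a library size in reads) overrides
    the track's own integral as the RPM denominator.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            if not (0 <= start < end):
                raise ParseError(f"{path}:{lineno}: invalid span {start}-{end}")
            intervals.append((fields[0], start, end, value))
    try:
        return SignalTrack(intervals, total_mass=total_mass)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample FPKM table (TSV, first column gene_id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if (frame.values < 0).any():
        raise ParseError(f"{path}: negative FPKM values")
    return frame


def write_enhancer_table(table: "RankedEnhancerTable", path: str | Path) -> None:
    """Write a ranked enhancer table as TSV, plus a BED6 super-enhancer sidecar.

    The sidecar path is the TSV path with a ``.super.bed`` suffix.
    """
    path = Path(path)
    if len(table.regions) > 0 and table.cutoff_index is None:
        raise ValueError("enhancer table not finalized: cutoff not computed")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "chrom", "start", "end", "n_constituent_peaks", "signal",
                "rank", "scaled_rank", "scaled_signal", "is_super",
            ]
        )
        for row in table.rows():
            writer.writerow(
                [
                    row.region.chrom, row.region.start, row.region.end,
                    row.region.n_constituents, _fmt(row.signal), row.rank,
                    _fmt(row.scaled_rank), _fmt(row.scaled_signal),
                    int(row.is_super),
                ]
            )
    sidecar = path.with_suffix(path.suffix + ".super.bed")
    supers = [
        GenomicInterval(
            r.region.chrom, r.region.start, r.region.end,
            name=f"SE_{i}", score=r.signal,
        )
        for i, r in enumerate(reversed(list(table.rows())), start=1)
        if r.is_super
    ]
    write_bed(supers, sidecar)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
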