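"""Readers and writers for the formats the pipeline touches.

MAF alignment blocks, BED intervals with declared extra columns, FASTA,
and the tab-separated results table. Coordinates are 0-based half-open
everywhere; only human-facing reports use 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord


class MafFormatError(ValueError):
    """A MAF block violates the format contract (names the offending block/line)."""


class BedFormatError(ValueError):
    """A BED row violates the format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a reference sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise BedFormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise BedFormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class MafRow:
    """One 's' line of a MAF block.

    ``start`` counts from the 5' end of ``strand``; ``size`` is the number of
    non-gap characters in ``text``; ``src_size`` is the full source length.
    """

    species: str
    chrom: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def src(self) -> str:
        return f"{self.species}.{self.chrom}" if self.chrom else self.species


@dataclass
class AlignmentBlock:
    rows: list[MafRow]
    score: float | None = None

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def row_for(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.rows]

    def validate(self, index: int = -1) -> None:
        where = f"block {index}" if index >= 0 else "block"
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise MafFormatError(f"{where}: rows have unequal aligned lengths {sorted(widths)}")
        for row in self.rows:
            non_gap = sum(1 for c in row.text if c != "-")
            if non_gap != row.size:
                raise MafFormatError(
                    f"{where}, row {row.src}: declared size {row.size} != "
                    f"{non_gap} non-gap characters"
                )


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        species, chrom = src.split(".", 1)
        return species, chrom
    return src, ""


def read_maf_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Parse a MAF file into validated :class:`AlignmentBlock` objects.

    Gap characters are normalized to ``-`` and sequence to upper case. If a
    block's reference (first) row is on the minus strand the whole block is
    reverse-complemented into reference forward orientation, per UCSC MAF
    semantics.
    """
    blocks: list[AlignmentBlock] = []
    try:
        parsed = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise MafFormatError(f"{path}: {exc}") from exc
    for i, msa in enumerate(parsed):
        rows = []
        for rec in msa:
            ann = rec.annotations
            species, chrom = _split_src(rec.id)
            text = str(rec.seq).upper().replace(".", "-")
            rows.append(
                MafRow(
                    species=species,
                    chrom=chrom,
                    start=int(ann.get("start", 0)),
                    size=int(ann.get("size", sum(1 for c in text if c != "-"))),
                    strand="-" if ann.get("strand", 1) in (-1, "-") else "+",
                    src_size=int(ann.get("srcSize", 0)),
                    text=text,
                )
            )
        block = AlignmentBlock(rows=rows, score=msa.annotations.get("score"))
        block.validate(index=i)
        if block.rows and block.rows[0].strand == "-":
            block = _flip_block(block)
        blocks.append(block)
    return blocks


def _flip_block(block: AlignmentBlock) -> AlignmentBlock:
    """Reverse-complement every row so the reference row reads on '+'."""
    flipped = []
    for row in block.rows:
        flipped.append(
            MafRow(
                species=row.species,
                chrom=row.chrom,
                start=row.src_size - row.start - row.size,
                size=row.size,
                strand="+" if row.strand == "-" else "-",
                src_size=row.src_size,
                text=reverse_complement(row.text),
            )
        )
    return AlignmentBlock(rows=flipped, score=block.score)


def write_maf_blocks(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    """Write blocks in UCSC MAF dialect (inverse of :func:`read_maf_blocks`)."""
    msas = []
    for block in blocks:
        records = []
        for row in block.rows:
            rec = SeqRecord(Seq(row.text), id=row.src, description="")
            rec.annotations.update(
                {
                    "start": row.start,
                    "size": row.size,
                    "strand": -1 if row.strand == "-" else 1,
                    "srcSize": row.src_size,
                }
            )
            records.append(rec)
        msa = MultipleSeqAlignment(records)
        if block.score is not None:
            msa.annotations["score"] = block.score
        msas.append(msa)
    with open(path, "w") as handle:
        AlignIO.write(msas, handle, "maf")


# BED ------------------------------------------------------------------

_BED_TYPES = {"str": str, "float": float, "int": int}


def read_bed_intervals(
    path: str | Path,
    extra_columns: dict[int, tuple[str, str]] | None = None,
) -> list[GenomicInterval]:
    """Read BED3+ rows into intervals, input order preserved.

    ``extra_columns`` maps 0-based column index to ``(attribute_name, type)``
    with type one of ``str``/``int``/``float``; parsed values are stored in
    ``interval.attributes``.
    """
    extra_columns = extra_columns or {}
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise BedFormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            attrs = {}
            for idx, (attr, typ) in extra_columns.items():
                if idx < len(fields):
                    attrs[attr] = _BED_TYPES[typ](fields[idx])
            intervals.append(
                GenomicInterval(chrom, start, end, strand, name, attrs)
            )
    return intervals


def write_bed_intervals(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    extra_attrs: Sequence[str] = (),
) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, "0", iv.strand]
            for attr in extra_attrs:
                fields.append(str(iv.attributes.get(attr, ".")))
            handle.write("\t".join(fields) + "\n")


# FASTA ----------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# Results table --------------------------------------------------------

RESULT_COLUMNS = [
    "feature_id",
    "chrom",
    "start",
    "end",
    "strand",
    "d_F",
    "d_LN",
    "SR",
    "GC",
    "degapped_len",
    "SI",
    "FDR",
    "class",
]

_FLOAT_COLUMNS = ["d_F", "d_LN", "SR", "GC", "SI", "FDR"]


def write_results(results: Sequence, path: str | Path) -> None:
    """Write SelectionResult rows as a TSV, floats at 6 decimals, NA for absent."""
    rows = []
    for r in results:
        iv = r.interval
        rows.append(
            {
                "feature_id": r.feature_id,
                "chrom": iv.chrom if iv else "NA",
                "start": iv.start if iv else "NA",
                "end": iv.end if iv else "NA",
                "strand": iv.strand if iv else "NA",
                "d_F": r.d_f,
                "d_LN": r.d_ln,
                "SR": r.sr,
                "GC": r.gc,
                "degapped_len": r.degapped_len,
                "SI": r.si,
                "FDR": r.fdr,
                "class": r.label,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    with open(path, "w") as handle:
        handle.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            out = []
            for col in RESULT_COLUMNS:
                val = row[col]
                if val is None or (isinstance(val, float) and math.isnan(val)):
                    out.append("NA")
                elif col in _FLOAT_COLUMNS:
                    out.append(f"{float(val):.6f}")
                else:
                    out.append(str(val))
            handle.write("\t".join(out) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
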