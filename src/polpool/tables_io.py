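"""Readers and writers for the pipeline's external representations.

Formats handled here: per-gene peak-value tables (TSV), BED6 gene models and
SICER island files, FASTA genomes/promoters, GMT gene sets, plain-text motif
files, and the pool-assignment report.  All genomic intervals are 0-based
half-open (BED convention); 1-based inputs must be converted at this boundary
(``one_based=True`` on the BED reader).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "NON_INPUT_CONDITIONS",
    "TableFormatError",
    "GenePeakRecord",
    "GeneModel",
    "GeneSet",
    "read_gene_peak_table",
    "write_gene_peak_table",
    "read_gene_models",
    "read_fasta",
    "write_fasta",
    "read_gene_sets",
    "write_gene_sets",
    "read_motif_file",
    "write_motif_file",
    "read_islands_bed",
    "sicer_gene_flags",
    "excel_to_tsv",
    "read_gene_list",
    "write_gene_list",
]


class Condition(str, Enum):
    """The five ChIP-seq samples: wild-type and Parp14-null Th2 cells, each
    with or without the pan-PARP inhibitor PJ34, plus the input control."""

    WT = "WT"
    KO = "KO"
    WT_PJ34 = "WT_PJ34"
    KO_PJ34 = "KO_PJ34"
    INPUT = "INPUT"


NON_INPUT_CONDITIONS: tuple[Condition, ...] = (
    Condition.WT,
    Condition.KO,
    Condition.WT_PJ34,
    Condition.KO_PJ34,
)


class TableFormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenePeakRecord:
    """One gene's average Pol II peak value per condition plus per-sample
    SICER significance flags — the classifier's atomic input.

    Peak values are dimensionless normalized tag densities and must be
    non-negative; all five conditions and all four non-input flags must be
    present.
    """

    gene_id: str
    peak: dict[Condition, float]
    sicer_significant: dict[Condition, bool]

    def __post_init__(self) -> None:
        for cond in Condition:
            if cond not in self.peak:
                raise TableFormatError(
                    f"gene {self.gene_id!r}: missing peak value for {cond.value}"
                )
            if not (self.peak[cond] >= 0):
                raise TableFormatError(
                    f"gene {self.gene_id!r}: negative peak for {cond.value}"
                )
        for cond in NON_INPUT_CONDITIONS:
            if cond not in self.sicer_significant:
                raise TableFormatError(
                    f"gene {self.gene_id!r}: missing SICER flag for {cond.value}"
                )

    def max_noninput_peak(self) -> float:
        return max(self.peak[c] for c in NON_INPUT_CONDITIONS)


@dataclass
class GeneModel:
    """A gene interval with strand and derived TSS (0-based half-open).

    The TSS is ``start`` for + strand genes and ``end - 1`` for − strand
    genes; it is derived automatically when not supplied.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TableFormatError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise TableFormatError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        expected = self.start if self.strand == "+" else self.end - 1
        if self.tss is None:
            self.tss = expected
        elif self.tss != expected:
            raise TableFormatError(
                f"gene {self.gene_id!r}: tss {self.tss} inconsistent with strand rule"
            )


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.members:
            raise TableFormatError(f"gene set {self.set_id!r} has no members")


# ---------------------------------------------------------------------------
# peak tables

DEFAULT_PEAK_COLUMNS: dict[Condition, str] = {c: c.value for c in Condition}
FLAG_SUFFIX = "_sig"


def _parse_flag(value: object, row: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in ("1", "true"):
        return True
    if text in ("0", "false"):
        return False
    raise TableFormatError(f"row {row}: column {column!r} has non-boolean flag {value!r}")


def read_gene_peak_table(
    path: str | Path,
    column_map: Mapping[Condition, str] | None = None,
    gene_column: str = "gene_id",
    flag_suffix: str = FLAG_SUFFIX,
) -> list[GenePeakRecord]:
    """Read a TSV of per-gene average peak values into GenePeakRecords.

    ``column_map`` maps each condition to its peak column; flag columns are
    the non-input peak columns suffixed with ``flag_suffix``.  Row order is
    preserved and gene ids must be unique.
    """
    cols = dict(DEFAULT_PEAK_COLUMNS if column_map is None else column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = [gene_column] + [cols[c] for c in Condition] + [
        cols[c] + flag_suffix for c in NON_INPUT_CONDITIONS
    ]
    for name in needed:
        if name not in df.columns:
            raise TableFormatError(f"{path}: missing required column {name!r}")

    records: list[GenePeakRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row_d = dict(zip(df.columns, row))
        gene = str(row_d[gene_column])
        if gene in seen:
            raise TableFormatError(f"duplicate gene_id {gene!r}")
        seen.add(gene)
        peaks: dict[Condition, float] = {}
        for cond in Condition:
            raw = row_d[cols[cond]]
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise TableFormatError(
                    f"row {i}: column {cols[cond]!r} not numeric: {raw!r}"
                ) from exc
            if value < 0:
                raise TableFormatError(f"row {i}: negative peak value {value} for {gene!r}")
            peaks[cond] = value
        flags = {
            cond: _parse_flag(row_d[cols[cond] + flag_suffix], i, cols[cond] + flag_suffix)
            for cond in NON_INPUT_CONDITIONS
        }
        records.append(GenePeakRecord(gene, peaks, flags))
    return records


def write_gene_peak_table(
    records: Sequence[GenePeakRecord],
    path: str | Path,
    column_map: Mapping[Condition, str] | None = None,
    gene_column: str = "gene_id",
    flag_suffix: str = FLAG_SUFFIX,
) -> None:
    """Inverse of :func:`read_gene_peak_table` (canonical shortest-repr floats)."""
    cols = dict(DEFAULT_PEAK_COLUMNS if column_map is None else column_map)
    header = [gene_column] + [cols[c] for c in Condition] + [
        cols[c] + flag_suffix for c in NON_INPUT_CONDITIONS
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            fields = [rec.gene_id]
            fields += [str(float(rec.peak[c])) for c in Condition]
            fields += [str(int(rec.sicer_significant[c])) for c in NON_INPUT_CONDITIONS]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene models (BED6)


def read_gene_models(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    """Read BED6-like gene models; TSS derived per strand.

    Set ``one_based=True`` for inputs with 1-based inclusive starts (they are
    converted to BED half-open on the way in).
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise TableFormatError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start_s, end_s, name, _score, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start >= end:
                raise TableFormatError(f"{path}:{lineno}: start >= end")
            if strand not in ("+", "-"):
                raise TableFormatError(f"{path}:{lineno}: bad strand {strand!r}")
            models.append(GeneModel(name, chrom, start, end, strand))
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.gene_id}\t0\t{m.strand}\n")


# ---------------------------------------------------------------------------
# FASTA

_ALLOWED = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}; alphabet restricted to ACGTN."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise TableFormatError(f"{path}: empty record {rec.id!r}")
        for pos, base in enumerate(seq, start=1):
            if base not in _ALLOWED:
                raise TableFormatError(
                    f"{path}: record {rec.id!r} has illegal character {base!r} at position {pos}"
                )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (set_id, description, then members; tab-delimited)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableFormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            members = [p for p in parts[2:] if p]
            unique = set(members)
            if len(unique) < len(members):
                logger.warning("%s:%d: duplicate members collapsed in set %r", path, lineno, parts[0])
            sets.append(GeneSet(parts[0], parts[1], unique))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name] + sorted(gs.members)) + "\n")


# ---------------------------------------------------------------------------
# motif files (one motif per line: id, sequence, max_mismatches)


def read_motif_file(path: str | Path):
    from .motifs import Motif  # local import to avoid a cycle

    motifs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise TableFormatError(f"{path}:{lineno}: motif line needs id and sequence")
            max_mm = int(parts[2]) if len(parts) > 2 else None
            motifs.append(Motif(parts[0], parts[1].upper(), max_mm))
    return motifs


def write_motif_file(motifs, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"{m.motif_id}\t{m.sequence}\t{m.max_mismatches}\n")


# ---------------------------------------------------------------------------
# SICER islands -> per-gene significance flags


def read_islands_bed(path: str | Path) -> list[tuple[str, int, int]]:
    islands = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableFormatError(f"{path}:{lineno}: expected >=3 BED columns")
            islands.append((parts[0], int(parts[1]), int(parts[2])))
    return islands


def sicer_gene_flags(
    models: Sequence[GeneModel], islands: Iterable[tuple[str, int, int]]
) -> dict[str, bool]:
    """Flag each gene significant if >=1 bp of its body overlaps any island.

    The gene-body rule is a declared default; the upstream caller reported
    gene-level significance without stating its overlap convention.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in islands:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return {
        m.gene_id: bool(trees[m.chrom].overlap(m.start, m.end)) if m.chrom in trees else False
        for m in models
    }


# ---------------------------------------------------------------------------
# Excel supplementary tables -> TSV, and plain gene lists


def excel_to_tsv(path: str | Path, out_path: str | Path, sheet: int | str = 0) -> None:
    """Thin conversion of a supplementary Excel sheet to TSV for ingestion."""
    df = pd.read_excel(path, sheet_name=sheet)
    df.to_csv(out_path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
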