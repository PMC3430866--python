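"""Readers, writers and container types for the formats the pipeline exchanges.

Coordinate convention
---------------------
Every coordinate in this package is 0-based half-open (BED-native): a feature
occupies ``[start, end)``.  The TSS of a ``+``-strand gene is ``start``; the
TSS of a ``-``-strand gene is ``end - 1`` (the last base inside the
interval).  A single convention everywhere removes off-by-one drift between
the simulator, the annotator and the tests.

Formats
-------
* genes: BED6 (name = gene id, score ignored, strand required)
* peaks: BED6+7 — columns 7..13 are summit offset from ``start``, heights in
  populations 2/3/4, and 0/1 presence calls in populations 2/3/4
* repeat masks / plain intervals: BED3+
* coverage: bedGraph (variable-step four-column dialect only)
* expression: TSV with a gene-id column followed by four population columns
* knockout table: TSV whose replicate column names encode genotype, e.g.
  ``het_b1_t2`` = heterozygote, biological replicate 1, technical replicate 2
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ParseError",
    "GeneModel",
    "Peak",
    "CoverageTrack",
    "ExpressionMatrix",
    "read_genes_bed",
    "write_genes_bed",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_ko_tsv",
    "write_ko_tsv",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.10g"

POPULATIONS = ("pop1", "pop2", "pop3", "pop4")
#: populations profiled by ChIP (the regulator is not bound in population 1)
CHIP_POPULATIONS = ("pop2", "pop3", "pop4")


class ParseError(ValueError):
    """A malformed record in an input file; carries file and line context."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = str(path)
        self.lineno = lineno
        where = f"{path}" if lineno is None else f"{path}:{lineno}"
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates and strand; the anchor for peak assignment."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A binding interval with summit, per-population heights and calls.

    ``heights`` and ``called`` are ordered (population 2, 3, 4).
    """

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    heights: Tuple[float, float, float]
    called: Tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"peak {self.peak_id}: bad interval")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )
        if len(self.heights) != 3 or len(self.called) != 3:
            raise ValueError(f"peak {self.peak_id}: need 3 heights and 3 calls")
        if any(h < 0 for h in self.heights):
            raise ValueError(f"peak {self.peak_id}: negative height")

    def __len__(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Per-chromosome step-function coverage (sorted, non-overlapping)."""

    def __init__(self, intervals: Mapping[str, Sequence[Tuple[int, int, float]]]):
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in intervals.items():
            if not ivals:
                continue
            starts = np.asarray([i[0] for i in ivals], dtype=np.int64)
            ends = np.asarray([i[1] for i in ivals], dtype=np.int64)
            values = np.asarray([i[2] for i in ivals], dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted coverage interval")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping coverage intervals")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative coverage value")
            self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._data)

    def intervals(self, chrom: str):
        return self._data.get(chrom)

    def integral(self, chrom: str, a: int, b: int) -> float:
        """Sum of coverage over the bases of ``[a, b)``; absent regions are 0."""
        if b <= a:
            return 0.0
        rec = self._data.get(chrom)
        if rec is None:
            return 0.0
        starts, ends, values = rec
        lo = np.searchsorted(ends, a, side="right")
        hi = np.searchsorted(starts, b, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], a)
        e = np.minimum(ends[lo:hi], b)
        return float(np.sum((e - s) * values[lo:hi]))

    def mean(self, chrom: str, a: int, b: int) -> float:
        return self.integral(chrom, a, b) / (b - a) if b > a else 0.0


@dataclass
class ExpressionMatrix:
    """Genes x 4 populations of non-negative linear expression values."""

    platform: str
    values: pd.DataFrame  # index: gene ids; columns: POPULATIONS

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(POPULATIONS):
            raise ValueError(
                f"expression matrix needs columns {POPULATIONS}, "
                f"got {list(self.values.columns)}"
            )
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated gene ids: {list(dups)[:5]}")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _bed_rows(path, min_cols: int):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    path, lineno, f"expected >= {min_cols} columns, got {len(fields)}"
                )
            yield lineno, fields


def _parse_int(path, lineno, text, what) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {text!r}") from None


def _parse_float(path, lineno, text, what) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {text!r}") from None


def _check_interval(path, lineno, start, end):
    if start < 0:
        raise ParseError(path, lineno, f"negative start {start}")
    if start >= end:
        raise ParseError(path, lineno, f"start {start} >= end {end}")


def read_genes_bed(path) -> List[GeneModel]:
    """Read gene models from BED6 (0-based half-open, strand required)."""
    genes: List[GeneModel] = []
    seen = set()
    for lineno, f in _bed_rows(path, 6):
        start = _parse_int(path, lineno, f[1], "start")
        end = _parse_int(path, lineno, f[2], "end")
        _check_interval(path, lineno, start, end)
        if f[5] not in ("+", "-"):
            raise ParseError(path, lineno, f"unknown strand symbol {f[5]!r}")
        if f[3] in seen:
            raise ParseError(path, lineno, f"duplicate gene id {f[3]!r}")
        seen.add(f[3])
        genes.append(GeneModel(f[3], f[0], start, end, f[5]))
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_peaks_bed(path) -> List[Peak]:
    """Read peaks from the BED6+7 dialect (summit offset, heights, calls)."""
    peaks: List[Peak] = []
    seen = set()
    for lineno, f in _bed_rows(path, 13):
        start = _parse_int(path, lineno, f[1], "start")
        end = _parse_int(path, lineno, f[2], "end")
        _check_interval(path, lineno, start, end)
        if f[5] not in ("+", "-", "."):
            raise ParseError(path, lineno, f"unknown strand symbol {f[5]!r}")
        if f[3] in seen:
            raise ParseError(path, lineno, f"duplicate peak id {f[3]!r}")
        seen.add(f[3])
        summit_off = _parse_int(path, lineno, f[6], "summit offset")
        heights = tuple(
            _parse_float(path, lineno, f[i], "peak height") for i in (7, 8, 9)
        )
        called = []
        for i in (10, 11, 12):
            if f[i] not in ("0", "1"):
                raise ParseError(path, lineno, f"presence call must be 0/1, got {f[i]!r}")
            called.append(f[i] == "1")
        try:
            peaks.append(
                Peak(f[3], f[0], start, end, start + summit_off, heights, tuple(called))
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            h = "\t".join(_FLOAT_FMT % x for x in p.heights)
            c = "\t".join("1" if x else "0" for x in p.called)
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                f"{p.summit - p.start}\t{h}\t{c}\n"
            )


def read_intervals_bed(path) -> List[Tuple[str, int, int]]:
    """Read plain (chrom, start, end) intervals from BED3+."""
    out = []
    for lineno, f in _bed_rows(path, 3):
        start = _parse_int(path, lineno, f[1], "start")
        end = _parse_int(path, lineno, f[2], "end")
        _check_interval(path, lineno, start, end)
        out.append((f[0], start, end))
    return out


def write_intervals_bed(intervals: Iterable[Tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path, keep_case: bool = False) -> Dict[str, str]:
    """Read FASTA into an id -> sequence map.

    Sequences are upper-cased unless ``keep_case`` (soft-masked lowercase is
    meaningful to the motif-core extractor).  Letters outside ACGTN are
    rejected; duplicate record ids are an error.
    """
    records: Dict[str, str] = {}
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    for rec in parsed:
        if rec.id in records:
            raise ParseError(path, None, f"duplicate record id {rec.id!r}")
        seq = str(rec.seq)
        bad = set(seq.upper()) - _FASTA_ALPHABET
        if bad:
            raise ParseError(
                path, None, f"record {rec.id!r}: letters outside ACGTN: {sorted(bad)}"
            )
        records[rec.id] = seq if keep_case else seq.upper()
    return records


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path) -> CoverageTrack:
    """Read four-column bedGraph into a :class:`CoverageTrack`.

    Only the variable-step ``chrom start end value`` dialect is accepted.
    """
    per_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
    for lineno, f in _bed_rows(path, 4):
        if f[0] in ("fixedStep", "variableStep"):
            raise ParseError(path, lineno, "wiggle step lines are not supported")
        start = _parse_int(path, lineno, f[1], "start")
        end = _parse_int(path, lineno, f[2], "end")
        _check_interval(path, lineno, start, end)
        value = _parse_float(path, lineno, f[3], "coverage value")
        per_chrom.setdefault(f[0], []).append((start, end, value))
    try:
        return CoverageTrack(per_chrom)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from None


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{_FLOAT_FMT % v}\n")


# ---------------------------------------------------------------------------
# expression and knockout tables
# ---------------------------------------------------------------------------


def read_expression_tsv(path, platform: str | None = None) -> ExpressionMatrix:
    """Read a gene x 4-population expression TSV.

    The header must name a gene-id column followed by exactly four population
    columns.  Non-numeric cells and duplicate gene ids are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 5:
        raise ParseError(
            path, 1, f"expected gene id + 4 population columns, got {df.shape[1]}"
        )
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        dup = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise ParseError(path, None, f"duplicated gene id {dup!r}")
    values = pd.DataFrame(index=pd.Index(df[gene_col], name="gene_id"))
    for j, col in enumerate(df.columns[1:]):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            i = int(numeric.index[numeric.isna()][0])
            raise ParseError(
                path,
                i + 2,  # +1 header, +1 one-based
                f"non-numeric cell in column {col!r}: {df[col].iloc[i]!r}",
            )
        values[POPULATIONS[j]] = numeric.to_numpy(dtype=float)
    return ExpressionMatrix(platform or Path(str(path)).stem, values)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(POPULATIONS) + "\n")
        for gene, row in zip(df.index, df.to_numpy()):
            fh.write(gene + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


def parse_ko_column(name: str) -> Tuple[str, int, int]:
    """Split a replicate column name like ``het_b1_t2`` into its parts."""
    parts = name.split("_")
    if (
        len(parts) != 3
        or parts[0] not in ("het", "null")
        or not parts[1].startswith("b")
        or not parts[2].startswith("t")
    ):
        raise ValueError(f"malformed knockout column name {name!r}")
    return parts[0], int(parts[1][1:]), int(parts[2][1:])


def read_ko_tsv(path) -> pd.DataFrame:
    """Read a knockout replicate table (gene_id + genotype-encoded columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    gene_col = df.columns[0]
    if df[gene_col].duplicated().any():
        raise ParseError(path, None, "duplicated gene id in knockout table")
    for col in df.columns[1:]:
        parse_ko_column(col)  # raises on malformed names
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(path, None, f"non-numeric cell in column {col!r}")
    return df.set_index(gene_col).astype(float)


def write_ko_tsv(table: pd.DataFrame, path) -> None:
    genotypes = [parse_ko_column(c)[0] for c in table.columns]
    with open(path, "w") as fh:
        fh.write("#genotype\t" + "\t".join(genotypes) + "\n")
        fh.write("gene_id\t" + "\t".join(table.columns) + "\n")
        for gene, row in zip(table.index, table.to_numpy()):
            fh.write(gene + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
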