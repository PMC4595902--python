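"""Readers and writers for the plain-text formats used by the pipeline.

Everything downstream works in the DNA alphabet: ``U`` is mapped to ``T`` on
read (sequencers emit T; uridylation is therefore read as a T tail) and all
sequences are case-folded to upper case.  FASTA/FASTQ parsing is delegated to
Biopython; this module only adds normalisation, validation and the miRBase
mature-to-hairpin linkage convention.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class ParseError(ValueError):
    """Malformed input file (names the offending record / line)."""


_U_TO_T = str.maketrans("Uu", "Tt")
_VALID_READ = frozenset("ACGTN")
_VALID_REF = frozenset("ACGT")


def normalize_seq(seq: str) -> str:
    """Map RNA to DNA alphabet and upper-case."""
    return seq.translate(_U_TO_T).upper()


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; ``qual`` is carried but unused downstream."""

    read_id: str
    seq: str
    qual: str | None = None

    def truncated(self, length: int) -> "ReadRecord":
        qual = self.qual[:length] if self.qual is not None else None
        return replace(self, seq=self.seq[:length], qual=qual)


@dataclass
class ReferenceSet:
    """Hairpin precursors plus mature miRNAs linked to their hairpin of origin."""

    hairpins: dict[str, str]
    matures: dict[str, tuple[str, str]]  # mature_id -> (seq, hairpin_id)
    rejects: list[tuple[str, str]] = field(default_factory=list)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(fh: IO[str]) -> str:
    first = fh.read(1)
    fh.seek(0)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"cannot detect format from first byte {first!r} (line 1)")


def read_sequences(path: str | Path, format: str = "auto") -> Iterator[ReadRecord]:
    """Stream reads from a FASTA/FASTQ file (one record in memory at a time).

    ``format='auto'`` sniffs '>' vs '@' from the first byte.  Raises
    :class:`ParseError` naming the record/line on malformed input.
    """
    with _open_text(path) as fh:
        fmt = _sniff_format(fh) if format == "auto" else format
        if fmt == "fasta":
            for n, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
                seq = normalize_seq(str(rec.seq))
                if not seq:
                    raise ParseError(f"empty sequence for record {rec.id!r} (record {n}) in {path}")
                yield ReadRecord(rec.id, seq, None)
        elif fmt == "fastq":
            n = 0
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    if not seq:
                        raise ParseError(
                            f"empty sequence (record {n + 1}, near line {4 * n + 1}) in {path}"
                        )
                    yield ReadRecord(title.split()[0], normalize_seq(seq), qual)
                    n += 1
            except ParseError:
                raise
            except ValueError as exc:  # Biopython's length/format complaints
                raise ParseError(
                    f"{exc} (record {n + 1}, near line {4 * n + 1}) in {path}"
                ) from exc
        else:
            raise ValueError(f"unknown format {fmt!r}")


# miRBase arm suffixes: -5p, -3p, -5p.1 style sub-arms, and the legacy star form.
_ARM_SUFFIX = re.compile(r"(-[35]p(\.\d+)?|\*)$")


def mature_stem(mature_id: str) -> str:
    """Hairpin name implied by a mature ID (arm suffix stripped, miR -> mir)."""
    return _ARM_SUFFIX.sub("", mature_id).replace("miR", "mir")


def load_reference(hairpin_path: str | Path, mature_path: str | Path) -> ReferenceSet:
    """Load a hairpin/mature FASTA pair and resolve mature->hairpin linkage.

    Linkage is by naming convention first (``hsa-miR-21-5p`` -> ``hsa-mir-21``),
    falling back to an exact-substring search of the mature sequence across all
    hairpins when the name resolves nothing; matures that still cannot be
    linked go to ``rejects`` rather than aborting the run.
    """
    hairpins: dict[str, str] = {}
    for rec in SeqIO.parse(str(hairpin_path), "fasta"):
        seq = normalize_seq(str(rec.seq))
        if not seq:
            raise ParseError(f"empty hairpin sequence {rec.id!r} in {hairpin_path}")
        if set(seq) - _VALID_REF:
            raise ParseError(f"hairpin {rec.id!r} has non-ACGT bases in {hairpin_path}")
        if rec.id in hairpins:
            raise ParseError(f"duplicate hairpin id {rec.id!r} in {hairpin_path}")
        hairpins[rec.id] = seq

    matures: dict[str, tuple[str, str]] = {}
    rejects: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(mature_path), "fasta"):
        seq = normalize_seq(str(rec.seq))
        if not seq:
            raise ParseError(f"empty mature sequence {rec.id!r} in {mature_path}")
        if set(seq) - _VALID_REF:
            raise ParseError(f"mature {rec.id!r} has non-ACGT bases in {mature_path}")
        stem = mature_stem(rec.id)
        if stem in hairpins:
            matures[rec.id] = (seq, stem)
            continue
        hits = [hid for hid, hseq in hairpins.items() if seq in hseq]
        if len(hits) == 1:
            matures[rec.id] = (seq, hits[0])
        elif not hits:
            rejects.append((rec.id, "no hairpin by name or sequence"))
        else:
            rejects.append((rec.id, f"ambiguous: {len(hits)} hairpins contain it"))
    return ReferenceSet(hairpins, matures, rejects)


def _fmt_cell(value) -> str:
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)  # shortest round-tripping representation
    return str(value)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled matrix as TSV with a '#'-prefixed header.

    Rows are sorted lexicographically so re-writing the same matrix is
    byte-identical.  MultiIndex rows become multiple leading key columns.
    """
    if matrix.index.has_duplicates:
        raise ValueError("duplicate row labels")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate column labels")
    matrix = matrix.sort_index()
    names = [n if n is not None else f"key{i}" for i, n in enumerate(matrix.index.names)]
    if len(names) == 1 and matrix.index.names[0] is None:
        names = ["id"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join([*names, *(str(c) for c in matrix.columns)]) + "\n")
        for idx, row in matrix.iterrows():
            key = list(idx) if isinstance(idx, tuple) else [idx]
            fh.write("\t".join(_fmt_cell(v) for v in [*key, *row]) + "\n")


def read_matrix(path: str | Path, index_cols: int = 1) -> pd.DataFrame:
    """Inverse of :func:`write_matrix` (``index_cols`` leading key columns)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.startswith("#"):
        raise ParseError(f"missing '#' header line in {path}")
    cols = header[1:].split("\t")
    df = pd.read_csv(path, sep="\t", skiprows=1, header=None, names=cols)
    if df.empty:
        df = pd.DataFrame(columns=cols)
    df = df.set_index(cols[:index_cols])
    if index_cols == 1:
        df.index.name = cols[0]
    return df


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")
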