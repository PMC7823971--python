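"""Case-preserving FASTA input/output for soft-masked assemblies.

Soft-masked assemblies (the Ensembl/NCBI convention) encode repeat
annotation in letter case: lowercase residues are repeat-masked, uppercase
residues are unmasked.  Everything downstream of this module depends on
that case information surviving the read, so sequences are never
normalised here.

Files may be plain FASTA or gzip-compressed; both yield identical record
streams.  Records are streamed one at a time — whole-assembly residency is
never required.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FormatError, InputError

PathLike = Union[str, Path]

_WRAP = 60  # output line width; cosmetic only, both databases wrap FASTA

# Residues that participate in GC%/rep% denominators.  Everything else
# (N, IUPAC ambiguity codes, gaps) is retained verbatim but classified
# as "other" downstream.
CANONICAL_BASES = frozenset("ACGTacgt")


@dataclass(frozen=True)
class MaskedSequenceRecord:
    """One FASTA record with letter case preserved exactly.

    Attributes
    ----------
    id:
        First whitespace-delimited token of the header line.
    description:
        Full header line (without the leading ``>``).
    residues:
        The sequence, case intact: lowercase = soft-masked repeat,
        uppercase = unmasked DNA.
    """

    id: str
    description: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def masked_base_count(self) -> int:
        """Number of lowercase (soft-masked) residues."""
        codes = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        return int(((codes >= ord("a")) & (codes <= ord("z"))).sum())


@dataclass(frozen=True)
class RecordFilter:
    """Pure predicate on (id, length); never touches residues.

    Assemblies routinely carry unplaced scaffolds alongside chromosomes;
    this filter is how callers restrict profiling to chromosome-scale
    records.
    """

    min_length: int = 0
    id_pattern: Optional[str] = None
    max_records: Optional[int] = None

    def matches(self, record_id: str, length: int) -> bool:
        if length < self.min_length:
            return False
        if self.id_pattern is not None and not re.search(self.id_pattern, record_id):
            return False
        return True


def _open_text(path: PathLike) -> IO[str]:
    """Open plain or gzip FASTA transparently, by magic bytes not suffix."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"input file does not exist: {p}")
    with open(p, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(p, "rb"), encoding="ascii")
    return open(p, "rt", encoding="ascii")


def _check_leading_content(path: PathLike) -> None:
    """Raise FormatError with a byte offset if residues precede any '>'."""
    offset = 0
    with _open_text(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped:
                offset += len(line)
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"not FASTA: content before first '>' header at byte offset "
                    f"{offset + line.index(stripped[0])} in {path}"
                )
            return
    # Empty file: zero records, not an error.


def read_assembly(
    path: PathLike, record_filter: Optional[RecordFilter] = None
) -> Iterator[MaskedSequenceRecord]:
    """Stream records from a (possibly gzipped) soft-masked FASTA file.

    Records are yielded in file order; only those passing ``record_filter``
    are emitted.  Line wrapping in the source is ignored (lines are
    concatenated) and letter case is preserved exactly.  An empty record
    body yields a record of length 0.
    """
    record_filter = record_filter or RecordFilter()
    _check_leading_content(path)
    emitted = 0
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            if (
                record_filter.max_records is not None
                and emitted >= record_filter.max_records
            ):
                break
            rec_id = title.split()[0] if title.split() else ""
            if not record_filter.matches(rec_id, len(seq)):
                continue
            emitted += 1
            yield MaskedSequenceRecord(id=rec_id, description=title, residues=seq)


def write_assembly(records: Iterable[MaskedSequenceRecord], path: PathLike) -> None:
    """Write records as FASTA, wrapped at 60 columns, case preserved.

    A ``.gz`` suffix selects gzip compression.
    """
    p = Path(path)
    opener = gzip.open if p.suffix == ".gz" else open
    with opener(p, "wt", encoding="ascii") as out:  # type: ignore[operator]
        for rec in records:
            header = rec.description if rec.description else rec.id
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), _WRAP):
                out.write(rec.residues[i : i + _WRAP] + "\n")


@dataclass(frozen=True)
class RecordSummary:
    id: str
    length: int
    masked_base_count: int


def assembly_summary(
    records: Iterable[MaskedSequenceRecord],
) -> list[RecordSummary]:
    """Per-record (id, length, masked base count) in input order."""
    return [
        RecordSummary(rec.id, rec.length, rec.masked_base_count())
        for rec in records
    ]
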