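"""Alignment I/O and the reference reading-frame coordinate system.

Every downstream report locates lesions in *reference coordinates*: 1-based
nucleotide positions where +1 is the adenine of the reference start codon
(ATG) of the gene's first exon. Alignment columns are an internal detail and
are never exposed in reports; :func:`map_to_reference` is the single place
where the column <-> reference-position translation happens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "SequenceRecord",
    "CodonAlignment",
    "RefMap",
    "FastaFormatError",
    "read_fasta",
    "parse_fasta",
    "write_fasta",
    "map_to_reference",
    "translate",
    "GENETIC_CODE",
    "STOP_CODONS",
]

# IUPAC nucleotide alphabet plus gap. 'N' and the two-/three-fold ambiguity
# codes are accepted on input; codons containing them never count as stops.
_AMBIGUITY = set("NRYSWKMBDHV")
_LEGAL = set("ACGT-") | _AMBIGUITY

_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA


class FastaFormatError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned (or unaligned) nucleotide sequence."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - _LEGAL
        if bad:
            raise ValueError(
                f"record {self.id!r} contains illegal symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def parse_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text into records (ids unique, sequences uppercased)."""
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(at_line: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(f"record {header!r} has no sequence", header_line)
        records.append(SequenceRecord(header, seq))
        header, chunks = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush(lineno)
            name = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
            if not name:
                raise FastaFormatError("header with no identifier", lineno)
            if name in seen:
                raise FastaFormatError(
                    f"duplicate id {name!r} (first seen at line {seen[name]})", lineno
                )
            seen[name] = lineno
            header, header_line = name, lineno
        else:
            if header is None:
                raise FastaFormatError("sequence data before any '>' header", lineno)
            chunk = line.upper()
            bad = set(chunk) - _LEGAL
            if bad:
                raise FastaFormatError(
                    f"illegal sequence symbols {sorted(bad)}", lineno
                )
            chunks.append(chunk)
    _flush(-1)
    return records


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file. Empty file -> empty list; gaps are preserved."""
    with open(path) as fh:
        return parse_fasta(fh.read())


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass
class CodonAlignment:
    """An aligned set of sequences anchored to a reference reading frame.

    ``ref_offset`` is the reference position (1-based) of the first alignment
    column; it must sit on a codon boundary (offset == 1 mod 3) so that the
    reference frame is defined for every column.
    """

    records: list[SequenceRecord]
    ref_id: str
    ref_offset: int = 1

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        if self.ref_id not in set(ids):
            raise KeyError(f"reference id {self.ref_id!r} not in alignment")
        if self.ref_offset < 1 or self.ref_offset % 3 != 1:
            raise ValueError(
                f"ref_offset must be 1-based and on a codon boundary "
                f"(offset % 3 == 1), got {self.ref_offset}"
            )
        self._index = {r.id: r for r in self.records}

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def species(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def reference(self) -> SequenceRecord:
        return self._index[self.ref_id]

    def get(self, species: str) -> SequenceRecord:
        try:
            return self._index[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in alignment") from None


class RefMap:
    """Bidirectional map between alignment columns and reference positions.

    Columns where the reference has a base map to that base's 1-based
    reference position. Insertion columns (gap in the reference) map to the
    flanking reference pair ``(p, p + 1)``. The map is strictly monotone over
    non-gap reference columns.
    """

    def __init__(self, aln: CodonAlignment):
        ref = aln.reference.seq
        offset = aln.ref_offset
        col2ref: list[int | tuple[int, int]] = []
        ref2col: dict[int, int] = {}
        pos = offset - 1  # last assigned reference position
        for col, base in enumerate(ref, start=1):
            if base == "-":
                col2ref.append((pos, pos + 1))
            else:
                pos += 1
                col2ref.append(pos)
                ref2col[pos] = col
        self._col2ref = col2ref
        self._ref2col = ref2col
        self.first = offset
        self.last = pos

    def ref_position(self, column: int):
        """Reference position (or flanking pair) for a 1-based column."""
        return self._col2ref[column - 1]

    def column(self, position: int) -> int:
        """1-based alignment column holding reference ``position``."""
        try:
            return self._ref2col[position]
        except KeyError:
            raise KeyError(f"reference position {position} not in alignment") from None

    def __len__(self) -> int:
        return len(self._col2ref)


def map_to_reference(aln: CodonAlignment) -> RefMap:
    return RefMap(aln)


def dedupe_identical(records, crop: tuple[int, int] | None = None):
    """Optional pre-filter: drop records identical to an earlier one.

    ``crop`` restricts the comparison (and the retained sequences) to the
    1-based inclusive column window, mirroring the common practice of
    cropping ragged alignment ends before a substitution-rate analysis and
    excluding sequences that become identical afterwards. Returns
    (kept_records, dropped_ids).
    """
    import logging

    seen: dict[str, str] = {}
    kept, dropped = [], []
    for rec in records:
        seq = rec.seq if crop is None else rec.seq[crop[0] - 1 : crop[1]]
        if seq in seen:
            dropped.append(rec.id)
            logging.getLogger(__name__).info(
                "dropping %r: identical to %r after cropping",
                rec.id, seen[seq])
            continue
        seen[seq] = rec.id
        kept.append(rec if crop is None else SequenceRecord(rec.id, seq))
    return kept, dropped


def translate(seq: str, remove_gaps: bool = True) -> str:
    """Translate an in-frame nucleotide string under the standard code.

    Stop codons render as ``*``; codons containing N or any IUPAC ambiguity
    code render as ``X`` and never count as stops. Gap characters are removed
    first (set ``remove_gaps=False`` to forbid them instead).
    """
    s = seq.upper()
    if remove_gaps:
        s = s.replace("-", "")
    elif "-" in s:
        raise ValueError("gap characters present and remove_gaps=False")
    if len(s) % 3 != 0:
        raise ValueError(f"sequence length {len(s)} not divisible by 3")
    out = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if set(codon) & _AMBIGUITY:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(GENETIC_CODE[codon])
    return "".join(out)
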