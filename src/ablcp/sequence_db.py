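"""Concatenated sentinel-separated text model of a protein FASTA database.

All downstream structures (suffix array, LCP, cleavage index, prefix masses)
are built over a single string ``T`` obtained by joining every protein
sequence with one ``'$'`` sentinel appended to each, so ``T`` always ends in
``'$'`` and contains exactly one sentinel per protein.  Coordinates are
0-based, half-open throughout.
"""

from __future__ import annotations

import hashlib
import struct
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

SENTINEL = "$"

#: Residues with no defined monoisotopic mass; retained in the text under the
#: ``mask`` policy but never emitted inside a peptide.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_MAGIC_DB = b"ABLCPDB1"
_DB_VERSION = 1


class FastaParseError(ValueError):
    """Malformed FASTA input (bad residues, empty sequence, no header)."""


class CacheFormatError(ValueError):
    """Binary database cache has a wrong magic/version or is truncated."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry and where its residues live in the joined text."""

    accession: str
    description: str
    sequence: str
    start_offset: int

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end_offset(self) -> int:
        """Position of this protein's sentinel in the concatenated text."""
        return self.start_offset + len(self.sequence)


@dataclass(frozen=True)
class ConcatenatedDatabase:
    """All proteins joined into one sentinel-terminated text ``T``."""

    text: str
    proteins: tuple[ProteinRecord, ...]
    alphabet: frozenset[str] = field(default=frozenset())

    @property
    def n(self) -> int:
        return len(self.text)

    def text_digest(self) -> bytes:
        """16-byte digest of ``T``, used to detect stale index files."""
        return hashlib.md5(self.text.encode("ascii")).digest()

    def protein_at(self, position: int) -> ProteinRecord:
        """Protein whose residue span contains ``position``.

        Raises ``ValueError`` for out-of-range or sentinel positions.
        """
        if not 0 <= position < self.n:
            raise ValueError(f"position {position} outside text of length {self.n}")
        if self.text[position] == SENTINEL:
            raise ValueError(f"position {position} is a sentinel, not a residue")
        starts = [p.start_offset for p in self.proteins]
        k = bisect_right(starts, position) - 1
        return self.proteins[k]


def _build(records: list[tuple[str, str, str]]) -> ConcatenatedDatabase:
    parts: list[str] = []
    proteins: list[ProteinRecord] = []
    offset = 0
    for accession, description, seq in records:
        proteins.append(ProteinRecord(accession, description, seq, offset))
        parts.append(seq)
        parts.append(SENTINEL)
        offset += len(seq) + 1
    text = "".join(parts)
    return ConcatenatedDatabase(
        text=text,
        proteins=tuple(proteins),
        alphabet=frozenset(text) - {SENTINEL},
    )


def from_sequences(
    entries: list[tuple[str, str]] | dict[str, str],
    residue_policy: str = "mask",
) -> ConcatenatedDatabase:
    """Build a database from in-memory ``(accession, sequence)`` pairs."""
    if isinstance(entries, dict):
        entries = list(entries.items())
    records = []
    for accession, seq in entries:
        records.append((accession, accession, _clean_sequence(seq, accession, residue_policy)))
    return _build(records)


def _clean_sequence(raw: str, accession: str, residue_policy: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise FastaParseError(f"entry {accession!r} has an empty sequence")
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        if residue_policy == "strict" or not bad.issubset(NONSTANDARD_RESIDUES):
            raise FastaParseError(
                f"entry {accession!r} contains non-standard residues {sorted(bad)}"
            )
    return seq


def load_fasta(path: str | Path, residue_policy: str = "mask") -> ConcatenatedDatabase:
    """Parse a FASTA protein database into the concatenated text model.

    Parameters
    ----------
    path:
        FASTA file; multi-line sequences allowed, accession is the first
        whitespace-delimited header token.
    residue_policy:
        ``"mask"`` (default) keeps the ambiguity codes B/J/O/U/X/Z in the
        text (peptides containing them are dropped at emission time);
        ``"strict"`` rejects any residue outside the 20 standard letters.
    """
    if residue_policy not in ("strict", "mask"):
        raise ValueError(f"unknown residue policy {residue_policy!r}")
    path = Path(path)
    records = []
    with path.open() as handle:
        first = handle.read(1)
        if first != ">":
            raise FastaParseError(f"{path}: line 1: expected '>' header, got {first!r}")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            accession = rec.id
            if not accession:
                raise FastaParseError(f"{path}: record with empty header")
            seq = _clean_sequence(str(rec.seq), accession, residue_policy)
            records.append((accession, rec.description, seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return _build(records)


def write_binary(db: ConcatenatedDatabase, path: str | Path) -> None:
    """Persist the database in the fixed little-endian block-read cache."""
    path = Path(path)
    with path.open("wb") as fh:
        fh.write(_MAGIC_DB)
        fh.write(struct.pack("<B", _DB_VERSION))
        fh.write(struct.pack("<Q", db.n))
        fh.write(db.text.encode("ascii"))
        fh.write(struct.pack("<Q", len(db.proteins)))
        for p in db.proteins:
            acc = p.accession.encode("utf-8")
            desc = p.description.encode("utf-8")
            fh.write(struct.pack("<QII", p.start_offset, len(acc), len(desc)))
            fh.write(acc)
            fh.write(desc)


def load_binary(path: str | Path) -> ConcatenatedDatabase:
    """Load a cache written by :func:`write_binary`; verifies magic/version."""
    path = Path(path)
    data = path.read_bytes()

    def take(fmt: str, off: int):
        size = struct.calcsize(fmt)
        if off + size > len(data):
            raise CacheFormatError(f"{path}: truncated database cache")
        return struct.unpack_from(fmt, data, off), off + size

    if data[:8] != _MAGIC_DB:
        raise CacheFormatError(f"{path}: not an ABLCP database cache (bad magic)")
    (version,), off = take("<B", 8)
    if version != _DB_VERSION:
        raise CacheFormatError(f"{path}: unsupported cache version {version}")
    (n,), off = take("<Q", off)
    if off + n > len(data):
        raise CacheFormatError(f"{path}: truncated database cache")
    text = data[off : off + n].decode("ascii")
    off += n
    (n_prot,), off = take("<Q", off)
    proteins = []
    for _ in range(n_prot):
        (start, la, ld), off = take("<QII", off)
        if off + la + ld > len(data):
            raise CacheFormatError(f"{path}: truncated database cache")
        acc = data[off : off + la].decode("utf-8")
        off += la
        desc = data[off : off + ld].decode("utf-8")
        off += ld
        seq_end = text.index(SENTINEL, start)
        proteins.append(ProteinRecord(acc, desc, text[start:seq_end], start))
    db = ConcatenatedDatabase(
        text=text, proteins=tuple(proteins), alphabet=frozenset(text) - {SENTINEL}
    )
    if db.n != n:
        raise CacheFormatError(f"{path}: inconsistent length field")
    return db


def protein_at(db: ConcatenatedDatabase, position: int) -> ProteinRecord:
    """Module-level alias of :meth:`ConcatenatedDatabase.protein_at`."""
    return db.protein_at(position)
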