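"""Suffix array, rank and position-indexed LCP over the concatenated text.

The suffix array is built by prefix doubling on numpy arrays (O(n log n),
alphabet-independent); the LCP is induced from it with Kasai's linear-time
algorithm.  Unusually for the literature — but deliberately, because every
digestion walk here iterates in *text* order — the LCP array is indexed by
text position: ``lcp[i]`` is the length of the longest common prefix of
``Suffix[i]`` and its rank-predecessor, with the rank-0 suffix assigned 0.

The LCP is the only structure persisted between the preprocessing and
digestion stages: one byte per text position (values clamped at a cap that
must be at least the maximum peptide length), plus a header binding the file
to a digest of the database text and to the enzyme it was adjusted for.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .sequence_db import SENTINEL, ConcatenatedDatabase

_MAGIC_LCP = b"ABLCPLX1"
_LCP_VERSION = 1


class IndexIntegrityError(ValueError):
    """sa/rank/lcp arrays are mutually inconsistent or malformed."""


class StaleIndexError(ValueError):
    """A persisted LCP file does not match the current database text."""


@dataclass(frozen=True)
class SuffixArrayIndex:
    """Suffix array ``sa`` (rank -> position), its inverse ``rank``, and the
    position-indexed ``lcp``.  ``enzyme_id`` is empty for an unadjusted LCP
    and carries the enzyme name after site-specific adjustment."""

    sa: np.ndarray
    rank: np.ndarray
    lcp: np.ndarray
    enzyme_id: str = ""

    @property
    def n(self) -> int:
        return len(self.sa)

    def with_lcp(self, lcp: np.ndarray, enzyme_id: str) -> "SuffixArrayIndex":
        return replace(self, lcp=lcp, enzyme_id=enzyme_id)


def naive_lcp(y: str, z: str) -> int:
    """Length of the longest common prefix of two strings (definitional)."""
    k = 0
    for a, b in zip(y, z):
        if a != b:
            break
        k += 1
    return k


def build_suffix_array(text: str) -> np.ndarray:
    """Suffix array of ``text`` by prefix doubling.

    The text must be non-empty and end with the sentinel; the sentinel's
    ASCII code is below every residue letter, so plain byte order realises
    the required collation.
    """
    if not text:
        raise ValueError("cannot build a suffix array over an empty text")
    if not text.endswith(SENTINEL):
        raise ValueError("text must end with the sentinel character")
    data = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    n = len(data)
    rank = np.unique(data, return_inverse=True)[1].astype(np.int64)
    order = np.argsort(rank, kind="stable")
    k = 1
    while rank[order[-1]] != n - 1:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        k *= 2
    return order


def build_rank(sa: np.ndarray) -> np.ndarray:
    """Inverse permutation of the suffix array: ``rank[sa[j]] = j``."""
    sa = np.asarray(sa)
    n = len(sa)
    rank = np.full(n, -1, dtype=np.int64)
    if n and (sa.min() < 0 or sa.max() >= n):
        raise IndexIntegrityError("suffix array entries out of range")
    rank[sa] = np.arange(n)
    if (rank < 0).any():
        raise IndexIntegrityError("suffix array is not a permutation")
    return rank


def build_lcp_kasai(text: str, sa: np.ndarray, rank: np.ndarray) -> np.ndarray:
    """Kasai induction of the position-indexed LCP array.

    Exploits lcp(Suffix[i+1], pred) >= lcp(Suffix[i], pred) - 1 so the total
    number of character comparisons is O(n).
    """
    n = len(text)
    if len(sa) != n or len(rank) != n or (rank[sa] != np.arange(n)).any():
        raise IndexIntegrityError("sa/rank inconsistent with the text")
    tb = text.encode("ascii")
    sa_l = sa.tolist()
    rank_l = rank.tolist()
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = rank_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and tb[i + h] == tb[j + h]:
                h += 1
            lcp[i] = h
            if h:
                h -= 1
        else:
            lcp[i] = 0
            h = 0
    return np.asarray(lcp, dtype=np.int64)


def build_index(db: ConcatenatedDatabase) -> SuffixArrayIndex:
    """SA + rank + unadjusted Kasai LCP for a database in one call."""
    sa = build_suffix_array(db.text)
    rank = build_rank(sa)
    lcp = build_lcp_kasai(db.text, sa, rank)
    return SuffixArrayIndex(sa=sa, rank=rank, lcp=lcp)


def save_lcp(
    lcp: np.ndarray,
    cap: int,
    path: str | Path,
    *,
    db_digest: bytes,
    enzyme_id: str = "",
    max_peptide_length: int | None = None,
) -> None:
    """Store the LCP one byte per entry, clamped at ``cap``.

    ``cap`` must be at least the maximum peptide length ever digested with
    this file; clamping is then invisible downstream because generation never
    extends past that length anyway.
    """
    if not 0 < cap <= 255:
        raise ValueError(f"cap must be in [1, 255], got {cap}")
    if max_peptide_length is not None and cap < max_peptide_length:
        raise ValueError(
            f"LCP cap {cap} is below the maximum peptide length {max_peptide_length}"
        )
    if len(db_digest) != 16:
        raise ValueError("db_digest must be a 16-byte text digest")
    enz = enzyme_id.encode("utf-8")
    clamped = np.minimum(np.asarray(lcp, dtype=np.int64), cap).astype(np.uint8)
    with Path(path).open("wb") as fh:
        fh.write(_MAGIC_LCP)
        fh.write(struct.pack("<BB", _LCP_VERSION, cap))
        fh.write(struct.pack("<H", len(enz)))
        fh.write(enz)
        fh.write(db_digest)
        fh.write(struct.pack("<Q", len(clamped)))
        fh.write(clamped.tobytes())


def load_lcp(path: str | Path, *, db_digest: bytes) -> tuple[np.ndarray, int, str]:
    """Load a persisted LCP; returns ``(lcp, cap, enzyme_id)``.

    Raises :class:`StaleIndexError` when the stored digest does not match
    the digest of the database the caller is about to digest.
    """
    data = Path(path).read_bytes()
    if data[:8] != _MAGIC_LCP:
        raise StaleIndexError(f"{path}: not an ABLCP LCP file (bad magic)")
    version, cap = struct.unpack_from("<BB", data, 8)
    if version != _LCP_VERSION:
        raise StaleIndexError(f"{path}: unsupported LCP file version {version}")
    (enz_len,) = struct.unpack_from("<H", data, 10)
    off = 12
    enzyme_id = data[off : off + enz_len].decode("utf-8")
    off += enz_len
    stored_digest = data[off : off + 16]
    off += 16
    if stored_digest != db_digest:
        raise StaleIndexError(
            f"{path}: LCP file was built for a different database text"
        )
    (n,) = struct.unpack_from("<Q", data, off)
    off += 8
    if off + n > len(data):
        raise StaleIndexError(f"{path}: truncated LCP file")
    lcp = np.frombuffer(data[off : off + n], dtype=np.uint8).astype(np.int64)
    return lcp, cap, enzyme_id
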