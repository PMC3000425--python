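"""Brute-force reference digestion, redundancy statistics, synthetic data.

``naive_digest`` is the peptide-index-style workflow: enumerate every
substring occurrence protein by protein, apply the terminal, missed-cleavage,
length and mass rules directly, then sort and deduplicate.  It deliberately
shares no code with the suffix-array generators — no suffix array, no LCP,
per-occurrence rescanning of cleavage context — so that set equality between
the two routes is a meaningful correctness check rather than a tautology.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .digest import RESIDUE_MASS, WATER_MASS, DigestParams
from .enzyme import EnzymeRule
from .sequence_db import ConcatenatedDatabase
from .suffix_lcp import SuffixArrayIndex, naive_lcp

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class RedundancyReport:
    """Occurrence vs distinct-string counts for one digestion setting."""

    redundant_count: int
    nonredundant_count: int

    @property
    def redundancy_ratio(self) -> float:
        """Percentage of peptide occurrences that are duplicates."""
        if self.redundant_count == 0:
            return 0.0
        return (1.0 - self.nonredundant_count / self.redundant_count) * 100.0


def _cleaves(seq: str, b: int, enzyme: EnzymeRule) -> bool:
    """Does the enzyme cut between seq[b-1] and seq[b] (b == len: C-term)?"""
    if b <= 0:
        return False
    if enzyme.terminal_side == "C":
        if seq[b - 1] not in enzyme.cleavage_residues:
            return False
        return b == len(seq) or seq[b] not in enzyme.blocked_next_residues
    return b < len(seq) and seq[b] in enzyme.cleavage_residues


def _occurrences(db, enzyme, params):
    """Yield every qualifying substring occurrence directly from proteins.

    Per start position the end is extended one residue at a time with a
    running mass and missed-cleavage count; both are monotone in the end
    position, so the mass ceiling and cleavage cap stop the extension early.
    """
    spec = params.specificity
    if spec != "none" and enzyme is None:
        raise ValueError("site-specific digestion requires an enzyme")
    for prot in db.proteins:
        seq = prot.sequence
        ln = len(seq)
        for i in range(ln):
            nterm_ok = spec == "none" or i == 0 or _cleaves(seq, i, enzyme)
            if spec == "full" and not nterm_ok:
                continue
            mass = WATER_MASS
            mc = 0
            for j in range(i + 1, min(i + params.max_length, ln) + 1):
                m = RESIDUE_MASS.get(seq[j - 1])
                if m is None:
                    break  # every longer span contains the unmassed residue
                mass += m
                if spec != "none":
                    if j - 1 > i and _cleaves(seq, j - 1, enzyme):
                        mc += 1
                    if mc > params.max_missed_cleavages:
                        break
                if mass > params.max_mass:
                    break
                if j - i < params.min_length or mass < params.min_mass:
                    continue
                if spec != "none":
                    cterm_ok = _cleaves(seq, j, enzyme) or (
                        j == ln and params.allow_protein_cterm
                    )
                    if spec == "full" and not cterm_ok:
                        continue
                    if spec == "semi" and not (nterm_ok or cterm_ok):
                        continue
                yield seq[i:j]


def naive_digest(
    db: ConcatenatedDatabase,
    enzyme: EnzymeRule | None,
    params: DigestParams,
) -> list[str]:
    """Sorted, deduplicated peptide strings by direct enumeration."""
    return sorted(set(_occurrences(db, enzyme, params)))


def redundancy_stats(
    db: ConcatenatedDatabase,
    enzyme: EnzymeRule | None,
    params: DigestParams,
) -> RedundancyReport:
    """Occurrence and distinct-string counts; every occurrence is counted,
    including repeats within a single protein."""
    total = 0
    distinct = set()
    for pep in _occurrences(db, enzyme, params):
        total += 1
        distinct.add(pep)
    return RedundancyReport(redundant_count=total, nonredundant_count=len(distinct))


def adjust_lcp_bruteforce(
    text: str, idx: SuffixArrayIndex, is_ss: np.ndarray
) -> np.ndarray:
    """Definition-based SS adjustment: for each SS suffix, the character-by-
    character LCP against the nearest rank-preceding SS suffix (0 if none).
    Quadratic; used as the oracle for the linear rank sweep."""
    adjusted = idx.lcp.copy()
    prev_ss = None
    for r in range(len(text)):
        p = int(idx.sa[r])
        if is_ss[p]:
            if prev_ss is None:
                adjusted[p] = 0
            else:
                adjusted[p] = naive_lcp(text[p:], text[prev_ss:])
            prev_ss = p
    return adjusted


def generate_synthetic_fasta(
    path: str | Path,
    n_proteins: int,
    length_distribution,
    duplication_fraction: float = 0.0,
    seed: int = 0,
) -> Path:
    """Write a reproducible synthetic protein FASTA.

    Sequences are drawn i.i.d. uniform over the 20 standard residues.
    ``length_distribution`` may be an int (fixed length), a ``(lo, hi)``
    tuple (uniform inclusive), or a callable taking the numpy Generator.
    ``round(n_proteins * duplication_fraction)`` entries, scattered after
    the first, are exact copies of randomly chosen earlier entries.
    """
    if not 0 <= duplication_fraction < 1:
        raise ValueError("duplication_fraction must be in [0, 1)")
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)

    if callable(length_distribution):
        draw_len = lambda: int(length_distribution(rng))
    elif isinstance(length_distribution, tuple):
        lo, hi = length_distribution
        draw_len = lambda: int(rng.integers(lo, hi + 1))
    else:
        fixed = int(length_distribution)
        draw_len = lambda: fixed

    n_dup = round(n_proteins * duplication_fraction)
    dup_slots = set()
    if n_dup:
        dup_slots = set(
            rng.choice(np.arange(1, n_proteins), size=n_dup, replace=False).tolist()
        )
    alphabet = np.frombuffer(_AA20.encode("ascii"), dtype=np.uint8)
    sequences: list[str] = []
    path = Path(path)
    with path.open("w") as fh:
        for k in range(n_proteins):
            if k in dup_slots:
                src = int(rng.integers(0, k))
                seq = sequences[src]
                desc = f"SYN{k:06d} duplicate_of=SYN{src:06d}"
            else:
                seq = bytes(rng.choice(alphabet, size=draw_len())).decode("ascii")
                desc = f"SYN{k:06d} synthetic random protein"
            sequences.append(seq)
            fh.write(f">{desc}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)))
            fh.write("\n")
    return path
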