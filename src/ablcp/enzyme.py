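"""Enzymatic cleavage rules, specific-suffix membership and LCP adjustment.

A peptide produced by a site-specific digest must start right after a
cleavage boundary (or at a protein N-terminus) and end on one (or at the
protein C-terminus).  A *specific suffix* (SS) is a suffix of the
concatenated text whose start position is a legal peptide N-terminus; only
SS suffixes can generate full-specific peptides.

Because the plain LCP relates each suffix to its rank-predecessor over *all*
suffixes, using it directly during a site-specific walk omits peptides whose
first occurrence sits in a non-SS suffix.  The fix is to re-point every SS
suffix at its nearest preceding SS suffix in rank order.  The LCP of two
arbitrary-rank suffixes is the minimum of the adjacent-pair LCPs between
them, so a single rank-order sweep carrying a running minimum since the last
SS suffix computes the adjusted array in O(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_db import SENTINEL, ConcatenatedDatabase
from .suffix_lcp import SuffixArrayIndex


@dataclass(frozen=True)
class EnzymeRule:
    """A single-residue cleavage rule.

    ``terminal_side == "C"`` cleaves after a residue in ``cleavage_residues``
    (trypsin-like); ``"N"`` cleaves before one.  ``blocked_next_residues``
    suppresses a C-side cleavage when the *following* residue is in the set
    (the classic case being trypsin/P, where K/R followed by proline does
    not cut).
    """

    name: str
    cleavage_residues: frozenset[str]
    terminal_side: str = "C"
    blocked_next_residues: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.cleavage_residues:
            raise ValueError("cleavage_residues must be non-empty")
        if SENTINEL in self.cleavage_residues:
            raise ValueError("the sentinel cannot be a cleavage residue")
        if self.terminal_side not in ("C", "N"):
            raise ValueError(f"terminal_side must be 'C' or 'N', got {self.terminal_side!r}")
        if self.terminal_side == "N" and self.blocked_next_residues:
            raise NotImplementedError(
                "blocked-context rules are only supported for C-terminal enzymes"
            )

    @property
    def context_free(self) -> bool:
        return not self.blocked_next_residues


def _rule(name, residues, side="C", blocked=()):
    return EnzymeRule(name, frozenset(residues), side, frozenset(blocked))


#: Built-in enzyme registry; keys are the names accepted by the CLI.
ENZYMES: dict[str, EnzymeRule] = {
    "trypsin": _rule("trypsin", "KR"),
    "trypsin/p": _rule("trypsin/p", "KR", blocked="P"),
    "lys-c": _rule("lys-c", "K"),
    "glu-c": _rule("glu-c", "E"),
    "asp-n": _rule("asp-n", "D", side="N"),
}


def get_enzyme(name: str) -> EnzymeRule:
    try:
        return ENZYMES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; known: {sorted(ENZYMES)}") from None


@dataclass(frozen=True)
class CleavageIndex:
    """Per-position cleavage structures for one (database, enzyme) pair.

    ``is_ss[i]``
        position ``i`` starts a residue and is a legal peptide N-terminus.
    ``site_prefix_count[i]``
        number of cleaving boundaries at positions <= ``i`` within the same
        protein (resets at protein starts) — the paper-style prefix count
        that makes missed-cleavage lookups O(1).
    ``boundary_cleaving[j]``
        the boundary between ``T[j-1]`` and ``T[j]`` is a cleaving boundary;
        defined for ``j`` in ``[0, n]`` with ``boundary_cleaving[0] = False``
        and protein-end boundaries (``T[j]`` a sentinel / ``j == n``)
        included for C-side enzymes.
    """

    enzyme: EnzymeRule
    is_ss: np.ndarray
    site_prefix_count: np.ndarray
    boundary_cleaving: np.ndarray
    _cut_cumsum: np.ndarray = field(repr=False, default=None)

    def interior_missed_cleavages(self, i: int, j: int) -> int:
        """Cleaving boundaries strictly inside the occupance ``T[i, j)``."""
        return int(self._cut_cumsum[j - 1] - self._cut_cumsum[i])


def build_cleavage_index(db: ConcatenatedDatabase, enzyme: EnzymeRule) -> CleavageIndex:
    text = db.text
    n = len(text)
    arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    is_res = arr != ord(SENTINEL)

    def member(chars: frozenset[str]) -> np.ndarray:
        mask = np.zeros(256, dtype=bool)
        for c in chars:
            mask[ord(c)] = True
        return mask[arr]

    in_cleave = member(enzyme.cleavage_residues)
    in_blocked = member(enzyme.blocked_next_residues)

    # boundary_cleaving[j]: boundary between T[j-1] and T[j] cuts; j in [0, n].
    bc = np.zeros(n + 1, dtype=bool)
    if enzyme.terminal_side == "C":
        bc[1:n] = in_cleave[:-1] & ~(is_res[1:] & in_blocked[1:])
        bc[n] = in_cleave[n - 1]
    else:
        bc[1:n] = in_cleave[1:]
    # interior cut: both flanking characters are residues
    cut = np.zeros(n, dtype=bool)
    cut[1:] = bc[1:n] & is_res[:-1] & is_res[1:]
    cut_cumsum = np.cumsum(cut)

    # protein-start positions: 0 or right after a sentinel
    prot_start = np.zeros(n, dtype=bool)
    prot_start[0] = True
    prot_start[1:] = arr[:-1] == ord(SENTINEL)
    prot_start &= is_res  # an empty tail cannot happen (text ends in '$')

    is_ss = np.zeros(n, dtype=bool)
    is_ss[cut] = True
    is_ss |= prot_start
    is_ss &= is_res

    # per-protein prefix counts: subtract the cumulative count at each
    # protein start (interior cuts never cross sentinels, so a global cumsum
    # re-based per protein is exact)
    base_at_start = np.where(prot_start, cut_cumsum - cut.astype(np.int64), 0)
    fill = np.maximum.accumulate(np.where(prot_start, base_at_start, -1))
    fill = np.maximum(fill, 0)
    site_prefix_count = cut_cumsum - fill

    return CleavageIndex(
        enzyme=enzyme,
        is_ss=is_ss,
        site_prefix_count=site_prefix_count,
        boundary_cleaving=bc,
        _cut_cumsum=cut_cumsum,
    )


def adjust_lcp_specific(idx: SuffixArrayIndex, cleav: CleavageIndex) -> np.ndarray:
    """Re-point each SS suffix's LCP at its rank-preceding SS suffix.

    One sweep in rank order keeps the running minimum of adjacent-pair LCP
    values since the last SS suffix; by the min-composition property of the
    LCP that running minimum *is* the LCP against that SS suffix.  Entries at
    non-SS positions are copied through untouched (they are never read by
    the site-specific generators).
    """
    sa = idx.sa
    lcp = idx.lcp
    is_ss = cleav.is_ss
    adjusted = lcp.copy()
    run_min = 0
    seen_ss = False
    INF = np.iinfo(np.int64).max
    run_min = INF
    sa_l = sa.tolist()
    lcp_l = lcp.tolist()
    for r in range(len(sa_l)):
        p = sa_l[r]
        if r > 0:
            v = lcp_l[p]
            if v < run_min:
                run_min = v
        if is_ss[p]:
            adjusted[p] = run_min if seen_ss else 0
            seen_ss = True
            run_min = INF
    return adjusted


def adjust_lcp_for_enzyme(
    idx: SuffixArrayIndex, cleav: CleavageIndex, enzyme: EnzymeRule
) -> SuffixArrayIndex:
    """Enzyme-aware LCP adjustment; returns a new index flagged with the
    enzyme's name.

    For context-free rules this is exactly the SS adjustment.  For blocked
    rules (trypsin/P) the same adjustment is applied over the blocked-aware
    SS set; the residue *after* an occurrence can still invalidate its
    C-terminal boundary, which the generators handle with an emission-time
    rank scan, so the adjustment itself never needs to grow.
    """
    if cleav.enzyme != enzyme:
        raise ValueError("cleavage index was built for a different enzyme")
    adjusted = adjust_lcp_specific(idx, cleav)
    return idx.with_lcp(adjusted, enzyme.name)
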