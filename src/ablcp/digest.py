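"""Online non-redundant candidate peptide generation.

Three digestion modes stream candidates directly off the concatenated text,
its (possibly enzyme-adjusted) position-indexed LCP, and the cleavage index:

* non-specific — every suffix emits its prefixes of length LCP+1 and up, so
  each distinct substring is produced exactly once, at its rank-first
  occurrence;
* full-specific — the same walk restricted to specific suffixes (SS) with
  the SS-adjusted LCP, keeping only candidates whose C-terminal boundary is
  a cleavage boundary (or a protein end);
* semi-specific — the union of two disjoint parts: the non-specific walk
  keeping only cleavage-ending candidates, and the SS walk keeping only
  non-cleavage-ending ones.

Masses are integer monoisotopic daltons scaled by 1e4, taken in O(1) from a
per-protein running prefix sum; missed cleavages come from the cleavage-site
prefix counts, so the count is a property of the occurrence rather than of
the order the loop happened to visit boundaries in.

For context-dependent rules (trypsin/P) a candidate string can be a valid
peptide at one occurrence and not at another, because the residue *after*
the occurrence decides whether its C-terminal boundary cuts.  When the
generating occurrence is invalidated by a following proline, a short scan
forward through the rank-adjacent suffixes still sharing the candidate as a
prefix looks for a valid occurrence, so a string is emitted iff *some*
occurrence of it is a legal peptide — and still only once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from pyteomics import mass as _pmass

from .enzyme import CleavageIndex, EnzymeRule
from .sequence_db import SENTINEL, STANDARD_RESIDUES, ConcatenatedDatabase
from .suffix_lcp import SuffixArrayIndex

MASS_SCALE = 10_000
WATER_MASS = int(_pmass.calculate_mass(formula="H2O") * MASS_SCALE + 0.5)

#: Integer-scaled monoisotopic residue masses for the 20 standard residues.
RESIDUE_MASS: dict[str, int] = {
    aa: int(_pmass.std_aa_mass[aa] * MASS_SCALE + 0.5) for aa in sorted(STANDARD_RESIDUES)
}

_HUGE_MASS = 10**12


class DigestMisuseError(ValueError):
    """A generator was handed an LCP adjusted for the wrong purpose."""


@dataclass(frozen=True)
class DigestParams:
    """Filter settings shared by all digestion modes.

    Lengths are residue counts; masses are integer-scaled daltons (Da x 1e4).
    Defaults follow common search practice: 6-60 residues, up to two missed
    cleavage sites.
    """

    specificity: str = "full"
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 60
    min_mass: int = 0
    max_mass: int = _HUGE_MASS
    allow_protein_cterm: bool = True

    def __post_init__(self):
        if self.specificity not in ("none", "full", "semi"):
            raise ValueError(f"unknown specificity {self.specificity!r}")
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.min_mass > self.max_mass or self.min_mass < 0:
            raise ValueError("need 0 <= min_mass <= max_mass")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class Peptide:
    """One emitted candidate; ``first_position`` is the text offset of the
    occurrence that generated (or rescued) it."""

    sequence: str
    mass: int
    missed_cleavages: int
    first_position: int
    nterm_specific: bool = False
    cterm_specific: bool = False

    @property
    def mass_da(self) -> float:
        return self.mass / MASS_SCALE


@dataclass(frozen=True)
class MassModel:
    """Prefix-sum mass structure over the concatenated text.

    ``prefix_mass[i]`` is the summed residue mass of ``T[0, i)`` (sentinels
    and unmassed residues contribute 0, but any span containing them is
    rejected), so a peptide mass is two lookups and an addition of the mass
    of water.
    """

    residue_mass: dict[str, int]
    water_mass: int
    prefix_mass: np.ndarray
    next_unmassed: np.ndarray = field(repr=False, default=None)
    next_sentinel: np.ndarray = field(repr=False, default=None)

    def span_mass(self, i: int, j: int) -> int:
        return int(self.prefix_mass[j] - self.prefix_mass[i]) + self.water_mass


def build_mass_model(db: ConcatenatedDatabase) -> MassModel:
    text = db.text
    n = len(text)
    per_char = np.zeros(n, dtype=np.int64)
    unmassed = np.zeros(n, dtype=bool)
    sentinel = np.zeros(n, dtype=bool)
    for k, c in enumerate(text):
        if c == SENTINEL:
            sentinel[k] = True
        else:
            m = RESIDUE_MASS.get(c)
            if m is None:
                unmassed[k] = True
            else:
                per_char[k] = m
    prefix = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(per_char, out=prefix[1:])

    def next_of(mask: np.ndarray) -> np.ndarray:
        nxt = np.full(n, n, dtype=np.int64)
        last = n
        for k in range(n - 1, -1, -1):
            if mask[k]:
                last = k
            nxt[k] = last
        return nxt

    return MassModel(
        residue_mass=dict(RESIDUE_MASS),
        water_mass=WATER_MASS,
        prefix_mass=prefix,
        next_unmassed=next_of(unmassed),
        next_sentinel=next_of(sentinel),
    )


def compute_mass(mass: MassModel, i: int, j: int) -> int:
    """Integer-scaled monoisotopic mass of ``T[i, j)`` plus water."""
    if i > j:
        raise ValueError("need i <= j")
    if i < j:
        if mass.next_sentinel[i] < j:
            raise ValueError(f"span [{i}, {j}) crosses a protein boundary")
        if mass.next_unmassed[i] < j:
            raise ValueError(f"span [{i}, {j}) contains a residue without a defined mass")
    return mass.span_mass(i, j)


def candidates_in_mass_window(
    peptides, center: int, tol: float, *, ppm: bool = False
) -> Iterator[Peptide]:
    """Pass through peptides with ``|mass - center| <= half_width``.

    ``tol`` is the half-width in integer mass units, or in ppm of ``center``
    when ``ppm=True`` (converted with outward rounding so borderline
    candidates are kept).
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    half = int(math.ceil(center * tol / 1e6)) if ppm else int(tol)
    for pep in peptides:
        if abs(pep.mass - center) <= half:
            yield pep


# ---------------------------------------------------------------------------
# generators


def generate_nonspecific(
    db: ConcatenatedDatabase,
    idx: SuffixArrayIndex,
    mass: MassModel,
    params: DigestParams,
) -> Iterator[Peptide]:
    """All distinct sentinel-free substrings within the filters, once each.

    Every suffix contributes its prefixes longer than its LCP with the
    rank-preceding suffix; completeness and non-redundancy of the resulting
    string set follow from the rank-first-occurrence argument.
    """
    if params.specificity != "none":
        raise ValueError("generate_nonspecific requires specificity='none'")
    if idx.enzyme_id:
        raise DigestMisuseError(
            f"non-specific digestion needs the unadjusted LCP, got one "
            f"adjusted for {idx.enzyme_id!r}"
        )
    text = db.text
    lcp = idx.lcp
    prefix = mass.prefix_mass
    water = mass.water_mass
    nbad = mass.next_unmassed
    for prot in db.proteins:
        s, e = prot.start_offset, prot.end_offset
        for i in range(s, e):
            lo = max(int(lcp[i]) + 1, params.min_length)
            hi = min(e - i, params.max_length)
            if nbad[i] < i + lo:
                continue
            for L in range(lo, hi + 1):
                j = i + L
                if nbad[i] < j:
                    break
                m = int(prefix[j] - prefix[i]) + water
                if m > params.max_mass:
                    break
                if m < params.min_mass:
                    continue
                yield Peptide(text[i:j], m, 0, i)


def _cterm_state(bc: np.ndarray, j: int, e: int, params: DigestParams) -> bool:
    """Is the boundary at ``j`` (protein end ``e``) a valid peptide C-terminus?"""
    return bool(bc[j]) or (j == e and params.allow_protein_cterm)


def _ss_positions_by_rank(idx: SuffixArrayIndex, cleav: CleavageIndex) -> np.ndarray:
    sa = idx.sa
    return sa[cleav.is_ss[sa]]


def generate_full_specific(
    db: ConcatenatedDatabase,
    idx: SuffixArrayIndex,
    cleav: CleavageIndex,
    mass: MassModel,
    params: DigestParams,
    enzyme: EnzymeRule,
) -> Iterator[Peptide]:
    """Full-specific digest: both termini on cleavage boundaries.

    Walks only SS positions in text order with the enzyme-adjusted LCP; for
    blocked rules a following blocked residue at the generating occurrence
    triggers the rank-forward rescue scan described in the module docstring.
    """
    if params.specificity != "full":
        raise ValueError("generate_full_specific requires specificity='full'")
    if idx.enzyme_id != enzyme.name:
        raise DigestMisuseError(
            f"full-specific digestion needs the LCP adjusted for {enzyme.name!r}, "
            f"got {idx.enzyme_id or 'unadjusted'!r}"
        )
    text = db.text
    adj = idx.lcp
    bc = cleav.boundary_cleaving
    G = cleav._cut_cumsum
    prefix = mass.prefix_mass
    water = mass.water_mass
    nbad = mass.next_unmassed
    blocked = enzyme.blocked_next_residues
    c_side = enzyme.terminal_side == "C"
    # For plain C-side rules a candidate's C-terminal validity is the same at
    # every occurrence (last residue, or a sentinel that would have sorted
    # the occurrence first); context rules and N-side rules need the rescue.
    rescue_needed = (not enzyme.context_free) or not c_side
    if rescue_needed:
        ss_by_rank = _ss_positions_by_rank(idx, cleav)
        ss_order = np.full(len(text), -1, dtype=np.int64)
        ss_order[ss_by_rank] = np.arange(len(ss_by_rank))
    for prot in db.proteins:
        s, e = prot.start_offset, prot.end_offset
        for i in np.flatnonzero(cleav.is_ss[s:e]) + s:
            i = int(i)
            lo = max(int(adj[i]) + 1, params.min_length)
            hi = min(e - i, params.max_length)
            for L in range(lo, hi + 1):
                j = i + L
                mc = int(G[j - 1] - G[i])
                if mc > params.max_missed_cleavages:
                    break
                if nbad[i] < j:
                    break
                m = int(prefix[j] - prefix[i]) + water
                if m > params.max_mass:
                    break
                if m < params.min_mass:
                    continue
                if _cterm_state(bc, j, e, params):
                    yield Peptide(text[i:j], m, mc, i, True, True)
                    continue
                if not rescue_needed:
                    continue
                if c_side and not (j < e and text[j] in blocked):
                    continue
                # the string may still be valid at a later SS occurrence
                k = int(ss_order[i]) + 1
                while k < len(ss_by_rank):
                    q = int(ss_by_rank[k])
                    if int(adj[q]) < L:
                        break
                    qe = db.protein_at(q).end_offset
                    if _cterm_state(bc, q + L, qe, params):
                        yield Peptide(text[q : q + L], m, mc, q, True, True)
                        break
                    k += 1


def _any_occurrence_cterm_specific(
    db: ConcatenatedDatabase,
    idx: SuffixArrayIndex,
    unadj_lcp: np.ndarray,
    bc: np.ndarray,
    params: DigestParams,
    p: int,
    L: int,
) -> bool:
    """Does *any* text occurrence of ``T[p, p+L)`` end on a valid C-terminal
    boundary?  Scans the contiguous rank interval of suffixes sharing that
    prefix, which stays tiny for realistic peptide lengths."""
    sa = idx.sa
    rank = idx.rank
    n = len(sa)

    def occurrence_ok(q: int) -> bool:
        qe = db.protein_at(q).end_offset
        if q + L > qe:
            return False  # occurrence crosses a sentinel: not this string
        return _cterm_state(bc, q + L, qe, params)

    r0 = int(rank[p])
    if occurrence_ok(p):
        return True
    r = r0
    while r + 1 < n and int(unadj_lcp[sa[r + 1]]) >= L:
        r += 1
        if occurrence_ok(int(sa[r])):
            return True
    r = r0
    while r > 0 and int(unadj_lcp[sa[r]]) >= L:
        r -= 1
        if occurrence_ok(int(sa[r])):
            return True
    return False


def generate_semi_specific(
    db: ConcatenatedDatabase,
    idx: SuffixArrayIndex,
    idx_adjusted: SuffixArrayIndex,
    cleav: CleavageIndex,
    mass: MassModel,
    params: DigestParams,
    enzyme: EnzymeRule,
) -> Iterator[Peptide]:
    """Semi-specific digest: at least one terminus on a cleavage boundary.

    Part 1 runs the non-specific walk (unadjusted LCP) and keeps strings
    that end on a valid C-terminal boundary at some occurrence; part 2 runs
    the SS walk (adjusted LCP) and keeps strings that end on one at *no*
    occurrence.  C-terminal specificity therefore partitions the union, so
    the two parts cannot emit the same string.
    """
    if params.specificity != "semi":
        raise ValueError("generate_semi_specific requires specificity='semi'")
    if idx.enzyme_id:
        raise DigestMisuseError("idx must carry the unadjusted LCP")
    if idx_adjusted.enzyme_id != enzyme.name:
        raise DigestMisuseError(
            f"idx_adjusted must carry the LCP adjusted for {enzyme.name!r}"
        )
    text = db.text
    lcp = idx.lcp
    adj = idx_adjusted.lcp
    bc = cleav.boundary_cleaving
    G = cleav._cut_cumsum
    prefix = mass.prefix_mass
    water = mass.water_mass
    nbad = mass.next_unmassed
    blocked = enzyme.blocked_next_residues
    c_side = enzyme.terminal_side == "C"
    residues = enzyme.cleavage_residues

    # part 1: all suffixes, unadjusted LCP, C-terminally specific strings
    for prot in db.proteins:
        s, e = prot.start_offset, prot.end_offset
        for i in range(s, e):
            lo = max(int(lcp[i]) + 1, params.min_length)
            hi = min(e - i, params.max_length)
            for L in range(lo, hi + 1):
                j = i + L
                mc = int(G[j - 1] - G[i])
                if mc > params.max_missed_cleavages:
                    break
                if nbad[i] < j:
                    break
                m = int(prefix[j] - prefix[i]) + water
                if m > params.max_mass:
                    break
                if m < params.min_mass:
                    continue
                if _cterm_state(bc, j, e, params):
                    yield Peptide(text[i:j], m, mc, i, bool(cleav.is_ss[i]), True)
                    continue
                if c_side and (enzyme.context_free or text[j - 1] not in residues):
                    continue  # validity is occurrence-independent here
                # another occurrence may end on a valid boundary; this walk
                # visits the rank-first occurrence, so scan forward only
                sa, rank = idx.sa, idx.rank
                r = int(rank[i])
                n = len(sa)
                while r + 1 < n and int(lcp[sa[r + 1]]) >= L:
                    r += 1
                    q = int(sa[r])
                    qe = db.protein_at(q).end_offset
                    if _cterm_state(bc, q + L, qe, params):
                        yield Peptide(
                            text[q : q + L], m, mc, q, bool(cleav.is_ss[q]), True
                        )
                        break

    # part 2: SS suffixes, adjusted LCP, C-terminally non-specific strings
    for prot in db.proteins:
        s, e = prot.start_offset, prot.end_offset
        for i in np.flatnonzero(cleav.is_ss[s:e]) + s:
            i = int(i)
            lo = max(int(adj[i]) + 1, params.min_length)
            hi = min(e - i, params.max_length)
            for L in range(lo, hi + 1):
                j = i + L
                mc = int(G[j - 1] - G[i])
                if mc > params.max_missed_cleavages:
                    break
                if nbad[i] < j:
                    break
                m = int(prefix[j] - prefix[i]) + water
                if m > params.max_mass:
                    break
                if m < params.min_mass:
                    continue
                last = text[j - 1]
                if c_side and not blocked:
                    if last in residues:
                        continue  # specific at every occurrence: part 1's
                    if not params.allow_protein_cterm:
                        yield Peptide(text[i:j], m, mc, i, True, False)
                        continue
                if _any_occurrence_cterm_specific(db, idx, lcp, bc, params, i, L):
                    continue
                yield Peptide(text[i:j], m, mc, i, True, False)


def digest_database(
    db: ConcatenatedDatabase,
    params: DigestParams,
    enzyme: EnzymeRule | None = None,
) -> Iterator[Peptide]:
    """Build every needed structure for ``db`` and stream the digest.

    Convenience wrapper over :func:`generate` for one-shot use; pipelines
    that digest the same database repeatedly should build the index once
    and call the generators directly.
    """
    from .enzyme import adjust_lcp_for_enzyme, build_cleavage_index
    from .suffix_lcp import build_index

    idx = build_index(db)
    mass = build_mass_model(db)
    if params.specificity == "none":
        return generate_nonspecific(db, idx, mass, params)
    if enzyme is None:
        raise ValueError("site-specific digestion requires an enzyme")
    cleav = build_cleavage_index(db, enzyme)
    idx_adj = adjust_lcp_for_enzyme(idx, cleav, enzyme)
    return generate(db, idx, mass, params, enzyme, cleav, idx_adj)


def generate(
    db: ConcatenatedDatabase,
    idx_unadjusted: SuffixArrayIndex,
    mass: MassModel,
    params: DigestParams,
    enzyme: EnzymeRule | None = None,
    cleav: CleavageIndex | None = None,
    idx_adjusted: SuffixArrayIndex | None = None,
) -> Iterator[Peptide]:
    """Dispatch to the generator matching ``params.specificity``."""
    if params.specificity == "none":
        return generate_nonspecific(db, idx_unadjusted, mass, params)
    if enzyme is None or cleav is None or idx_adjusted is None:
        raise ValueError("site-specific digestion needs enzyme, cleav and idx_adjusted")
    if params.specificity == "full":
        return generate_full_specific(db, idx_adjusted, cleav, mass, params, enzyme)
    return generate_semi_specific(db, idx_unadjusted, idx_adjusted, cleav, mass, params, enzyme)
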