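"""Map identified peptides back to all containing proteins.

After peptide-spectrum matching, each identified peptide sequence must be
attributed to every database protein containing it.  All peptides are
compiled into one Aho-Corasick trie-automaton (goto + failure + output
links, built in time linear in the total pattern length), and each protein
sequence is then scanned once; a pass over the whole database therefore
resolves every peptide simultaneously.  Matching runs on the per-protein
sequences, never on the concatenated text, so offsets are protein-local and
no match can span a sentinel.  Overlapping and nested occurrences are all
reported.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator

from .sequence_db import SENTINEL, ConcatenatedDatabase

PeptideLocationMap = dict[str, list[tuple[str, int]]]


class AhoCorasickAutomaton:
    """Classic multi-pattern matcher over residue strings."""

    def __init__(self, patterns: Iterable[str]):
        patterns = list(patterns)
        if not patterns:
            raise ValueError("at least one pattern is required")
        for p in patterns:
            if not p:
                raise ValueError("empty patterns are not allowed")
            if SENTINEL in p:
                raise ValueError(f"pattern {p!r} contains the sentinel character")
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[str]] = [[]]
        for pat in patterns:
            self._insert(pat)
        self._build_failure_links()

    def _insert(self, pat: str) -> None:
        node = 0
        for c in pat:
            nxt = self._goto[node].get(c)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._fail.append(0)
                self._out.append([])
                self._goto[node][c] = nxt
            node = nxt
        if pat not in self._out[node]:
            self._out[node].append(pat)

    def _build_failure_links(self) -> None:
        queue = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for c, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and c not in self._goto[f]:
                    f = self._fail[f]
                fallback = self._goto[f].get(c, 0)
                self._fail[child] = fallback if fallback != child else 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def iter_matches(self, text: str) -> Iterator[tuple[str, int]]:
        """Yield ``(pattern, end_offset)`` for every occurrence in ``text``;
        ``end_offset`` is the index one past the match's last character."""
        node = 0
        for k, c in enumerate(text):
            while node and c not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(c, 0)
            for pat in self._out[node]:
                yield pat, k + 1


def build_automaton(peptides: Iterable[str]) -> AhoCorasickAutomaton:
    """Compile identified peptide sequences into one trie-automaton."""
    return AhoCorasickAutomaton(peptides)


def map_peptides(
    db: ConcatenatedDatabase, peptides: Iterable[str]
) -> PeptideLocationMap:
    """Locate every occurrence of every peptide in every protein.

    Returns ``{peptide: [(accession, protein-local 0-based offset), ...]}``
    with an entry for each input peptide (possibly empty), in one automaton
    pass per protein.
    """
    peptides = list(dict.fromkeys(peptides))
    automaton = build_automaton(peptides)
    result: PeptideLocationMap = {p: [] for p in peptides}
    for prot in db.proteins:
        for pat, end in automaton.iter_matches(prot.sequence):
            result[pat].append((prot.accession, end - len(pat)))
    return result
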