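# ablcp

Non-redundant candidate peptide generation for tandem-MS database searching,
built on suffix arrays and longest common prefixes.

## The problem

Shotgun proteomics search engines score candidate peptides from a protein
sequence database against measured spectra. Databases are highly redundant —
homologous proteins share most of their tryptic peptides — so a naive
protein-by-protein digest scores the same peptide string many times, and a
precomputed *peptide index* that deduplicates offline costs large amounts of
time and disk (up to 100× more for semi/non-specific digests) and must be
rebuilt whenever a digestion parameter changes.

`ablcp` takes the suffix-array route instead. All proteins are concatenated
into one text `T` with a `$` sentinel after each. Over `T` we build the
suffix array `SA` (suffixes in ascending lexicographic order), its inverse
`Rank`, and the longest-common-prefix array `LCP`, stored **indexed by text
position**: `LCP[i]` is the shared-prefix length of `Suffix[i]` and its
rank-predecessor. Then the suffix starting at `i` emits exactly its prefixes
of length `LCP[i]+1 … ` (up to the next sentinel / length and mass limits).
Every distinct substring is produced exactly once — at its rank-first
occurrence — so deduplication costs nothing and needs no peptide index. Only
the one-byte-per-position LCP is kept on disk; digestion parameters (missed
cleavages, length, mass window, full vs non-specific) can change freely
without any rebuild.

For enzymatic (site-specific) digestion the plain LCP is wrong: a peptide's
first occurrence may sit in a suffix that is not a legal peptide start. The
fix re-points each *specific suffix* (SS: preceded by a cleavage boundary,
or a protein N-terminus) at its nearest preceding SS suffix in rank order,
using the identity

    lcp(Suffix[SA[x]], Suffix[SA[z]]) = min_{x<y<=z} LCP-of-adjacent-pair(y)

computed in one linear sweep. Semi-specific digestion is the disjoint union
of the non-specific walk keeping cleavage-ending strings and the SS walk
keeping the rest. Trypsin/P-style context rules (K/R not followed by P) are
handled with an emission-time rank scan so that a peptide valid at *any*
occurrence is emitted, still exactly once. Identified peptides are mapped
back to all containing proteins with an Aho-Corasick automaton in a single
database pass.

## Worked example

```python
import ablcp
from ablcp.digest import DigestParams

db = ablcp.from_sequences([("P1", "MSQVQVQV")])   # text "MSQVQVQV$", n = 9
idx = ablcp.build_index(db)
print(idx.sa.tolist())    # [8, 0, 6, 4, 2, 1, 7, 5, 3]
print(idx.lcp.tolist())   # [0, 0, 4, 3, 2, 1, 0, 0, 0]
```

`sa[2] = 6`: the third suffix in ascending order is `Suffix[6] = "QV$"`.
`lcp[2] = 4`: `Suffix[2] = "QVQVQV$"` shares `"QVQV"` with its predecessor
`"QVQV$"`. The suffix `"VQVQV"` at position 3 has `lcp[3] = 3`, so it emits
exactly two substrings (`"VQVQ"`, `"VQVQV"`); over all positions the walk
emits the 26 distinct substrings of the protein, each once.

A tryptic digest:

```python
peps = list(ablcp.digest_database(
    db=ablcp.from_sequences([("P1", "MKAR")]),
    params=DigestParams(specificity="full", min_length=1),
    enzyme=ablcp.get_enzyme("trypsin")))
print(sorted((p.sequence, p.missed_cleavages) for p in peps))
# [('AR', 0), ('MK', 0), ('MKAR', 1)]
```

From the shell, against a synthetic database with 20 % duplicated entries:

```console
$ ablcp synthesize --out demo.fasta --n-proteins 50 --length 120 --duplication 0.2 --seed 7
$ ablcp build --fasta demo.fasta --out-dir index
$ ablcp digest --db-dir index --specificity full --out peps.tsv
[ablcp] wrote 1197 peptides to peps.tsv (0.02s)
$ ablcp stats --db-dir index --out stats.json
{"specificity": "full", "nonredundant": 1197, "redundant": 1490, "redundancy_percent": 19.7}
```

1197 distinct tryptic peptides cover 1490 occurrences; the 19.7 % redundancy
ratio is the fraction of peptide-spectrum matching work the non-redundant
stream avoids, and tracks the 20 % duplication built into the database.

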