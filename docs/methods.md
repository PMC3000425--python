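# Methods

## Text model

A FASTA database is concatenated into one ASCII text `T`: each protein
sequence (uppercased, one trailing `*` stripped) followed by a single `$`
sentinel, so `T` ends in `$` and contains exactly one sentinel per protein.
All coordinates are 0-based, half-open. The sentinel's ASCII code is below
every residue letter, so the sentinel-first collation needed by the
suffix-array construction is plain byte order. Ambiguity codes
(B, J, O, U, X, Z) are kept in the text under the default `mask` policy so
the index covers the whole database; any candidate containing one is
discarded at emission time because it has no defined monoisotopic mass (the
`strict` policy rejects such databases up front). Decoy entries are ordinary
proteins; the package has no notion of target/decoy.

## Index construction

The suffix array is built by prefix doubling on numpy arrays
(O(n log n) with O(n) memory traffic per round). The construction contract
is correctness only — any algorithm producing the sorted suffix permutation
would do — and it is verified against a naive sort-of-explicit-suffixes
oracle on randomized texts. `Rank` is the inverse permutation. The LCP array
is induced with Kasai's linear-time algorithm and stored **indexed by text
position** (`lcp[i]` refers to `Suffix[i]`, with the rank-0 suffix at 0).
This is the opposite of the rank-indexed convention most of the literature
uses; it is deliberate, because every digestion walk iterates positions in
text order. Suffixes beginning with `$` participate in the ordering but can
never start a peptide.

Only the LCP is persisted: one byte per position, values clamped at a cap
(default 255) that must be at least the maximum peptide length — clamping is
then invisible because generation never extends a candidate past that
length. The file header stores the cap, the enzyme the array was adjusted
for (empty for unadjusted) and an MD5 digest of the text; loading against a
database with a different digest raises a staleness error. The suffix array
itself is discarded after preprocessing; stages that need rank-order scans
(context rules, semi-specific digestion) rebuild it in memory, which is a
few seconds even for large databases.

## Digestion

**Non-specific.** Position `i` emits prefixes of `Suffix[i]` of length
`lcp[i]+1` up to the distance to the next sentinel, intersected with the
length and mass windows. Each distinct substring is emitted exactly once, at
its rank-first occurrence; the test suite asserts both this non-redundancy
and the count identity Σ max(dist_to_sentinel − lcp, 0) = number of
distinct substrings.

**Cleavage model.** An enzyme is (cleavage residues, terminal side, blocked
next-residues). C-side rules cut after a cleavage residue unless the next
residue is blocked; N-side rules cut before one (blocked context is not
supported on the N side and raises). A position is a *specific suffix* (SS)
start iff it is a protein N-terminus or the boundary before it cuts. A
candidate's C-terminal boundary is valid iff it cuts or is the protein end
(`allow_protein_cterm`, default on; the off switch reproduces the stricter
convention that accepts only cleavage-residue endings). Whether a protein
end counts as a specific boundary in the semi-specific partition follows
the same flag, keeping the N- and C-terminal conventions symmetric.

**Full-specific.** The non-specific walk restricted to SS positions, with
the LCP re-pointed at the nearest rank-preceding SS suffix. The adjustment
uses the min-composition property of adjacent LCPs and runs as one linear
rank-order sweep carrying a running minimum since the last SS suffix; a
definitional quadratic oracle (explicit `lcp` against the rank-preceding SS
suffix) is kept in `redundancy_oracle` for testing. Without the adjustment,
a peptide whose first occurrence lies in a non-SS suffix is silently lost;
the two-protein fixture `XAAKB`/`KAAKC` (tryptic `AAK`) is the permanent
regression for this.

**Missed cleavages** are counted intrinsically: a prefix count of cleaving
boundaries per protein gives the number of uncut boundaries strictly inside
an occurrence in O(1). Counting loop iterations instead would undercount
whenever the inner loop starts past length 1, since cleavage residues inside
the skipped prefix are never visited. Extension stops once the interior
count exceeds the cap (the count is monotone in the end position). For every
supported rule the interior boundaries depend only on the candidate string,
so the count is string-intrinsic.

**Context rules (trypsin/P).** With blocked contexts a string can be a
valid peptide at one occurrence and not at another (the residue *after* the
occurrence decides). A string is emitted iff any occurrence is valid.
Mechanically: SS membership already respects blocking; when the generating
occurrence's C-terminus is invalidated by a blocked residue, the generator
scans forward through rank-adjacent (SS-)suffixes that still share the
candidate as a prefix — the shared-prefix run is delimited by the (adjusted)
LCP dropping below the candidate length — and emits at the first valid
occurrence found. The same reasoning shows no scan is ever needed for plain
C-side rules: validity there depends only on the last residue or on a
protein-end continuation, and a `$` continuation always sorts first, i.e.
into the generating occurrence itself. N-side rules, whose C-terminal
validity depends on the following residue too, use the same rescue. These
scans are bounded by the size of the shared-prefix rank interval, which is
tiny at realistic peptide lengths.

**Semi-specific.** Two disjoint parts: the non-specific walk keeping
strings with a valid C-terminal boundary at some occurrence, and the SS
walk (adjusted LCP) keeping strings with a valid C-terminal boundary at no
occurrence. C-terminal specificity is a property of the string's occurrence
set, so the two parts partition the output and the union is exactly the
set of strings with at least one specific terminus.

**Masses.** Monoisotopic residue masses (pyteomics `std_aa_mass`, 20
standard residues) scaled by 10⁴ and rounded to the nearest integer; water
is 180106 integer units (18.010565 Da). A running prefix sum over the text
gives any within-protein span mass as a difference plus water. The mass
window is applied per candidate with early termination (mass is monotone in
length); ppm tolerances are converted against the window centre and rounded
outward. All stored masses are exact integers, so there is no floating-point
tie-breaking anywhere in the pipeline.

## Reference enumeration and redundancy statistics

`redundancy_oracle.naive_digest` re-implements digestion as the
peptide-index workflow would: per protein, per start, extend the end one
residue at a time, re-checking the terminal rules directly on the protein
string, then sort and deduplicate. It shares no machinery with the
suffix-array generators — no SA, no LCP, no cleavage index — which is what
makes the string-set equality tests between the two routes meaningful.
`redundancy_stats` counts every qualifying occurrence (including repeats
within one protein) against distinct strings and reports the redundancy
ratio `1 − distinct/occurrences` as a percentage.

## Synthetic databases

`generate_synthetic_fasta` draws protein sequences i.i.d. uniform over the
20 standard residues, with a chosen count, length distribution and an exact
fraction `d` of entries that duplicate a random earlier entry; output is
deterministic given the seed. This emulates the one property of real
databases the algorithm targets — exact sequence duplication, whose peptide
redundancy ratio approaches `100·d`% — but not homology (near-duplicates
with point differences), realistic residue composition, or the heavy-tailed
length distribution of real proteomes. Equivalence tests on it therefore
demonstrate algorithmic correctness, not realistic redundancy magnitudes;
real databases show higher ratios than duplication alone would predict
because of homologous, non-identical entries. Test scales — randomized
databases of up to a few hundred residues for oracle equivalence (hundreds
of cases), 200 proteins × 300 residues for duplication-rate recovery, texts
up to n = 2000 for suffix-array/Kasai oracles — were chosen so the
definitional quadratic oracles stay cheap while still exercising every code
path (repeats, shared prefixes spanning sentinels, blocked contexts,
ambiguity codes).

## Design choices and limitations

- The quadratic backward-scan formulation of the SS adjustment is retained
  only as a test oracle; the production path is the linear sweep with
  identical output.
- The blocked-context adjustment is deliberately conservative (never larger
  than the plain SS adjustment over the blocked-aware SS set) with validity
  resolved at emission; its correctness is established by exhaustive
  randomized equivalence against the reference enumeration rather than by a
  closed-form argument.
- Emitted `Peptide` records carry the occurrence that generated (or
  rescued) them; for context rules, duplicate strings with differing
  occurrence metadata collapse to the first valid occurrence.
- No modification enumeration, no spectrum I/O or scoring, no multi-enzyme
  digests, no enzymes with multi-residue recognition motifs, no compressed
  or external-memory suffix structures, and no parallelism. Protein
  inference is containment mapping only — no grouping, parsimony or FDR.
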