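# Methods

This note documents the models and procedures implemented in `bgckit`, the
choices made where the design was genuinely open, and what the synthetic
test data does and does not demonstrate.

## Assembly-line distance metric

A trans-AT PKS assembly line is reduced to the ordered list of clade labels
of its ketosynthase (KS) domains. The distance between two lines *a*, *b*
combines three components, each in [0, 1]:

- **Jaccard distance** `d_J = 1 − |S_a ∩ S_b| / |S_a ∪ S_b|`, where `S_x`
  is the *set* of clade labels — which chemistries occur at all.
- **Goodman–Kruskal gamma distance**. Over all unordered pairs of *shared*
  clade labels, a pair is concordant when the first occurrences of the two
  labels appear in the same relative order in both lines, discordant
  otherwise; `γ = (C − D)/(C + D)` and `d_γ = (1 − γ)/2` — in what order the
  chemistries occur.
- **Duplication distance** `d_dup = Σ_c |n_a(c) − n_b(c)| / Σ_c max(n_a(c),
  n_b(c))` over shared labels `c` with copy counts `n` — how often each
  chemistry occurs.

The combined distance is the weighted sum with default weights
**0.5 / 0.25 / 0.25** (Jaccard / gamma / duplication), configurable but
pinned to these empirically determined values.

Open points we had to decide:

- *Gamma on repeated clades.* γ is defined on clade **types** via
  first-occurrence positions. Repeats would make the rank statistic
  ill-defined; copy-number disagreement is already measured by `d_dup`, so
  γ stays a pure order statistic.
- *Gamma normalisation.* γ ∈ [−1, 1] is mapped to a distance by the standard
  affine map `(1 − γ)/2`.
- *Degenerate shared sets.* No shared labels: `d_γ = d_dup = 1` (maximally
  unrelated lines reach the maximal combined distance of exactly 1). One
  shared label: `d_γ = 0` (a single label carries no order conflict).
- *Duplication restricted to shared labels*, so presence/absence is not
  double-counted between `d_J` and `d_dup`.

All components are symmetric, zero on identical lines, and bounded in
[0, 1]; these conservation laws are property-tested on fuzzed lines.

## Reference selection, clustering and alignment

The **top n = 15** references closest to the query (ascending combined
distance, ties by lexicographic id) are selected and clustered together with
the query by **UPGMA** under the same metric. UPGMA is implemented directly
(merge the minimal pair; new distances are size-weighted arithmetic means;
node height = merge distance / 2) rather than through a generic linkage
routine so that ties break deterministically by the lexicographically
smallest pair of cluster representatives — reruns are byte-identical. The
output is ultrametric by construction, and on ultrametric inputs the
cophenetic distances reproduce the input matrix exactly (oracle-tested).

Domain-level alignment is global dynamic programming over clade-label
strings with **match +2 / mismatch −2 / gap −1** and traceback tie order
diagonal > up > left. Multiple lines are merged progressively along the
UPGMA guide tree ("once a gap, always a gap"); profile columns are scored
by the average cross-pair substitution score, which reduces exactly to the
pairwise scheme for single-sequence profiles. The scheme is the simplest
one that yields the intended column semantics (same-clade domains aligned,
insertions as gap columns); nothing downstream depends on the particular
scores beyond match > gap > mismatch ordering.

Per-domain percent identity between homologous (same-clade) aligned domains
uses pairwise global alignment (match +1 / mismatch −1 / gap −2, terminal
overhangs excluded from the column count), via Biopython's `PairwiseAligner`.
A multiple-alignment program would give marginally different identities for
divergent pairs; for homologous KS domains the difference is small, and the
pairwise route keeps the package self-contained and deterministic. A domain
without a stored sequence yields identity "unavailable" (`None`), never 0.

## Monophyly-rule chemistry prediction

For a query enzyme and a labelled reference set (terpene cyclization
patterns, A-domain substrates, or KS clades):

1. all-vs-all percent identities (same aligner as above);
2. **neighbor joining** (Saitou–Nei) on `d = 1 − identity/100`, implemented
   in-package with negative branch lengths clamped to 0 and Q-criterion ties
   broken by lexicographic pair, so the topology is taxon-order invariant;
3. **midpoint rooting** (NJ trees are unrooted; the sister-group test needs
   a root; midpoint is standard and parameter-free);
4. the query's sister group is read off: if every reference leaf in it
   carries one identical label (and the group has at least
   `min_sister_size = 1` leaves), that label is the prediction; otherwise
   no label is assigned.

The nearest characterized homolog (argmax identity, ties by lexicographic
id) and its identity are reported whether or not a label was assigned.
Terpene predictions are gated on Pfam content: PF01397 and/or PF03936 must
be present. Per-domain KS clade assignment applies the same rule per domain,
with `"unclassified"` for unresolved domains.

Distance-based NJ on alignment identities is a deliberate simplification of
the original external-aligner-plus-placement machinery; only the monophyly
rule itself is modelled. NJ correctness is oracle-tested: on exactly
additive matrices the output tree's path lengths reproduce the input to
1e−9.

## TTA codon scanning

Only **in-frame** TTA codons inside annotated CDS are reported: the
biological signal is translational (the *bldA* tRNA reads the Leu codon
UUA), so out-of-frame TTA trinucleotides are meaningless. Reverse-strand
codons are mapped back to forward-axis coordinates. A GC-content gate warns
(never suppresses) below 60% GC, since the regulation is specific to
high-GC actinobacteria. CDS lengths not divisible by 3 lose the trailing
partial codon with a warning.

## Small-ORF discovery and peptide masses

`find_small_orfs` performs a six-frame scan for maximal start→stop ORFs
(starts ATG/GTG/TTG; per stop codon, the earliest in-frame start since the
previous stop), keeps those of 20–120 aa whose extent overlaps no annotated
CDS by more than 10 nt, and merges in annotated genes already within the
size bounds. The bounds and overlap allowance are flags; the defaults
bracket typical RiPP precursor lengths. Alternative starts are translated
as Met (bacterial initiation). The scan is oracle-tested against an
independent stop-anchored brute-force scanner on random ≤ 2 kb sequences.

Peptide masses use the standard residue tables (via pyteomics):

    mass = Σ residues + H₂O − (macrolactam ? H₂O : 0) − n_SS · 2H

The macrolactam term models the lasso peptide's N-terminal isopeptide ring
(a condensation, −18.0106 Da monoisotopic); each disulfide removes two
hydrogens (−2.0157 Da). Both monoisotopic and average masses are always
reported, since which one a downstream user needs depends on their MS
workflow. Mass additivity (concatenation loses exactly one water) is
property-tested.

## Input model

GenBank and FASTA(+GFF3) inputs are normalised to one record model with
**0-based half-open** internal coordinates; all user-facing output is
1-based inclusive. Join/complement CDS locations collapse to their overall
extent with strand ±1 — adequate for bacterial gene structures, a documented
limitation for spliced genes. Translation defaults to genetic code table 11;
a stored `/translation` qualifier always wins over recomputation. EMBL input
is not implemented (GenBank plus FASTA/GFF3 covers the same information with
less parsing surface). Reports are deterministic JSON (sorted keys, floats
at 6 significant digits): identical inputs give byte-identical files.

## Synthetic data: what it shows and what it does not

The fixture generators are first-class, seeded code:

- **Assembly lines**: reference *i* is the query after *i − 1* random edits
  (clade substitution, domain duplication, adjacent swap), so the first
  reference is an exact copy and edit counts grow with rank. The manifest
  records edit counts and the metric-derived ranking; tests check
  self-consistency and that edit count correlates positively with distance.
- **Reference families**: one ancestor per label, derived from a common root
  mutated at `between_divergence/2` per ancestor (pairwise ancestor
  separation ≈ `between_divergence`); members and held-out queries mutate
  their ancestor at `within_divergence`. Defaults — 3 labels, 5 sequences
  per label, 5% within, 40% between, 50 queries, 150-aa proteins — define
  the regime in which label recovery is assessed (accuracy ≥ 0.9 expected).
- **Toy GenBank**: three CDS (one reverse-strand), three in-frame TTA
  codons and one unannotated 25-aa intergenic ORF. Intergenic filler uses
  only C/T, which makes start and stop codons impossible outside the planted
  elements on either strand, so the planted features are provably the only
  recoverable ones.

These generators emulate divergence structure, not real biology: mutations
are i.i.d. uniform substitutions (no rate heterogeneity, indels in proteins,
codon bias or realistic GC content), clade labels are arbitrary symbols, and
no real Pfam models or curated KS clades are shipped. Passing tests
demonstrate algorithmic correctness and calibration in this controlled
regime — not predictive accuracy on real enzymes, which depends entirely on
the user-supplied curated reference sets.

## Problem sizes and determinism

Default test/verification sizes: 30 reference lines of ~12 domains; 15
reference proteins plus 50 queries for label recovery; 1000 fuzzed line
pairs for the metric laws; 15–30 random instances per oracle suite; ≤ 2 kb
sequences for the ORF oracle. Everything derives from explicit integer
seeds through `numpy.random.default_rng`; there is no global random state,
and every pipeline rerun with the same inputs produces byte-identical
output files.
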