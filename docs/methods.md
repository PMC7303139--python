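# Methods

This note documents the models, statistics and numerical choices behind
`leechmine`, and what the synthetic benchmarks do and do not demonstrate.

## Alignment and search statistics

Pairwise alignment is an affine-gap Gotoh dynamic programme with three
states (match, gap-in-query, gap-in-target). A gap run of length L costs
`gap_open + gap_extend·L` (BLAST existence+extension convention; defaults
11/1 with BLOSUM62). Two modes share the fill:

* **local** (Smith–Waterman) for database search;
* **semiglobal** (Needleman–Wunsch with free terminal gaps) for
  candidate/archetype comparison: both sequences appear in full, one leading
  and one lagging gap are free, internal gaps are charged. This mirrors an
  align-then-truncate workflow, so `trim_terminal_gaps` always leaves
  internal indels intact.

Traceback is deterministic (tie order diagonal > up > left; ties between
equal-scoring end cells resolve in a fixed scan order), making all outputs
bit-reproducible. The fill is vectorised row-wise; the within-row gap state
is resolved by a running-maximum scan, so alignment of two 300-residue
proteins costs a few hundred short numpy operations.

`X` is the only ambiguity code accepted and scores 0 against everything;
other codes are rejected at parse time because the scoring model is defined
over the 20 canonical letters.

Search statistics are the standard Karlin–Altschul normalisation with the
published gapped BLOSUM62/11/1 constants λ = 0.267, K = 0.041 (overridable):
bit score S′ = (λS − ln K)/ln 2, expectation E = m·n·2^(−S′) with m the query
length and n the summed residue count of the database. No composition-based
statistics and no finite-size edge correction are applied — E-values here are
a consistent ranking statistic on the same scale as BLASTp, not a re-creation
of its exact numbers. Accordingly the screening cutoff (E ≤ 10⁻⁵) is applied
to these internal E-values.

## Screening decisions

The reciprocal screen operationalises "a better hit against a completely
unrelated protein" as: the best reciprocal hit in some database (i) has an
E-value at least `rejection_margin` (default 10×) smaller than the best
family-consistent reciprocal hit (family-consistency = case-insensitive
substring match against the family's synonym list, which always contains the
family name), and (ii) carries an informative description. Descriptions like
"hypothetical protein" / "uncharacterized protein" / "unnamed protein
product" never reject. The margin guards against float-noise rejections when
two databases return near-identical E-values; it also makes the decision
monotone: improving the family-consistent hit can only rescue, never reject.
When no database returns any family-consistent hit, the forward E-value
stands in as the comparison baseline.

## Copy number, dedup, tandem arrays

A proteome member is a copy of a family when the family's top hit aligns to
it with E ≤ 10⁻⁵, aligned span covering ≥ 50% of the member's length, and
≥ 70% similarity (identical or positive-scoring columns) over the aligned
region. "Coverage of the target" is the default reading of the length
threshold; a literal query/target length-ratio mode and an identity-only
similarity mode are available as configuration switches. Counting is
monotone: tightening any threshold can only lower a family's copy number.

Cross-family dedup assigns each protein to the family whose query scores it
with the highest bit score (ties: lower E-value, then lexicographically
first family name), recording losing assignments.

Tandem arrays are maximal runs of same-family copies at consecutive
per-scaffold gene indices (`max_gap` intervening genes allowed, default 0).
Gene order is genomic (ascending start coordinate) regardless of strand,
since arrays are a positional, not transcriptional, notion. Exon/intron
length conservation across copies is the mean over positionally paired
lengths of 1 − |a−b|/max(a,b), averaged over all copy pairs, with unpaired
positions scoring 0; classes are strong (≥ 0.9), low (< 0.6), else mixed.
The 0.9/0.6 cut points are package conventions chosen to separate
"essentially identical" from "clearly drifted" structures; the source
analyses this reproduces used only qualitative labels. Note that 50%
multiplicative intron-length jitter lands the expected conservation near the
0.6 boundary (~0.56), so such families split between "low" and "mixed".

## Conservation statistics

All statistics are computed on the trimmed alignment. Shared columns are
those with a residue in both rows; identity and similarity percentages use
shared columns as denominator, so gaps never dilute them. Cysteine
conservation counts archetype cysteines whose column holds C in both rows.
Both identity and similarity are always reported: for near-identical pairs
the two are indistinguishable, for divergent pairs "similarity" (which
includes positive-scoring substitutions) is systematically higher, and
published figures use the word loosely. Signal-peptide regions are included
in the statistics unless mature-peptide-only mode is switched on and an
annotation provides the region — signal peptides are always consumed from
annotation files, never predicted.

## Trees, bootstrap, clans

The bundled tree builder is deliberately distance-based: Poisson-corrected
distances d = −ln(1−p) (p the differing fraction of shared columns, capped
at 0.95 to keep saturated pairs finite) and Saitou–Nei neighbor joining with
a content-based tie-break (lexicographically smallest representative leaf
labels), so topologies are invariant under input order. Negative
branch-length estimates are clamped to zero. Maximum-likelihood inference is
intentionally out of scope — externally computed trees import via newick,
with numeric internal node labels read as edge supports and any rooting
dissolved — because the analysis this package owns is the clan test, not
tree inference.

Bootstrap supports resample alignment columns with replacement, rebuild the
distance+NJ tree per replicate, and score each original internal edge by the
percentage of replicates containing the same bipartition.

A clan is a leaf set separated from the rest by a single edge. The smallest
clan containing a candidate and its archetype decides orthology:
`not_orthologue` when the clan contains a leaf annotated with a different
family, otherwise `orthologue_supported` iff the defining edge's support
reaches the threshold (default 75%, the conventional cut between weak and
moderate bootstrap support). On multifurcating imports the smallest clan may
be non-unique; ties prefer a support-bearing clan, then the
lexicographically smallest leaf set. Adjacent groups (the unrooted analogue
of sister groups) are obtained by deleting the complement-side endpoint of
the clan's defining edge; each subtree hanging from it is an adjacent clan.
When the candidate and archetype radiate from a star-like centre, the
smallest clan's defining edge is a noise edge: calls then legitimately come
out `orthologue_unsupported`, which is a property of the data, not a defect
of the test.

## Synthetic data

The generator plants what the mining pipeline must detect:

* **Archetypes**: uniform random sequences over the 19 non-cysteine letters
  with a planted cysteine scaffold (default length 300, 10 cysteines —
  typical of the cysteine-rich protease-inhibitor families of interest).
* **Substitutions**: 20-state Jukes–Cantor; a site differs after divergence
  t with probability (19/20)(1 − e^(−20t/19)), replacements uniform over the
  19 alternatives. The uniform model (rather than BLOSUM-biased) keeps this
  expectation in closed form, which the calibration tests check directly.
  Cysteine sites substitute at the baseline rate scaled by
  (1 − cys_retention_p); with full retention (default) deletions are also
  placed around cysteines, so the planted scaffold is exact truth.
* **Indels**: Poisson count (default rate 1 per sequence), geometric lengths
  (default p = 0.4, mean 2.5), uniform positions, insertion/deletion
  equiprobable; insertions draw non-cysteine letters.
* **Layout**: per family (default 3 families × 4 copies at t = 0.1, matching
  the copy numbers and divergences at which the real analysis operates),
  round(tandem_fraction × copies) members occupy consecutive gene positions
  on one scaffold; the rest disperse among 20 independent random decoys on 8
  scaffolds, with a layout check that forbids accidental same-family
  adjacency so the truth table's tandem annotation is exact. Gene models
  carry family-shared exon-length fractions and per-copy jittered intron
  lengths.
* **Fixture global databases** ("nr", "swissprot", "pfam" stand-ins) contain
  the archetypes under family-consistent descriptions plus named unrelated
  and "hypothetical protein" entries, so both branches of the reciprocal
  screen are exercised.

Identical configurations produce byte-identical FASTA/GFF3/TSV outputs.

What passing the synthetic benchmarks shows: the decision procedures recover
exactly what was planted under the stated generative model, at desk scale,
with no downloads. What it does not show: robustness to real-world
compositional bias, low-complexity regions, fragmented gene models, splice
variants, or the heuristics of production BLAST — real proteomes should be
screened with the same thresholds but their E-values will differ from
BLASTp's, and conclusions near the cutoffs deserve manual review.

## Problem sizes

Defaults keep every stage interactive on one CPU: proteomes of tens of
proteins (32 by default), pairwise DPs of ~300×300, bootstrap with 100–1000
replicates over ≤ 10-leaf trees. The acceptance script measures recovery
over 3 planted genomes, 50 conservation replicates and 25 tree replicates
(~20 s total); the test suite's brute-force oracles enumerate alignments up
to length 8 and clans up to 10 leaves.
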