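# Methods

This note documents the models, conventions, and design choices behind
`barcodekit`, in the order the pipeline applies them.

## Quality screens

Reads are trimmed with standard trace-trimming semantics: from each end
inward, a terminal window of `qc.window` bases (default 20; the whole
remaining span when shorter) is removed while it contains at least
`qc.bad_per_window` bases (default 4, the "at least" reading of the rule)
with QV below `qc.qv_floor` (default 20). Interior segments are never
excised — a low-quality island inside an otherwise good read stays, since
its bases still carry information and downstream distances use pairwise
deletion anyway. A read is accepted when the kept span is at least
`qc.min_keep_frac` (default 60%) of the original length and its mean QV is
at least `qc.min_mean_qv` (default 30). Trimming is idempotent: re-running
it on a kept span changes nothing.

Forward/reverse overlap is scored by local alignment (match +1, mismatch
−1, gap −2; the reverse read is reverse-complemented internally). Coverage
is `overlap_columns / (len(fwd) + len(rev) − overlap_columns)`, i.e. the
overlap as a fraction of the consensus (union) span; a pair is usable when
coverage exceeds `qc.min_overlap` (default 0.70 strictly; a relaxed 0.50
floor can be selected for the occasional short-overlap pair). The 5.8S
motif screen is an exact forward-strand substring match; when both the
plant and the fungal variant occur the fungal call wins and a warning is
logged, because a fungal hit anywhere is grounds for manual review.

## Alignment

The built-in progressive aligner is deliberately simple: guide tree from
neighbor joining on pairwise 6-mer Jaccard distances (alignment-free,
deterministic), then post-order profile merging, where two profiles are
merged by globally aligning their column-majority consensus sequences
(match +1, mismatch −1, gap open −4, gap extend −1; a length-1 gap costs
the open score) and propagating the resulting gap columns into every row.
Consensus-based merging was chosen over full profile-profile dynamic
programming for speed and code simplicity; it is adequate for barcode-
scale data (loci under ~1 kb, modest indel load) but is not an iterative
refiner, and column-level agreement with any external aligner is not
promised. For that reason a pass-through mode accepts externally aligned
FASTA unchanged, and all downstream results can be produced from either
route. Pairwise global alignment itself is delegated to Biopython's
`PairwiseAligner` with deterministic first-traceback tie-breaking.

Concatenation keeps only samples present in every input locus — the only
samples for which a multi-locus barcode exists — and records per-locus
column boundaries in a partition table.

## Distances and summaries

p-distances are uncorrected (no multiple-hit correction) under pairwise
deletion: a column contributes to a pair only when both rows have A/C/G/T.
Ambiguity codes are excluded by default (`distance.ambiguity=missing`);
the `partial_match` policy instead counts a column as a match when one
row's IUPAC set contains the other row's base. A pair with zero comparable
columns has no distance (NaN) and is reported as missing with a warning.

A column is *variable* when ≥ 2 distinct unambiguous bases occur in it,
and *parsimony-informative* when ≥ 2 distinct bases each occur in ≥ 2
rows; percentages are over aligned columns. Mean sequence length is over
ungapped input sequences. Inter/intra-specific divergence means are
pair-weighted by default (each sample pair counts once); a
species-weighted alternative (mean of species means) is available, since
either convention appears in the barcode literature.

## Neighbor joining and bootstrap monophyly

NJ is the classical Saitou–Nei agglomeration with explicit deterministic
semantics: the Q-matrix minimum is taken at the lexicographically smallest
(i, j) pair; negative branch lengths are clamped to zero with the deficit
moved to the sister edge (path lengths through the join are preserved);
missing distances are imputed as the matrix's maximum observed distance —
conservative, because inflating a distance can only break, never fake, a
species clade.

Bootstrap support for a species is the percentage of column-resampled
replicates (resample alignment columns with replacement, rebuild the
distance matrix and NJ tree) in which the species' leaves form a clade,
i.e. some edge bipartition separates exactly them. Replicate *r* draws
from RNG stream `(seed, r)`, so supports are independent of evaluation
order and parallelization. A species is resolved by the tree method when
it is monophyletic in the full-alignment tree **and** its support is
≥ `tree.support_cutoff` (default 50, inclusive); a support-only mode is
provided, and a majority-rule/strict consensus writer is available for
figures. Scoring support per species on the replicates is equivalent, at
the 50% threshold, to reading the species clade off a majority-rule
consensus, and avoids consensus-polytomy ambiguity.

## Gap and best-match resolution

The barcoding-gap criterion uses strict inequality: `min_inter >
max_intra`, with `min_inter` taken against all other samples in the data
set (not congeners only), and the percentage computed over multi-accession
species. Best-match identification emulates a standalone-BLAST search of a
self database with an in-process scorer — default a local alignment score
(BLAST-like best-hit semantics, ties at the top score), alternatively
p-distance over a pairwise global alignment — keeping the pipeline
hermetic. Each query's own record is excluded by sample id (not sequence
equality, so identical sequences from different specimens remain
legitimate hits). A query is correct when all top hits are conspecific,
ambiguous when the ties span species; a species is identified when all its
queries are correct (any-query and majority rules are selectable).

## Statistics

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
(k − 1 df); Dunn's post-hoc compares rank means under the pooled
tie-corrected variance, Bonferroni-adjusted by default (Holm and
unadjusted available). The Wilcoxon matched-pair test drops zero
differences and mid-ranks tied magnitudes; for ≤ 25 nonzero differences
the p-value is exact, computed from the full sign-flip distribution of the
signed-rank sum (a convolution equivalent to enumerating all 2^n sign
assignments), otherwise a normal approximation with continuity and tie
correction is used. Tests default to two-sided and report which side is
larger.

## Synthetic data generator

The generator emulates the structure of a barcode reference collection:
genera × species × accessions at one or more loci, with singletons and
per-locus dropout to exercise the set 2/set 3 partition and concatenation
intersection. Per locus, each genus gets an independent uniform-random
root sequence; species ancestors and accessions diverge on star
phylogenies (no coalescent), keeping expected distances closed-form.
Substitutions are Jukes–Cantor-style: each site mutates independently with
the branch probability, to a uniform choice of the other three bases.

Divergence parameters are *per-lineage realized divergences*: two
accessions of one species differ at ≈ 2 × `intra_divergence`
substitutions/site, and two accessions of congeneric species at
≈ 2 × `inter_divergence` (the species-ancestor branch therefore carries
`inter − intra`). This parametrization makes `intra == inter` collapse the
within- and between-species distance distributions onto each other —
the no-barcoding-gap regime — and keeps realized distances slightly below
their nominal values through back-mutation (≈ 1% relative at the default
rates). Defaults (10 species in 5 genera, 3 accessions, 600 bp, intra
0.005, inter 0.05) represent a clean congeneric study in which a usable
barcode should resolve everything.

Deliberately not simulated: concerted evolution and paralogy of ITS,
secondary-structure-driven error patterns, rate variation across sites,
and realistic base composition. Passing tests on this generator therefore
demonstrate the correctness of the pipeline's computations and the
qualitative behavior of the three methods, not the discrimination
percentages any particular real flora would yield — real data adds
alignment ambiguity and non-star genealogy that typically lower
resolution. The truth table accompanying each dataset records per-species
realized `max_intra`/`min_inter` computed on the substitution-only
sequences (before indels and ambiguities are applied), where p-distance is
well defined without alignment.

Quality-read generation wraps each sequence in a forward/reverse pair
overlapping by a configurable fraction of the template, with either a
clean QV profile (all 40) or noisy ends (terminal bases at QV 10) sized to
trigger the window-trimming rule.

## Problem sizes

The test suite and the acceptance script run the study at 10 species × 3
accessions and 600/400-bp loci with 200 bootstrap replicates, and average
the degraded intra = inter control over 20 generator seeds; these sizes
give stable percentages (resolution estimates move by at most one species,
10 points, between seeds) while keeping a full run in well under a minute
per locus. Larger collections are supported directly; bootstrap cost grows
as replicates × n³ for the NJ step.

## Known limitations

* The progressive aligner's consensus merging can misplace gaps between
  highly divergent groups (e.g. across unrelated genera); distances there
  are already saturated, so discrimination results are unaffected, but
  column-level alignments across genera should not be over-interpreted.
* NJ ties are broken by index order; on exactly tied Q values a different
  but equally optimal join order may exist.
* `best_match_identify` scores all query × reference pairs; for
  collections beyond a few thousand records an indexed search would be
  needed.
* The exact Wilcoxon path doubles mid-ranks to integers; with > 25 nonzero
  differences the normal approximation is used regardless of ties.
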