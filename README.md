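# barcodekit

Evaluation of candidate DNA barcode loci for species discrimination.

DNA barcoding identifies species from a short standardized DNA region
(for plants, typically *rbcL*, *matK*, the nuclear ITS region, ITS2, or
the *trnH-psbA* intergenic spacer). Before a locus can be recommended as
a barcode for a group of organisms, its discriminatory power must be
measured on a reference collection of specimens with expert-verified
species labels. `barcodekit` implements that desk evaluation as a
reusable, fully scriptable pipeline, aimed at researchers assessing
barcode markers on their own collections — from raw bidirectional Sanger
reads through per-locus and multi-locus species-resolution percentages.

## What it computes

Given per-locus FASTA files plus a sample metadata table (or a synthetic
dataset from the built-in generator), the pipeline:

1. **Screens sequence quality** — windowed QV trimming (terminal 20-bp
   windows with ≥ 4 bases below QV 20 are removed; a read must keep ≥ 60%
   of its length with mean QV ≥ 30), forward/reverse overlap coverage
   (> 70% of the consensus span), and the conserved 5.8S motif check that
   distinguishes plant ITS amplicons (`GAATTGCAGAATCC`) from endophytic
   fungal contaminants (`GAATTGCAGAATTC`).
2. **Builds the three analysis data sets** — set 1: all samples; set 2:
   species with ≥ 2 accessions; set 3: congeneric species each with ≥ 2
   accessions.
3. **Aligns** each locus (built-in progressive aligner, or pass-through of
   an external alignment) and concatenates loci over shared accessions.
4. **Computes uncorrected p-distances under pairwise deletion** — for rows
   *i*, *j*, `d_ij = n_mismatch / n_compared` over columns where both rows
   carry an unambiguous base — plus the usual summaries: % variable sites,
   % parsimony-informative sites, mean inter-/intra-specific divergence.
5. **Scores species discrimination by three methods**:
   * *barcoding gap* — species *s* is resolved iff
     `min_inter(s) > max_intra(s)`, its smallest distance to any other
     species strictly exceeding its largest within-species distance;
   * *NJ bootstrap monophyly* — species *s* is resolved iff its accessions
     are monophyletic in the neighbor-joining tree with bootstrap support
     ≥ 50% (column resampling, NJ per replicate);
   * *best match* — leave-one-out identification against a self database:
     every query scored against all other records, correct iff all
     top-scoring hits are conspecific; a species is identified iff all its
     queries are correct.
6. **Tests divergence differences** — Kruskal–Wallis with Dunn's post-hoc
   across loci, and the exact Wilcoxon matched-pair signed-rank test
   between each species' `min_inter` and `max_intra`.

## Worked example

```python
from barcodekit import (SyntheticSpec, generate, progressive_align,
                        distance_matrix, gap_resolution, best_match_identify,
                        bootstrap_support, species_resolution_tree,
                        divergence_summary)

spec = SyntheticSpec(n_genera=5, species_per_genus=2, accessions_per_species=3,
                     locus_lengths={"ITS": 600}, inter_divergence=0.05,
                     intra_divergence=0.005, seed=1)
collections, truth = generate(spec)
its = collections["ITS"]
aln = progressive_align(its)
dm = distance_matrix(aln)

summary = divergence_summary(dm, its.species_of)
print(f"mean intra-specific p-distance: {summary.mean_intraspecific:.4f}")
print(f"mean inter-specific p-distance: {summary.mean_interspecific:.4f}")

gaps, gap_pct = gap_resolution(dm, its.species_of)
print(f"barcoding-gap resolution: {gap_pct:.1f}% of {len(gaps)} species")

results = bootstrap_support(aln, its.species_of, n_reps=200, seed=1)
print(f"NJ-bootstrap resolution: {species_resolution_tree(results):.1f}%")

_, bm_pct = best_match_identify(its, its)
print(f"best-match identification: {bm_pct:.1f}% of species")
```

prints

```
mean intra-specific p-distance: 0.0091
mean inter-specific p-distance: 0.5529
barcoding-gap resolution: 100.0% of 10 species
NJ-bootstrap resolution: 100.0%
best-match identification: 100.0% of species
```

The simulated study has 10 species (5 genera × 2 congeners, 3 accessions
each). Within-species pairs differ at ≈ 2 × 0.005 substitutions/site and
congeneric pairs at ≈ 2 × 0.05, so intra- and inter-specific distance
distributions are cleanly separated and all three methods resolve every
species — the regime a good barcode locus should produce. Raising
`intra_divergence` to equal `inter_divergence` collapses the two
distributions and resolution drops toward zero.

A command-line interface mirrors each stage
(`barcodekit simulate | qc | partition | align | dist | gap | tree |
identify | stats | all`); `barcodekit all -c config.yaml` runs everything
from a YAML config and writes TSV/JSON/Newick/FASTA artifacts.

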