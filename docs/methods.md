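# Methods

## The problem

Back-translating a protein into a gene requires choosing one synonymous codon
per residue. Frequency-only codon optimizers pick each amino acid's most
frequent (modal) codon, which erases low-frequency ("rare") codons. In natural
genes, however, rare codons are often conserved and functionally relevant —
they modulate local translation speed and co-translational folding — and their
placement depends on the *peptide context*, not only on the amino acid.
`presyncodon` learns that context dependence from a host's coding sequences
and reproduces it at design time.

## Training corpus

Input is a nucleotide CDS FASTA. Validation drops records whose length is not
a multiple of 3, that contain ambiguity characters, or an internal stop codon
(a single trailing stop is removed). Three filters then build the
non-redundant corpus:

1. **Length**: genes must have strictly more than `min_codons` (default 100)
   sense codons.
2. **Redundancy**: proteins are clustered greedily, longest first; a sequence
   joins the first cluster whose founder shares more than
   `identity_threshold` (default 0.40) global identity, computed as matched
   columns / alignment length of a Needleman–Wunsch alignment (BLOSUM62, gap
   open 10, extend 1). This is the greedy incremental strategy CD-HIT uses,
   implemented internally so no external binary is needed and the result is
   deterministic (ties broken by lexicographic id). The exact CD-HIT word
   heuristics are not reproduced; at the 40% level the partition on
   well-separated families is the same as single-linkage components (tested).
3. **Homolog count**: only clusters with at least `min_cluster_size`
   (default 3) members survive — singletons are likely horizontal-transfer or
   otherwise atypical genes. Each surviving cluster contributes one
   representative, its founder (the longest member; ties by id). "Typical
   gene" of a cluster is not otherwise defined, so representative-by-length
   is a deliberate, documented choice.

## Codon selection index (CSI)

Each corpus gene is split into sliding windows of w = 5 and 7 residues. For
each distinct fragment the CSI stores:

* the codon counts observed for the **middle** residue, and
* per fragment position, the mean background relative usage of the codons
  observed there (one scalar per position, averaged over occurrences).

Background usage is the per-amino-acid relative synonymous frequency (each
amino acid's codon frequencies sum to 1); this normalization, rather than
RSCU, keeps values in [0, 1] and comparable across amino acids. Fragments
whose middle residue is Met or Trp have no codon choice and are excluded.
Position means are stored rounded to 6 decimals, which makes the TSV
serialization a lossless round trip.

## Fragment matching and features

A query fragment is compared against every CSI fragment sharing its middle
residue with a positionwise substitution-matrix sum (BLOSUM62 by default,
middle position included): matched score *s*, maximal score *m* = the query's
self-score, matched percent *p = s/m*. Entries with *p* above a cut-off *c*
are selected; *c* = 1 is read as *p* ≥ 1 (exact matches pass — a strict
inequality would select nothing). Entries with *s* ≤ 0 are discarded; all
grid cut-offs are ≥ 0.7 so this never changes grid behavior. The precise
historical form of the *s/m* score is not documented, so the scoring matrix is
configurable; the defaults give *p* = 1 exactly for an identical fragment and
a meaningful 0.7–1 grid.

The classifier input for a middle amino acid with k synonymous codons is the
unweighted arithmetic mean of the selected entries' vectors: the normalized
middle-codon distribution (k values, codon-lexicographic) concatenated with
the per-position usage means (w values) — dimensionality k + w.

## Classifiers

One multi-class random forest per (degenerate amino acid × window × cut-off);
with windows {5, 7} and cut-offs {0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1} that is
a grid of 252 cells. The training label is the observed middle codon.
Positions with no CSI match above the cut-off are excluded from training and
handled by fallback at design time. Class imbalance is left untouched: the
label priors *are* the host's codon-usage signal.

* `n_trees` defaults to 200 (the CLI's `--full` flag restores 10,000);
  forest accuracy plateaus far below 10,000 trees at these dimensionalities
  (k + w ≤ 13).
* Every forest is seeded (per-cell seeds derived deterministically from the
  bundle seed) and fit single-threaded, so training, evaluation, and design
  are bit-reproducible.
* A single-label training set produces a constant predictor flagged
  `degenerate`.

Evaluation is seeded ten-fold cross validation, stratified by codon label
whenever every class has at least ten members (plain shuffled folds
otherwise). Note that CSI features are computed from the full corpus before
fold splitting — at *c* = 1 a position's feature contains its own fragment's
codon distribution — so CV accuracy rises toward 1 as the cut-off grows.
That trend — accuracy increasing with cut-off and window size — is a
property of the method itself, not of this implementation.

## Gene design

For an input protein: positions 1–2 and n−1–n come from positional codon
tables (the modal codon per amino acid at those positions across the corpus;
ties broken by higher background usage, then lexicographically). Met/Trp
positions are emitted directly. Every other position takes the w-residue
window centered on it and walks a descending cut-off cascade (default 0.9,
0.8, 0.7): the first cut-off with both a trained model and at least one CSI
match wins; its model predicts the codon. If the cascade is exhausted — or
the window does not fit near the termini, or a table cell is absent — the
position falls back to the host's modal codon. The original service does not
document the served (window, cut-off) combination or the no-match behavior;
the cascade (long window, large cut-off first, always-emitting fallback) is
this package's design, fully configurable. No stop codon is appended unless
requested.

The one invariant everything else defers to: the designed DNA translates back
to the input protein exactly; it is asserted at the end of every design call
and fuzz-tested.

## Synthetic data

The generator emulates what the pipeline needs from real genomes, with known
ground truth:

* **Families**: founder proteins drawn uniformly (Met-initial), members are
  point-mutated copies. The default within-family mutation rate is 0.02 —
  family members model orthologs across strains of a single species, which is
  what multi-genome same-species corpora contain — so the ≥3-homolog cluster
  filter is exercised rather than bypassed (the founder, generated unmutated
  as member 0, is the representative that survives).
* **Background**: per amino acid, codon frequencies decay geometrically with
  ratio 3/7 over lexicographic order, giving 0.7/0.3 for two-codon amino
  acids — so "rare codon" is meaningful.
* **Planted rules**: a rule (target amino acid, neighbor offset, trigger
  residue, codon-if-trigger, codon-otherwise, strength) fixes the codon
  choice at context positions with known probability. Strength 1.0 is
  deterministic; 0.5 carries no signal. The built-in set plants six rules
  that switch two-codon amino acids to their rare codon next to a common
  neighbor, at offsets ±1 and ±2 (within both window sizes). Every
  rule-governed position is written to a truth table that can be re-derived
  from the sequences alone.

What the generator does **not** model: phylogenetic tree structure, indels,
GC/amelioration gradients, expression-level covariates, and genuine biological
context rules beyond single-neighbor triggers. Passing tests therefore show
that the pipeline recovers context-dependent codon choices it was given, at
the stated strengths and divergences — not that any particular host has such
rules of that form.

## Recovery evaluation

`evaluate_recovery` designs held-out family members and scores rule-governed
positions: agreement with the codon actually used (recovery), with the rule
codon, and with the context-free modal baseline. Only model-eligible
positions count — interior positions where the design window fits; gene
termini are designed from positional tables and window-edge positions by
fallback, by the method's construction, so they say nothing about the context
models and are reported separately as excluded. Evaluation sets use 20
held-out members per family (>1000 rule positions), sizing the recovery
estimate's sampling noise (~2 points) well inside the 5-point comparisons the
tests make.

Expected values under the defaults: at strength 1.0, recovery ≈ 0.96 — the
shortfall from 1.0 is dominated by mutation-created contexts absent from the
founder (≈ 1 − 0.98² ≈ 4% of positions, where the best available match
carries background rather than rule information). At strength 0.5, recovery
equals the baseline: there is nothing to learn.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale study conditions
chosen once: a 150-gene corpus (30 families × 5 members, 110–200 codons),
50-tree forests for grid-level runs, 20-tree forests for unit-level runs.
Tolerances on stochastic checks are set from binomial noise at the realized
sample sizes. Ties anywhere (modal codons, match ranking, cluster joining)
are broken lexicographically for determinism. Degenerate inputs (empty
corpus, empty match set, single-label cells, proteins shorter than the
window) each have a defined behavior rather than an error wherever the
pipeline's contract requires an output — the design path always emits a
full gene.

## Known limitations

* Standard genetic code only (translation table 1).
* The *s/m* score is a reconstruction (see above); other reconstructions can
  be explored via the configurable matrix but are not implemented.
* Greedy clustering approximates CD-HIT, not bit-for-bit.
* Corpus sizes and absolute cross-validation accuracies for real hosts
  depend on multi-genome downloads and are out of scope;
  only the qualitative trends are asserted, on synthetic corpora.
* Design throughput is adequate for desk use (hundreds of proteins per
  minute at desk-scale CSIs); no large-scale index precomputation is done.
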