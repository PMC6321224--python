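# presyncodon

Context-dependent synonymous codon usage learning and host-tuned
back-translation of proteins into genes.

## Why

Of the 20 standard amino acids, 18 are encoded by multiple synonymous codons,
and every genome uses them with a strong bias. Conventional codon optimizers
back-translate a protein by picking each amino acid's most frequent codon in
the expression host — which systematically erases low-frequency (**rare**)
codons. But rare codons are often evolutionarily conserved at specific
positions, where they tune local translation speed and co-translational
folding. Which codon a natural gene uses at a position depends not just on
the amino acid but on its **peptide context**.

`presyncodon` learns that context dependence from a host's coding sequences
and reproduces it when designing new genes, for anyone building heterologous
expression constructs who wants host-like codon choices — including the rare
ones — rather than a wall of modal codons.

## Method

1. **Corpus** — validate CDS records, drop genes of ≤ 100 codons, cluster
   proteins at 40% global identity (greedy longest-first, Needleman–Wunsch /
   BLOSUM62), keep one representative per cluster with ≥ 3 homologs.
2. **Codon selection index (CSI)** — slide windows of w ∈ {5, 7} residues
   over every gene; for each distinct peptide fragment record the codon
   distribution of the middle residue and the mean background usage per
   position.
3. **Matching** — score a query fragment against every same-middle CSI
   fragment: matched score *s* (positionwise BLOSUM62 sum), maximal score
   *m* (query self-score), matched percent *p = s/m*. Fragments with *p*
   above a cut-off *c* contribute; the feature vector is the arithmetic mean
   of their coding vectors and has dimension *k + w* (*k* = number of
   synonymous codons of the middle amino acid).
4. **Models** — one multi-class random forest per (amino acid × window ×
   cut-off): 18 × 2 × 7 = 252 models per host, labels = the observed middle
   codon, evaluated by seeded ten-fold cross validation.
5. **Design** — termini from positional codon tables (modal codon at the
   first/last two gene positions), Met/Trp fixed, every other position
   predicted through a descending cut-off cascade (0.9 → 0.8 → 0.7) with a
   modal-codon fallback. The designed DNA always translates back to the
   input protein exactly.

A synthetic-data module generates family-structured corpora with **planted
context rules** (e.g. "Lys before Pro uses AAG") of known strength, so every
stage is testable against known answers without downloading genomes.

See `docs/methods.md` for assumptions, parameter choices, and limitations.

## Worked example

Train on a synthetic host whose genes follow a deterministic context rule
("K before P → AAG, the rare codon"), then design a held-out homolog of one
of its gene families:

```sh
presyncodon simulate --families 12 --members 5 --strength 1.0 --seed 42 \
    --eval-members 1 --out synth.fna --truth truth.tsv \
    --eval-out eval.fna --eval-truth eval_truth.tsv
# 60 genes, 70 rule-governed positions -> synth.fna

presyncodon build-corpus --cds synth.fna --out corpus.fna --report attrition.tsv
# length_filter: 60 -> 60
# clustering: 60 -> 12
# cluster_size_filter: 12 -> 12
# representatives: 12 -> 12

presyncodon train --corpus corpus.fna --windows 7 --cutoffs 0.9,0.8,0.7 \
    --trees 100 --seed 7 --out bundle
# trained 54 / 54 grid cells (0 skipped) -> bundle

# homolog.faa holds the protein of held-out gene fam003_e00 (from eval.fna)
presyncodon design --protein homolog.faa --bundle bundle \
    --out designed.fna --report design.tsv
# fam003_e00: 110 aa, 5 rare codons, sources {'model@0.9': 0.664,
#   'non-degenerate': 0.136, 'model@0.8': 0.082, 'model@0.7': 0.073,
#   'fallback': 0.036, 'tail-table': 0.009}
```

The per-position report around the planted context (`design.tsv`):

```text
record      position  amino_acid  codon  source          background_usage  rare
fam003_e00  98        N           AAC    model@0.9       0.694118          False
fam003_e00  99        K           AAG    model@0.9       0.308511          False
fam003_e00  100       P           CCA    model@0.9       0.703297          False
```

At position 99 the designed gene uses **AAG** — the host's rare Lys codon
(background usage 0.31) — because the next residue is Pro, exactly the
planted rule; the gene's other Lys positions get the modal AAA. A
frequency-only optimizer would emit AAA everywhere. Two thirds of the
positions were predicted by the strictest (c = 0.9) models because the
held-out protein is ~98% identical to a training family; unrelated proteins
fall back to modal codons, which is the designed behavior when the host
corpus carries no context information.

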