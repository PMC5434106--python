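# hcbprimer

Evaluating how well universal bacterial 16S rRNA gene PCR primer pairs
detect obligate hydrocarbonoclastic bacteria (HCB) — the marine genera
*Alcanivorax*, *Cycloclasticus*, *Marinobacter*, *Neptunomonas*,
*Oleiphilus*, *Oleispira*, *Thalassolituus* and *Thalassospira* that bloom
after oil spills and whose detection in amplicon sequencing surveys depends
entirely on primer coverage and correct taxonomic classification.

The package is aimed at microbial ecologists choosing primers for 16S
amplicon surveys, and at method developers who need every stage of such an
evaluation as a testable library:

1. **Curation** — dereplication, greedy centroid OTU clustering at 97%
   identity (representative = most abundant unique sequence), template-based
   alignment, and removal of alignment columns that are gaps in ≥ 90% of
   sequences.
2. **Phylogenetic validation** — neighbor-joining trees (Jukes–Cantor
   distances, bootstrap bipartition support) and the monophyly rule:
   sequences forming a monophyletic group with a genus's type strain on an
   outgroup-rooted tree are assigned to that genus.
3. **Primer evaluation** — perfect-match scanning of degenerate (IUPAC)
   primer pairs, in-silico amplicon extraction, per-genus coverage,
   amplicon size classes (small 100–400 bp, medium >400–<1000 bp, large
   ≥1000 bp), and the ≥95% per-taxon coverage filter.
4. **Classification testing** — a word-based naïve Bayesian genus
   classifier (8-mers, presence/absence) with bootstrap confidence, used to
   check that extracted amplicons classify back to the correct genus.
5. **Synthetic data** — a generator producing genus-labeled 16S-like
   reference sets with controlled divergence and engineered primer-binding
   sites, so every downstream number has a known truth.

## The core computations

**Perfect-match coverage.** A primer position with IUPAC code *c* matches a
target base *b* iff *b* ∈ set(*c*) and *b* ∈ {A,C,G,T} (an ambiguous target
base never counts as a perfect match — a conservative convention). A pair
covers a sequence when a forward site lies strictly upstream of a reverse
binding site with a plausible span; coverage of taxon *T* is
|matched| / |*T*|. The amplicon runs from the forward primer's 5′ position
through the 3′ end of the reverse binding site, so a pair named
`S-D-Bact-0343-a-S-15` / `S-D-Bact-0908-a-A-18` has a nominal span of
(908 + 18 − 1) − 343 + 1 = 583 bp.

**Naïve Bayes classification.** With n(w)/m_g(w) the number of training
sequences containing word w overall / in genus g, and N/M_g the sequence
counts:

    prior(w) = (n(w) + 0.5) / (N + 1)
    P(w|g)   = (m_g(w) + prior(w)) / (M_g + 1)

a query is assigned to argmax_g Σ_{w∈words(query)} log P(w|g); confidence is
the fraction of 100 bootstrap replicates (⌊|words|/8⌋ words each) agreeing
with the full-word call.

**Neighbor joining.** Saitou–Nei agglomeration on Jukes–Cantor-corrected
distances d = −(3/4)·ln(1 − 4p/3), with deterministic tie-breaking and
negative branch lengths clamped to zero (deficit moved to the sister
branch); bootstrap support = percentage of column-resampled replicate trees
containing the same bipartition.

## Worked example

`examples/evaluate_primer_coverage.py` engineers a three-genus reference set
in which 100% / 80% / 50% of each genus's sequences carry intact binding
sites for one medium-size primer pair, then recomputes coverage:

```
pair demo: nominal amplicon 583 bp, size class medium
pair_id          taxon  n_targets  n_matched  coverage
   demo    Alcanivorax         20         20       1.0
   demo Cycloclasticus         20         16       0.8
   demo   Marinobacter         20         10       0.5

pairs with >= 95% coverage for every genus: none
```

The recovered coverages equal the engineered fractions exactly, and the
pair fails the ≥95%-per-taxon filter because one genus sits at 50%.
The other scripts in `examples/` demonstrate the generator, tree building
with monophyly validation, amplicon classification (per-genus accuracy and
the ≥80%-confidence fraction), and the full pipeline
(`hcbprimer run --config run.cfg` is the CLI equivalent).

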