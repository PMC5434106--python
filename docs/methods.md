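# Methods

This note documents the models, conventions and numerical choices behind
hcbprimer, in the order the pipeline applies them.

## Synthetic reference sets

The generator emulates the statistical structure a primer-coverage analysis
relies on, not real rRNA biology. A root sequence of length L (default
1500 nt) is drawn uniformly over {A,C,G,T}; degenerate positions of each
configured primer-site motif are instantiated to one concrete base, which is
recorded. Each genus gets an ancestor derived from the root by independent
per-site substitutions with probability `between_genus_divergence` (default
0.15), uniform over the three alternative bases (Jukes–Cantor-like); tips
derive from their ancestor at `within_genus_divergence` (default 0.02), with
optional 1–3 nt indels at per-site rate `indel_rate` (default 0.005) on tip
branches. Defaults are five genera with 40 sequences each and one type
strain per genus — a desk-scale set on which genus structure is
unambiguous while the full machinery (clustering, trees, classification)
still has work to do.

Three deliberate shields make primer coverage an *engineered* quantity:

- primer-site intervals are excluded from background substitutions on every
  branch;
- indels never create, delete or split a site (insertions inside a site and
  deletions overlapping one are suppressed), so "perfect match" stays
  length-preserving and site coordinates are tracked exactly through indels;
- within each genus, exactly `round(fraction · n)` tips keep a perfect
  site; each remaining tip receives one substitution at a site position,
  drawn from *outside* the motif's degeneracy set, so the match is
  guaranteed broken. One per-genus tip permutation orders breakage across
  sites, so a pair built from two sites with equal fractions has coverage
  exactly equal to that fraction (and min of the fractions otherwise).

The truth table records every sequence's genus and every site's state and
post-indel coordinates. `expected_pairwise_identity` gives the exact
expected identity for the indel-free case from the 4×4 substitution
transition matrices (shielded positions contribute identity 1); for the
defaults it yields ≈0.961 within and ≈0.711 between genera. What passing
tests on these sets shows is that the *computations* are correct under the
assumed structure; real 16S data adds features the generator omits —
secondary-structure-driven conservation, chimeras, rate variation among
sites and lineages, intragenomic operon variants — so real coverage numbers
will differ even for a correct implementation.

## Curation

Dereplication collapses identical strings, sums abundances, keeps the
first-seen id, and OR-s the type-strain flag so anchors survive collapse.
Output order (descending abundance, then id) fixes the greedy clustering
order. Clustering is greedy centroid assignment: a record joins the first
centroid (founding order) with identity ≥ threshold (0.97 default), else
founds an OTU; `assign="best"` switches to highest-identity assignment. The
centroid is therefore always the most abundant unique sequence of its OTU.

Pairwise identity is computed from a global alignment (match +1, mismatch
−1, gap open −2, gap extend −1; Biopython's `PairwiseAligner`) as
matches / columns, excluding terminal-gap columns. Sequence-identity
thresholds like "97%" are only meaningful relative to such a dialect, so the
metric is stated here rather than treated as self-evident; the test suite
cross-checks the alignment scores against an independent Gotoh dynamic
program.

Template alignment is NAST-like: each record is globally aligned to the
ungapped template reference, record bases are projected onto template
columns, and insertions relative to the template are discarded (counted per
record). A record whose matching bases cover < 50% of its length is dropped
as unalignable. This preserves fixed coordinates so that column filtering —
removing columns that are gaps in ≥ 90% of rows, boundary inclusive — is
well-defined; identical post-filter rows are dereplicated again before tree
building.

## Phylogeny and genus validation

Distances use pairwise deletion (columns gapped in either sequence are
skipped per pair) and default to the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), consistent with the generator's substitution
model; saturated pairs (p ≥ 0.75) are an error rather than an infinity.
Neighbor joining follows Saitou–Nei with two determinism rules: Q-criterion
ties resolve to the smallest index pair in the current working order, and a
negative estimated branch length is clamped to zero with the deficit moved
to the sister branch (their sum is preserved). Bootstrap support resamples
alignment columns with replacement (default 100 replicates; 1000 mirrors
common practice at higher cost) and reports, per internal edge, the
percentage of replicate trees containing the same bipartition.

Genus validation roots the tree conceptually on the outgroup edge and takes
the smallest rooted clade containing all of the genus's type strains and
every leaf labeled with the genus. The genus is monophyletic if no leaf of
a *different* labeled genus sits inside; genus-unlabeled leaves never break
monophyly (environmental sequences typically lack genus labels, and clade
membership is precisely how they get their genus call). On failure the
conservative fallback selects only the type strains themselves. Validated
taxon sets then expand each selected OTU representative to all of its OTU
members.

## Primer evaluation

Perfect-match semantics: a primer base matches a target base iff the target
base is a concrete A/C/G/T within the primer code's set. Ambiguity codes in
the target never match (`target_ambig="compatible"` offers set-intersection
semantics for sensitivity analyses). Antisense primers are scanned as their
IUPAC reverse complement on the sense strand. Amplicons span from the
forward primer's 5′ position through the 3′ end of the reverse binding site
— both binding regions included, which is what makes the recommended pair's
nomenclature positions (343/908, lengths 15/18) give 583 bp. When multiple
site pairs are valid, the shortest span wins (shorter products amplify
preferentially), ties to the smallest forward position; spans outside
[50, 3000] bp are rejected as pathological.

Size classes follow the published grouping — small 100–400 bp, medium
>400–<1000 bp, large >1000 bp — which leaves exactly 1000 bp unassigned; it
is placed in `large` here. Classes come from the nominal (name-derived)
length when the nomenclature parses, else from the median realized amplicon
length over matched targets. The coverage filter keeps pairs at ≥ 95%
(inclusive) for *every* target taxon; survivors are re-scored against the
entire reference set as a whole-community check. Histograms bin coverage
into [0,10), …, [90,100] percent with the top bin closed. The recommended
pair is the medium-class survivor with the highest mean per-taxon coverage,
ties to the smaller nominal amplicon.

## Classification

The classifier is a word-presence naïve Bayes over 8-mers with the joint
smoothing prior(w) = (n(w)+0.5)/(N+1) and
P(w|g) = (m_g(w)+prior(w))/(M_g+1); scores are summed logs over the query's
*distinct* words, ties broken lexicographically. Confidence bootstraps
⌊|words|/8⌋ words per replicate (100 replicates); each query's generator is
seeded from (run seed, CRC32 of the sequence id) so batch results do not
depend on processing order. Word size 8, the one-eighth subsample and 100
replicates are the classic defaults for this family of rRNA classifiers.
Evaluation dereplicates amplicons first, reports per-genus accuracy and the
share of correct calls at ≥ 80% confidence, and counts genera absent from
the model as incorrect. Training uses full-length sequences; evaluated
amplicons are proper substrings, so train and test sets never share a
sequence.

## Determinism and problem sizes

All randomness flows from explicit seeds (one per generator config, one per
pipeline run); reruns are byte-identical, including SVG figures (fixed hash
salt, no timestamp metadata). Tests and examples run on sets of roughly
3–5 genera × 8–40 sequences of 400–1500 nt with 10–100 bootstrap
replicates — sizes at which every stage completes in seconds while leaving
the statistical structure (OTU splitting, imperfect sites, indel jitter)
non-trivial.

## Known limitations

- No chimera detection; inputs are assumed chimera-free.
- No mismatch-tolerant or thermodynamic (Tm/ΔG) primer model — coverage is
  strictly perfect-match, which is conservative.
- Maximum-likelihood tree inference is out of scope; NJ with bootstrap is
  the supported method.
- The classifier handles the genus rank only and trains in memory.
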