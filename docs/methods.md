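# Methods

`taxodelim` implements the multi-metric procedure used in modern bacterial
taxogenomics to delimit species, subspecies and genera among type strains,
together with a synthetic-clade generator that makes the whole procedure
testable at desk scale.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## The delimitation procedure

Five metrics are computed per strain pair and combined by fixed, inclusive
thresholds:

| metric | statistic | rule |
|---|---|---|
| 16S rDNA | percent identity of the aligned gene | < 98.6% ⇒ different species (exclusion only); ≥ 94.5% required within a genus |
| 4-gene MLSA | percent identity of concatenated partial 16S/gyrB/rpoB/rpoD | ≥ 97% ⇒ same-species candidate |
| ANIb | mean identity of accepted 1020-nt fragment hits, bidirectional mean | ≥ 95% ⇒ same species |
| dDDH(-style) | logistic of pooled genome distance (surrogate) or external values | ≥ 70% species, ≥ 80% subspecies |
| POCP | 100·(C1+C2)/(T1+T2) conserved proteins | ≥ 50% ⇒ same genus |

Pair verdicts follow a strict precedence: genomic metrics (ANIb, dDDH) are
individually sufficient; MLSA decides only when no genomic metric is
present (and is flagged "MLSA-only"); 16S can only exclude.  Conflicts
(e.g. MLSA ≥ 97 with ANIb < 95) are resolved in favor of the genomic
metric and recorded on the verdict, never discarded.

Rank partitions are dendrogram cuts: single-linkage clustering of the
percent-similarity matrix at the rank threshold (any chain of pairs at or
above the cutoff shares a cluster).  Complete linkage is available by
option for users who want non-chaining semantics.  Subspecies are cut at
dDDH 80 *within* each species cluster, so subspecies nest inside species
by construction.  Genus clustering on POCP can be gated on 16S ≥ 94.5%,
and pairs within ±3 points of the POCP cutoff are flagged as borderline.

Synonymy: within any cluster holding two or more type strains, the name
with the earliest publication year is senior; every other type-strain name
is listed as a later heterotypic synonym of it.  Year ties are broken
alphabetically and flagged rather than silently resolved.

## Alignment engines

*MLSA.* Markers are aligned pairwise (not by MSA) with global affine-gap
dynamic programming (match +1, mismatch −1, first gap column −5, later
columns −2; Biopython's PairwiseAligner).  Identity counts only columns
where both sequences have a residue, so terminal and internal gap columns
are excluded from the denominator, and IUPAC ambiguity codes match only
when the letters are equal.  Per-pair marker alignments are pooled by
summed columns in the fixed order 16S, gyrB, rpoB, rpoD — a concatenation,
so longer markers weigh more, rather than an average of per-marker
percentages.  Jukes–Cantor distances d = −(3/4)·ln(1 − 4p/3) are defined
for p < 3/4; saturated pairs raise an explicit error.

*ANIb.* Query genomes are cut into consecutive non-overlapping 1020-nt
windows (trailing fragment kept only if ≥ 100 nt; fragments never span
FASTA record boundaries).  Each fragment is searched on both subject
strands by exact 15-mer seeding; candidate diagonals (up to 4 per strand,
ranked by seed count) get a banded (±32) affine Smith–Waterman extension
(match +1, mismatch −3, gaps 5/2), implemented as one numba kernel shared
with the protein search.  Subjects up to 5 kb skip seeding and run the
exhaustive DP, which is also the reference the test oracles compare
against.  A fragment is accepted when its best hit reaches ≥ 30% identity
over ≥ 70% of the fragment length — the established ANIb convention; the
cited source for the procedure states only the 95% species cutoff.
One-way ANI is the mean identity of accepted fragments; the reported ANIb
is the arithmetic mean of the two directions, which makes it exactly
symmetric.  When a direction accepts no fragment (far beyond genus range)
the ANI is reported as undefined, never as a number.

*POCP.* Proteins are compared by Smith–Waterman with BLOSUM62 and
BLAST-style gaps (open 11, extend 1), prefiltered by shared exact 4-mers
(`exact=True` disables the prefilter).  E-values use ungapped
Karlin–Altschul statistics for BLOSUM62 (λ = 0.3176, K = 0.134) with the
subject proteome's residue total as database size — an approximation when
applied to gapped scores, acceptable because accepted orthologs sit many
orders of magnitude below the 1e−5 bound.  A hit is conserved at
E ≤ 1e−5, identity ≥ 50% and query coverage ≥ 50%; the coverage term comes
from the original definition of the index and can be switched off
(`coverage_filter=False`) to apply the bare E-value/identity wording.
Both modes are tested.  Strong proteome-size asymmetry (ratio > 1.5) is
flagged, not corrected.

*Surrogate dDDH.* The pipeline the procedure imitates obtains dDDH from an
external service whose regression model is not public here, so the package
computes a clearly labeled surrogate: distance = 1 − Σmatches/Σcolumns
over all accepted ANIb hits of both directions, mapped through a fixed
logistic 100/(1 + exp(s·(dist − m))) with steepness s = 32 and midpoint
m = 0.065.  The constants were chosen from band geometry so that the 70%
species bound sits near identity 96% (consistent with ANIb 95) and the
70–80% subspecies band is wide enough in distance (p ≈ 0.022–0.039) to be
robust to sampling noise on ~50-kb genomes; they encode no information
from any published dDDH value.  Identical genomes map to the configured
maximum 100/(1 + e^(−s·m)) ≈ 89%, not 100.  Every output column is named
`ddh_surrogate`, and externally computed dDDH always takes precedence in
the decision engine.

## Trees

Neighbor-joining uses the canonical Q-criterion with deterministic
tie-breaking (lexicographically smallest pair of cluster representatives),
so identical matrices give identical trees on any platform.  Negative
branch-length estimates are clamped to zero with the deficit moved to the
sister branch.  NJ is exact on additive matrices; the tests verify
recovery of topology and branch lengths to 1e−9 and cross-check against an
independent NJ implementation.  Bootstrap support resamples alignment
columns of the concatenated markers (or whole markers, by option),
recomputes matrix and tree per replicate, and reports the percentage of
replicates containing each internal bipartition; column resampling
requires equal per-marker lengths across strains (positional homology),
which indel-free simulated data satisfies by construction.  Saturated
replicate p-distances are capped at 0.7499 with a warning rather than
aborting a run.  Midpoint rooting places the root halfway along the
longest leaf-to-leaf path, with lexicographic tie-breaks and a warning
fallback for all-zero branch lengths.

## The synthetic clade generator

The generator emulates exactly the regimes the thresholds operate on:

* Sites evolve under Jukes–Cantor — the model the distance machinery
  assumes — so observed identity has the closed form
  1/4 + (3/4)e^(−4d/3) and parameter recovery is a closed loop.
* Protein-coding genes (default 200 per ancestral genome, 50–150 codons,
  start/stop codons enforced, internal stops resampled without changing
  the per-site substitution probability) are lost per branch with
  probability 1 − (1 − p_loss)^L and gained as novel random genes at a
  Poisson rate per unit branch, so POCP declines with divergence.
* Four marker genes (1300/800/900/750 nt) persist in every leaf; 16S
  evolves at 0.1× the genome rate, reproducing its notorious lack of
  resolution below the genus level.
* Genomes are assembled as genes plus markers, each followed by its own
  50-nt neutral spacer.  Spacers are independent sequences per element:
  an earlier design with one shared spacer sequence repeated at every
  junction made whole-genome identity inherit the sampling noise of just
  50 sites, which is why the per-element choice matters.
* Randomness: one master seed; each branch derives its stream by stable
  hashing of (seed, sorted leaf set below the branch), so a subtree's
  sequences do not depend on traversal order.

The documented fixture plants 2 genera × 3 species × 2–3 strains
(15 genomes): within-subspecies paths 0.012 substitutions/site, between
subspecies 0.032, between species ≈ 0.16, between genera ≈ 0.78, with
gene loss 0.7 and gain 5 per unit branch.  At these settings ANIb
resolves 98.8 / 97.0 / 85 / undefined, the surrogate dDDH ≈ 85 / 75 / <1,
MLSA ≈ 99.5 / 97.9 / 90.5, and POCP ≈ 99 / 92 / 85 / ~0 — every rank
boundary is crossed with multi-sigma margins, so exact partition recovery
is informative rather than fragile.

**What passing does not show.**  The simulator has no indels,
recombination, horizontal transfer, rate variation across genes, or
GC-content structure; alignments of real assemblies face all of these.
Calibration results (ANIb within 0.5 points of the JC closed form) are
statements about the engine under the model, not about agreement with any
external ANI implementation on real genomes.  Cross-genus ANIb being
*undefined* (no accepted fragments) is a faithful property of
fragment-acceptance ANIb at such distances, and the clustering layer
treats missing pairs as below-cutoff only when explicitly allowed.

## Numerical and edge-case choices

* All rank cutoffs are inclusive (≥ keeps the pair together), applied
  uniformly.
* Bidirectional ANIb is computed once from both one-way means, so
  anib(A,B) and anib(B,A) are bit-identical; strand invariance is exact
  when genome length is a multiple of the window and only approximate
  otherwise, because reverse-complementing a genome shifts its own
  fragment grid (a property of the windowing convention itself).
* Distance matrices are validated for symmetry (1e−8), diagonal and sign
  on construction; NaN entries are legal only in percent mode and only
  consumers that opt in may treat them as below-cutoff.
* Missing markers are a hard error per pair; `allow_missing` downgrades
  the pair to a flagged 16S-only comparison.
* Empty proteomes yield conserved count 0 with a warning; POCP with
  T1 + T2 = 0 is an error.
* The acceptance-style calibration of ANIb against the JC closed form
  uses uniform marker rates, because with the default slow 16S the genome
  legitimately contains a conserved block that lifts whole-genome
  identity above the uniform-rate expectation.

## Problem sizes

The shipped analyses and tests run the full 15-genome fixture with
200-gene ancestral genomes (~45–50 kb per leaf), 105 ANIb pairs and 210
directed proteome searches; bootstrap examples use 100 replicates.  These
sizes make the complete closed loop — simulate, measure, delineate,
compare to truth — run in a few minutes on one CPU while keeping every
statistical margin wide enough to be meaningful.
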