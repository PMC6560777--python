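# Methods

This note documents the models, rules and numerical choices behind
`pangloss`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Ortholog detection

Pairwise similarity is a global Needleman–Wunsch alignment under BLOSUM62
with affine gap costs (open −11, extend −1), normalized by the
self-alignment score of the shorter sequence.  The normalized score is
clamped to [0, 1]; identical sequences score exactly 1, and unrelated
random proteins typically score below 0.2.  Orthology uses reciprocal
best hits (RBH): a cross-proteome pair is kept only when each member is
the *unique* top hit of the other and the score reaches the threshold
(default 0.5).  Ties for best hit exclude the protein — a deliberate
strict reading of reciprocal uniqueness that avoids arbitrary paralog
pairings.  Clusters are connected components of the RBH graph; proteins
without edges become singleton clusters, so the cluster set is always a
partition of all proteins.  Cluster ids are the lexicographically
smallest member, which makes output stable across runs.

Two scale-dependent conventions used by database-search pipelines are
intentionally replaced here by deterministic, size-independent
equivalents: an E-value cutoff (whose meaning depends on database size)
becomes the normalized-score threshold, and Markov clustering becomes
connected components, which coincides with MCL on the low-noise graphs
this package targets.  Real MCL or OrthoMCL output can be substituted at
any time through the `groups`-file reader, which is format-compatible.

## Pan-genome partitioning

"Present" always means count ≥ 1.  Species sequenced as multiple strains
are collapsed by presence-OR (count-maximum) before core and specificity
tests, so the unit of the core genome is the species, not the strain.
The subset-specificity rule is *all-but-one*: a cluster is specific to a
taxon subset if it is present in at least |subset|−1 of its members and
absent from every taxon outside.  Clade-distribution categories are
assigned with the fixed precedence genus-wide > multi-clade > clade-only
> species-only, because the underlying column definitions overlap and a
deterministic assignment is needed for a partition.  The per-species
summary's "two species from each clade" criterion requires every ingroup
clade to contribute ≥ 2 species simultaneously; a flag
(`require_all_clades=False`) switches to the per-clade reading, since
either interpretation is defensible.

Exclusive intersection counts follow the UpSet convention: for each
non-empty combination of named taxon groups, the number of clusters
hitting every included group and no excluded group.  These counts sum to
the number of clusters present in at least one group, which the tests
verify against brute-force enumeration.

Report rounding: shares and strain-difference percentages are printed as
integers (matching the precision such tables are usually published at);
everything else is left at full precision in the TSVs.

## Orphan genes and chromosome geometry

Orphans are defined set-theoretically at three scopes: genus (present in
every ingroup species, absent from every outgroup — hence a subset of the
core genome), clade (subset-specific to the clade, which automatically
excludes outgroups), and species (clusters whose members all belong to
one taxon, including unclustered singletons).

A chromosomal orphan cluster is a maximal run of ≥ 2 orphan genes
consecutive in gene order (ordinals assigned by start coordinate).  By
default no intervening non-orphan gene is tolerated; `max_gap` exposes a
looser reading because published descriptions of such clusters rarely
state the adjacency rule.  Multi-copy orphans count once per locus.

Subtelomeric classification uses the gene midpoint: a gene is
subtelomeric when min(midpoint, L − midpoint) ≤ window (default 100 kb,
inclusive boundary), with 1-based inclusive coordinates.  The midpoint
rule avoids double-counting genes straddling the window edge.

## SSCP classification

The filter is: length < 300 residues (strict), cysteine fraction ≥ 5%
(inclusive), secreted.  Unknown residues (X) are excluded from cysteine
counts.  Within the filtered set, class-II-type hydrophobins are proteins
with exactly 8 cysteines whose 2nd/3rd and 6th/7th cysteines form
directly adjacent CC doublets — the canonical class-II motif; "pairs" is
interpreted as adjacency, the strictest reading.  Cerato-platanins are
filtered proteins with exactly 4 cysteines; the homology-confirmation
step that published pipelines add is out of scope, so counts on real data
are upper bounds.  Remaining filtered proteins are generic SSCPs; classes
are mutually exclusive with precedence hydrophobin > cerato-platanin >
sscp.  Hydrophobin subtypes (class II vs pseudo-class I) are not
distinguished — no published rule separates them — but an inter-cysteine
spacing profile is emitted for manual inspection.

Secretion is decided by a deterministic N-terminal heuristic modelled on
the classic tripartite signal-peptide architecture: a positively charged
n-region (≥ 1 K/R in positions 1–5), a hydrophobic h-region (8
consecutive residues within positions 6–25 with ≥ 6 of A,I,L,M,F,V,W),
and small residues (A,G,S) at the −3/−1 positions of a cleavage site
placed three residues after the h-region.  Sequences shorter than 25
residues are non-secreted by definition.  This is a transparent,
reproducible stand-in for dedicated predictors; external per-protein
calls can be supplied as a TSV and then override the heuristic
(recorded as `source=external`).

## Gain/loss reconstruction

Ancestral family states on the dated tree are reconstructed by Wagner
parsimony via the Sankoff dynamic program.  Presence mode uses binary
states with unit change cost; count mode uses integer states 0..max
observed with cost |i−j|.  The minimal total cost is exact (verified
exhaustively against enumeration of all internal-state assignments on
every rooted tree shape with ≤ 6 leaves).  Among minimal reconstructions
the smaller state is preferred at the root and at each child given its
parent — a deterministic tie-break that places gains as late as possible
and never invents ancestral presence without support.  Per-branch gains
and losses are parent→child state increases and decreases; rates are
(gains + losses)/branch length in Mya, with zero-length branches reported
as NaN rather than infinity.

Dollo parsimony is provided for characters unlikely to arise twice (such
as orphan families): one gain at the MRCA of the possessing taxa, losses
at the stems of the maximal possession-free subtrees beneath it.  A gain
at the root itself is an event with no branch row.

This is a deliberate parsimony treatment: no birth–death rate (λ)
estimation and no family-wise significance filtering is performed.
Parsimony is a lower bound on the true event count, so branch rates are
conservative; simulated gain-only histories are nonetheless recovered
exactly, and mixed histories are reconstructed at cost ≤ the true event
count.

## Molecular evolution

Amino-acid distances: p is the proportion of differing sites after
pairwise deletion of gap/X columns (pairwise, not complete, deletion —
the operations only ever see two sequences).  Poisson correction
d = −ln(1−p); gamma-rates correction d = α((1−p)^(−1/α) − 1), default
shape α = 4, which is decreasing in α and converges to the Poisson form.
The ortholog similarity matrix reports mean 100·(1−p) over single-copy
clusters per taxon pair — i.e. percent identity, labelled as such, with
unequal-length members globally aligned first.

dN/dS uses Nei–Gojobori (1986) counting: per codon, each position
contributes one site split into synonymous/nonsynonymous fractions over
the mutations that do not create a stop codon; site totals are averaged
over the two sequences.  Observed differences at codons differing at 2–3
positions are averaged over all shortest substitution pathways that avoid
stop intermediates (with stop-crossing pathways admitted only if every
pathway crosses a stop).  pN and pS are Jukes–Cantor corrected,
dX = −(3/4)ln(1 − (4/3)pX); ω = dN/dS is undefined at dS = 0 and the
correction raises an error at saturation (pX ≥ 3/4).  The implementation
is verified to 1e-9 against an independent pathway-enumeration oracle.
A codon-model maximum-likelihood estimator would give different absolute
values on real data; the purifying/neutral/diversifying classification
(thresholds 1 ± τ, τ = 0.1) is the quantity this package relies on, and
it is recovered correctly from simulations at both ω = 0.1 and ω = 1.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume,
with full truth labels:

* **Family evolution.**  Families present at the root (default 40) evolve
  down the tree; on a branch of length b a family is lost with
  probability 1 − exp(−λb) (at most one loss per family per branch — a
  presence/absence simplification adequate for presence truth) and new
  families arise as Poisson(γb).  Defaults γ = 0.05, λ = 0.002 per family
  per Mya give a handful of events across the ~250-My default tree.
  Planted categories force presence patterns and are never lost: 10 core
  families in every leaf, 6 genus orphans in every ingroup leaf and no
  outgroup, 4 families per clade, 2 orphans per ingroup species.
* **The default tree** is ultrametric with three ingroup clades of two
  species each (one species as two strains splitting 2 Mya), an ingroup
  crown at 60 Mya and outgroups at 200/250 Mya — the shape of a
  multi-clade genus compared against family-level outgroups.
* **Proteomes.**  Every family draws an independent random ancestral
  sequence (mean length 120); each member substitutes sites with
  probability 1 − exp(−s·path) where path is the origin-to-leaf distance.
  Independence across families realizes the orphan property (no
  detectable similarity to outgroup proteins) for free.  The default
  s = 0.0005 substitutions/site/Mya keeps the deepest ortholog pairs at
  ~75–80% identity, comfortably detectable — mirroring the strong
  conservation of orthologs in real genus-level comparisons — while the
  members of one family still diverge measurably.  Divergence is a star
  from the family ancestor (no within-family phylogenetic correlation),
  which is sufficient for clustering truth but means the similarity
  matrix does not reproduce clade structure; it does respond
  monotonically to the divergence scale, which is what the tests check.
* **SSCPs** are planted with a signal-peptide prefix satisfying the
  heuristic, cysteines at controlled positions (adjacent doublets for
  hydrophobins, four spread cysteines for cerato-platanins), plus decoys
  failing exactly one criterion each (length exactly 300; < 5% cysteine;
  unsecreted).
* **Chromosome layouts** place orphan runs of requested sizes separated
  by filler genes, a chosen share of them with midpoints inside the
  100-kb window at either chromosome end; truth records the realized
  histogram and fraction.
* **Codon pairs** evolve from a random stop-free ancestor by proposed
  point mutations (Poisson(t/2 · sites) per lineage), rejecting stops and
  accepting nonsynonymous changes with relative probability ω.

Not emulated: indels and domain architecture, codon-usage bias,
within-family tree-correlated divergence, paralogs (one protein per
taxon per family), horizontal transfer, and genome-scale gene counts.
Tests passing on this generator therefore demonstrate the correctness of
the analysis logic under its stated definitions — not robustness to
annotation noise, alignment ambiguity or deep-divergence saturation in
real data.

All generator randomness derives from one integer seed split
deterministically per sub-generator (`SeedSequence([seed, stream])`), so
a fixed configuration reproduces byte-identical files.

## Problem sizes

The shipped study conditions are desk-scale by design: 9 taxa, ~120
families, ~55 proteins per taxon for the full-pipeline analyses;
exhaustive parsimony checks cover every rooted tree shape with ≤ 6
leaves; dN/dS recovery uses 10^4 codons for the neutral regime and 10^3
for the purifying regime, 20 replicates each; orphan-geometry recovery
uses 50 seeded layouts.  These sizes make every result reproducible in
seconds while still exercising each code path the definitions contain.

## Known limitations

* Connected-component clustering merges families linked by even one
  spurious RBH edge; at realistic noise levels MCL would be preferable
  (use the groups-file reader).
* The signal-peptide heuristic is a coarse stand-in; on real proteomes,
  supply external predictor calls.
* Parsimony undercounts events on long branches and cannot see
  gain-then-loss on the same branch.
* NG86 assumes no transition/transversion bias and no codon-usage bias;
  with kappa ≠ 1 simulations it is mildly biased, as expected.
* The strain-difference operation counts unclustered genes only when
  explicit per-strain totals are supplied, since a cluster table alone
  does not know about unclustered genes.
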