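# Methods

This note records the models, conventions and numerical choices behind
`gutcore`, in the order the pipeline applies them.

## Data model

An `OtuTable` is an integer read-count matrix (samples × OTUs) tagged with
the 16S marker it came from. Counts are never stored as fractions:
rarefaction requires integer reads, and every relative-abundance view is
derived on demand. The two markers ("V12", "V34") have disjoint OTU id
spaces; Greengenes-style 7-rank lineages are the only join key between
them, so taxonomy parsing enforces canonical rank order and records
unassigned ranks explicitly. Host metadata maps every sample to exactly one
species, and every species to exactly one genus, tribe, diet class and
origin (wild/lab); all grouping factors resolve through this table.

One master seed governs every stochastic stage. Each stage derives an
independent `numpy` generator keyed by a stage name (CRC-32 of the name as
a `SeedSequence` spawn key), so streams never interact and adding a stage
never perturbs another; with fixed inputs, config and seed the pipeline's
outputs are byte-identical across runs.

## Filtering

Two retention rules, applied per marker table: (i) keep OTUs occurring in
≥ 2 samples, plus single-sample OTUs with ≥ 4 reads — "more than three
reads" read strictly, exposed as a parameter; (ii) remove OTUs whose
lineage contains an excluded taxon name (default the phylum Cyanobacteria,
treated as chloroplasts of ingested material) unless the lineage also
matches an exception clade (default Melainabacteria, YS2, 4C0d-2 — the gut
Melainabacteria, which are genuine gut residents despite their Greengenes
placement). Both filters are idempotent and report per-rule removal lists.

## Rarefaction

Subsampling without replacement to a fixed depth is a multivariate
hypergeometric draw per sample (`Generator.multivariate_hypergeometric`),
so rarefied counts have exactly the hypergeometric distribution rather
than the multinomial approximation. Samples below the depth are dropped
with a logged warning by default (`error` mode available): depth 500 with
10 iterations is the default convention for desk-scale 454 data, and the
handling of too-shallow specimens is deliberately explicit because surveys
rarely state it.

## Rank aggregation

Aggregation at a rank sums OTU columns whose lineage labels agree at that
rank. Labels are lineage prefixes truncated at the rank; an OTU unassigned
at the rank keeps its maximal assigned prefix (the taxonomy-summary
convention), and only fully unassigned OTUs pool into an explicit
`unassigned` column. This makes aggregation path-independent (species →
phylum equals direct phylum aggregation) and keeps partially classified
taxa distinct in cross-marker matching, where `unassigned` is never allowed
to match.

## Diversity

Alpha: Chao1 bias-corrected by default, S_obs + F₁(F₁−1)/(2(F₂+1)), so
zero doubletons stay defined (classic form available); Shannon in log base
2 (bits), the convention of the classic amplicon toolchain; Faith's PD by
the whole-tree convention, i.e. the branch length of the minimal subtree
spanning the present tips *and the root*. All three are averaged over
independent rarefactions (default 10 × 500 reads).

Beta: binary Jaccard on presence sets; UniFrac computed by an explicit
edge walk over the rooted tree — unweighted is branch length unique to one
sample over branch length covered by either; weighted is Σ bᵢ|Aᵢ−Bᵢ|,
normalized by Σ bᵢ(Aᵢ+Bᵢ) by default (both variants exposed, since the
normalization choice in ordination comparisons is often unstated); and the
Manhattan distance on arcsin-√ transformed relative abundances. The arcsin
transform includes the square root (the variance-stabilising convention for
proportions) and is configurable, because "arcsin transformed" alone is
ambiguous. On raw fractions Manhattan equals exactly twice Bray–Curtis,
which the tests assert to 1e-12.

PCoA double-centres the squared distance matrix and eigendecomposes;
axes are ordered by eigenvalue, coordinates scaled by √λ over positive
eigenvalues, negative eigenvalues reported but never corrected, and
proportion explained computed over the positive spectrum. Procrustes
superimposes one ordination on the other (translation, rotation, scaling,
via `scipy.spatial.procrustes`), with M² the normalized residual sum of
squares in [0, 1]; significance permutes the row assignment of the second
configuration. UPGMA jackknife support is the fraction of rarefied
replicates whose average-linkage tree contains each clade of the full-data
tree.

All permutation and Monte-Carlo p-values use (b + 1)/(B + 1), which is
never zero and is exact under exchangeability; exhaustive enumeration
(PERMANOVA at small n) reports exact fractions instead. Boxplot distance
comparisons use Welch's unequal-variance t-test with Bonferroni
multiplication capped at 1 — the plain "two-sample t-test" leaves the
variance assumption unstated, and unequal group sizes make pooling
unattractive. The Mann-Whitney comparison of species-averaged alpha values
enumerates the exact null for pooled n ≤ 12 without ties and otherwise uses
the tie-corrected normal approximation; the rank-sum variant adds the
continuity correction and reports W in the R `wilcox.test` convention.

## Core microbiota

Prevalence thresholds use the ceiling, ⌈p·N⌉, so "at least 80%" is a hard
lower bound (with 25 wild fish, 20 individuals; floor mode available). The
in-scope population is wild individuals only — lab-reared fish are excluded
from core computation and from every permutation pool. Cross-marker
concordance applies to taxa only: OTU ids are marker-specific, so an
OTU-level intersection would be meaningless.

The core-length permutation test computes each species' observed relative
core length on its own n conspecifics (threshold ⌈p·n⌉) and a single
shared null of B = 1000 draws of five wild individuals without replacement,
species labels ignored — the draws are unconstrained, not forced to span
species, matching the plain reading of the procedure. Species with one
individual are excluded (no conspecific core exists). The p-value is
one-sided (core longer than chance), the direction the question is asked
in. Note the fixed draw of five makes species with n ≠ 5 conservative or
anticonservative relative to the null; calibration properties are therefore
asserted on species whose n equals the draw size.

Pairwise shared-OTU fractions use the Jaccard similarity convention
|A∩B|/|A∪B| — the natural symmetric choice where the denominator is
otherwise ambiguous — split into intra- vs inter-specific pairs and
compared by the continuity-corrected rank-sum test, with an optional tribe
scope filter.

## PERMANOVA and indicator values

PERMANOVA partitions Σd²/n into within- and between-group parts;
pseudo-F = (SS_B/(a−1))/(SS_W/(n−a)), R² = SS_B/SS_T, significance by free
label permutation (one-sided, large F), exhaustive when the label
orderings number no more than the requested permutations. The level-wise
battery runs aggregate → relative → arcsin√ → Manhattan → PERMANOVA at each
bacterial rank, plus presence/absence + Jaccard at the OTU level.

IndVal follows the original 1997 definition (no cluster-size correction):
A_ij from *mean relative abundances* per sample by default — library-size
robust — with raw-count means available since the original is stated on
abundance; both modes are tested against a brute-force oracle. Argmax ties
break lexicographically by cluster name and are flagged. Significance
permutes cluster labels freely over samples (a stratified scheme would also
be defensible; free shuffle is the simpler null and the one implemented).
The concordance filter retains taxa significant in both markers, assigned
to the same cluster in both, with IndVal ≥ 0.6 in at least one.

## Synthetic communities

The generator emulates the statistical structure of a small wild-fish
survey, not its sequences (no reads, chimeras or PCR error): 30 gut
samples — five Perissodini species with 5/4/5/5/1 wild individuals, a wild
outgroup species (5) and a lab population of the same species (5) — and two
markers. Per sample, a relative-abundance vector is assembled: a dominant
OTU whose share is Beta-distributed with mean 0.30 (concentration 30);
19 further family-core OTUs present with probability 0.99 in every fish;
17 species-core OTUs per species present with probability 0.9 in
conspecifics (leak 0.03 elsewhere); 350 shared accessory OTUs at presence
0.25; 30 outgroup-exclusive taxa (presence 0.6, wild outgroup only,
including a YS2/Melainabacteria-like clade); 8 Clostridium-like taxa whose
abundance is multiplied 3× in scale-eater samples and renormalized
(a quantitative, not qualitative, diet effect); and 150 sparse noise OTUs
(presence 0.02, minute weight — mostly singletons, one fifth with
chloroplast lineages so the taxon filter has real work). Counts are a
single multinomial draw per sample and marker at a log-normal library size
(median 8000 reads, σ = 0.5); the dominant share is imposed after each
marker's dropout so the parameter means "share of this library's reads".
Presence-weight magnitudes (log-normal weights per compartment) are
order-of-magnitude choices, not fitted values.

With these defaults the planted conspecific cores come out at 13–15% of
each species' observed OTUs and the dominant OTU at ~30% of reads — the
regime the analyses are meant for. The family-core presence probability of
0.99 reflects what such taxa are: near-ubiquitous residents found even in
captivity.

Marker divergence is independent per-OTU dropout at 1 − recovery
probability (default 0.9) with marker-specific ids and shared lineages. Two
deliberate deviations from pure independence: the dominant OTU is exempt
(the design posits one dominant OTU shared by both markers; dropout models
failed recovery of minor taxa), and an OTU dropped by *both* markers is
reassigned to one at random so that every planted id remains resolvable in
at least one table. The lab population is a diversity-depleted subset: each
non-family-core OTU is removed from the lab pool with probability 1 −
retention (default 0.5) once per population. Multinomial (not
Dirichlet-multinomial) sampling is the default — the simplest model
satisfying the downstream assumptions; overdispersion can be emulated by
the per-sample log-normal weight jitter already present.

`SimulationDesign.exchangeable()` switches off all species-specific planted
structure (species cores, outgroup exclusives, diet fold), making wild
individuals statistically exchangeable — the null condition under which
permutation tests are calibration-checked.

What the generator does *not* emulate: sequence-level error, chimeras,
primer bias beyond uniform dropout, phylogenetic signal in which taxa drop
out, spatial/temporal structure among conspecifics, and compositional
overdispersion beyond log-normal jitter. Passing recovery and calibration
tests on these communities therefore shows the statistics are correct and
well-calibrated under the stated model, not that real surveys meet the
model.

## Numerical choices and degenerate inputs

Tolerances: permutation-tie comparisons use a 1e-12 slack so exact ties
count as hits (conservative); UniFrac and IndVal oracle agreement is
asserted to 1e-10/1e-12; PCoA reconstruction of Euclidean matrices to
1e-8. Degenerate inputs fail loudly: empty samples reject relative
abundance and weighted UniFrac; all-zero vectors reject Chao1/Shannon;
single groups reject PERMANOVA and IndVal; a single-member group yields
flagged NaNs in distance summaries rather than silent zeros. Orientation of
OTU tables on disk is auto-detected against metadata sample ids, and
ambiguity is an error, never a guess. BIOM support covers the dense JSON
dialect, adequate at desk scale.

## Problem sizes in the test suite

The suite validates stochastic properties at sizes chosen for tight Monte
Carlo error at desk scale: calibration of the core-length test over 500
synthetic communities (B = 1000 each, rejection rate asserted in
[0.02, 0.08]); power over 100 communities with planted cores (≥ 0.8);
PERMANOVA Monte Carlo vs the exhaustive 720-permutation enumeration at
n = 6 with B = 10 000; Procrustes null uniformity over 1000 replicates;
UniFrac oracle agreement over 50 random 8-tip trees; IndVal oracle
agreement over 100 random 10 × 8 tables. The full pipeline determinism
check runs the complete analysis twice at depth 400 and B = 100 and
compares every output byte for byte.
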