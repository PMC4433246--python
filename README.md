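# gutcore

Core gut-microbiota estimation, rarefaction diversity and indicator-taxon
analysis for paired-marker 16S amplicon surveys.

## The problem

Comparative gut-microbiome surveys of closely related wild hosts — here
modelled on African cichlid fishes spanning a recent dietary shift from
zooplanktivory to scale-eating — ask two questions of an OTU table:

1. **What is shared?** Is there a *core microbiota*, a set of taxa and OTUs
   carried by (nearly) all individuals of a species or of the whole host
   clade, and is the conspecific core larger than a random pool of
   individuals would produce?
2. **What distinguishes?** Which taxa *indicate* a host species, genus,
   tribe or diet class, once sequencing artefacts are excluded by requiring
   that two independent 16S markers (amplicons with disjoint OTU id spaces,
   matched through shared taxonomy) agree?

`gutcore` implements the complete analysis chain for these questions on
integer OTU count tables, plus a seeded synthetic-community generator with a
planted ground truth so every statistic can be validated by
parameter-recovery and calibration tests.

## The statistics at the core

**Multi-criterion core.** A member is core when present in
≥ ⌈p·N⌉ of the N in-scope (wild) individuals (default p = 0.8), in ≥ 1
individual of every host species, and — for taxa, never OTUs — recovered by
both markers.

**Relative core length and its permutation test.** For a set of n
individuals, L = (# OTUs present in ≥ ⌈p·n⌉ of them) / (# OTUs present in
any of them). Each species' observed L is compared one-sidedly against B
draws of five individuals taken from all wild fish with species labels
ignored; p = (b + 1)/(B + 1).

**Indicator values** (Dufrêne–Legendre). For taxon i and cluster j,
IndVal_ij = A_ij · B_ij with specificity A_ij = x̄_ij / Σ_k x̄_ik (mean
relative abundance concentrated in the cluster) and fidelity B_ij (fraction
of cluster-j samples containing the taxon); IndVal_i = max_j, significance
by free label permutation, and a cross-marker concordance filter
(significant in both markers, same assigned cluster, IndVal ≥ 0.6 in at
least one).

Around these sit the standard machinery, implemented or wrapped behind one
surface: Chao1 / Shannon / Faith's PD with rarefaction averaging, binary
Jaccard, unweighted and weighted UniFrac (explicit edge walk), Manhattan
distance on arcsin-√ transformed relative abundances (= 2 × Bray–Curtis on
fractions), PCoA by double-centred eigendecomposition, distance-based
PERMANOVA, Procrustes M² with Monte-Carlo significance, UPGMA jackknife
support, and Mann-Whitney / Wilcoxon rank-sum comparisons.

## Worked example

```sh
python examples/05_core_microbiota.py
```

```
V12: 20 core OTUs among 25 wild fish (planted family core: 20)
V34: 18 core OTUs among 25 wild fish (planted family core: 20)
core genera recovered by BOTH markers: 23 (concordance filters out marker-specific artefacts)
relative core length per species (share of a species' OTUs that are core):
  Astbur   n=5  L=0.163  null mean=0.086  p=0.0010*
  Hapmic   n=5  L=0.151  null mean=0.086  p=0.0010*
  Haptri   n=4  L=0.100  null mean=0.086  p=0.0779
  Permic   n=5  L=0.152  null mean=0.086  p=0.0010*
  Plestr   n=5  L=0.161  null mean=0.086  p=0.0010*
(* = conspecifics share significantly more OTUs than random fish)
```

The core computation recovers the 20 planted family-wide core OTUs from
each marker table (V34 misses two that its simulated dropout never
recovered), conspecific cores sit at 13–16% of each species' OTUs, and the
permutation test rejects the random-pool null for every species with five
conspecifics. Other examples cover simulation, filtering/rarefaction, alpha
diversity with between-marker R², beta diversity with PERMANOVA and
Procrustes, and indicator taxa.

The same analyses run from the shell:

```sh
gutcore simulate --seed 42 --out data/
gutcore run-all --in-dir data/ --seed 42 --out results/
```

Identical seeds produce byte-identical result files.

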