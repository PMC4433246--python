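"""Indicator-value analysis with cross-marker concordance.

For each genus and host grouping, IndVal = specificity x fidelity: it
reaches 1 only for a taxon exclusive to one cluster and present in all
of its samples.  Taxa are reported only when significant in both
markers, assigned to the same cluster, with IndVal >= 0.6 in at least
one marker.
"""

from gutcore import (
    SimulationDesign, aggregate_by_rank, concordant_indicators,
    generate_dataset, indval, indval_significance,
)

tables, taxonomy, tree, metadata, truth = generate_dataset(SimulationDesign(seed=42))

per_marker = {}
for marker, table in tables.items():
    genus = aggregate_by_rank(table, taxonomy, "genus")
    clusters = metadata.groups("host_tribe", genus.sample_ids)
    res = indval(genus, clusters)
    p = indval_significance(genus, clusters, permutations=999, seed_or_rng=6)
    per_marker[marker] = (res, p)

(ra, pa), (rb, pb) = per_marker["V12"], per_marker["V34"]
table3 = concordant_indicators(ra, pa, rb, pb, alpha=0.05, min_indval=0.6)
print(f"{len(table3)} concordant indicator genera for host tribe:")
for _, row in table3.head(12).iterrows():
    genus = row["taxon"].split(";")[-1].strip().split("__")[-1]
    print(f"  {genus:28s} -> {row['cluster']:12s} "
          f"V12={row['indval_a']:.3f} V34={row['indval_b']:.3f}")
print("(high values mark taxa concentrated in, and faithful to, one tribe;")
print(" the planted outgroup-exclusive clades should dominate this list)")
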