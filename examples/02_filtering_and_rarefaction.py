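"""OTU retention filters and rarefaction to an even depth.

Filtering keeps OTUs seen in at least two samples plus single-sample
OTUs backed by more than three reads, then removes Cyanobacteria
(chloroplasts of ingested material) while keeping the gut
Melainabacteria (YS2 / 4C0d-2) exception clades.
"""

from gutcore import SimulationDesign, filter_low_occurrence, filter_taxa, generate_dataset, rarefy

tables, taxonomy, tree, metadata, _ = generate_dataset(SimulationDesign(seed=42))
table = tables["V12"]

t1, rep1 = filter_taxa(table, taxonomy)
print(f"Cyanobacteria rule: removed {rep1.n_removed} chloroplast-like OTUs, "
      f"kept the YS2/Melainabacteria clades")

t2, rep2 = filter_low_occurrence(t1)
print(f"low-occurrence rule: {rep2.n_input} -> {rep2.n_retained} OTUs "
      f"({rep2.n_removed} removed, mostly environmental singletons)")

even = rarefy(t2, depth=500, seed_or_rng=0)
print(f"rarefied to 500 reads/sample: every row sums to "
      f"{set(even.sample_sums())} -- sequencing effort is equalised")
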