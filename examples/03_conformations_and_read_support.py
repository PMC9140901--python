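"""Enumerate repeat-mediated conformations and count long-read support.

A direct repeat pair lets the master circle recombine into two subgenomic
circles.  This example plants one such repeat, simulates an ultralong-read
pool from a 50/50 master/recombinant mixture, classifies every read at the
repeat's junctions, and prints the support table and the inferred
multipartite model.
"""

import numpy as np

import mitoforms as mf

spec = mf.SimGenomeSpec(
    genome_length=100_000,
    repeat_plants=(mf.RepeatPlant(3000, 8_000, 58_000, "direct"),),
    seed=3,
)
genome, _, _ = mf.build_genome(spec)
(pair,) = mf.find_dispersed_repeats(genome)
confs = mf.enumerate_conformations(genome, pair, flank=1000)
print(f"repeat {pair.id}: {pair.length} bp direct pair")
print(
    f"alternative conformation: two circles of "
    f"{confs.subcircle_sizes[0]:,} and {confs.subcircle_sizes[1]:,} bp "
    f"(sum = {sum(confs.subcircle_sizes):,} = master length)"
)

read_spec = mf.ReadSimSpec(
    conformation_weights={"master": 0.5, confs.conformation_id: 0.5},
    n_reads=500,
    substitution_rate=0.03,
    insertion_rate=0.01,
    deletion_rate=0.01,
    seed=4,
)
reads = mf.simulate_reads(genome, [confs], read_spec)
labels = mf.classify_reads([r.sequence for r in reads], confs)
(record,) = mf.support_table({pair.id: labels}, [pair])
print(
    f"\nread support: {record.n_master} master / {record.n_alt} alternative "
    f"({record.n_uninformative} uninformative of {len(reads)})"
)
print(f"frac_master = {record.frac_master:.2f} %, frac_alt = {record.frac_alt:.2f} %")

model = mf.infer_multipartite([record], genome, [pair], activity_threshold=20.0)
print("\nmultipartite model:")
print(model.to_json())
print(
    "\nA frac_alt near 50 % means the recombinant arrangement is as abundant"
    "\nas the assembled master circle — the repeat is recombinationally active."
)
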