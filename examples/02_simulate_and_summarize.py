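"""Simulate the built-in 21-population scenario and summarize polymorphism.

Prints per-population and species-level polymorphism statistics: percentage
of heterozygous larvae, heterozygous inversions per larva, and the numbers
of banding sequences and genotypic combinations per population.
"""

from cytopoly import aggregate_summaries, generate_scenario, paper_like_scenario, summarize

samples, truth = generate_scenario(paper_like_scenario(seed=1))

print(f"{'population':10s} {'N':>4s} {'het %':>6s} {'het inv/larva':>14s} {'seqs':>5s}")
for sample in samples[:5]:
    s = summarize(sample)
    print(
        f"{s.population:10s} {s.n:4d} {s.pct_heterozygotes:6.1f} "
        f"{s.het_inversions_per_larva:14.2f} {s.n_sequences:5d}"
    )
print("... (21 populations total)\n")

# Species-level aggregate: unweighted mean +/- SE across populations with at
# least 10 larvae (populations are the sampling unit).
agg = aggregate_summaries([summarize(s) for s in samples], min_n=10)
pct = agg["pct_heterozygotes"]
inv = agg["het_inversions_per_larva"]
seqs = agg["n_sequences"]
combos = agg["n_genotype_combinations"]
print(f"heterozygous larvae: {pct['mean']:.1f} +/- {pct['se']:.1f} % (SD {pct['sd']:.1f})")
print(f"heterozygous inversions per larva: {inv['mean']:.2f} +/- {inv['se']:.2f} (SD {inv['sd']:.2f})")
print(f"banding sequences per population: {seqs['mean']:.1f} (SD {seqs['sd']:.1f})")
print(f"genotypic combinations per population: {combos['mean']:.1f} (SD {combos['sd']:.1f})")
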