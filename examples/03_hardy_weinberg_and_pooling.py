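"""Hardy-Weinberg testing and pooling of samples across collection dates.

Generates one population in equilibrium and one with a heterozygote excess
(negative inbreeding coefficient), tests every arm, then shows how two
same-locality samples are pooled when their frequencies do not differ.
"""

from cytopoly import generate_population, hw_scan, merge_samples, pooling_test
from cytopoly.synthetic_data import PopulationConfig

freqs = {arm: {1: 0.6, 2: 0.4} for arm in "ABCDEFG"}

null_pop = PopulationConfig("RIV-EQ", "Europe", n=120, freqs=freqs)
excess_pop = PopulationConfig("RAL-MA", "W-Siberia", n=120, freqs=freqs, inbreeding_f=-0.45)

for cfg, label in [(null_pop, "equilibrium"), (excess_pop, "heterozygote excess")]:
    sample = generate_population(cfg, rng=7)
    flagged = [r for r in hw_scan(sample, method="exact", alpha=0.05) if r.significant]
    print(f"{cfg.population} ({label}): {len(flagged)} arm(s) deviate from Hardy-Weinberg")
    for r in flagged:
        print(f"  arm {r.arm}: p = {r.p_value:.2e}, direction: {r.direction}")

# Two collections from the same locality in different years: pooled when the
# per-sequence Fisher tests (Bonferroni-corrected) find no difference.
a = generate_population(PopulationConfig("NSK-BE", "W-Siberia", n=60, freqs=freqs), rng=1)
b = generate_population(PopulationConfig("NSK-BE", "W-Siberia", n=45, freqs=freqs), rng=2)
a.dates, b.dates = ["2007-06-25"], ["2008-05-05"]
decisions: list[str] = []
merged = merge_samples([a, b], pooling_test(alpha=0.05), log=decisions)
print(f"\npooling NSK-BE samples: {len(merged)} group(s), N = {[m.n for m in merged]}")
for line in decisions:
    print(" ", line)
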