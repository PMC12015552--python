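"""Band-order rearrangement algebra: reversals, breakpoints, inversion steps.

Builds a small banding sequence, derives others by inversions, and measures
how far apart they are; then loads the packaged registry and prints the
derivation graph recorded for the species' banding-sequence pool.
"""

from cytopoly import (
    BandOrder,
    BandingSequence,
    apply_reversal,
    breakpoint_count,
    build_derivation_graph,
    enumerate_intermediates,
    load_registry,
    registry_arm_counts,
    reversal_steps,
)

# An arm mapped as seven band regions, centromere at the left end.
ancestral = BandOrder.from_labels("A", ["1", "2", "3", "4", "5", "6", "7"], 0)

# One paracentric inversion of regions 2-4: the segment order reverses and
# every segment flips orientation (a minus sign = reversed reading).
inverted, record = apply_reversal(ancestral, 1, 3)
print("ancestral order:", " ".join(ancestral.labels()))
print("after inversion:", " ".join(inverted.labels()), "| pericentric:", record.pericentric)

# Breakpoints are segment adjacencies broken between the two orders; one
# inversion breaks two, and the minimal number of inversion steps follows.
print("breakpoints:", breakpoint_count(ancestral, inverted))
print("inversion steps:", int(reversal_steps(ancestral, inverted)))

# A complex (two-step) derivative and its hypothetical intermediates: the
# unobserved orders that lie on a minimal inversion path.
two_step, _ = apply_reversal(inverted, 4, 6)
parent = BandingSequence("p'borA1", "A", order=ancestral)
child = BandingSequence("p'borA5", "A", order=two_step)
print("steps to two-step derivative:", int(reversal_steps(ancestral, two_step)))
for mid in enumerate_intermediates(parent, child):
    print("  hypothetical intermediate:", " ".join(mid.order.labels()))

# The packaged registry records the species' 40 named banding sequences.
registry = load_registry()
print("\nregistry per-arm counts:", registry_arm_counts(registry))
graph = build_derivation_graph(registry)
print("derivation edges (first five):")
for parent_name, child_name, data in list(graph.edges(data=True))[:5]:
    print(f"  {parent_name} -> {child_name}  [{data['kind']}, {data['n_steps']} step(s)]")
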