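"""Banding-sequence classes and cytogenetic structure types.

Runs the four-class classification (main / alternative / rare / unique) on
the simulated survey and assigns each population its cytogenetic type: "0"
when every arm's main sequence is dominant, otherwise the letters of the
arms where it is not (e.g. "G", "DFG").
"""

from collections import Counter

from cytopoly import (
    assign_type,
    classify_sequences,
    generate_scenario,
    paper_like_scenario,
    sequence_frequencies,
    type_census,
)

samples, truth = generate_scenario(paper_like_scenario(seed=1))

reports = classify_sequences(samples)
print("sequence classes:", dict(Counter(r.seq_class for r in reports)))
for r in reports:
    if r.seq_class == "alternative":
        print(f"  alternative: arm {r.arm} serial {r.serial}, dominant in {r.n_dominant} population(s)")

tables = [sequence_frequencies(s) for s in samples]
assignments = [assign_type(t) for t in tables]
census = type_census(assignments)
print(f"\n{census['n_types']} cytogenetic types found:")
for type_string, pops in census["types"].items():
    print(f"  type {type_string:4s}: {', '.join(pops)}")
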