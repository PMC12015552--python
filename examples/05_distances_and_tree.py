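"""Cytogenetic distances and the neighbor-joining tree of populations.

Computes Nei's standard genetic distance between all population pairs
(arms as loci, banding sequences as alleles), prints the distance summary,
and builds the NJ tree in Newick form.
"""

from pathlib import Path

from cytopoly import (
    distance_matrix,
    generate_scenario,
    neighbor_joining,
    paper_like_scenario,
    sequence_frequencies,
    write_newick,
    write_phylip,
)
from cytopoly.distance_phylogeny import within_between_means

samples, truth = generate_scenario(paper_like_scenario(seed=1))
tables = [sequence_frequencies(s) for s in samples]

dm = distance_matrix(tables, metric="nei_standard")
s = dm.summary
print(
    f"pairwise distances ({s['n_pairs']} pairs): "
    f"{s['min']:.3f} - {s['max']:.3f}, mean {s['mean']:.3f} +/- {s['se']:.3f}"
)
wb = within_between_means(dm, truth["regions"])
print(f"mean within regions {wb['within_mean']:.3f}, between regions {wb['between_mean']:.3f}")

tree = neighbor_joining(dm)
out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_phylip(dm, out / "dist.phylip")
newick = write_newick(tree, out / "tree.nwk")
print(f"\nNJ tree ({len(tree.leaves())} leaves) written to {out / 'tree.nwk'}:")
print(newick[:120] + "...")
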