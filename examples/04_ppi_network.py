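"""Prune an interactome to the candidate list.

Reads MITAB interaction records, keeps human protein-protein rows, and
restricts edges to pairs inside the candidate list (removing first
interactors, self-loops, duplicates and isolated proteins).
"""

import tempfile
from pathlib import Path

from proteomark import (
    SyntheticConfig,
    annotate_directions,
    differential_abundance,
    filter_records,
    generate_abundance,
    generate_interactome,
    prune_to_input,
    read_mitab,
)

matrix, truth = generate_abundance(SyntheticConfig(n_proteins=300, n_markers=24, seed=2))
mitab = Path(tempfile.mkdtemp()) / "interactome.mitab"
counts = generate_interactome(truth, matrix.accessions, mitab, seed=2,
                              background_edge_prob=0.001)
print(f"interactome rows: {counts['total']} "
      f"({counts['decoy_taxid']} non-human decoys, {counts['self_loops']} self-loops)")

records = read_mitab(mitab)
kept = filter_records(records, taxid=9606, protein_only=True)
graph = prune_to_input(kept, {a.split("-")[0] for a in truth.marker_ids})
stats = differential_abundance(matrix)
stats.index = [a.split("-")[0] for a in stats.index]
stats = stats[~stats.index.duplicated()]
split = annotate_directions(graph, stats)
print(f"pruned network: {graph.number_of_nodes()} connected proteins, "
      f"{graph.number_of_edges()} edges ({split['n_up']} up, {split['n_down']} down)")
# Only proteins physically interacting within the candidate list survive —
# the network is the final filter before pathway analysis.
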