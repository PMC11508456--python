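"""Multivariate marker selection: PLS-DA with recursive feature elimination.

Each iteration refits the classifier and discards the protein with the
smallest absolute component-1 loading, until 5% of the input list remains.
"""

from proteomark import SyntheticConfig, generate_abundance, rfe

matrix, truth = generate_abundance(SyntheticConfig(n_proteins=500, n_markers=25, seed=1))
trace = rfe(matrix, n_components=2, target_fraction=0.05)

print(f"retained {trace.n_retained}/{matrix.n_proteins} proteins "
      f"(ceil(0.05 x {matrix.n_proteins}))")
ve = trace.variance_explained_final
print("variance explained on the final matrix: "
      + ", ".join(f"component {k + 1}: {v:.0%}" for k, v in enumerate(ve)))
recall = len(set(trace.retained) & truth.marker_ids) / len(truth.marker_ids)
print(f"planted-marker recall in the retained 5%: {recall:.0%}")
print("first eliminations:", [acc for _, acc, _ in trace.eliminated[:3]])
# Component 1 separates the groups; its variance share grows as noise
# proteins are eliminated, mirroring the behaviour expected on real cohorts.
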