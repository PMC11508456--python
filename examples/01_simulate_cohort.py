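"""Generate a synthetic two-group salivary-proteomics cohort.

Builds an abundance matrix shaped like a 10-case / 20-control label-free
study with planted differential proteoforms, then prints what was planted.
"""

from proteomark import SyntheticConfig, generate_abundance

config = SyntheticConfig(n_proteins=500, n_markers=25, effect_log2fc=2.0, seed=1)
matrix, truth = generate_abundance(config)

n_up = sum(1 for d in truth.direction.values() if d == "up")
print(f"matrix: {matrix.n_proteins} proteoforms x {matrix.n_samples} samples")
print(f"planted markers: {len(truth.marker_ids)} ({n_up} up, "
      f"{len(truth.marker_ids) - n_up} down), |log2FC| = {config.effect_log2fc}")
print(f"isoform rows: {sum('-' in a for a in matrix.accessions)}")
# The markers are the ground truth every downstream stage is judged against:
# a good pipeline should rediscover most of them from the abundances alone.
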