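"""Simulate a laser-capture-style cohort with ground truth.

Builds the default design — 12 plaque-niche vs 12 distal non-plaque
samples from 6-month TgCRND8 cortex — with a niche-enriched gene module
nested inside a transgene-progression module, and prints what was planted.
"""

from plaquesig import SimConfig, simulate_cohort, truth_sets

config = SimConfig.lcm_default(n_genes=2000, seed=1)
counts, samples, truth = simulate_cohort(config)

print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print("treatment groups:", dict(samples.group_labels.value_counts()))
print("planted modules:", truth.genes["module"].value_counts().to_dict())

coll = truth_sets(truth)
niche_all = coll["niche_all"]
prog_all = coll["progressive_all"]
shared = niche_all.members & prog_all.members
print(f"niche signature: {len(niche_all)} genes, of which {len(shared)} "
      f"are shared with the {len(prog_all)}-gene progression signature")
# The shared block is what makes the plaque-niche screen recover a subset
# of the cortex-progression signature, as in the real experiment.
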