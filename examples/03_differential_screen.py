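"""The plaque-vs-distal differential screen with plug-in FDR.

Runs the per-gene equal-variance Student's t test on log10 ratios at
p < 0.001 and reports the comparison-level plug-in FDR — the same summary
the published whole-cortex and LCM comparisons print (e.g. 82 of 12,461
detected genes at FDR < 15%).
"""

import math
from dataclasses import replace

from plaquesig import SimConfig
from plaquesig.workflows import lcm_screen

d = math.log2(3.0)
config = SimConfig.lcm_default(n_genes=12_500, seed=1)
config = replace(config, modules={
    name: (replace(spec, niche_log2fc=(d, d))
           if spec.niche_log2fc != (0.0, 0.0) else spec)
    for name, spec in config.modules.items()})

screen = lcm_screen(config, alpha=0.001)
sig, fdr = screen["significant"], screen["fdr"]
print(f"detected genes: {len(screen['detected'])}")
print(f"significant at p<0.001: {sig.n_up} up / {sig.n_down} down "
      f"({sig.percent_up}% up), plug-in FDR {fdr.fdr_percent}%")
print(f"niche-module recovery: {100 * screen['niche_recovery']:.1f}%")
ov = screen["overlap"]
print(f"overlap of recovered set with progression truth: {ov.k} of "
      f"{ov.K} x {ov.n} on {ov.N} background, p = {ov.p_hyper:.3g}")
# The recovered up-signature is dominated by the planted niche modules and
# overlaps the progression module far beyond chance — the simulated analogue
# of the published cortex/plaque-niche signature nesting.
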