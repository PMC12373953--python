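"""Generate design sets at exact mutational distances under several model
families and compare their scores.

Families: RUM (uniform random), BPR (canonical base-pair replacement),
SB (structure-guided MCMC), DCA (coupling-model MCMC at temperature T) and
DCA-SB (both scores combined at T=0.3). All designs sit at the exact
requested Hamming distance from the reference.
"""

import numpy as np

from riboneutral import (
    ModelSpec,
    ToySpec,
    generate_design_set,
    make_toy_potts,
    make_toy_ribozyme,
)

ref, struct = make_toy_ribozyme(length=60, seed=0)
# stand-in coupling model at the toy scale (in practice: train_boltzmann)
potts = make_toy_potts(ToySpec(L=60, q=4, topology="random", edge_prob=0.08,
                               coupling_scale=0.8, field_scale=0.5, seed=2))

specs = [
    ModelSpec(tag="RUM"),
    ModelSpec(tag="BPR", struct=struct),
    ModelSpec(tag="SB", struct=struct, sweeps=60, burn_in=60),
    ModelSpec(tag="DCA", potts=potts, T=1.0, sweeps=100, burn_in=100),
    ModelSpec(tag="DCA-SB", potts=potts, struct=struct, T=0.3,
              sweeps=60, burn_in=60),
]
designs = generate_design_set(ref, specs, bin_plan=[(10, 5)], seed=0)
man = designs.manifest()

print(f"{len(designs)} designs, all at distance "
      f"{sorted(set(man['distance']))} from the reference\n")
for tag, grp in man.groupby("model_tag"):
    e, s = grp["dca_energy"].mean(), grp["sb_score"].mean()
    parts = [f"{tag:7s}"]
    if np.isfinite(e):
        parts.append(f"mean coupling energy {e:8.2f}")
    if np.isfinite(s):
        parts.append(f"mean SB score {s:7.2f}")
    print("  ".join(parts))
print("\nstructure-aware families fold better (lower SB); coupling-guided")
print("families have lower energy than random designs at the same distance.")
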