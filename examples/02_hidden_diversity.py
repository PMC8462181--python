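"""Propagate detection uncertainty into diversity metrics: the hidden-diversity table.

Simulates a community, fits the N-mixture model, then compares diversity
computed from the observed counts with diversity computed from each posterior
draw of the true abundances.  HD = (observed - mean estimated) / sd estimated:
negative HD for richness means species were missed; the quadrant column says
whether an SES pattern survives detection correction (noise) or flips (bias).
"""

import numpy as np
import pandas as pd
import dendropy

import hiddendiv as hd

species = [f"sp_{k:02d}" for k in range(10)]

# phylogeny (caterpillar with increasing depths) and a mixed trait table
nwk = f"({species[0]}:1,{species[1]}:1)"
for i, sp in enumerate(species[2:], start=2):
    nwk = f"({nwk}:1,{sp}:{i}.0)"
tree = dendropy.Tree.get(data=nwk + ";", schema="newick", preserve_underscores=True)
rng = np.random.default_rng(1)
traits = hd.TraitMatrix(
    pd.DataFrame({
        "forewing_mm": rng.normal(25, 4, 10).round(2),
        "wing_loading": rng.normal(1.2, 0.2, 10).round(3),
        "iridescent": rng.integers(0, 2, 10),
    }, index=species),
    binary=("iridescent",),
)

sim = hd.simulate_metacommunity(hd.build_setting_grid(n_species=10, seed=5)[6])
draws = hd.fit_model(sim.y, sim.design,
                     hd.MCMCConfig(n_chains=3, n_iter=2000, n_burn=1000, thin=10, seed=5))
obs = hd.observed_community(sim.y, species=species)

table = hd.hidden_diversity_pipeline(
    obs, list(hd.posterior_abundance_matrices(draws)[:100]),
    tree=tree, traits=traits, metrics=("pd", "mpd"),
    null=hd.NullModelSpec("tip_shuffle", n_perm=99, seed=5),
)
summary = (table.groupby("metric")
           .agg(mean_hd=("hd", "mean"),
                n_noise=("quadrant", lambda q: (q == "noise").sum()),
                n_bias=("quadrant", lambda q: q.str.startswith("bias").sum()))
           .round(2))
print(summary.to_string())
print("\nmean_hd < 0 for TD/abundance: observed data underestimate richness and")
print("abundance (the model only adds false negatives); for SES metrics the sign")
print("says whether the observed structure over- or understates the corrected one,")
print("and n_noise/n_bias count sites whose pattern holds vs flips.")
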