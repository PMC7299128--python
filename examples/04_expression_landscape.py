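"""Stage-level expression summaries: PCA of sporophyte samples and the
cross-species Spearman divergence matrix over one-to-one orthologs."""
import pandas as pd

import heterochron as hc
from heterochron import de, landscape

cfg = hc.SimulationConfig(n_shared_orthologs=500, n_specific_per_species=0,
                          shift_fraction=0.0, seed=9)
sim = hc.simulate_two_species(cfg)

def stage_matrix(cm):
    filtered = de.filter_low_counts(cm)
    sf = de.estimate_size_factors(filtered)
    return landscape.stage_means(filtered, sf), filtered, sf

sm_a, cm_a, sf_a = stage_matrix(sim.counts_a)
sm_b, _, _ = stage_matrix(sim.counts_b)

# PCA over sporophyte replicate samples (observations) x genes (variables)
sporo = cm_a.sporophyte()
obs = pd.DataFrame(
    (sporo.counts.to_numpy(float) / sf_a[sporo.sample_ids].to_numpy()).T,
    index=sporo.sample_ids, columns=sporo.gene_ids,
)
res = landscape.pca(obs)
print("variance explained by PC1-PC3:",
      [f"{v:.1%}" for v in res.variance_explained[:3]])

pairs = [hc.OrthologPair(g[cfg.species[0]][0], g[cfg.species[1]][0])
         for g in sim.orthogroups.genes_by_species.values()]
rho, n = landscape.spearman_divergence(sm_a, sm_b, pairs)
print("\nSpearman divergence matrix (rows: species-A stages, "
      "cols: species-B stages):")
print(rho.round(3).to_string())
print()
print("With no planted shifts the diagonal dominates: the same stage in the")
print("two species shows the most similar ortholog expression ranking.")
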