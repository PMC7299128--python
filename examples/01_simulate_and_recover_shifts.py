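"""Simulate two species with planted heterochronic shifts, then recover
them: cluster species A's stage profiles by fuzzy c-means, project species
B's orthologs onto those clusters, condense to early/mid/late major
clusters, and call each ortholog pair conserved or heterochronic."""
from heterochron.evaluation import shift_recovery_benchmark

result = shift_recovery_benchmark(
    n_orthologs=1000, shift_fraction=0.3, nb_dispersion=0.05, seed=1
)

print(f"orthologs clustered:        {result['n_orthologs']}")
print(f"pairs confidently called:   {result['n_called']}")
print(f"ARI vs planted archetypes:  {result['ari_minor_clusters']:.3f}")
print(f"shift sensitivity:          {result['shift_sensitivity']:.3f}")
print(f"shift specificity:          {result['shift_specificity']:.3f}")
print(f"recovered heterochronic %:  {result['recovered_shift_pct']:.1f}"
      f"  (planted {result['planted_shift_pct']:.0f}%)")
print()
print("An ARI near 1 means the fuzzy c-means clusters coincide with the")
print("planted temporal archetypes; the recovered heterochronic percentage")
print("tracking the planted 30% shows the cross-species projection and the")
print("major-cluster condensation call shifts, not noise.")
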