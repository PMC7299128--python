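# heterochron

Cross-species comparison of developmental gene expression, built around the
moss life cycle: two related species grow sporophytes of very different
complexity, and the question is whether that divergence is driven by
species-specific genes or by *heterochrony* — shared genes whose expression
peaks at different developmental times in the two species.

Given gene-level RNA-seq count matrices for two species (four sporophyte
stages × replicates, plus gametophyte samples), an orthogroup table and
protein alignment hit tables, the package:

1. **Filters and normalizes** counts (total count ≥ 10; median-of-ratios
   size factors).
2. **Calls preferentially sporophyte-expressed genes** with a
   negative-binomial Wald test (NB2, Var = μ + αμ²) of sporophyte vs
   gametophyte samples: a gene is *preferential* when p_adj ≤ 0.05 (BH) and
   log₂FC ≥ 2.
3. **Classifies genes** as homologous vs species-specific: orthogroup
   membership spanning both species, else a protein hit passing E ≤ 10⁻⁶,
   query coverage ≥ 80% and similarity ≥ 35%, else rescue by a
   protein-vs-genome hit at the same thresholds; extracts one-to-one
   orthologs; tests homolog depletion among preferential genes with a 2×2
   Pearson χ² (df = 1, no continuity correction).
4. **Summarizes the expression landscape**: PCA over gene subsets
   (all / homologous / species-specific) and a 4×4 cross-species Spearman
   divergence matrix over one-to-one orthologs on log₂(normalized + 1)
   stage means.
5. **Detects heterochronic shifts** — the core procedure. Standardized
   stage profiles of species A are clustered by fuzzy c-means, minimizing

   J = Σᵢ Σⱼ uᵢⱼᵐ ‖xᵢ − cⱼ‖²,  Σⱼ uᵢⱼ = 1,

   with the fuzzifier m estimated from the data dimensions
   (m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134))
   and the cluster number chosen from the minimum-centroid-distance (Dmin)
   profile over k = 4..40 (default k = 12). Species B ortholog profiles are
   projected onto the fixed centroids with the same membership formula.
   Minor clusters condense into major temporal clusters by centroid peak
   (stage 1 → early, 2–3 → mid, 4 → late; ambiguous bimodal centroids stay
   unassigned), and each ortholog pair is called *conserved* (same major
   cluster in both species) or *heterochronic* (different).
6. **GO enrichment** of preferential gene subsets with the parent-child
   hypergeometric test (union variant) over an `is_a` OBO DAG.

A synthetic-data module generates two-species NB counts with planted
temporal archetypes, planted major-cluster shifts, planted fold changes and
species-specific genes, so the whole pipeline is testable without any
download.

## Worked example

`examples/01_simulate_and_recover_shifts.py` simulates 1,000 one-to-one
orthologs with 30% planted heterochronic shifts (NB dispersion 0.05),
clusters species A, projects species B, and scores the calls against the
planted truth:

```
orthologs clustered:        1000
pairs confidently called:   842
ARI vs planted archetypes:  0.941
shift sensitivity:          0.996
shift specificity:          0.993
recovered heterochronic %:  29.9  (planted 30%)
```

The adjusted Rand index near 1 means the fuzzy c-means minor clusters
coincide with the planted temporal archetypes; the recovered heterochronic
percentage tracking the planted 30% shows that the cross-species projection
and major-cluster condensation detect genuine timing shifts rather than
noise. The other example scripts walk through differential expression,
homology classification, the expression landscape and GO enrichment the
same way.

The same stages are available from a shell:

```bash
heterochron simulate --n-orthologs 1000 --outdir sim/
heterochron run --config pipeline.yaml --seed 1 --outdir results/
```

`run` writes every intermediate table (`de_*.tsv`, `classification.tsv`,
`one_to_one.tsv`, `divergence_matrix.tsv`, `cluster_model.tsv`,
`memberships.tsv`, `shift_table.tsv`, `shift_summary.tsv`, …) plus a
manifest; identical config + seed reproduce every file byte for byte.

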