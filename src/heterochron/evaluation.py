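"""Recovery benchmarks on synthetic data with planted ground truth.

These run the actual pipeline stages on generator output and score the
results against the plant: cluster recovery (adjusted Rand index against
planted archetypes), heterochronic-shift recovery (sensitivity/specificity
of the conserved-vs-shifted call) and DE calibration (null false-positive
rate, planted fold-change recovery).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering, de, landscape
from .simulate import SimulationConfig, simulate_two_species


def shift_recovery_benchmark(
    n_orthologs: int = 1000,
    shift_fraction: float = 0.3,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    k: int = 12,
    membership_min: float = clustering.MEMBERSHIP_MIN,
) -> dict:
    """Simulate two species, run the clustering/projection/shift pipeline,
    and score recovery against the planted truth.

    Returns ARI between recovered and planted minor clusters of the
    clustered species, sensitivity/specificity of the heterochronic call,
    and the recovered heterochronic fraction (percent of non-excluded
    pairs).
    """
    cfg = SimulationConfig(
        n_shared_orthologs=n_orthologs,
        n_specific_per_species=0,
        nb_dispersion=nb_dispersion,
        shift_fraction=shift_fraction,
        de_fraction=0.0,
        seed=seed,
    )
    sim = simulate_two_species(cfg)
    truth = sim.truth.set_index("gene_a")

    def standardized(cm):
        filtered = de.filter_low_counts(cm)
        sf = de.estimate_size_factors(filtered)
        sm = landscape.stage_means(filtered, sf)
        z, _ = landscape.standardize_profiles(sm)
        return z

    za = standardized(sim.counts_a)
    zb = standardized(sim.counts_b)
    pairs = [
        p for p in
        (p for og in sim.orthogroups.genes_by_species.values()
         for p in [(og[cfg.species[0]][0], og[cfg.species[1]][0])])
        if p[0] in za.index and p[1] in zb.index
    ]
    xa = za.loc[[a for a, _ in pairs]]
    xb = zb.loc[[b for _, b in pairs]]

    m = clustering.estimate_fuzzifier(len(xa), xa.shape[1])
    model = clustering.fcm_fit(xa, k=k, m=m, seed=seed)
    xb_aligned = xb.copy()
    xb_aligned.index = xa.index
    _, hard_b, maxmem_b = clustering.project_profiles(model, xb_aligned)
    major_map = clustering.assign_major_clusters(model)

    hard_a = model.hard_assignments()
    maxmem_a = model.max_memberships()
    from .datamodel import OrthologPair

    hard_b.index = [b for _, b in pairs]
    maxmem_b.index = [b for _, b in pairs]
    shift_table, summary = clustering.classify_shifts(
        hard_a, maxmem_a, hard_b, maxmem_b, major_map,
        [OrthologPair(a, b) for a, b in pairs], membership_min,
    )

    planted_arch = truth.loc[xa.index, "archetype_a"].to_numpy(int)
    ari = adjusted_rand_score(planted_arch, hard_a.to_numpy())

    called = shift_table[shift_table["call"] != clustering.EXCLUDED]
    is_het = (called["call"] == clustering.HETEROCHRONIC).to_numpy()
    planted_shift = truth.loc[called["gene_a"], "shifted"].to_numpy(bool)
    tp = int((is_het & planted_shift).sum())
    fn = int((~is_het & planted_shift).sum())
    tn = int((~is_het & ~planted_shift).sum())
    fp = int((is_het & ~planted_shift).sum())
    return {
        "n_orthologs": len(pairs),
        "n_called": len(called),
        "ari_minor_clusters": float(ari),
        "shift_sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "shift_specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "recovered_shift_pct": 100.0 * is_het.mean(),
        "planted_shift_pct": 100.0 * shift_fraction,
        "summary": summary,
    }


def de_null_calibration(n_genes: int = 2000, seed: int = 0) -> dict:
    """Null simulation (no planted effect): fraction of genes called
    preferential at padj <= 0.05 and log2FC >= 2."""
    cfg = SimulationConfig(
        n_shared_orthologs=n_genes, n_specific_per_species=0,
        de_fraction=0.0, shift_fraction=0.0, seed=seed,
    )
    cm = simulate_two_species(cfg).counts_a
    sf = de.estimate_size_factors(cm)
    res = de.nb_wald_test(cm, sf)
    pref = de.preferential_sporophyte_set(res)
    return {
        "n_genes": len(res),
        "null_preferential_fraction": len(pref) / len(res),
    }


def de_planted_calibration(
    n_planted: int = 500,
    de_fraction: float = 0.1,
    log2fc: float = 3.0,
    baseline_mean: float = 200.0,
    seed: int = 0,
) -> dict:
    """Planted-effect simulation: genes with a known log2FC among a null
    majority; reports mean estimated log2FC of the planted genes and the
    sensitivity of the preferential call."""
    n_genes = round(n_planted / de_fraction)
    cfg = SimulationConfig(
        n_shared_orthologs=n_genes, n_specific_per_species=0,
        n_stages=3, n_replicates=1, n_gametophyte_samples=3,
        archetypes=np.ones((1, 3)), nb_dispersion=0.05,
        baseline_mean=baseline_mean, de_fraction=de_fraction,
        de_log2fc=log2fc, shift_fraction=0.0, seed=seed,
    )
    sim = simulate_two_species(cfg)
    cm = sim.counts_a
    sf = de.estimate_size_factors(cm)
    res = de.nb_wald_test(cm, sf)
    pref = de.preferential_sporophyte_set(res)
    planted = set(sim.truth.loc[sim.truth["de_planted"], "gene_a"])
    by_gene = res.set_index("gene_id")
    return {
        "n_planted": len(planted),
        "mean_estimated_log2fc": float(
            by_gene.loc[sorted(planted), "log2fc"].mean()
        ),
        "de_sensitivity": len(pref & planted) / len(planted),
    }
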