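"""End-to-end orchestration: filter -> DE -> homology -> landscape ->
cluster/project/compare -> GO enrichment, with a YAML config, per-stage
logging and a run manifest.  Identical config + seed gives identical
outputs."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering, de, goenrich, homology, landscape
from . import io as hio
from .datamodel import CountMatrix, OrthologPair

log = logging.getLogger("heterochron")


@dataclass
class PipelineConfig:
    species_a: str
    species_b: str
    counts_a: str
    samples_a: str
    counts_b: str
    samples_b: str
    orthogroups: str
    hits_ab: str | None = None
    hits_ba: str | None = None
    qlen_a: str | None = None
    qlen_b: str | None = None
    genome_hits_ab: str | None = None
    genome_hits_ba: str | None = None
    go_obo: str | None = None
    go_annotations_a: str | None = None
    go_annotations_b: str | None = None
    tf_list: str | None = None
    lfc_threshold: float = 2.0
    fdr: float = 0.05
    evalue_max: float = 1e-6
    coverage_min: float = 0.80
    similarity_min: float = 35.0
    membership_min: float = 0.3
    k: int | None = 12  # None -> choose by the Dmin elbow rule
    fuzzifier: float | None = None  # None -> estimated from data dimensions
    n_restarts: int = 10
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValueError("species labels must be distinct")
        if not (0 < self.fdr <= 1) or self.lfc_threshold < 0:
            raise ValueError("invalid DE thresholds")
        if not (0 < self.coverage_min <= 1) or not (0 <= self.similarity_min <= 100):
            raise ValueError("invalid homology thresholds")
        if not (0 <= self.membership_min <= 1):
            raise ValueError("membership_min must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # surface which stage failed
                raise StageError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all intermediate tables plus a run
    manifest into ``config.outdir``.  Returns the result bundle (in-memory
    tables keyed by name)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    # --- load + low-count filter ------------------------------------------
    @_stage("load")
    def load():
        cm_a = hio.read_count_matrix(config.counts_a, config.samples_a)
        cm_b = hio.read_count_matrix(config.counts_b, config.samples_b)
        return cm_a, cm_b

    cm_a_raw, cm_b_raw = load()
    cm_a = de.filter_low_counts(cm_a_raw)
    cm_b = de.filter_low_counts(cm_b_raw)
    log.info(
        "filter: %s %d->%d genes; %s %d->%d genes",
        config.species_a, cm_a_raw.n_genes, cm_a.n_genes,
        config.species_b, cm_b_raw.n_genes, cm_b.n_genes,
    )
    bundle["expressed_a"], bundle["expressed_b"] = cm_a, cm_b

    # --- differential expression ------------------------------------------
    @_stage("de")
    def run_de(cm: CountMatrix, tag: str):
        sf = de.estimate_size_factors(cm)
        results = de.nb_wald_test(cm, sf)
        results = de.mark_preferential(results, config.lfc_threshold, config.fdr)
        hio.write_table(results, out / f"de_{tag}.tsv")
        log.info("de[%s]: %d genes, %d preferential", tag, len(results),
                 int(results["preferential"].sum()))
        return sf, results

    sf_a, de_a = run_de(cm_a, "a")
    sf_b, de_b = run_de(cm_b, "b")
    pref_a = set(de_a.loc[de_a["preferential"], "gene_id"])
    pref_b = set(de_b.loc[de_b["preferential"], "gene_id"])
    bundle.update(size_factors_a=sf_a, size_factors_b=sf_b,
                  de_a=de_a, de_b=de_b,
                  preferential_a=pref_a, preferential_b=pref_b)

    # --- homology ----------------------------------------------------------
    @_stage("homology")
    def run_homology():
        ogt = hio.read_orthogroups(
            config.orthogroups, [config.species_a, config.species_b]
        )
        def passing(path, qlen_path):
            if path is None:
                return []
            hits = hio.read_hit_table(path)
            qlen = hio.read_query_lengths(qlen_path) if qlen_path else None
            return homology.filter_hits(
                hits, qlen, config.evalue_max, config.coverage_min,
                config.similarity_min,
            )
        hits_ab = passing(config.hits_ab, config.qlen_a)
        hits_ba = passing(config.hits_ba, config.qlen_b)
        calls_a = homology.classify_genes(
            cm_a.gene_ids, config.species_a, config.species_b, ogt, hits_ab
        )
        calls_b = homology.classify_genes(
            cm_b.gene_ids, config.species_b, config.species_a, ogt, hits_ba
        )
        calls_a = homology.rescue_with_genome_hits(
            calls_a, passing(config.genome_hits_ab, config.qlen_a)
        )
        calls_b = homology.rescue_with_genome_hits(
            calls_b, passing(config.genome_hits_ba, config.qlen_b)
        )
        pairs = homology.extract_one_to_one(
            ogt, config.species_a, config.species_b
        )
        enrich_a = homology.chi_square_enrichment(calls_a, pref_a)
        enrich_b = homology.chi_square_enrichment(calls_b, pref_b)
        hio.write_table(homology.classification_frame(calls_a + calls_b),
                        out / "classification.tsv")
        hio.write_table(
            [{"gene_a": p.gene_a, "gene_b": p.gene_b} for p in pairs],
            out / "one_to_one.tsv",
        )
        hio.write_table(
            [
                {"species": tag, "chi2": r.chi2, "df": r.df, "p": r.p,
                 "observed": json.dumps(r.observed)}
                for tag, r in (("a", enrich_a), ("b", enrich_b))
            ],
            out / "enrichment.tsv",
        )
        log.info("homology: %d one-to-one pairs; chi2 a=%.2f b=%.2f",
                 len(pairs), enrich_a.chi2, enrich_b.chi2)
        return ogt, calls_a, calls_b, pairs, enrich_a, enrich_b

    ogt, calls_a, calls_b, pairs, enrich_a, enrich_b = run_homology()
    bundle.update(orthogroups=ogt, classification_a=calls_a,
                  classification_b=calls_b, pairs=pairs,
                  enrichment_a=enrich_a, enrichment_b=enrich_b)

    # --- expression landscape ---------------------------------------------
    @_stage("landscape")
    def run_landscape():
        sm_a = landscape.stage_means(cm_a, sf_a)
        sm_b = landscape.stage_means(cm_b, sf_b)
        pca_scores = {}
        for tag, cm, sf, calls in (
            ("a", cm_a, sf_a, calls_a), ("b", cm_b, sf_b, calls_b),
        ):
            sporo = cm.sporophyte()
            norm = sporo.counts.to_numpy(float) / sf[sporo.sample_ids].to_numpy()
            obs = pd.DataFrame(norm.T, index=sporo.sample_ids,
                               columns=sporo.gene_ids)
            hom = {c.gene_id for c in calls if c.label == homology.HOMOLOGOUS}
            spec = {c.gene_id for c in calls if c.label == homology.SPECIES_SPECIFIC}
            for subset_name, subset in (
                ("all", None), ("homologous", hom), ("species_specific", spec),
            ):
                if subset is not None and not subset:
                    continue
                res = landscape.pca(obs, subset)
                scores = res.scores.copy()
                scores.insert(0, "sample_id", scores.index)
                scores.insert(1, "subset", subset_name)
                pca_scores[(tag, subset_name)] = (scores, res.variance_explained)
        rho, n_used = landscape.spearman_divergence(sm_a, sm_b, pairs)
        rho.to_csv(out / "divergence_matrix.tsv", sep="\t")
        all_scores = pd.concat([s for s, _ in pca_scores.values()][:1])
        hio.write_table(all_scores, out / "pca_scores.tsv")
        hio.write_table(
            pd.DataFrame(
                [
                    {"species": t, "subset": s,
                     "component": f"PC{i+1}", "variance_explained": v}
                    for (t, s), (_, ve) in pca_scores.items()
                    for i, v in enumerate(ve)
                ]
            ),
            out / "variance_explained.tsv",
        )
        log.info("landscape: divergence matrix over %d stage pairs", rho.size)
        return sm_a, sm_b, pca_scores, rho, n_used

    sm_a, sm_b, pca_scores, rho, n_used = run_landscape()
    bundle.update(stage_means_a=sm_a, stage_means_b=sm_b,
                  pca=pca_scores, divergence=rho, divergence_n=n_used)

    # --- clustering + heterochronic shifts --------------------------------
    @_stage("cluster")
    def run_cluster():
        # pre-clustering filter: one-to-one orthologs expressed (post
        # low-count filter) in both species with nonzero stage variance
        za, dropped_a = landscape.standardize_profiles(sm_a)
        zb, dropped_b = landscape.standardize_profiles(sm_b)
        usable = [
            p for p in pairs
            if p.gene_a in za.index and p.gene_b in zb.index
        ]
        if len(usable) < 3:
            raise ValueError("too few clusterable ortholog pairs")
        xa = za.loc[[p.gene_a for p in usable]]
        xb = zb.loc[[p.gene_b for p in usable]]
        xb.index = xa.index  # align on the pair's species-A gene for projection
        m = config.fuzzifier or clustering.estimate_fuzzifier(
            len(xa), xa.shape[1]
        )
        if config.k is None:
            profile = clustering.dmin_profile(
                xa, range(4, 41), m, seed=config.seed
            )
            k = clustering.select_k(profile)
        else:
            k = config.k
        model = clustering.fcm_fit(
            xa, k, m, seed=config.seed, n_restarts=config.n_restarts
        )
        mem_b, hard_b, maxmem_b = clustering.project_profiles(model, xb)
        major_map = clustering.assign_major_clusters(model)
        hard_a = model.hard_assignments()
        maxmem_a = model.max_memberships()
        # shift classification is keyed by each species' own gene ids
        hard_b_genes = hard_b.copy(); hard_b_genes.index = [p.gene_b for p in usable]
        maxmem_b_genes = maxmem_b.copy(); maxmem_b_genes.index = [p.gene_b for p in usable]
        shift_table, summary = clustering.classify_shifts(
            hard_a, maxmem_a, hard_b_genes, maxmem_b_genes, major_map,
            usable, config.membership_min,
        )
        model.centroids.to_csv(out / "cluster_model.tsv", sep="\t",
                               index_label="cluster")
        model.memberships.to_csv(out / "memberships.tsv", sep="\t",
                                 index_label="gene_id")
        hio.write_table(
            [{"minor_cluster": j, "major_cluster": mc}
             for j, mc in sorted(major_map.items())],
            out / "major_map.tsv",
        )
        hio.write_table(shift_table, out / "shift_table.tsv")
        hio.write_table([summary], out / "shift_summary.tsv")
        with open(out / "cluster_meta.json", "w", encoding="utf-8") as fh:
            json.dump({"k": k, "m": m, "objective": model.objective,
                       "n_clustered": len(usable), "seed": config.seed}, fh,
                      indent=1)
        log.info(
            "cluster: %d orthologs, k=%d, m=%.3f; %d conserved / %d "
            "heterochronic / %d excluded",
            len(usable), k, m, summary["n_conserved"],
            summary["n_heterochronic"], summary["n_excluded"],
        )
        tf_result = None
        if config.tf_list:
            tf_genes = hio.read_gene_list(config.tf_list)
            tf_result = clustering.tf_subset_comparison(shift_table, tf_genes)
            hio.write_table(
                [{"chi2": tf_result.chi2, "df": tf_result.df, "p": tf_result.p,
                  "observed": json.dumps(tf_result.observed)}],
                out / "tf_contrast.tsv",
            )
        return model, major_map, shift_table, summary, tf_result

    model, major_map, shift_table, shift_summary, tf_result = run_cluster()
    bundle.update(cluster_model=model, major_map=major_map,
                  shift_table=shift_table, shift_summary=shift_summary,
                  tf_contrast=tf_result)

    # --- GO enrichment ------------------------------------------------------
    if config.go_obo:
        @_stage("enrich")
        def run_enrich():
            dag = goenrich.load_go_dag(config.go_obo)
            results = {}
            for tag, cm, pref, calls, ann_path in (
                ("a", cm_a, pref_a, calls_a, config.go_annotations_a),
                ("b", cm_b, pref_b, calls_b, config.go_annotations_b),
            ):
                if not ann_path:
                    continue
                closed = goenrich.propagate_annotations(
                    dag, goenrich.read_annotations(ann_path)
                )
                universe = set(cm.gene_ids)
                hom = {c.gene_id for c in calls if c.label == homology.HOMOLOGOUS}
                for subset_name, study in (
                    ("homologous", pref & hom), ("species_specific", pref - hom),
                ):
                    res = goenrich.parent_child_fisher(
                        dag, closed, study, universe
                    )
                    enriched = goenrich.filter_enriched(res, alpha=0.05)
                    results[(tag, subset_name)] = enriched
                    hio.write_table(
                        [dataclasses.asdict(r) for r in enriched],
                        out / f"go_enriched_{tag}_{subset_name}.tsv",
                    )
            log.info("enrich: %s", {k: len(v) for k, v in results.items()})
            return results

        bundle["go_enrichment"] = run_enrich()

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": dataclasses.asdict(config),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return bundle


def report(bundle: dict) -> pd.DataFrame:
    """Summarize the run: per species the expressed / preferential /
    homologous counts and percentages, the enrichment chi-squares, and the
    conserved-vs-heterochronic breakdown of clustered orthologs."""
    required = ["expressed_a", "expressed_b", "preferential_a",
                "preferential_b", "classification_a", "classification_b",
                "enrichment_a", "enrichment_b", "shift_summary"]
    missing = [k for k in required if k not in bundle]
    if missing:
        raise ValueError(f"result bundle incomplete: missing {missing}")
    rows = []
    for tag in ("a", "b"):
        cm = bundle[f"expressed_{tag}"]
        pref = bundle[f"preferential_{tag}"]
        calls = bundle[f"classification_{tag}"]
        hom = [c for c in calls if c.label == homology.HOMOLOGOUS]
        pref_hom = [c for c in hom if c.gene_id in pref]
        n, npref, nhom = cm.n_genes, len(pref), len(hom)
        rows.append(
            {
                "species": tag,
                "n_expressed": n,
                "n_preferential": npref,
                "pct_preferential": 100.0 * npref / n,
                "n_homologous": nhom,
                "pct_homologous": 100.0 * nhom / n,
                "n_species_specific": n - nhom,
                "pct_homologous_in_preferential":
                    100.0 * len(pref_hom) / npref if npref else float("nan"),
                "enrichment_chi2": bundle[f"enrichment_{tag}"].chi2,
                "enrichment_p": bundle[f"enrichment_{tag}"].p,
            }
        )
    summary = bundle["shift_summary"]
    for row in rows:
        row.update(
            n_clustered=summary["n_assigned"] + summary["n_excluded"],
            n_conserved=summary["n_conserved"],
            n_heterochronic=summary["n_heterochronic"],
            pct_conserved=summary["pct_conserved"],
            pct_heterochronic=summary["pct_heterochronic"],
        )
        if bundle.get("tf_contrast") is not None:
            row["tf_contrast_chi2"] = bundle["tf_contrast"].chi2
            row["tf_contrast_p"] = bundle["tf_contrast"].p
    return pd.DataFrame(rows)
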