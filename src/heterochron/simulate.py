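"""Two-species synthetic count data with planted ground truth.

Emulates the comparative design downstream stages expect: two species
sharing one-to-one orthologs plus species-specific genes, negative-binomial
counts over four sporophyte stages x three replicates and a set of
gametophyte baseline samples, twelve planted temporal archetypes grouped
into early / mid / late major phases, a planted fraction of orthologs whose
species-B archetype is moved to a different major phase (heterochronic
shifts), and a planted fraction of sporophyte-preferential genes with a
stated log2 fold change.

Counts are NB2: Y ~ NB(mean = size_factor * baseline * archetype(stage) *
2^log2fc_planted, Var = mu + dispersion * mu^2), with per-sample size
factors drawn log-uniform in [0.5, 2] to exercise normalization.
Gametophyte samples carry the archetype-free baseline mean.  Every archetype
multiplier profile averages 1 across stages, so planted log2 fold changes
are exact in expectation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AlignmentHit, CountMatrix, OrthogroupTable, SampleRecord
from . import io as hio

# Twelve standardized 4-stage temporal shapes (rows sum to 0, sd 1), three
# peaking at each stage, designed once by constrained annealing for mutual
# separation (min pairwise distance 1.33) with each peak dominating stages
# of other major phases, so planted major-phase labels are unambiguous.
ARCHETYPE_SHAPES: np.ndarray = np.array(
    [
        [0.8683, 0.2888, 0.2855, -1.4426],
        [1.4999, -0.4911, -0.4951, -0.5137],
        [1.0427, 0.6691, -0.8467, -0.8650],
        [-0.0681, 1.4354, -0.6735, -0.6938],
        [-1.1454, 1.2948, -0.0611, -0.0883],
        [-0.2873, 1.0507, 0.4907, -1.2541],
        [-1.2191, 0.5739, 1.0213, -0.3761],
        [-0.0788, -0.0365, 1.2795, -1.1642],
        [-0.7521, -0.5940, 1.4397, -0.0935],
        [-0.8682, -0.8455, 0.6792, 1.0345],
        [-1.4679, 0.3424, 0.3452, 0.7803],
        [-0.5079, -0.4986, -0.4934, 1.5000],
    ]
)
# peak stage 1 -> early, stages 2-3 -> mid, stage 4 -> late
ARCHETYPE_MAJORS: list[str] = ["early"] * 3 + ["mid"] * 6 + ["late"] * 3
ARCHETYPE_CONTRAST = 0.6  # multiplier profile = 1 + contrast * shape (> 0)


@dataclass
class SimulationConfig:
    n_shared_orthologs: int = 1000
    n_specific_per_species: int = 200
    n_stages: int = 4
    n_replicates: int = 3
    n_gametophyte_samples: int = 6
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    archetypes: np.ndarray | None = None  # stage-multiplier profiles, rows avg 1
    archetype_majors: list[str] | None = None
    shift_fraction: float = 0.3
    de_fraction: float = 0.1
    de_log2fc: float = 3.0
    species: tuple[str, str] = ("speciesA", "speciesB")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.shift_fraction <= 1 and 0 <= self.de_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_stages < 2:
            raise ValueError("need at least 2 stages")
        if self.nb_dispersion < 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion must be >= 0 and baseline mean > 0")
        if self.n_shared_orthologs < 1 or self.n_specific_per_species < 0:
            raise ValueError("invalid gene counts")
        if self.species[0] == self.species[1]:
            raise ValueError("species labels must be distinct")
        if self.archetypes is None:
            if self.n_stages != 4:
                raise ValueError(
                    "default archetypes are 4-stage; supply archetypes for "
                    "other stage counts"
                )
            self.archetypes = 1.0 + ARCHETYPE_CONTRAST * ARCHETYPE_SHAPES
            self.archetype_majors = list(ARCHETYPE_MAJORS)
        else:
            self.archetypes = np.asarray(self.archetypes, dtype=float)
            if self.archetypes.ndim != 2 or self.archetypes.shape[1] != self.n_stages:
                raise ValueError("archetypes must be (n_archetypes, n_stages)")
            if (self.archetypes <= 0).any():
                raise ValueError("archetype multipliers must be positive")
            if self.archetype_majors is None:
                peak_major = (
                    lambda p: "early" if p == 0
                    else ("late" if p == self.n_stages - 1 else "mid")
                )
                self.archetype_majors = [
                    peak_major(int(np.argmax(a))) for a in self.archetypes
                ]
        if len(self.archetype_majors) != len(self.archetypes):
            raise ValueError("archetype_majors length mismatch")


@dataclass
class SimulationResult:
    counts_a: CountMatrix
    counts_b: CountMatrix
    orthogroups: OrthogroupTable
    hits_ab: list[AlignmentHit]
    hits_ba: list[AlignmentHit]
    query_lengths_a: dict[str, int]
    query_lengths_b: dict[str, int]
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _sample_sheet(species: str, cfg: SimulationConfig) -> list[SampleRecord]:
    samples = []
    for stage in range(1, cfg.n_stages + 1):
        for rep in range(1, cfg.n_replicates + 1):
            samples.append(
                SampleRecord(
                    sample_id=f"{species}_S{stage}_r{rep}",
                    species=species,
                    phase="sporophyte",
                    stage=str(stage),
                    replicate=rep,
                )
            )
    for g in range(1, cfg.n_gametophyte_samples + 1):
        samples.append(
            SampleRecord(
                sample_id=f"{species}_G_r{g}",
                species=species,
                phase="gametophyte",
                stage="G",
                replicate=g,
            )
        )
    return samples


def simulate_two_species(config: SimulationConfig) -> SimulationResult:
    """Generate both species' count matrices, the orthogroup table,
    reciprocal alignment hits for the shared orthologs, query-length tables,
    and the planted ground truth.  Fully deterministic under the config
    seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sp_a, sp_b = cfg.species
    n_arch = len(cfg.archetypes)
    n_shared = cfg.n_shared_orthologs
    n_spec = cfg.n_specific_per_species

    width = max(5, len(str(n_shared)))
    shared_a = [f"{sp_a}_og{i:0{width}d}" for i in range(n_shared)]
    shared_b = [f"{sp_b}_og{i:0{width}d}" for i in range(n_shared)]
    spec_a = [f"{sp_a}_sp{i:0{width}d}" for i in range(n_spec)]
    spec_b = [f"{sp_b}_sp{i:0{width}d}" for i in range(n_spec)]

    # planted archetypes; shifted orthologs move to a different major phase in B
    arch_a_shared = rng.integers(0, n_arch, n_shared)
    arch_b_shared = arch_a_shared.copy()
    n_shift = round(cfg.shift_fraction * n_shared)
    shifted = np.zeros(n_shared, dtype=bool)
    shifted[rng.permutation(n_shared)[:n_shift]] = True
    majors = np.array(cfg.archetype_majors)
    for i in np.flatnonzero(shifted):
        other = np.flatnonzero(majors != majors[arch_a_shared[i]])
        if other.size == 0:
            raise ValueError("cannot plant shifts: all archetypes share one major")
        arch_b_shared[i] = rng.choice(other)
    arch_spec_a = rng.integers(0, n_arch, n_spec)
    arch_spec_b = rng.integers(0, n_arch, n_spec)

    # planted sporophyte-preferential genes (shared units: both copies)
    n_units = n_shared + n_spec  # per-species gene count == n_units
    n_de = round(cfg.de_fraction * n_units)
    de_units = np.zeros(n_units, dtype=bool)
    de_units[rng.permutation(n_units)[:n_de]] = True

    samples_a = _sample_sheet(sp_a, cfg)
    samples_b = _sample_sheet(sp_b, cfg)

    def species_counts(samples, arch_ids, de_flags):
        sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
        stage_idx = np.array(
            [int(s.stage) - 1 if s.phase == "sporophyte" else -1 for s in samples]
        )
        n_genes = len(arch_ids)
        mu = np.empty((n_genes, len(samples)))
        for j, s in enumerate(samples):
            if stage_idx[j] >= 0:
                profile = cfg.archetypes[arch_ids, stage_idx[j]]
                mu[:, j] = (
                    sf[j]
                    * cfg.baseline_mean
                    * profile
                    * np.where(de_flags, 2.0**cfg.de_log2fc, 1.0)
                )
            else:
                mu[:, j] = sf[j] * cfg.baseline_mean
        return _nb_draw(rng, mu, cfg.nb_dispersion)

    genes_a = shared_a + spec_a
    genes_b = shared_b + spec_b
    arch_a_all = np.concatenate([arch_a_shared, arch_spec_a])
    arch_b_all = np.concatenate([arch_b_shared, arch_spec_b])
    de_a = np.concatenate([de_units[:n_shared], de_units[n_shared:]])
    counts_a = species_counts(samples_a, arch_a_all, de_a)
    counts_b = species_counts(samples_b, arch_b_all, de_a)

    cm_a = CountMatrix(
        pd.DataFrame(counts_a, index=genes_a,
                     columns=[s.sample_id for s in samples_a]),
        samples_a,
    )
    cm_b = CountMatrix(
        pd.DataFrame(counts_b, index=genes_b,
                     columns=[s.sample_id for s in samples_b]),
        samples_b,
    )

    orthogroups = OrthogroupTable(
        {
            f"OG{i:0{width}d}": {sp_a: [shared_a[i]], sp_b: [shared_b[i]]}
            for i in range(n_shared)
        }
    )

    qlen = 300
    hit_template = dict(
        percent_similarity=80.0, alignment_length=285, mismatches=40,
        gap_opens=2, q_start=10, q_end=294, s_start=10, s_end=294,
        evalue=1e-120, bitscore=500.0,
    )
    hits_ab = [
        AlignmentHit(query_id=shared_a[i], subject_id=shared_b[i], **hit_template)
        for i in range(n_shared)
    ]
    hits_ba = [
        AlignmentHit(query_id=shared_b[i], subject_id=shared_a[i], **hit_template)
        for i in range(n_shared)
    ]
    qlen_a = {g: qlen for g in genes_a}
    qlen_b = {g: qlen for g in genes_b}

    truth_rows = []
    for i in range(n_shared):
        truth_rows.append(
            {
                "gene_a": shared_a[i],
                "gene_b": shared_b[i],
                "archetype_a": int(arch_a_shared[i]),
                "archetype_b": int(arch_b_shared[i]),
                "major_a": majors[arch_a_shared[i]],
                "major_b": majors[arch_b_shared[i]],
                "shifted": bool(shifted[i]),
                "de_planted": bool(de_units[i]),
                "true_log2fc": cfg.de_log2fc if de_units[i] else 0.0,
                "species_specific": False,
            }
        )
    for i in range(n_spec):
        for gene_col, gene, arch in (
            ("gene_a", spec_a[i], arch_spec_a[i]),
            ("gene_b", spec_b[i], arch_spec_b[i]),
        ):
            row = {
                "gene_a": "", "gene_b": "",
                "archetype_a": "", "archetype_b": "",
                "major_a": "", "major_b": "",
                "shifted": False,
                "de_planted": bool(de_units[n_shared + i]),
                "true_log2fc": cfg.de_log2fc if de_units[n_shared + i] else 0.0,
                "species_specific": True,
            }
            side = "a" if gene_col == "gene_a" else "b"
            row[f"gene_{side}"] = gene
            row[f"archetype_{side}"] = int(arch)
            row[f"major_{side}"] = majors[arch]
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    return SimulationResult(
        counts_a=cm_a, counts_b=cm_b, orthogroups=orthogroups,
        hits_ab=hits_ab, hits_ba=hits_ba,
        query_lengths_a=qlen_a, query_lengths_b=qlen_b,
        truth=truth, config=cfg,
    )


def truth_summary(truth: pd.DataFrame) -> dict:
    """Counts of planted features; matches a brute-force recount of the
    truth table."""
    if truth.empty:
        return {
            "n_rows": 0, "n_shared": 0, "n_species_specific": 0,
            "n_shifted": 0, "n_conserved": 0, "n_de": 0,
            "shifted_fraction": float("nan"),
        }
    shared = truth[~truth["species_specific"]]
    n_shifted = int(shared["shifted"].sum())
    return {
        "n_rows": len(truth),
        "n_shared": len(shared),
        "n_species_specific": int(truth["species_specific"].sum()),
        "n_shifted": n_shifted,
        "n_conserved": len(shared) - n_shifted,
        "n_de": int(truth["de_planted"].sum()),
        "shifted_fraction": n_shifted / len(shared) if len(shared) else float("nan"),
    }


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Emit the simulation in the pipeline's external file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp_a, sp_b = result.config.species
    paths = {
        "counts_a": outdir / "counts_a.tsv",
        "samples_a": outdir / "samples_a.tsv",
        "counts_b": outdir / "counts_b.tsv",
        "samples_b": outdir / "samples_b.tsv",
        "orthogroups": outdir / "orthogroups.tsv",
        "hits_ab": outdir / "hits_ab.tsv",
        "hits_ba": outdir / "hits_ba.tsv",
        "qlen_a": outdir / "qlen_a.tsv",
        "qlen_b": outdir / "qlen_b.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    hio.write_count_matrix(result.counts_a, paths["counts_a"], paths["samples_a"])
    hio.write_count_matrix(result.counts_b, paths["counts_b"], paths["samples_b"])
    hio.write_orthogroups(result.orthogroups, paths["orthogroups"], [sp_a, sp_b])
    hio.write_hit_table(result.hits_ab, paths["hits_ab"])
    hio.write_hit_table(result.hits_ba, paths["hits_ba"])
    hio.write_query_lengths(result.query_lengths_a, paths["qlen_a"])
    hio.write_query_lengths(result.query_lengths_b, paths["qlen_b"])
    hio.write_table(result.truth, paths["ground_truth"])
    return paths
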