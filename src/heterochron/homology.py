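"""Homology classification and one-to-one ortholog extraction.

A gene is *homologous* if its orthogroup contains at least one gene of the
other species, or failing that if it has a cross-species protein alignment
hit passing the E-value / query-coverage / similarity filters; genes still
unaccounted for can be rescued by a passing protein-vs-genome hit.
Everything else is *species-specific*.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AlignmentHit, OrthogroupTable, OrthologPair

EVALUE_MAX = 1e-6
COVERAGE_MIN = 0.80
SIMILARITY_MIN = 35.0  # percent

HOMOLOGOUS = "homologous"
SPECIES_SPECIFIC = "species_specific"
EVIDENCE_ORTHOGROUP = "orthogroup"
EVIDENCE_PROTEIN_HIT = "protein_hit"
EVIDENCE_GENOME_RESCUE = "genome_rescue"
EVIDENCE_NONE = "none"


@dataclass(frozen=True)
class HomologyCall:
    gene_id: str
    species: str
    label: str  # homologous | species_specific
    evidence: str  # orthogroup | protein_hit | genome_rescue | none


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 Pearson chi-square test (df=1, no continuity correction)."""

    observed: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    p: float


def filter_hits(
    hits: Iterable[AlignmentHit],
    query_lengths: Mapping[str, int] | None = None,
    evalue_max: float = EVALUE_MAX,
    coverage_min: float = COVERAGE_MIN,
    similarity_min: float = SIMILARITY_MIN,
) -> list[AlignmentHit]:
    """Keep hits with E-value <= 1e-6, query coverage >= 80% and sequence
    similarity >= 35%.

    Coverage is the query span (q_end - q_start + 1) over the query length;
    each hit is judged independently (no HSP tiling).  A query with no known
    length is a hard error.
    """
    passing = []
    for hit in hits:
        length = hit.query_length
        if length is None:
            if query_lengths is None or hit.query_id not in query_lengths:
                raise ValueError(
                    f"query length unknown for {hit.query_id!r}; coverage "
                    "filtering is impossible"
                )
            length = query_lengths[hit.query_id]
        if (
            hit.evalue <= evalue_max
            and hit.query_coverage(length) >= coverage_min
            and hit.percent_similarity >= similarity_min
        ):
            passing.append(hit)
    return passing


def classify_genes(
    gene_ids: Sequence[str],
    species: str,
    other_species: str,
    orthogroups: OrthogroupTable,
    passing_hits: Iterable[AlignmentHit],
) -> list[HomologyCall]:
    """Classify each gene of ``species`` as homologous or species-specific.

    Evidence precedence: orthogroup membership spanning both species, then a
    passing protein hit; otherwise species-specific.
    """
    og_homologous: set[str] = set()
    for per_species in orthogroups.genes_by_species.values():
        if per_species.get(other_species):
            og_homologous.update(per_species.get(species, []))
    with_hit = {h.query_id for h in passing_hits}
    calls = []
    for gene in gene_ids:
        if gene in og_homologous:
            calls.append(HomologyCall(gene, species, HOMOLOGOUS, EVIDENCE_ORTHOGROUP))
        elif gene in with_hit:
            calls.append(HomologyCall(gene, species, HOMOLOGOUS, EVIDENCE_PROTEIN_HIT))
        else:
            calls.append(HomologyCall(gene, species, SPECIES_SPECIFIC, EVIDENCE_NONE))
    return calls


def rescue_with_genome_hits(
    classification: Sequence[HomologyCall],
    passing_genome_hits: Iterable[AlignmentHit],
) -> list[HomologyCall]:
    """Upgrade species-specific genes that have a passing protein-vs-genome
    hit in the other species; already-homologous genes are untouched."""
    rescued = {h.query_id for h in passing_genome_hits}
    out = []
    for call in classification:
        if call.label == SPECIES_SPECIFIC and call.gene_id in rescued:
            out.append(
                replace(call, label=HOMOLOGOUS, evidence=EVIDENCE_GENOME_RESCUE)
            )
        else:
            out.append(call)
    return out


def extract_one_to_one(
    orthogroups: OrthogroupTable, species_a: str, species_b: str
) -> list[OrthologPair]:
    """One-to-one orthologs: orthogroups with exactly one gene per focal
    species."""
    pairs = []
    for per_species in orthogroups.genes_by_species.values():
        genes_a = per_species.get(species_a, [])
        genes_b = per_species.get(species_b, [])
        if len(genes_a) == 1 and len(genes_b) == 1:
            pairs.append(OrthologPair(genes_a[0], genes_b[0]))
    return pairs


def chi_square_2x2(table) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    observed = np.asarray(table, dtype=float)
    if observed.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(observed, correction=False)
    obs_int = tuple(tuple(int(x) for x in row) for row in np.asarray(table))
    return ContingencyResult(observed=obs_int, chi2=float(chi2), df=int(df), p=float(p))


def chi_square_enrichment(
    classification: Sequence[HomologyCall], preferential: set[str]
) -> ContingencyResult:
    """Test whether species-specific genes are enriched among preferentially
    sporophyte-expressed genes.  Rows: {preferential, not}; columns:
    {homologous, species_specific}."""
    table = [[0, 0], [0, 0]]
    for call in classification:
        row = 0 if call.gene_id in preferential else 1
        col = 0 if call.label == HOMOLOGOUS else 1
        table[row][col] += 1
    return chi_square_2x2(table)


def classification_frame(calls: Sequence[HomologyCall]) -> pd.DataFrame:
    return pd.DataFrame([call.__dict__ for call in calls])
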