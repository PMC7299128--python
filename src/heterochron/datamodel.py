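"""Shared data model for the two-species comparative expression pipeline.

The pipeline compares gene expression across sporophyte development in two
moss species.  Samples belong to one of the two life-cycle phases
(haploid gametophyte, diploid sporophyte); sporophyte samples additionally
carry a developmental stage 1..4.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GAMETOPHYTE = "gametophyte"
SPOROPHYTE = "sporophyte"
PHASES = (GAMETOPHYTE, SPOROPHYTE)


class FormatError(ValueError):
    """A file does not conform to its expected tabular layout."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (ids, sample sets, orthogroups) do not."""


class EstimationError(RuntimeError):
    """A statistical estimate cannot be formed from the given data."""


@dataclass(frozen=True)
class SampleRecord:
    """One RNA-seq library: identity plus its place in the sampling design."""

    sample_id: str
    species: str
    phase: str
    stage: str  # "1".."4" for sporophyte samples, free label otherwise
    replicate: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"sample {self.sample_id!r}: phase must be one of {PHASES}, "
                f"got {self.phase!r}"
            )
        if self.phase == SPOROPHYTE and str(self.stage) not in {"1", "2", "3", "4"}:
            raise ValueError(
                f"sample {self.sample_id!r}: sporophyte stage must be 1..4, "
                f"got {self.stage!r}"
            )
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )

    @property
    def stage_number(self) -> int:
        if self.phase != SPOROPHYTE:
            raise ValueError(f"sample {self.sample_id!r} is not a sporophyte sample")
        return int(self.stage)


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with its sample metadata.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample, column order following ``samples``.
    """

    counts: pd.DataFrame
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConsistencyError(f"duplicate sample ids: {dup}")
        if list(self.counts.columns) != ids:
            raise ConsistencyError(
                "count matrix columns do not match the sample sheet order"
            )
        if self.counts.index.has_duplicates:
            dup = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise FormatError(f"duplicate gene ids: {dup}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        """Restrict to ``gene_ids``, preserving the current gene order."""
        keep = set(gene_ids)
        idx = [g for g in self.counts.index if g in keep]
        return CountMatrix(self.counts.loc[idx], list(self.samples))

    def subset_samples(self, predicate) -> "CountMatrix":
        kept = [s for s in self.samples if predicate(s)]
        return CountMatrix(self.counts[[s.sample_id for s in kept]], kept)

    def sporophyte(self) -> "CountMatrix":
        return self.subset_samples(lambda s: s.phase == SPOROPHYTE)

    def phase_labels(self) -> pd.Series:
        return pd.Series(
            [s.phase for s in self.samples], index=self.sample_ids, name="phase"
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular protein alignment report.

    Positions are 1-based inclusive on query and subject (the tabular
    alignment convention); ``percent_similarity`` holds whichever
    identity/positives column the hit file carries, on the 0..100 scale.
    """

    query_id: str
    subject_id: str
    percent_similarity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    query_length: int | None = None

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if self.evalue < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value"
            )

    def query_coverage(self, query_length: int | None = None) -> float:
        """Fraction of the query spanned by this alignment (query span
        convention: (q_end - q_start + 1) / query_length)."""
        length = query_length if query_length is not None else self.query_length
        if length is None:
            raise ValueError(
                f"query length unknown for {self.query_id!r}; cannot compute coverage"
            )
        return (self.q_end - self.q_start + 1) / length


@dataclass
class OrthogroupTable:
    """Orthogroups: per group, the member gene ids of each species.

    A gene id may appear in at most one orthogroup.
    """

    genes_by_species: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # orthogroup_id -> {species -> [gene ids]}

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og, per_species in self.genes_by_species.items():
            for genes in per_species.values():
                for g in genes:
                    if g in seen and seen[g] != og:
                        raise ConsistencyError(
                            f"gene {g!r} listed in orthogroups {seen[g]!r} and {og!r}"
                        )
                    seen[g] = og

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.genes_by_species)

    def species_of_gene(self) -> dict[str, tuple[str, str]]:
        """gene id -> (orthogroup id, species)."""
        out: dict[str, tuple[str, str]] = {}
        for og, per_species in self.genes_by_species.items():
            for sp, genes in per_species.items():
                for g in genes:
                    out[g] = (og, sp)
        return out


@dataclass(frozen=True)
class OrthologPair:
    """A one-to-one ortholog pair, one gene per species."""

    gene_a: str
    gene_b: str
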