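"""Readers and writers for the pipeline's external tabular formats.

All inputs and outputs are plain TSV: a counts file (genes x samples), a
sample sheet, 12/13-column tabular alignment hit files, an orthogroup table
with comma-separated per-species gene lists, and simple id/length and id
list files.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AlignmentHit,
    ConsistencyError,
    CountMatrix,
    FormatError,
    OrthogroupTable,
    SampleRecord,
)

SAMPLESHEET_COLUMNS = ["sample_id", "species", "phase", "stage", "replicate"]
HIT_COLUMNS = 12  # the classic tabular alignment layout; col 13 = query length


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise ValueError(
                f"{path}: replicate {row['replicate']!r} of sample "
                f"{row['sample_id']!r} is not an integer"
            ) from exc
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                species=row["species"],
                phase=row["phase"],
                stage=str(row["stage"]),
                replicate=rep,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dup}")
    return records


def read_count_matrix(
    path_counts: str | Path, path_samplesheet: str | Path
) -> CountMatrix:
    """Read a genes x samples TSV and its sample sheet into a CountMatrix.

    The sample sheet is the source of truth for sample metadata; the counts
    header must contain exactly its sample ids, and columns are reordered to
    sample-sheet order.
    """
    samples = read_sample_sheet(path_samplesheet)
    df = pd.read_csv(path_counts, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path_counts}: duplicate gene ids {dup}")
    sheet_ids = [s.sample_id for s in samples]
    extra = [c for c in df.columns if c not in set(sheet_ids)]
    missing = [c for c in sheet_ids if c not in set(df.columns)]
    if extra or missing:
        raise ConsistencyError(
            f"{path_counts}: samples disagree with the sample sheet "
            f"(missing from sheet: {extra}; missing from counts: {missing})"
        )
    df = df[sheet_ids]
    for col in df.columns:
        values = df[col]
        as_float = pd.to_numeric(values, errors="coerce")
        bad = as_float.isna() | (as_float != np.floor(as_float)) | (as_float < 0)
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path_counts}: non-integer or negative count "
                f"{values.loc[gene]!r} at gene {gene!r}, sample {col!r}"
            )
    return CountMatrix(df.astype(np.int64), samples)


def write_count_matrix(cm: CountMatrix, path_counts, path_samplesheet) -> None:
    cm.counts.to_csv(path_counts, sep="\t", index_label="gene_id")
    write_table([dataclasses.asdict(s) for s in cm.samples], path_samplesheet)


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file (optional 13th column =
    query length).  No filtering is applied at read time."""
    hits: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (HIT_COLUMNS, HIT_COLUMNS + 1):
                raise FormatError(
                    f"{path}:{lineno}: expected {HIT_COLUMNS} or "
                    f"{HIT_COLUMNS + 1} columns, got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_similarity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    query_length=int(fields[12]) if len(fields) == 13 else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fields = [
                h.query_id, h.subject_id, f"{h.percent_similarity:g}",
                str(h.alignment_length), str(h.mismatches), str(h.gap_opens),
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                f"{h.evalue:g}", f"{h.bitscore:g}",
            ]
            if h.query_length is not None:
                fields.append(str(h.query_length))
            fh.write("\t".join(fields) + "\n")


def read_orthogroups(
    path: str | Path, species_labels: Sequence[str]
) -> OrthogroupTable:
    """Read an orthogroup TSV: an orthogroup-id column followed by one
    comma-separated gene-list column per species.  Columns for species not in
    ``species_labels`` are ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    missing = [sp for sp in species_labels if sp not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing species columns {missing}")
    table: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = row[og_col]
        table[og] = {
            sp: [g.strip() for g in row[sp].split(",") if g.strip()]
            for sp in species_labels
        }
    return OrthogroupTable(table)


def write_orthogroups(
    table: OrthogroupTable, path, species_labels: Sequence[str]
) -> None:
    rows = [
        {
            "orthogroup": og,
            **{
                sp: ", ".join(per_species.get(sp, []))
                for sp in species_labels
            },
        }
        for og, per_species in table.genes_by_species.items()
    ]
    header = ["orthogroup", *species_labels]
    _write_rows(rows, header, path, allow_comma=True)


def read_query_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (id, length) derived from a FASTA index."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "length"], dtype=str)
    return {row["id"]: int(row["length"]) for _, row in df.iterrows()}


def write_query_lengths(lengths: dict[str, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene, length in lengths.items():
            fh.write(f"{gene}\t{length}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (e.g. a transcription-factor list)."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_rows(rows, header, path, allow_comma=True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            cells = []
            for col in header:
                cell = "" if row.get(col) is None else str(row[col])
                if "\t" in cell or "\n" in cell:
                    raise ValueError(
                        f"field {col!r} contains a delimiter character: {cell!r}"
                    )
                cells.append(cell)
            fh.write("\t".join(cells) + "\n")


def write_table(records, path) -> None:
    """Write records (dataclasses, dicts, or a DataFrame) as a TSV with
    header, preserving input order.  Fields containing tabs or newlines are
    rejected rather than quoted."""
    if isinstance(records, pd.DataFrame):
        rows = records.to_dict(orient="records")
        header = list(records.columns)
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records
        ]
        header = list(rows[0]) if rows else []
    if not header and not rows:
        # empty record list with no known schema: emit an empty file
        Path(path).write_text("", encoding="utf-8")
        return
    _write_rows(rows, header, path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
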