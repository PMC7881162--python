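"""Readers and writers for the pipeline's tabular formats.

Native tables are TSV with a header and 0-based half-open coordinates.
Two foreign dialects are supported for per-sample event tables:

* ``mats_like`` — rMATS-style columns (``exonStart_0base`` already 0-based,
  inclusion/skipping junction counts, per-condition inclusion levels);
* ``irfinder_like`` — IRFinder-style intron tables with 1-based inclusive
  starts (converted on read); every row is a retained intron.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, List, Sequence

import pandas as pd

from .events import SpliceEvent, ValidationError

NATIVE_COLUMNS = [
    "event_id", "gene", "event_class", "chrom", "start", "end", "strand",
    "p_value", "inclusion_reads", "exclusion_reads",
    "psi_treated", "psi_control", "delta_psi",
]

_MATS_CLASS_MAP = {"SE": "CE", "CE": "CE", "RI": "RI", "MXE": "MXE",
                   "A3SS": "A3SS", "A5SS": "A5SS"}


class SchemaError(ValueError):
    """A required column is absent from an input table."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _events_from_native(df: pd.DataFrame, path) -> List[SpliceEvent]:
    events = []
    for idx, row in df.iterrows():
        try:
            events.append(SpliceEvent(
                event_id=str(row["event_id"]),
                gene=str(row["gene"]),
                event_class=str(row["event_class"]),
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row["strand"]),
                p_value=float(row["p_value"]),
                inclusion_reads=int(row["inclusion_reads"]),
                exclusion_reads=int(row["exclusion_reads"]),
                psi_treated=float(row["psi_treated"]),
                psi_control=float(row["psi_control"]),
                delta_psi=float(row["delta_psi"]) if "delta_psi" in df.columns else None,
            ))
        except ValidationError as err:
            raise ValidationError(f"{path}: row {idx}: {err}") from err
    return events


def read_event_table(path: str | Path, dialect: str = "native") -> List[SpliceEvent]:
    """Read a per-sample event table into :class:`SpliceEvent` records.

    Coordinates are normalized to 0-based half-open regardless of dialect.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if dialect == "native":
        _require_columns(df, [c for c in NATIVE_COLUMNS if c != "delta_psi"], path)
        return _events_from_native(df, path)
    if dialect == "mats_like":
        required = ["ID", "GeneID", "event_type", "chr", "strand",
                    "exonStart_0base", "exonEnd", "PValue",
                    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IncLevel1", "IncLevel2"]
        _require_columns(df, required, path)
        native = pd.DataFrame({
            "event_id": df["ID"].astype(str),
            "gene": df["GeneID"],
            "event_class": df["event_type"].map(_MATS_CLASS_MAP),
            "chrom": df["chr"],
            "start": df["exonStart_0base"],
            "end": df["exonEnd"],
            "strand": df["strand"],
            "p_value": df["PValue"],
            "inclusion_reads": df["IJC_SAMPLE_1"],
            "exclusion_reads": df["SJC_SAMPLE_1"],
            "psi_treated": df["IncLevel1"],
            "psi_control": df["IncLevel2"],
        })
        return _events_from_native(native, path)
    if dialect == "irfinder_like":
        required = ["Chr", "Start", "End", "Name", "Strand", "p_diff",
                    "IntronDepth", "SpliceExact", "IRratio_treated",
                    "IRratio_control"]
        _require_columns(df, required, path)
        native = pd.DataFrame({
            "event_id": df["Name"].astype(str),
            "gene": df["Name"].astype(str).str.split("/").str[0],
            "event_class": "RI",
            "chrom": df["Chr"],
            "start": df["Start"] - 1,  # 1-based inclusive -> 0-based half-open
            "end": df["End"],
            "strand": df["Strand"],
            "p_value": df["p_diff"],
            "inclusion_reads": df["IntronDepth"],
            "exclusion_reads": df["SpliceExact"],
            "psi_treated": df["IRratio_treated"],
            "psi_control": df["IRratio_control"],
        })
        return _events_from_native(native, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_event_table(events: Iterable[SpliceEvent], path: str | Path) -> None:
    rows = [{col: getattr(ev, col) for col in NATIVE_COLUMNS} for ev in events]
    pd.DataFrame(rows, columns=NATIVE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_bed(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """Export events as BED6 (chrom, start, end, event_id, score=0, strand)."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.event_id}\t0\t{ev.strand}\n")


# ---------------------------------------------------------------------------
# Matrix-shaped and assay-shaped tables
# ---------------------------------------------------------------------------

def read_psi_matrix(path: str | Path) -> pd.DataFrame:
    """Events x samples PSI matrix; blank cells are missing quantifications."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_psi_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="event_id")


def read_labels(path: str | Path) -> pd.Series:
    """Sample -> responder label ('good'/'poor') table."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["sample_id", "label"], path)
    return df.set_index("sample_id")["label"]


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False)


def read_protein_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["gene", "log2fc", "detected"], path)
    return df


def write_protein_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> set:
    """One gene symbol per line."""
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_lda_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["arm", "cells_per_well", "wells", "positive_wells"], path)
    return df


def write_lda_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["assay_id", "sample_id", "condition", "size_bp",
                          "concentration"], path)
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["sample_id", "compound", "dose_nM", "replicate",
                          "response"], path)
    return df


def write_dose_response_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def file_checksum(path: str | Path) -> str:
    """sha256 of a file's bytes, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
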