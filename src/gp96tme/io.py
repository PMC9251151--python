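"""Readers and writers for the pipeline's delimited-text formats.

Cell tables and clinical tables are CSV, expression matrices are TSV
(genes × samples, TPM), gene sets are GMT, per-gene DE statistics are
CSV (gene, log2fc, padj).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .quantify import CELL_COLUMNS, CoreCellTable

CLINICAL_COLUMNS = ("patient_id", "grade", "idh", "os_months", "event")


def write_cores(cores: Iterable[CoreCellTable], path: str | Path) -> None:
    """All cores in one CSV: core_id, cell_id, area_mm2, x_um, y_um, flags."""
    frames = []
    for core in cores:
        df = core.cells.loc[:, list(CELL_COLUMNS)].copy()
        df.insert(0, "core_id", core.core_id)
        df.insert(1, "cell_id", [f"{core.core_id}_c{i}" for i in range(len(df))])
        df.insert(2, "area_mm2", core.area_mm2)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cores(path: str | Path) -> list[CoreCellTable]:
    df = pd.read_csv(path)
    required = {"core_id", "area_mm2", *CELL_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    cores = []
    for core_id, sub in df.groupby("core_id", sort=False):
        areas = sub["area_mm2"].unique()
        if len(areas) != 1:
            raise ValueError(f"{path}: core {core_id} has inconsistent area_mm2")
        cores.append(CoreCellTable(
            core_id=str(core_id), area_mm2=float(areas[0]),
            cells=sub.loc[:, list(CELL_COLUMNS)].reset_index(drop=True)))
    return cores


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    return df


def write_expression(tpm: pd.DataFrame, path: str | Path) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene symbols")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative TPM values")
    return df


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    from gseapy.parser import read_gmt

    return read_gmt(str(path))


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def write_deg_table(deg: pd.DataFrame, path: str | Path) -> None:
    deg.to_csv(path, index_label="gene")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    missing = {"log2fc", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DEG table missing columns {sorted(missing)}")
    return df
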