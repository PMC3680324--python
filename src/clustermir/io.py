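"""Readers and writers for the pipeline's tabular formats.

Everything is plain TSV so that inputs can be inspected and produced by hand:

* expression matrix — feature ids in the first column, sample ids in the
  header, one label file mapping sample id -> case/control;
* methylation probes — probe_id, chrom, pos, then one M-value column per
  sample;
* predictor target sites — mirna_id, gene_id, utr_id, chrom, start, end
  [, strand], either 0-based half-open or 1-based inclusive (converted on
  read);
* qPCR Ct wells — long format sample_id, assay_id, replicate, ct;
* gene sets — GMT (set id, description, member genes, tab separated).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

SITE_COLUMNS = ["mirna_id", "gene_id", "utr_id", "chrom", "start", "end"]


# -- expression ------------------------------------------------------------

def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs sample and group columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if ser.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in label file {path}")
    return ser


def write_labels(group: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": group.index, "group": group.values}).to_csv(
        path, sep="\t", index=False
    )


def read_expression_matrix(path: str | Path, label_path: str | Path) -> ExpressionMatrix:
    """Read a feature-by-sample TSV plus its sample label file.

    Raises if any matrix sample lacks a label or a feature id repeats.
    Missing cells (empty / NA) become NaN.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), read_labels(label_path))


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, label_path: str | Path | None = None
) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    if label_path is not None:
        write_labels(matrix.group, label_path)


# -- methylation probes ----------------------------------------------------

def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Probe table: probe_id, chrom, pos, then per-sample M-value columns."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = ["probe_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"probe table {path} missing columns {missing}")
    if df.shape[1] <= 3:
        raise ValueError(f"probe table {path} has no sample columns")
    if df["probe_id"].duplicated().any():
        raise ValueError(f"duplicate probe ids in {path}")
    df["pos"] = df["pos"].astype(int)
    return df


def write_probe_table(probes: pd.DataFrame, path: str | Path) -> None:
    probes.to_csv(path, sep="\t", index=False)


# -- predictor target sites ------------------------------------------------

def read_site_table(
    path: str | Path, source: str, coords: str = "bed"
) -> pd.DataFrame:
    """Read one predictor's target-site list.

    ``coords`` names the dialect: "bed" (0-based half-open, stored as-is) or
    "one-based" (1-based inclusive; converted by start -= 1). A ``strand``
    column is kept when present.
    """
    if coords not in ("bed", "one-based"):
        raise ValueError(f"unknown coordinate dialect {coords!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} missing columns {missing}")
    df = df.copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if coords == "one-based":
        df["start"] -= 1
    if (df["start"] >= df["end"]).any():
        raise ValueError(
            f"site table {path}: non-positive interval width after coordinate "
            f"conversion; check the coords dialect"
        )
    df["source"] = source
    return df


def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


# -- qPCR ------------------------------------------------------------------

def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format Ct wells: sample_id, assay_id, replicate, ct."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay_id": str})
    required = ["sample_id", "assay_id", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table {path} missing columns {missing}")
    df["ct"] = df["ct"].astype(float)
    if (df["ct"] <= 0).any() or not np.isfinite(df["ct"]).all():
        raise ValueError(f"Ct table {path}: Ct values must be finite and > 0")
    return df


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- gene sets (GMT) -------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read GMT gene sets: one set per line, id <tab> name <tab> genes..."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            set_id, name = parts[0], parts[1]
            members = sorted({g for g in parts[2:] if g})
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {set_id} is empty")
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id}")
            sets[set_id] = {"name": name, "members": members}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, rec in sets.items():
            fh.write("\t".join([set_id, rec["name"], *rec["members"]]) + "\n")
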