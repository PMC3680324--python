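"""qPCR ΔCt / ΔΔCt fold-change analysis.

Replicate wells are averaged per (sample, assay); ΔCt normalizes each assay
to the mean of the reference assays within the same sample (miR-92a for
miRNA panels, B2M for mRNA); ΔΔCt subtracts the mean control ΔCt per assay;
fold change is 2^(-ΔΔCt) assuming perfect doubling. Calls use inclusive
boundaries: fold change <= fc_down is "down", >= fc_up "up", in between
"non_differential".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .de import mann_whitney


@dataclass
class CtTable:
    """Long-format Ct wells plus the normalization/grouping metadata."""

    wells: pd.DataFrame  # sample_id, assay_id, replicate, ct
    reference_assays: list[str]
    group: pd.Series  # sample_id -> case/control

    def __post_init__(self) -> None:
        if not self.reference_assays:
            raise ValueError("at least one reference assay is required")
        if (self.wells["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")
        samples = self.wells["sample_id"].unique()
        unlabeled = [s for s in samples if s not in self.group.index]
        if unlabeled:
            raise ValueError(f"samples without a group label: {unlabeled[:5]}")
        have = self.wells.groupby("sample_id")["assay_id"].apply(set)
        for s in samples:
            missing = set(self.reference_assays) - have[s]
            if missing:
                raise ValueError(
                    f"sample {s!r} lacks reference assay(s) {sorted(missing)}"
                )


def collapse_replicates(table: CtTable, flag_cycles: float = 1.0) -> pd.DataFrame:
    """Average replicate wells per (sample, assay).

    Reports the replicate spread (max - min) and flags pairs whose spread
    exceeds ``flag_cycles`` or that have a single well; flagged values are
    retained.
    """
    g = table.wells.groupby(["sample_id", "assay_id"])["ct"]
    out = g.agg(ct="mean", spread=lambda v: v.max() - v.min(), n_rep="count")
    out = out.reset_index()
    out["flagged"] = (out["spread"] > flag_cycles) | (out["n_rep"] == 1)
    return out


def delta_ct(table: CtTable, flag_cycles: float = 1.0) -> pd.DataFrame:
    """ΔCt per (sample, assay): mean replicate Ct minus the mean of the
    sample's reference-assay Cts. Reference assays stay in the output (a
    single reference normalizes to ΔCt 0 against itself)."""
    collapsed = collapse_replicates(table, flag_cycles)
    ref = (
        collapsed[collapsed["assay_id"].isin(table.reference_assays)]
        .groupby("sample_id")["ct"].mean()
        .rename("ref_ct")
    )
    out = collapsed.merge(ref, on="sample_id")
    out["delta_ct"] = out["ct"] - out["ref_ct"]
    out["group"] = out["sample_id"].map(table.group)
    return out


@dataclass
class FoldChangeCalls:
    """Per case-sample and per-assay ΔΔCt fold changes and labels."""

    per_sample: pd.DataFrame  # sample_id, assay_id, delta_ct, delta_delta_ct, fold_change, label
    per_assay: pd.DataFrame  # assay_id, mean ΔΔCt across cases, fold_change, label

    def summary(self) -> str:
        counts = self.per_assay["label"].value_counts()
        n = len(self.per_assay)
        down = counts.get("down", 0)
        return (
            f"Fold-change classification over {n} assays: {down} down "
            f"({100 * down / n:.0f}%), {counts.get('up', 0)} up, "
            f"{counts.get('non_differential', 0)} non-differential."
        )


def _label(fc: np.ndarray, config: RunConfig) -> np.ndarray:
    return np.select(
        [fc <= config.fc_down, fc >= config.fc_up],
        ["down", "up"], default="non_differential",
    )


def fold_change_calls(delta_cts: pd.DataFrame, config: RunConfig,
                      exclude_references: list[str] | None = None) -> FoldChangeCalls:
    """ΔΔCt fold changes of case samples relative to the mean control ΔCt.

    The per-assay table averages ΔΔCt over case samples before converting to
    a fold change, mirroring a per-miRNA (rather than per-sample) call.
    """
    df = delta_cts
    if exclude_references:
        df = df[~df["assay_id"].isin(exclude_references)]
    baseline = (
        df[df["group"] == "control"].groupby("assay_id")["delta_ct"]
        .mean().rename("baseline")
    )
    assays = df["assay_id"].unique()
    missing = [a for a in assays if a not in baseline.index]
    if missing:
        raise ValueError(f"assay(s) with no control samples: {missing[:5]}")
    cases = df[df["group"] == "case"].merge(baseline, on="assay_id")
    cases = cases.copy()
    cases["delta_delta_ct"] = cases["delta_ct"] - cases["baseline"]
    cases["fold_change"] = np.exp2(-cases["delta_delta_ct"])
    cases["label"] = _label(cases["fold_change"].to_numpy(), config)
    per_sample = cases[["sample_id", "assay_id", "delta_ct",
                        "delta_delta_ct", "fold_change", "label"]]
    per_assay = (
        cases.groupby("assay_id", as_index=False)["delta_delta_ct"].mean()
    )
    per_assay["fold_change"] = np.exp2(-per_assay["delta_delta_ct"])
    per_assay["label"] = _label(per_assay["fold_change"].to_numpy(), config)
    return FoldChangeCalls(
        per_sample=per_sample.reset_index(drop=True), per_assay=per_assay
    )


def group_test(delta_cts: pd.DataFrame,
               exclude_references: list[str] | None = None) -> pd.DataFrame:
    """Two-tailed Mann-Whitney U test on ΔCt, case vs control, per assay."""
    df = delta_cts
    if exclude_references:
        df = df[~df["assay_id"].isin(exclude_references)]
    rows = []
    for assay, grp in df.groupby("assay_id"):
        x = grp.loc[grp["group"] == "case", "delta_ct"].to_numpy()
        y = grp.loc[grp["group"] == "control", "delta_ct"].to_numpy()
        if x.size == 0 or y.size == 0:
            raise ValueError(f"assay {assay!r} lacks a case or control group")
        res = mann_whitney(x, y, "two-sided")
        rows.append(dict(assay_id=assay, n_case=x.size, n_control=y.size,
                         u_stat=res.u_stat, p_two=res.p_value))
    return pd.DataFrame(rows)
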