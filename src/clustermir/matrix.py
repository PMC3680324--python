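"""Feature-by-sample expression container with case/control labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Normalized log-expression values for features x samples.

    ``values`` is a features-by-samples DataFrame (log scale; the pipeline
    never exponentiates, so the log base does not matter). ``group`` maps
    every sample id to "case" or "control". Missing observations are NaN and
    are dropped per feature at test time, never treated as zero.
    """

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        unlabeled = [s for s in self.values.columns if s not in self.group.index]
        if unlabeled:
            raise ValueError(
                f"samples without a group label: {unlabeled[:5]}"
            )
        self.group = self.group.reindex(self.values.columns)
        bad = self.group[~self.group.isin(GROUPS)]
        if len(bad):
            raise ValueError(
                f"group labels must be in {GROUPS}; offending samples: "
                f"{list(bad.index)[:5]}"
            )
        if (self.group == "case").sum() < 1 or (self.group == "control").sum() < 1:
            raise ValueError("need at least one case and one control sample")
        with np.errstate(invalid="ignore"):
            finite = np.isfinite(self.values.to_numpy(dtype=float))
        if (~finite & self.values.notna().to_numpy()).any():
            raise ValueError("expression values must be finite where present")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.group.index[self.group == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.group.index[self.group == "control"])

    @property
    def n_case(self) -> int:
        return len(self.case_samples)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def case_values(self) -> pd.DataFrame:
        return self.values[self.case_samples]

    def control_values(self) -> pd.DataFrame:
        return self.values[self.control_samples]

    def swap_labels(self) -> "ExpressionMatrix":
        """Return a copy with case and control labels exchanged."""
        swapped = self.group.map({"case": "control", "control": "case"})
        return ExpressionMatrix(self.values.copy(), swapped)
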