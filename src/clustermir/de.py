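"""Per-feature nonparametric differential expression.

The workhorse is the Mann-Whitney U test (two-tailed for significance,
one-tailed for direction), followed by multiplicity correction over the
features actually tested. A feature is called "down" when its corrected
one-tailed case<control p-value passes alpha, "up" symmetrically, else
"unchanged"; the median case-control difference is reported for annotation
only and never gates a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .matrix import ExpressionMatrix

TAILS = ("two-sided", "less", "greater")

#: largest per-group size at which the exact (enumeration) null is used
EXACT_MAX_N = 8

RESULT_COLUMNS = [
    "feature_id", "n_case", "n_control", "u_stat",
    "p_two", "p_less", "p_greater",
    "p_adj", "p_adj_less", "p_adj_greater", "p_adj_dir",
    "median_diff", "call",
]


@dataclass(frozen=True)
class MannWhitneyResult:
    u_stat: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(case_values, control_values, tail: str = "two-sided") -> MannWhitneyResult:
    """Mann-Whitney U test of case vs control values.

    Uses the exact enumeration null when both groups have at most
    ``EXACT_MAX_N`` observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections. ``tail="less"`` tests
    the alternative that cases are stochastically smaller than controls.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: no ordering information at all
        return MannWhitneyResult(x.size * y.size / 2.0, 1.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=tail, method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


def adjust_p(p_values, method: str, n_tests: int | None = None) -> np.ndarray:
    """Correct a vector of p-values for multiple testing.

    ``bonferroni`` multiplies by ``n_tests`` (default: the vector length,
    i.e. the number of features actually tested) capped at 1; ``bh_fdr`` is
    Benjamini-Hochberg step-up; ``none`` returns the input unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or not np.isfinite(p).all()):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        n = n_tests if n_tests is not None else p.size
        return np.minimum(1.0, p * n)
    if method == "bh_fdr":
        if n_tests is not None and n_tests != p.size:
            raise ValueError("bh_fdr corrects over the tested features only")
        if p.size == 0:
            return p.copy()
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction method {method!r}")


@dataclass
class DEResults:
    """Differential-expression table plus the features skipped for lack of data."""

    table: pd.DataFrame
    skipped: list[str] = field(default_factory=list)
    n_tested: int = 0

    @property
    def down_ids(self) -> list[str]:
        return list(self.table.loc[self.table["call"] == "down", "feature_id"])

    @property
    def up_ids(self) -> list[str]:
        return list(self.table.loc[self.table["call"] == "up", "feature_id"])

    def summary(self) -> str:
        t = self.table
        return (
            f"Differential expression: {self.n_tested} features tested, "
            f"{len(self.down_ids)} down, {len(self.up_ids)} up, "
            f"{(t['call'] == 'unchanged').sum()} unchanged; "
            f"{len(self.skipped)} skipped for missing data."
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _vectorised_tests(case: np.ndarray, control: np.ndarray) -> dict[str, np.ndarray]:
    """Asymptotic M-W p-values for every row at once (complete data only)."""
    out = {}
    for tail, key in (("two-sided", "p_two"), ("less", "p_less"), ("greater", "p_greater")):
        res = stats.mannwhitneyu(
            case, control, alternative=tail, method="asymptotic", axis=-1
        )
        out[key] = np.asarray(res.pvalue, dtype=float)
        if tail == "two-sided":
            out["u_stat"] = np.asarray(res.statistic, dtype=float)
    return out


def call_features(matrix: ExpressionMatrix, config: RunConfig) -> DEResults:
    """Test every feature and attach corrected directional calls.

    Features with no data in one of the groups are skipped and listed in the
    result. The correction N is the number of features tested, not the
    nominal array size.
    """
    case_df = matrix.case_values()
    ctrl_df = matrix.control_values()
    case = case_df.to_numpy(dtype=float)
    ctrl = ctrl_df.to_numpy(dtype=float)
    features = matrix.feature_ids

    complete = not (np.isnan(case).any() or np.isnan(ctrl).any())
    rows: list[dict] = []
    skipped: list[str] = []

    if complete and min(case.shape[1], ctrl.shape[1]) > EXACT_MAX_N:
        # fast path: one vectorised asymptotic call per tail
        degenerate = np.ptp(np.concatenate([case, ctrl], axis=1), axis=1) == 0
        stats_v = _vectorised_tests(case, ctrl)
        med_diff = np.median(case, axis=1) - np.median(ctrl, axis=1)
        for i, fid in enumerate(features):
            if degenerate[i]:
                rows.append(dict(
                    feature_id=fid, n_case=case.shape[1], n_control=ctrl.shape[1],
                    u_stat=case.shape[1] * ctrl.shape[1] / 2.0,
                    p_two=1.0, p_less=1.0, p_greater=1.0,
                    median_diff=0.0,
                ))
            else:
                rows.append(dict(
                    feature_id=fid, n_case=case.shape[1], n_control=ctrl.shape[1],
                    u_stat=float(stats_v["u_stat"][i]),
                    p_two=float(stats_v["p_two"][i]),
                    p_less=float(stats_v["p_less"][i]),
                    p_greater=float(stats_v["p_greater"][i]),
                    median_diff=float(med_diff[i]),
                ))
    else:
        for i, fid in enumerate(features):
            x = case[i][~np.isnan(case[i])]
            y = ctrl[i][~np.isnan(ctrl[i])]
            if x.size == 0 or y.size == 0:
                skipped.append(fid)
                continue
            two = mann_whitney(x, y, "two-sided")
            less = mann_whitney(x, y, "less")
            greater = mann_whitney(x, y, "greater")
            rows.append(dict(
                feature_id=fid, n_case=int(x.size), n_control=int(y.size),
                u_stat=two.u_stat, p_two=two.p_value,
                p_less=less.p_value, p_greater=greater.p_value,
                median_diff=float(np.median(x) - np.median(y)),
            ))

    table = pd.DataFrame(rows)
    n_tested = len(table)
    if n_tested:
        method = config.correction_method
        table["p_adj"] = adjust_p(table["p_two"], method, n_tested)
        table["p_adj_less"] = adjust_p(table["p_less"], method, n_tested)
        table["p_adj_greater"] = adjust_p(table["p_greater"], method, n_tested)
        down = table["p_adj_less"] < config.alpha
        up = table["p_adj_greater"] < config.alpha
        if config.require_two_tailed:
            passed = table["p_adj"] < config.alpha
            down &= passed
            up &= passed
        table["p_adj_dir"] = np.minimum(table["p_adj_less"], table["p_adj_greater"])
        table["call"] = np.select([down, up], ["down", "up"], default="unchanged")
        table = table[RESULT_COLUMNS]
    else:
        table = pd.DataFrame(columns=RESULT_COLUMNS)
    return DEResults(table=table, skipped=skipped, n_tested=n_tested)
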