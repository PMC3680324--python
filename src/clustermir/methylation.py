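"""Regional methylation scoring from Illumina 450K-style M-values.

M-values (log2 methylated/unmethylated intensity ratios) are converted to
beta-values with beta = 2^M / (2^M + 1); a genomic region is scored by the
median of all its probe-by-sample betas and called hypermethylated when the
median exceeds ``beta_hyper`` (strictly), hypomethylated below ``beta_hypo``,
normal otherwise. Significance of hypermethylation of a target region is
assessed with a one-tailed Welch t-test against probe-count-matched random
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import RunConfig
from .regions import GenomicRegion

LN2 = np.log(2.0)


def m_to_beta(m):
    """Convert M-values to beta-values: beta = 2^m / (2^m + 1).

    Computed as a logistic in base 2, which is numerically stable for large
    |m| and strictly increasing. Non-finite inputs propagate as NaN.
    """
    m = np.asarray(m, dtype=float)
    out = np.where(np.isfinite(m), expit(m * LN2), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def beta_to_m(beta):
    """Inverse of :func:`m_to_beta` on (0, 1): m = log2(beta / (1 - beta))."""
    beta = np.asarray(beta, dtype=float)
    out = np.log2(beta) - np.log2(1.0 - beta)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class RegionMethylation:
    region: GenomicRegion
    n_probes: int
    beta_values: np.ndarray  # pooled probe x sample betas, NaN dropped
    median_beta: float
    call: str  # hyper | hypo | normal

    def summary(self) -> str:
        return (
            f"{self.region.name}: {self.n_probes} probes, median beta "
            f"{self.median_beta:.3f} -> {self.call}"
        )


def _sample_columns(probes: pd.DataFrame) -> list[str]:
    return [c for c in probes.columns if c not in ("probe_id", "chrom", "pos")]


def score_region(
    probes: pd.DataFrame, region: GenomicRegion, config: RunConfig
) -> RegionMethylation:
    """Pool all in-region probe-by-sample betas and call methylation status.

    Calls use strict inequalities, so a median of exactly ``beta_hyper`` is
    still "normal".
    """
    mask = (probes["chrom"] == region.chrom) & \
           (probes["pos"] >= region.start) & (probes["pos"] < region.end)
    sub = probes.loc[mask, _sample_columns(probes)]
    if sub.empty:
        raise ValueError(f"region {region.name!r} contains no probes")
    m = sub.to_numpy(dtype=float).ravel()
    betas = m_to_beta(m[np.isfinite(m)])
    if betas.size == 0:
        raise ValueError(f"region {region.name!r} has no finite M-values")
    median = float(np.median(betas))
    if median > config.beta_hyper:
        call = "hyper"
    elif median < config.beta_hypo:
        call = "hypo"
    else:
        call = "normal"
    return RegionMethylation(
        region=region, n_probes=int(mask.sum()), beta_values=betas,
        median_beta=median, call=call,
    )


def pick_random_regions(
    probes: pd.DataFrame, target: GenomicRegion, n_regions: int, seed: int,
    tolerance: float = 0.1,
) -> list[GenomicRegion]:
    """Pick contiguous probe windows matched to the target's probe count.

    Windows cover consecutive probes on one chromosome, contain within
    +/- ``tolerance`` (default 10%) of the target region's probe count, and
    are disjoint from the target and from each other. Raises (reporting the
    achieved count) when the probe map cannot supply ``n_regions`` windows.
    """
    target_score_mask = (probes["chrom"] == target.chrom) & \
        (probes["pos"] >= target.start) & (probes["pos"] < target.end)
    n_target = int(target_score_mask.sum())
    if n_target == 0:
        raise ValueError(f"target region {target.name!r} contains no probes")
    k_min = max(1, int(np.ceil(n_target * (1 - tolerance))))
    k_max = int(np.floor(n_target * (1 + tolerance)))

    rng = np.random.default_rng(seed)
    by_chrom = {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in probes.groupby("chrom")
    }
    # candidate (chrom, start_index) pairs for a window of k_max probes are a
    # superset of smaller windows; enumerate starts for the minimum size
    candidates = [
        (chrom, i)
        for chrom, pos in by_chrom.items()
        for i in range(0, len(pos) - k_min + 1)
    ]
    order = rng.permutation(len(candidates))
    chosen: list[GenomicRegion] = []
    taken: list[GenomicRegion] = [target]
    for idx in order:
        if len(chosen) == n_regions:
            break
        chrom, i = candidates[idx]
        pos = by_chrom[chrom]
        k = int(rng.integers(k_min, min(k_max, len(pos) - i) + 1)) \
            if len(pos) - i >= k_min else 0
        if k < k_min:
            continue
        region = GenomicRegion(
            chrom, int(pos[i]), int(pos[i + k - 1]) + 1,
            name=f"random{len(chosen) + 1}",
        )
        if any(region.overlaps(t) for t in taken):
            continue
        chosen.append(region)
        taken.append(region)
    if len(chosen) < n_regions:
        raise ValueError(
            f"could only place {len(chosen)} of {n_regions} probe-matched "
            f"random regions"
        )
    return chosen


def hypermethylation_test(
    target: RegionMethylation, controls: list[RegionMethylation],
    mode: str = "pooled",
) -> float:
    """One-tailed Welch t-test that the target region's betas exceed the
    control regions'.

    ``mode="pooled"`` (default) pools every control probe-by-sample beta into
    one comparison group; ``mode="region_medians"`` compares the target's
    median beta against the control region medians (n = number of control
    regions), a conservative variant since pooling inflates n.
    """
    if not controls:
        raise ValueError("need at least one control region")
    if mode == "pooled":
        a = target.beta_values
        b = np.concatenate([c.beta_values for c in controls])
    elif mode == "region_medians":
        a = np.asarray([target.median_beta])
        b = np.asarray([c.median_beta for c in controls])
        # one observed target median vs the null spread of control medians
        if b.size < 2:
            raise ValueError("region_medians mode needs >= 2 control regions")
        t = (a[0] - b.mean()) / (b.std(ddof=1) * np.sqrt(1 + 1 / b.size))
        return float(stats.t.sf(t, df=b.size - 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 beta values in target and controls")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 1.0
        return 0.0 if a.mean() > b.mean() else 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)


@dataclass
class MethylationAnalysis:
    """Scored target + control regions and the hypermethylation test."""

    target: RegionMethylation
    controls: list[RegionMethylation]
    p_pooled: float
    p_region_medians: float | None

    def summary(self) -> str:
        lines = [self.target.summary()]
        lines += [c.summary() for c in self.controls]
        lines.append(f"Hypermethylation one-tailed t-test (pooled betas): "
                     f"p = {self.p_pooled:.3g}")
        if self.p_region_medians is not None:
            lines.append(f"Hypermethylation test (region medians): "
                         f"p = {self.p_region_medians:.3g}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rm, is_target in [(self.target, True)] + [(c, False) for c in self.controls]:
            rows.append(dict(
                region=rm.region.name, chrom=rm.region.chrom,
                start=rm.region.start, end=rm.region.end,
                n_probes=rm.n_probes, median_beta=rm.median_beta,
                call=rm.call, is_target=is_target,
            ))
        return pd.DataFrame(rows)


def analyse_target_region(
    probes: pd.DataFrame, target: GenomicRegion,
    control_regions: list[GenomicRegion] | None, config: RunConfig,
    n_random_regions: int | None = None,
) -> MethylationAnalysis:
    """Score the target against explicit and/or randomly picked control
    regions and run both test variants."""
    controls = list(control_regions or [])
    if n_random_regions:
        controls += pick_random_regions(
            probes, target, n_random_regions, config.rng_seed
        )
    if not controls:
        raise ValueError("no control regions given and none requested")
    target_rm = score_region(probes, target, config)
    control_rms = [score_region(probes, r, config) for r in controls]
    p_pooled = hypermethylation_test(target_rm, control_rms, mode="pooled")
    p_med = None
    if len(control_rms) >= 2:
        p_med = hypermethylation_test(target_rm, control_rms, mode="region_medians")
    return MethylationAnalysis(target_rm, control_rms, p_pooled, p_med)
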