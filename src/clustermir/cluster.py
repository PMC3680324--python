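"""Cluster-level coordinated-downregulation test.

Given per-feature down/up calls, decides whether a defined cluster (e.g. the
miR-379/miR-656 cluster on 14q32.31) contains more down-called members than
expected by chance, two ways:

* a 2x2 chi-square test of proportions — cluster vs the non-cluster
  complement, down vs not-down;
* a descriptive random-set null — repeated draws of non-cluster feature sets
  of the cluster's size, summarised by the range and a Student-t 95% CI of
  the mean down count (optionally an empirical tail probability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import RunConfig
from .de import DEResults


@dataclass(frozen=True)
class ClusterDefinition:
    name: str
    member_feature_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_feature_ids:
            raise ValueError(f"cluster {self.name!r} has no members")

    @classmethod
    def from_ids(cls, name: str, ids) -> "ClusterDefinition":
        return cls(name, frozenset(str(i) for i in ids))


@dataclass
class RandomSetNull:
    n_sets: int
    set_size: int
    down_counts: list[int]
    mean: float
    min: int
    max: int
    ci95: tuple[float, float] | None
    empirical_p: float | None = None

    def summary(self) -> str:
        ci = (
            f"95% CI of the mean {self.ci95[0]:.2f}-{self.ci95[1]:.2f}"
            if self.ci95 else "CI not available (<2 sets)"
        )
        return (
            f"Random-set null ({self.n_sets} sets of {self.set_size}): down "
            f"counts ranged {self.min}-{self.max}, mean {self.mean:.2f}; {ci}."
        )


@dataclass
class ClusterEnrichmentResult:
    cluster_name: str
    table: np.ndarray  # [[cluster down, cluster not-down], [bg down, bg not-down]]
    chi2_stat: float
    p_chi2: float
    yates: bool
    cluster_down_fraction: float
    background_down_fraction: float
    cluster_share_of_down: float
    null: RandomSetNull | None = None

    def summary(self) -> str:
        (cd, cn), (bd, bn) = self.table
        lines = [
            f"Cluster {self.cluster_name}: {cd}/{cd + cn} members down "
            f"({100 * self.cluster_down_fraction:.1f}%) vs background "
            f"{bd}/{bd + bn} ({100 * self.background_down_fraction:.1f}%).",
            f"Cluster accounts for {100 * self.cluster_share_of_down:.1f}% of "
            f"all down-regulated features.",
            f"Chi-square test of proportions: chi2 = {self.chi2_stat:.2f}, "
            f"p = {self.p_chi2:.3g}"
            + (" (Yates-corrected)." if self.yates else "."),
        ]
        if self.null is not None:
            lines.append(self.null.summary())
        return "\n".join(lines)


def draw_random_sets(
    feature_ids, cluster: ClusterDefinition, n_sets: int, seed: int,
    set_size: int | None = None,
) -> list[frozenset[str]]:
    """Draw ``n_sets`` feature sets from the non-cluster pool, each of the
    cluster's tested size, without replacement within a set."""
    ids = [str(f) for f in feature_ids]
    pool = np.array(sorted(set(ids) - cluster.member_feature_ids))
    if set_size is None:
        set_size = len(set(ids) & cluster.member_feature_ids)
    if set_size < 1:
        raise ValueError("cluster does not intersect the tested features")
    if pool.size < set_size:
        raise ValueError(
            f"non-cluster pool ({pool.size}) smaller than set size ({set_size})"
        )
    rng = np.random.default_rng(seed)
    return [
        frozenset(rng.choice(pool, size=set_size, replace=False).tolist())
        for _ in range(n_sets)
    ]


def null_summary(
    sets: list[frozenset[str]], de_results: DEResults,
    cluster_down_count: int | None = None,
) -> RandomSetNull:
    """Summarise the down-call counts of the random sets.

    The 95% CI of the mean uses Student-t with n_sets - 1 df. If
    ``cluster_down_count`` is given, an empirical tail probability (fraction
    of sets with at least that many down calls) is attached.
    """
    if not sets:
        raise ValueError("need at least one random set")
    down = set(de_results.down_ids)
    counts = [len(s & down) for s in sets]
    arr = np.asarray(counts, dtype=float)
    n = len(counts)
    mean = float(arr.mean())
    if n >= 2:
        sd = float(arr.std(ddof=1))
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    else:
        warnings.warn("fewer than 2 random sets: CI of the null mean omitted")
        ci = None
    emp = None
    if cluster_down_count is not None:
        emp = float(np.mean(arr >= cluster_down_count))
    return RandomSetNull(
        n_sets=n, set_size=len(next(iter(sets))), down_counts=counts,
        mean=mean, min=int(arr.min()), max=int(arr.max()), ci95=ci,
        empirical_p=emp,
    )


def chi_square_proportions(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 count table, optional Yates."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any() or not np.all(t == np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(
            "a table margin is zero: expected counts undefined "
            "(no down calls at all, or an empty group)"
        )
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=yates)
    assert dof == 1
    return float(chi2), float(p)


def assess_cluster(
    de_results: DEResults, cluster: ClusterDefinition, config: RunConfig,
    draw_null: bool = True,
) -> ClusterEnrichmentResult:
    """Build the cluster-vs-complement 2x2, test it, and attach the
    random-set null.

    Rows are cluster / non-cluster complement, columns down / not-down, over
    the features with test results. The "share of down" statistic counts the
    cluster's down calls against all down calls genome-wide (cluster
    included).
    """
    tested = list(de_results.table["feature_id"])
    down = set(de_results.down_ids)
    in_cluster = set(tested) & cluster.member_feature_ids
    if not in_cluster:
        raise ValueError(
            f"cluster {cluster.name!r} does not intersect the tested features"
        )
    bg = set(tested) - cluster.member_feature_ids
    c_down = len(in_cluster & down)
    b_down = len(bg & down)
    table = np.array([
        [c_down, len(in_cluster) - c_down],
        [b_down, len(bg) - b_down],
    ])
    chi2, p = chi_square_proportions(table, yates=config.yates)
    total_down = c_down + b_down
    null = None
    if draw_null:
        sets = draw_random_sets(
            tested, cluster, config.n_random_sets, config.rng_seed,
            set_size=len(in_cluster),
        )
        null = null_summary(sets, de_results, cluster_down_count=c_down)
    return ClusterEnrichmentResult(
        cluster_name=cluster.name,
        table=table,
        chi2_stat=chi2,
        p_chi2=p,
        yates=config.yates,
        cluster_down_fraction=c_down / len(in_cluster),
        background_down_fraction=b_down / len(bg) if bg else float("nan"),
        cluster_share_of_down=(c_down / total_down) if total_down else float("nan"),
        null=null,
    )
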