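"""Consensus miRNA target sites and EASE-score gene-set enrichment.

Two prediction tools emit candidate miRNA binding sites with genomic
coordinates. A site enters the consensus only when (miRNA, 3'UTR, chrom,
start, end) is identical in both lists; a (miRNA, UTR) pair predicted by
both tools but never at identical coordinates is excluded outright (a
discordance between predictors is treated as a likely false positive), and
single-tool pairs are simply absent. The consensus genes feed a
hypergeometric gene-set enrichment with the conservative EASE adjustment:
one gene is removed from the overlap cell before taking the upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .de import adjust_p

_KEY_BASE = ["mirna_id", "utr_id", "chrom", "start", "end"]


@dataclass
class ConsensusTargetSet:
    sites: pd.DataFrame
    genes: list[str]
    excluded_pairs: set[tuple[str, str]]
    stats: dict

    def summary(self) -> str:
        return (
            f"Consensus: {self.stats['consensus_sites']} sites / "
            f"{self.stats['consensus_pairs']} (miRNA, UTR) pairs over "
            f"{len(self.genes)} genes; {self.stats['excluded_pairs']} "
            f"coordinate-discordant pairs excluded; "
            f"{self.stats['single_source_pairs']} single-predictor pairs ignored."
        )


def _dedupe(sites: pd.DataFrame, key: list[str]) -> pd.DataFrame:
    return sites.drop_duplicates(subset=key + ["gene_id"]).reset_index(drop=True)


def consensus(sites_a: pd.DataFrame, sites_b: pd.DataFrame) -> ConsensusTargetSet:
    """Intersect two predictors' site tables by exact genomic coordinates.

    Strand is part of the match key only when both inputs carry a strand
    column; otherwise matching falls back to (chrom, start, end). Duplicate
    rows within one source are dropped before matching. The operation is
    symmetric in its two inputs.
    """
    for name, df in (("A", sites_a), ("B", sites_b)):
        missing = [c for c in _KEY_BASE + ["gene_id"] if c not in df.columns]
        if missing:
            raise ValueError(f"predictor {name} table missing columns {missing}")
        if (df["start"] >= df["end"]).any():
            raise ValueError(
                f"predictor {name}: non-positive site width; mixed coordinate "
                f"dialects?"
            )
    key = list(_KEY_BASE)
    if "strand" in sites_a.columns and "strand" in sites_b.columns \
            and sites_a["strand"].notna().all() and sites_b["strand"].notna().all():
        key.append("strand")
    a = _dedupe(sites_a, key)
    b = _dedupe(sites_b, key)

    merged = a.merge(b[key].drop_duplicates(), on=key, how="inner")
    merged = merged.sort_values(key).reset_index(drop=True)

    pairs_a = set(map(tuple, a[["mirna_id", "utr_id"]].drop_duplicates().to_numpy()))
    pairs_b = set(map(tuple, b[["mirna_id", "utr_id"]].drop_duplicates().to_numpy()))
    pairs_both = pairs_a & pairs_b
    consensus_pairs = set(
        map(tuple, merged[["mirna_id", "utr_id"]].drop_duplicates().to_numpy())
    )
    excluded = pairs_both - consensus_pairs
    genes = sorted(merged["gene_id"].unique())
    return ConsensusTargetSet(
        sites=merged,
        genes=genes,
        excluded_pairs=excluded,
        stats=dict(
            consensus_sites=len(merged),
            consensus_pairs=len(consensus_pairs),
            excluded_pairs=len(excluded),
            single_source_pairs=len((pairs_a | pairs_b) - pairs_both),
            genes=len(genes),
        ),
    )


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    set_size: int
    overlap: int
    expected: float
    ease_p: float
    p_adj: float = float("nan")


def ease_p_value(overlap: int, query_size: int, set_size: int, universe_size: int) -> float:
    """EASE score: hypergeometric upper tail with the overlap decremented by 1.

    ease_p = P(X >= overlap - 1) for X ~ Hypergeom(universe, set, query),
    with margins unchanged; an overlap of 0 or 1 therefore scores 1.0. Always
    at least the classical Fisher one-tailed p on the same table.
    """
    if overlap < 0 or overlap > min(query_size, set_size):
        raise ValueError("overlap exceeds the smaller margin")
    k = overlap - 1
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, set_size, query_size))


def ease_enrichment(
    query_genes, gene_sets: dict[str, dict], universe, config: RunConfig,
) -> pd.DataFrame:
    """Score every gene set against the query via the EASE statistic.

    Set members are intersected with the universe; sets whose overlap with
    the query is below ``ease_threshold_count`` are omitted. Remaining EASE
    p-values are corrected by the configured method.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError(
            f"{len(query - universe)} query genes are outside the universe"
        )
    u, q = len(universe), len(query)
    rows = []
    for set_id, rec in gene_sets.items():
        members = set(rec["members"]) & universe
        if not members:
            continue
        k = len(query & members)
        if k < config.ease_threshold_count:
            continue
        rows.append(EnrichmentResult(
            set_id=set_id, name=rec.get("name", set_id), set_size=len(members),
            overlap=k, expected=q * len(members) / u,
            ease_p=ease_p_value(k, q, len(members), u),
        ))
    df = pd.DataFrame([r.__dict__ for r in rows],
                      columns=["set_id", "name", "set_size", "overlap",
                               "expected", "ease_p", "p_adj"])
    if len(df):
        df["p_adj"] = adjust_p(df["ease_p"], config.correction_method)
        df = df.sort_values("ease_p", kind="stable").reset_index(drop=True)
    return df
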