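"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the four input families end to end — a case/control
log-expression matrix with a designated deregulated cluster, a 450K-style
M-value probe table with one hypermethylated region, two predictor site
lists with planted consensus structure, and a replicate-well qPCR Ct table —
each with a truth table sufficient to score the downstream callers.

Defaults follow the glioblastoma study conditions the pipeline was built
around: a 534-feature miRnome with a 38-member cluster, ~200 methylation
probes per region, Gaussian log-scale expression noise, and duplicate qPCR
wells. One global seed deterministically spawns independent per-stage
streams, so any stage can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .qpcr import CtTable
from .regions import GenomicRegion

_STAGES = ("expression", "methylation", "targets", "qpcr")

#: default per-assay true fold changes for the qPCR generator: a mixed panel
#: of clearly down, borderline and upregulated assays
DEFAULT_QPCR_FC = {
    "mir-q1": 0.3, "mir-q2": 0.5, "mir-q3": 0.6,
    "mir-q4": 1.0, "mir-q5": 1.4, "mir-q6": 2.5,
}


@dataclass
class SimulationSpec:
    """Knobs of the synthetic-data generator.

    ``cluster_effect`` is the mean log-expression shift added to case samples
    on cluster features (negative = downregulation, in the same log units as
    the matrix). ``background_de_frac`` of the non-cluster features receive a
    shift of the same magnitude, split evenly between up and down.
    M-values are Gaussian per region; the beta-scale structure is induced
    through the exact M-to-beta conversion so that conversion stays on the
    tested path.
    """

    n_features: int = 534
    cluster_size: int = 38
    n_case: int = 20
    n_control: int = 20
    cluster_effect: float = -2.0
    background_de_frac: float = 0.3
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_probes_region: int = 200
    hyper_m_mean: float = 2.5
    normal_m_mean: float = 0.0
    m_noise_sd: float = 0.5
    qpcr_true_fc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QPCR_FC)
    )
    qpcr_n_case: int = 3
    qpcr_n_control: int = 3
    qpcr_noise_sd: float = 0.15
    qpcr_reference_assay: str = "miR-92a"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cluster_size < self.n_features:
            raise ValueError("cluster_size must be smaller than n_features")
        for name in ("n_features", "cluster_size", "n_case", "n_control",
                     "n_probes_region", "qpcr_n_case", "qpcr_n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.background_de_frac <= 1.0:
            raise ValueError("background_de_frac must be in [0, 1]")
        if self.qpcr_noise_sd < 0 or self.m_noise_sd <= 0:
            raise ValueError("noise standard deviations must be non-negative")
        if any(fc <= 0 for fc in self.qpcr_true_fc.values()):
            raise ValueError("true fold changes must be > 0")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage random stream derived from the global seed."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence(self.seed)
        return np.random.default_rng(ss.spawn(len(_STAGES))[_STAGES.index(stage)])


# -- expression ------------------------------------------------------------

def cluster_feature_ids(spec: SimulationSpec) -> list[str]:
    return [f"c14-mir-{i + 1:03d}" for i in range(spec.cluster_size)]


def simulate_expression(spec: SimulationSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the log-expression matrix and its truth table.

    Per-feature baselines are Gaussian; cases receive ``cluster_effect`` on
    cluster features and +/- the same magnitude on the chosen background
    fraction; observation noise is Gaussian on the log scale. The truth table
    records each feature's membership and true direction.
    """
    rng = spec.rng("expression")
    n_bg = spec.n_features - spec.cluster_size
    features = cluster_feature_ids(spec) + [f"mir-{i + 1:03d}" for i in range(n_bg)]
    samples = [f"case{i + 1:03d}" for i in range(spec.n_case)] + \
              [f"ctrl{i + 1:03d}" for i in range(spec.n_control)]
    group = pd.Series(
        ["case"] * spec.n_case + ["control"] * spec.n_control, index=samples
    )

    effects = np.zeros(spec.n_features)
    effects[: spec.cluster_size] = spec.cluster_effect
    n_de = int(round(spec.background_de_frac * n_bg))
    bg_idx = spec.cluster_size + rng.choice(n_bg, size=n_de, replace=False)
    half = n_de // 2
    mag = abs(spec.cluster_effect)
    effects[bg_idx[:half]] = -mag
    effects[bg_idx[half:]] = +mag

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_features)
    values = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, (spec.n_features, len(samples))
    )
    values[:, : spec.n_case] += effects[:, None]

    direction = np.select([effects < 0, effects > 0], ["down", "up"], "none")
    truth = pd.DataFrame({
        "feature_id": features,
        "is_cluster": [i < spec.cluster_size for i in range(spec.n_features)],
        "true_effect": effects,
        "true_direction": direction,
    })
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), group
    )
    return matrix, truth


# -- methylation -----------------------------------------------------------

def default_methylation_regions(
    region_length: int = 60_000,
) -> tuple[GenomicRegion, list[GenomicRegion]]:
    """The default simulated genome layout: one target cluster region on
    chr14 plus eleven background regions (a control imprinted cluster on
    chr19 and ten spread over other chromosomes)."""
    target = GenomicRegion("chr14", 1_000_000, 1_000_000 + region_length, "C14")
    controls = [GenomicRegion("chr19", 1_000_000, 1_000_000 + region_length, "C19")]
    for i in range(10):
        controls.append(GenomicRegion(
            f"chr{i + 1}", 2_000_000, 2_000_000 + region_length, f"R{i + 1}"
        ))
    return target, controls


def simulate_methylation(
    spec: SimulationSpec, regions: list[GenomicRegion],
    hyper_region: str = "C14",
) -> pd.DataFrame:
    """Simulate a probe-by-sample M-value table over the given regions.

    The region named ``hyper_region`` gets M-values around
    ``hyper_m_mean`` (implied median beta above the hypermethylation
    threshold); all others around ``normal_m_mean`` (median beta ~0.5).
    Regions must be disjoint and long enough for ``n_probes_region`` distinct
    positions.
    """
    names = [r.name for r in regions]
    if hyper_region not in names:
        raise ValueError(f"no region named {hyper_region!r} among {names}")
    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            if a.overlaps(b):
                raise ValueError(f"regions {a.name!r} and {b.name!r} overlap")
        if len(a) < spec.n_probes_region:
            raise ValueError(
                f"region {a.name!r} too short for {spec.n_probes_region} probes"
            )
    rng = spec.rng("methylation")
    samples = [f"tumor{i + 1:03d}" for i in range(spec.n_case)]
    rows = []
    values = []
    probe_no = 0
    for region in regions:
        pos = np.sort(rng.choice(len(region), spec.n_probes_region, replace=False))
        mean = spec.hyper_m_mean if region.name == hyper_region else spec.normal_m_mean
        m = mean + rng.normal(0.0, spec.m_noise_sd,
                              (spec.n_probes_region, len(samples)))
        for j in range(spec.n_probes_region):
            probe_no += 1
            rows.append((f"cg{probe_no:06d}", region.chrom, region.start + int(pos[j])))
        values.append(m)
    probes = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    mvals = pd.DataFrame(np.concatenate(values), columns=samples)
    return pd.concat([probes, mvals], axis=1)


# -- predictor target sites ------------------------------------------------

def simulate_predictor_sites(
    spec: SimulationSpec,
    n_identical: int = 100, n_discordant: int = 30, n_singleton: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two predictor site tables with planted consensus structure.

    Three disjoint classes of (miRNA, 3'UTR) pairs are emitted: predicted by
    both tools at identical coordinates; predicted by both but only at
    discordant coordinates; predicted by a single tool. Returns
    (sites_a, sites_b, truth) where truth labels every pair.
    """
    rng = spec.rng("targets")
    site_len = 21
    chroms = [f"chr{c}" for c in range(1, 23)]

    def make_pair(i: int, klass: str) -> dict:
        return dict(
            mirna_id=f"mir-{rng.integers(1, spec.n_features + 1):03d}",
            gene_id=f"GENE{i:04d}", utr_id=f"utr{i:04d}", klass=klass,
        )

    rows_a, rows_b, truth = [], [], []
    idx = 0
    for _ in range(n_identical):
        idx += 1
        p = make_pair(idx, "identical")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1_000, 5_000_000))
        site = dict(mirna_id=p["mirna_id"], gene_id=p["gene_id"],
                    utr_id=p["utr_id"], chrom=chrom, start=start,
                    end=start + site_len)
        rows_a.append(site)
        rows_b.append(dict(site))
        truth.append(p)
    for _ in range(n_discordant):
        idx += 1
        p = make_pair(idx, "discordant")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1_000, 5_000_000))
        shift = site_len + int(rng.integers(10, 500))  # guaranteed different
        common = dict(mirna_id=p["mirna_id"], gene_id=p["gene_id"],
                      utr_id=p["utr_id"], chrom=chrom)
        rows_a.append(dict(common, start=start, end=start + site_len))
        rows_b.append(dict(common, start=start + shift,
                           end=start + shift + site_len))
        truth.append(p)
    for j in range(n_singleton):
        idx += 1
        p = make_pair(idx, "singleton_a" if j % 2 == 0 else "singleton_b")
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1_000, 5_000_000))
        site = dict(mirna_id=p["mirna_id"], gene_id=p["gene_id"],
                    utr_id=p["utr_id"], chrom=chrom, start=start,
                    end=start + site_len)
        (rows_a if j % 2 == 0 else rows_b).append(site)
        truth.append(p)

    cols = ["mirna_id", "gene_id", "utr_id", "chrom", "start", "end"]
    sites_a = pd.DataFrame(rows_a, columns=cols)
    sites_a["source"] = "predictorA"
    sites_b = pd.DataFrame(rows_b, columns=cols)
    sites_b["source"] = "predictorB"
    return sites_a, sites_b, pd.DataFrame(truth)


# -- qPCR ------------------------------------------------------------------

def simulate_qpcr(spec: SimulationSpec, n_replicates: int = 2) -> tuple[CtTable, pd.DataFrame]:
    """Simulate duplicate-well Ct data with planted per-assay fold changes.

    Each assay has a base Ct; every sample carries a loading offset (which
    the reference normalization must cancel); case samples are shifted by
    -log2(true fold change) on non-reference assays; wells add Gaussian
    noise. Returns the Ct table and a truth table of planted fold changes.
    """
    rng = spec.rng("qpcr")
    assays = dict(spec.qpcr_true_fc)
    ref = spec.qpcr_reference_assay
    if ref in assays:
        raise ValueError("the reference assay cannot carry a planted fold change")
    base_ct = {ref: float(rng.uniform(18, 22))}
    for a in assays:
        base_ct[a] = float(rng.uniform(22, 30))
    samples = [f"GBM{i + 1}" for i in range(spec.qpcr_n_case)] + \
              [f"CTRL{i + 1}" for i in range(spec.qpcr_n_control)]
    group = pd.Series(
        ["case"] * spec.qpcr_n_case + ["control"] * spec.qpcr_n_control,
        index=samples,
    )
    offsets = rng.normal(0.0, 0.5, len(samples))
    rows = []
    for s, offset in zip(samples, offsets):
        is_case = group[s] == "case"
        for a in [ref, *assays]:
            true_ct = base_ct[a] + offset
            if is_case and a != ref:
                true_ct += -np.log2(assays[a])
            for r in range(n_replicates):
                ct = true_ct + (rng.normal(0.0, spec.qpcr_noise_sd)
                                if spec.qpcr_noise_sd > 0 else 0.0)
                rows.append((s, a, r + 1, float(ct)))
    wells = pd.DataFrame(rows, columns=["sample_id", "assay_id", "replicate", "ct"])
    truth = pd.DataFrame(
        {"assay_id": list(assays), "true_fold_change": list(assays.values())}
    )
    return CtTable(wells=wells, reference_assays=[ref], group=group), truth
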