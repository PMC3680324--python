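"""Stage orchestration: run whichever analyses the provided inputs support
and write per-stage TSV tables plus one machine-readable JSON summary."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import ClusterDefinition, assess_cluster
from .config import RunConfig
from .de import call_features
from .io import (
    read_ct_table, read_expression_matrix, read_gmt, read_labels,
    read_probe_table, read_site_table,
)
from .methylation import analyse_target_region
from .qpcr import CtTable, delta_ct, fold_change_calls, group_test
from .regions import read_bed
from .targets import consensus, ease_enrichment

#: recognised input keys for run_pipeline
INPUT_KEYS = (
    "expression", "labels", "cluster",
    "probes", "regions", "target_region", "n_random_regions",
    "sites_a", "sites_b", "coords_a", "coords_b", "gene_sets",
    "ct", "ct_labels", "reference_assays",
)


def read_cluster_file(path: str | Path, name: str | None = None) -> ClusterDefinition:
    """Cluster membership file: one feature id per line, '#' comments allowed."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ClusterDefinition.from_ids(name or Path(path).stem, ids)


def run_pipeline(config: RunConfig, inputs: dict, out_dir: str | Path) -> dict:
    """Run every stage whose inputs are present; return the summary dict.

    Output tables and ``summary.json`` land in ``out_dir``. Two runs with the
    same config, seed and inputs write byte-identical summaries.
    """
    unknown = set(inputs) - set(INPUT_KEYS)
    if unknown:
        raise ValueError(f"unknown input keys: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    ran_any = False

    if "expression" in inputs:
        ran_any = True
        matrix = read_expression_matrix(inputs["expression"], inputs["labels"])
        de = call_features(matrix, config)
        de.to_tsv(out / "de_results.tsv")
        (out / "de_skipped.txt").write_text("".join(f"{f}\n" for f in de.skipped))
        stage = {
            "n_tested": de.n_tested,
            "n_skipped": len(de.skipped),
            "n_down": len(de.down_ids),
            "n_up": len(de.up_ids),
        }
        if "cluster" in inputs:
            cluster = read_cluster_file(inputs["cluster"])
            enr = assess_cluster(de, cluster, config)
            (cd, cn), (bd, bn) = enr.table
            row = {
                "cluster": enr.cluster_name,
                "cluster_down": int(cd), "cluster_size": int(cd + cn),
                "background_down": int(bd), "background_size": int(bd + bn),
                "chi2_stat": enr.chi2_stat, "p_chi2": enr.p_chi2,
                "cluster_down_fraction": enr.cluster_down_fraction,
                "background_down_fraction": enr.background_down_fraction,
                "cluster_share_of_down": enr.cluster_share_of_down,
                "null_min": enr.null.min, "null_max": enr.null.max,
                "null_mean": enr.null.mean,
                "null_ci95_low": enr.null.ci95[0] if enr.null.ci95 else float("nan"),
                "null_ci95_high": enr.null.ci95[1] if enr.null.ci95 else float("nan"),
            }
            pd.DataFrame([row]).to_csv(out / "cluster_enrichment.tsv",
                                       sep="\t", index=False)
            stage["cluster_enrichment"] = row
        summary["stages"]["expression"] = stage

    if "probes" in inputs:
        ran_any = True
        probes = read_probe_table(inputs["probes"])
        regions = read_bed(inputs["regions"])
        target_name = inputs.get("target_region", regions[0].name)
        by_name = {r.name: r for r in regions}
        if target_name not in by_name:
            raise ValueError(f"target region {target_name!r} not in BED file")
        target = by_name.pop(target_name)
        analysis = analyse_target_region(
            probes, target, list(by_name.values()), config,
            n_random_regions=inputs.get("n_random_regions"),
        )
        analysis.to_frame().to_csv(out / "methylation.tsv", sep="\t", index=False)
        summary["stages"]["methylation"] = {
            "target": target.name,
            "target_median_beta": analysis.target.median_beta,
            "target_call": analysis.target.call,
            "n_control_regions": len(analysis.controls),
            "p_pooled": analysis.p_pooled,
            "p_region_medians": analysis.p_region_medians,
        }

    if "sites_a" in inputs:
        ran_any = True
        a = read_site_table(inputs["sites_a"], "predictorA",
                            inputs.get("coords_a", "bed"))
        b = read_site_table(inputs["sites_b"], "predictorB",
                            inputs.get("coords_b", "bed"))
        cons = consensus(a, b)
        cons.sites.to_csv(out / "consensus_sites.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(cons.excluded_pairs),
                     columns=["mirna_id", "utr_id"]).to_csv(
            out / "excluded_pairs.tsv", sep="\t", index=False)
        summary["stages"]["targets"] = dict(cons.stats)
        if "gene_sets" in inputs:
            sets = read_gmt(inputs["gene_sets"])
            universe = sorted(set(a["gene_id"]) | set(b["gene_id"]))
            enr = ease_enrichment(cons.genes, sets, universe, config)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["stages"]["targets"]["n_sets_scored"] = len(enr)
            summary["stages"]["targets"]["n_sets_enriched"] = int(
                (enr["ease_p"] < config.ease_p).sum()
            ) if len(enr) else 0

    if "ct" in inputs:
        ran_any = True
        wells = read_ct_table(inputs["ct"])
        group = read_labels(inputs["ct_labels"])
        refs = inputs["reference_assays"]
        if isinstance(refs, str):
            refs = [r for r in refs.split(",") if r]
        table = CtTable(wells=wells, reference_assays=list(refs), group=group)
        dct = delta_ct(table, config.replicate_flag_cycles)
        calls = fold_change_calls(dct, config, exclude_references=table.reference_assays)
        tests = group_test(dct, exclude_references=table.reference_assays)
        calls.per_sample.to_csv(out / "qpcr_per_sample.tsv", sep="\t", index=False)
        calls.per_assay.to_csv(out / "qpcr_per_assay.tsv", sep="\t", index=False)
        tests.to_csv(out / "qpcr_group_test.tsv", sep="\t", index=False)
        counts = calls.per_assay["label"].value_counts()
        n_assays = len(calls.per_assay)
        summary["stages"]["qpcr"] = {
            "n_assays": int(n_assays),
            "n_down": int(counts.get("down", 0)),
            "n_up": int(counts.get("up", 0)),
            "n_non_differential": int(counts.get("non_differential", 0)),
            "down_fraction": float(counts.get("down", 0) / n_assays),
        }

    if not ran_any:
        raise ValueError(
            "no stage inputs provided; expected at least one of expression/"
            "probes/sites_a/ct"
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
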