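"""Run configuration shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

#: allowed multiple-testing corrections; "none" keeps raw p-values and exists
#: mainly for calibration runs where corrected calls would leave empty margins
CORRECTION_METHODS = ("bonferroni", "bh_fdr", "none")


@dataclass
class RunConfig:
    """Thresholds and switches for a pipeline run.

    Parameters
    ----------
    alpha
        Significance threshold applied to corrected p-values.
    n_random_sets
        Number of random feature sets drawn for the cluster-enrichment null.
    correction_method
        Multiple-testing correction: ``bonferroni`` (p * number of features
        tested, capped at 1), ``bh_fdr`` (Benjamini-Hochberg step-up) or
        ``none``.
    yates
        Apply the Yates continuity correction in the 2x2 chi-square test.
    rng_seed
        Seed for every stochastic step (random sets, random regions,
        simulation).
    fc_down, fc_up
        Fold-change cutoffs for the qPCR classifier; a fold change <= fc_down
        is called down, >= fc_up up (boundaries inclusive).
    beta_hyper, beta_hypo
        Median beta-value thresholds for calling a region hyper-/hypomethylated
        (strict inequalities).
    ease_threshold_count
        Minimum query/set overlap for a gene set to be scored.
    ease_p
        EASE-score significance threshold used in report summaries.
    require_two_tailed
        If True, a directional (up/down) call additionally requires the
        corrected two-tailed p to pass alpha.
    replicate_flag_cycles
        qPCR replicate spread (cycles) above which a well pair is flagged.
    """

    alpha: float = 0.05
    n_random_sets: int = 10
    correction_method: str = "bonferroni"
    yates: bool = False
    rng_seed: int = 0
    fc_down: float = 0.6
    fc_up: float = 2.0
    beta_hyper: float = 0.8
    beta_hypo: float = 0.2
    ease_threshold_count: int = 2
    ease_p: float = 0.1
    require_two_tailed: bool = False
    replicate_flag_cycles: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_random_sets < 1:
            raise ValueError(
                f"n_random_sets must be >= 1, got {self.n_random_sets}"
            )
        if self.correction_method not in CORRECTION_METHODS:
            raise ValueError(
                f"correction_method must be one of {CORRECTION_METHODS}, "
                f"got {self.correction_method!r}"
            )
        if not self.fc_down < 1.0 < self.fc_up:
            raise ValueError(
                f"fold-change cutoffs must satisfy fc_down < 1 < fc_up, "
                f"got fc_down={self.fc_down}, fc_up={self.fc_up}"
            )
        if not self.beta_hypo < self.beta_hyper:
            raise ValueError(
                f"beta thresholds must satisfy beta_hypo < beta_hyper, "
                f"got {self.beta_hypo} >= {self.beta_hyper}"
            )
        if self.ease_threshold_count < 0:
            raise ValueError("ease_threshold_count must be >= 0")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Read a flat key: value YAML document."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} is not a flat mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def replace(self, **kwargs) -> "RunConfig":
        d = self.to_dict()
        d.update(kwargs)
        return RunConfig.from_dict(d)
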