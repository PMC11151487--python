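"""Pipeline configuration: every scalar threshold of the analysis in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds of the recurrence analysis pipeline.

    Defaults are the published analysis choices: q <= 0.05 and linear fold
    change >= 1.5 for differential expression; adjusted p < 0.001 for the
    enrichment report tier; adjusted p < 0.05 with >= 5 (pathway) or >= 10
    (GO term) overlapping DE genes for the classifier curation tier; 10
    bootstraps; accuracy strictly > 0.80 for a high-performing model; Shapley
    importance >= 0.01 in >= 50% of high performers for consensus selection;
    per-sample z > 2 marks a sample "altered" for survival stratification.
    """

    q_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    enrich_report_cutoff: float = 0.001
    enrich_curation_cutoff: float = 0.05
    min_de_genes_pathway: int = 5
    min_de_genes_go: int = 10
    n_bootstraps: int = 10
    accuracy_cutoff: float = 0.80
    shap_cutoff: float = 0.01
    consensus_fraction: float = 0.50
    altered_z_cutoff: float = 2.0
    test_fraction: float = 0.20
    seed: int = 0

    # training hyper-parameters (not printed in the source analysis; overridable)
    epochs: int = 100
    learning_rate: float = 0.05
    batch_size: int = 32
    pp_pr_ratio: float = 1.0  # PP pairs subsampled per epoch to this multiple of PR
    shap_permutations: int = 20
    shap_max_instances: int = 20
    q_method: str = "bh"  # "bh" | "storey"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.q_cutoff <= 1, "q_cutoff in (0,1]"),
            (self.fc_cutoff > 1, "fc_cutoff > 1"),
            (0 < self.enrich_report_cutoff <= 1, "enrich_report_cutoff in (0,1]"),
            (0 < self.enrich_curation_cutoff <= 1, "enrich_curation_cutoff in (0,1]"),
            (self.min_de_genes_pathway >= 1, "min_de_genes_pathway >= 1"),
            (self.min_de_genes_go >= 1, "min_de_genes_go >= 1"),
            (self.n_bootstraps >= 1, "n_bootstraps >= 1"),
            (0 < self.accuracy_cutoff < 1, "accuracy_cutoff in (0,1)"),
            (self.shap_cutoff >= 0, "shap_cutoff >= 0"),
            (0 < self.consensus_fraction <= 1, "consensus_fraction in (0,1]"),
            (self.altered_z_cutoff > 0, "altered_z_cutoff > 0"),
            (0 < self.test_fraction < 1, "test_fraction in (0,1)"),
            (isinstance(self.seed, int) and self.seed >= 0, "seed is a non-negative integer"),
            (self.q_method in ("bh", "storey"), "q_method is 'bh' or 'storey'"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ValueError("invalid config: " + "; ".join(bad))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return asdict(self)
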