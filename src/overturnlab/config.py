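"""Analysis configuration: every threshold used by the pipeline, with the
experiment's values as defaults, serialisable to/from a YAML file."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # core_io / QC
    doc_outlier_percentile: float = 90.0      # upper percentile flagged as contaminated
    doc_outlier_min_group: int = 5            # smaller groups skipped
    doc_outlier_group_by: tuple = ("treatment", "bottle")
    filtrate_fraction: float = 0.70           # 0.2 µm filtrate volume fraction

    # growth kinetics
    fg_carbon_per_cell: float = 20.0          # fg C cell⁻¹ biomass conversion
    carbon_molar_mass: float = 12.011         # g mol⁻¹
    min_window_points: int = 3

    # dom diagenesis
    di_reference: str | None = None           # path to an alternative AA reference CSV

    # metabolomics
    aromaticity_modified: bool = True         # AI_mod vs unmodified AI
    weighted_over_classified_only: bool = False

    # qPCR
    standard_length_bp: dict = dataclasses.field(
        default_factory=lambda: {"amoA": 635, "cbbL": 1079}
    )
    replicate_merge: str = "mean_cq"          # mean Cq per (sample, gene)

    # community
    min_prevalence_samples: int = 4           # drop ASVs seen in fewer samples
    rarefaction_depth: int = 10_000
    filter_before_rarefy: bool = True
    family_other_threshold: float = 0.01      # families under 1% pooled into "other"
    asv_plot_threshold: float = 0.0015        # >0.15% ASVs kept for plotting tables
    copy_adjust_renormalize: bool = False

    # stats
    replicate_test: str = "paired_t"          # or "sign_flip_permutation"
    anova_scope: str = "per_timepoint"        # or "pooled"
    fdr_correction: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["doc_outlier_group_by"] = list(d["doc_outlier_group_by"])
        return d

    def hash(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "doc_outlier_group_by" in d:
            d = dict(d)
            d["doc_outlier_group_by"] = tuple(d["doc_outlier_group_by"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
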