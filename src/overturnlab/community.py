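"""ASV-table processing: prevalence filtering, rarefaction, diversity,
taxonomic aggregation and 16S copy-number adjustment.

The amplicon pipeline upstream of this module (denoising, taxonomy) is out
of scope; this module ingests its output — a samples × ASVs count matrix
with semicolon-delimited lineage strings — and reproduces the summary
statistics used for treatment comparison: ASVs seen in fewer than four
samples are removed, samples are rarefied to a common depth of 10,000
reads (exact subsampling without replacement), alpha diversity is reported
as Shannon (natural log) and Gini–Simpson 1 − Σp², relative abundances
are aggregated at a taxonomic rank with rare groups pooled into "other",
and relative abundances can be divided by 16S rRNA operon copy numbers —
by default without renormalisation, so a family at 75% of reads with three
operon copies reports as 25% of total ASVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

logger = logging.getLogger(__name__)

__all__ = [
    "AsvTable",
    "RANKS",
    "filter_low_prevalence",
    "rarefy",
    "diversity_indices",
    "diversity_table",
    "aggregate_taxa",
    "copy_number_adjust",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class AsvTable:
    """Samples × ASVs integer counts with per-ASV lineages and a copy map.

    ``counts``: DataFrame indexed by sample, columns are ASV ids.
    ``taxonomy``: ASV id → semicolon-delimited lineage
    (domain;phylum;class;order;family;genus, possibly truncated).
    ``copy_map``: taxon name → 16S copies (taxa absent default to 1).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str]
    copy_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be ≥ 0")
        missing = [a for a in self.counts.columns if a not in self.taxonomy]
        if missing:
            raise ValueError(f"ASV(s) without lineage: {missing[:5]}")
        bad = {t: c for t, c in self.copy_map.items() if c < 1}
        if bad:
            raise ValueError(f"copy numbers must be ≥ 1: {bad}")

    def lineage_at(self, asv: str, rank: str) -> str | None:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        parts = [p.strip() for p in self.taxonomy[asv].split(";")]
        i = RANKS.index(rank)
        return parts[i] if i < len(parts) and parts[i] else None


def filter_low_prevalence(table: AsvTable, min_samples: int = 4) -> AsvTable:
    """Remove ASVs with nonzero counts in fewer than ``min_samples`` samples."""
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence.index[prevalence >= min_samples]
    return AsvTable(
        counts=table.counts[keep].copy(),
        taxonomy={a: table.taxonomy[a] for a in keep},
        copy_map=dict(table.copy_map),
    )


def rarefy(table: AsvTable, depth: int = 10_000, seed: int = 0) -> AsvTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses a multivariate-hypergeometric draw (exact subsampling).  Samples
    with fewer than ``depth`` reads are dropped with a logged notice.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be ≥ 1")
    rng = np.random.default_rng(seed)
    rows = {}
    for sample, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            logger.info("sample %s has %d < %d reads; dropped", sample, total, depth)
            continue
        rows[sample] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.counts.columns)
    return AsvTable(counts=out, taxonomy=dict(table.taxonomy), copy_map=dict(table.copy_map))


def diversity_indices(counts) -> dict[str, float]:
    """Shannon (natural log) and Gini–Simpson (1 − Σp²) of one sample."""
    c = np.asarray(counts, float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty sample")
    p = c[c > 0] / total
    return {
        "shannon": float(_sstats.entropy(p)),     # −Σ p ln p
        "simpson": float(1.0 - np.sum(p**2)),
    }


def diversity_table(table: AsvTable) -> pd.DataFrame:
    rows = [
        {"sample": s, **diversity_indices(table.counts.loc[s])}
        for s in table.counts.index
    ]
    return pd.DataFrame(rows).set_index("sample")


def aggregate_taxa(table: AsvTable, rank: str = "family",
                   other_threshold: float = 0.01) -> pd.DataFrame:
    """Per-sample relative abundances summed within a taxonomic rank.

    Groups below ``other_threshold`` of the experiment-wide total are
    pooled into "other"; ASVs with no name at the rank go to
    "unclassified".  Rows (samples) sum to 1.
    """
    groups: dict[str, list[str]] = {}
    any_named = False
    for asv in table.counts.columns:
        name = table.lineage_at(asv, rank)
        if name is not None:
            any_named = True
        groups.setdefault(name or "unclassified", []).append(asv)
    if not any_named:
        raise ValueError(f"rank {rank!r} absent from all lineages")

    sums = pd.DataFrame({g: table.counts[cols].sum(axis=1) for g, cols in groups.items()})
    rel = sums.div(sums.sum(axis=1), axis=0)

    overall = sums.sum(axis=0) / sums.to_numpy().sum()
    minor = overall.index[(overall < other_threshold) & (overall.index != "other")]
    if len(minor):
        pooled = rel[minor].sum(axis=1)
        rel = rel.drop(columns=minor)
        rel["other"] = rel.get("other", 0.0) + pooled
    return rel


def copy_number_adjust(fractions: dict[str, float],
                       copy_map: dict[str, float],
                       renormalize: bool = False) -> dict[str, float]:
    """Divide each taxon's percentage by its 16S operon copy number.

    With ``renormalize=False`` the adjusted values remain percentages of
    the *original* total (the convention in which 75% of reads at 3 copies
    becomes 25% of total ASVs); with ``renormalize=True`` they are rescaled
    to sum to 100.
    """
    for taxon, frac in fractions.items():
        if not 0.0 <= frac <= 100.0:
            raise ValueError(f"fraction for {taxon} outside [0, 100]: {frac}")
        if copy_map.get(taxon, 1.0) < 1:
            raise ValueError(f"copy number < 1 for {taxon}")
    adjusted = {t: f / copy_map.get(t, 1.0) for t, f in fractions.items()}
    if renormalize:
        total = sum(adjusted.values())
        if total > 0:
            adjusted = {t: 100.0 * v / total for t, v in adjusted.items()}
    return adjusted


def read_asv_table(counts_path, taxonomy_path, copy_map_path=None) -> AsvTable:
    """Read counts (samples × ASVs TSV), taxonomy (ASV→lineage TSV) and an
    optional copy-number CSV (taxon, copies)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tax = pd.read_csv(taxonomy_path, sep="\t")
    taxonomy = dict(zip(tax["asv"], tax["lineage"]))
    copy_map: dict[str, float] = {}
    if copy_map_path is not None:
        cm = pd.read_csv(copy_map_path)
        copy_map = dict(zip(cm["taxon"], cm["copies"].astype(float)))
    return AsvTable(counts=counts, taxonomy=taxonomy, copy_map=copy_map)


def write_asv_table(table: AsvTable, counts_path, taxonomy_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"asv": list(table.taxonomy), "lineage": list(table.taxonomy.values())}
    ).to_csv(taxonomy_path, sep="\t", index=False)
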