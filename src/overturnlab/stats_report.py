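"""Treatment comparisons, replicate-equivalence checks and end-to-end
pipeline orchestration.

Treatment effects on an analyte are assessed with one-way ANOVA followed
by Tukey HSD pairwise comparisons, either per timepoint or pooled over the
series.  Replicate-bottle equivalence is a paired two-sided t-test on the
per-timepoint differences between the two bottles of each treatment (a
sign-flip permutation variant is available).  ``run_pipeline`` executes
every stage on a bundle directory and writes tidy result tables plus a
run log carrying the configuration hash, so a rerun on identical inputs
is byte-identical.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import community as community_mod
from . import core_io, diagenesis, growth, metabolomics, qpcr
from .config import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "treatment_anova",
    "replicate_equivalence",
    "run_pipeline",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class ComparisonResult:
    analyte: str
    scope: str                      # "pooled" or "day=<t>"
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame          # columns: group1, group2, diff, p_adj

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _anova_tukey(values_by_group: dict[str, np.ndarray], analyte: str,
                 scope: str) -> ComparisonResult:
    groups = sorted(values_by_group)
    for g in groups:
        if len(values_by_group[g]) < 2:
            raise ValueError(f"group {g!r} has <2 observations")
    arrays = [np.asarray(values_by_group[g], float) for g in groups]
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all observations identical: no variance anywhere
        pairs = [(a, b, 0.0, 1.0) for a, b in itertools.combinations(groups, 2)]
        pw = pd.DataFrame(pairs, columns=["group1", "group2", "diff", "p_adj"])
        return ComparisonResult(analyte, scope, 0.0, 1.0, pw)
    f, p = stats.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    tk = pairwise_tukeyhsd(flat, labels)
    pairs = list(itertools.combinations(tk.groupsunique, 2))
    pw = pd.DataFrame({
        "group1": [str(a) for a, _ in pairs],
        "group2": [str(b) for _, b in pairs],
        "diff": tk.meandiffs,
        "p_adj": tk.pvalues,
    })
    return ComparisonResult(analyte, scope, float(f), float(p), pw)


def treatment_anova(series: core_io.IncubationSeries, analyte: str,
                    scope: str = "pooled", day: float | None = None) -> ComparisonResult:
    """One-way ANOVA across treatments with Tukey HSD pairwise comparisons.

    scope="per_timepoint" with ``day`` compares bottle values at one
    timepoint; scope="pooled" uses all timepoints of every bottle.
    """
    df = series.data
    df = df[(df["analyte"] == analyte) & (df["qc_flag"] == "ok")]
    label = "pooled"
    if scope == "per_timepoint":
        if day is None:
            raise ValueError("per_timepoint scope requires a day")
        df = df[df["time_days"] == day]
        label = f"day={day:g}"
    groups = {t: g["value"].to_numpy(float) for t, g in df.groupby("treatment")}
    if len(groups) < 2:
        raise ValueError(f"need ≥2 treatments with data for {analyte}")
    return _anova_tukey(groups, analyte, label)


def replicate_equivalence(series: core_io.IncubationSeries, analyte: str,
                          method: str = "paired_t",
                          on_unpaired: str = "error") -> tuple[float, int]:
    """Two-sided test of bottle-A vs bottle-B equivalence within treatments.

    Per-timepoint differences between the two bottles of each treatment are
    pooled and tested against zero: paired t-test by default, or an exact
    sign-flip permutation test.  ``on_unpaired`` controls timepoints present
    in only one bottle (e.g. after QC flagging): "error" lists them,
    "intersect" silently pairs on the common timepoints.  Returns (p, N)
    where N is the number of paired timepoints pooled across treatments.
    """
    diffs = []
    mismatches = []
    for trt in series.treatments:
        bottles = series.bottles(trt)
        if len(bottles) != 2:
            raise ValueError(f"treatment {trt} has {len(bottles)} bottles; need exactly 2")
        a = series.select(trt, bottles[0], analyte).set_index("time_days")["value"]
        b = series.select(trt, bottles[1], analyte).set_index("time_days")["value"]
        common = a.index.intersection(b.index)
        extra = a.index.symmetric_difference(b.index)
        if len(extra):
            mismatches.extend((trt, float(t)) for t in extra)
        diffs.append((a[common] - b[common]).to_numpy(float))
    if mismatches and on_unpaired == "error":
        raise ValueError(f"unpaired timepoints: {mismatches}")
    d = np.concatenate(diffs)
    n = len(d)
    if np.allclose(d, 0.0):
        return 1.0, n
    if method == "paired_t":
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    elif method == "sign_flip_permutation":
        res = stats.permutation_test(
            (d,), lambda x: np.mean(x), permutation_type="samples",
            alternative="two-sided", n_resamples=9999,
            rng=np.random.default_rng(0),
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, n


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(indir, outdir, config: AnalysisConfig | None = None) -> dict:
    """Run every analysis stage on a bundle directory and write a report.

    Stages: QC → growth/BGE → amino-acid diagenesis → metabolomics → qPCR →
    community → treatment comparisons.  Outputs are tidy CSVs plus
    ``run_log.json`` (config hash, stage status) and ``summary.txt``.
    Any stage failure raises :class:`PipelineError` naming the stage;
    partial outputs are left in place with a failure marker.
    """
    cfg = config or AnalysisConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": cfg.hash(), "stages": {}}
    summary_lines = [f"overturnlab report (config {cfg.hash()})"]

    def fail(stage: str, exc: Exception):
        log["stages"][stage] = f"failed: {exc}"
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
        raise PipelineError(stage, str(exc)) from exc

    # -- core_io / QC ----------------------------------------------------
    stage = "core_io"
    try:
        series = core_io.read_timeseries(indir / "timeseries.csv")
        series = core_io.flag_doc_outliers(
            series, "DOC", cfg.doc_outlier_percentile, cfg.doc_outlier_min_group,
            tuple(cfg.doc_outlier_group_by))
        core_io.write_timeseries(series, outdir / "timeseries_qc.csv")
        log["stages"][stage] = "ok"
    except Exception as exc:  # noqa: BLE001 — report which stage failed
        fail(stage, exc)

    # -- growth kinetics -------------------------------------------------
    stage = "growth_kinetics"
    try:
        fits = growth.growth_table(series, fg_per_cell=cfg.fg_carbon_per_cell)
        fits.to_csv(outdir / "growth_fits.csv", index=False)
        for row in fits.itertuples(index=False):
            err = getattr(row, "fit_error", "")
            if isinstance(err, str) and err:
                summary_lines.append(f"{row.treatment} bottle {row.bottle}: {err}")
                continue
            summary_lines.append(
                f"{row.treatment} bottle {row.bottle}: "
                f"mu={getattr(row, 'mu', float('nan')):.4f} d-1, "
                f"t_stationary={getattr(row, 't_stationary', float('nan')):.2f} d, "
                f"BGE={getattr(row, 'bge_percent', float('nan')):.1f}%"
            )
        log["stages"][stage] = "ok"
    except Exception as exc:
        fail(stage, exc)

    # -- amino-acid diagenesis ------------------------------------------
    stage = "dom_diagenesis"
    try:
        profiles = diagenesis.read_aa_profiles(indir / "aa_profiles.csv")
        doc_by_sample = {}
        for p in profiles:
            code, _, day = p.sample_id.partition("|day")
            if day:
                d = series.select(treatment=code, analyte="DOC")
                d = d[d["time_days"] == float(day)]
                if len(d):
                    doc_by_sample[p.sample_id] = float(d["value"].mean())
        ref = (diagenesis.AAReference.from_csv(cfg.di_reference)
               if cfg.di_reference else None)
        dtab = diagenesis.diagenesis_table(profiles, doc_by_sample, ref)
        dtab.to_csv(outdir / "diagenesis.csv", index=False)
        log["stages"][stage] = "ok"
    except Exception as exc:
        fail(stage, exc)

    # -- metabolomics ----------------------------------------------------
    stage = "metabolomics"
    try:
        feat_dir = indir / "features"
        rules = metabolomics.default_ruleset(cfg.aromaticity_modified)
        idx_rows, frac_rows = [], []
        for f in sorted(feat_dir.glob("*.csv")):
            feats = metabolomics.read_feature_table(f)
            row = {"sample": f.stem}
            row.update(metabolomics.magnitude_weighted_indices(
                feats, classified_only=cfg.weighted_over_classified_only,
                ruleset=rules))
            row.update(metabolomics.element_class_counts(feats))
            idx_rows.append(row)
            for cls, frac in metabolomics.class_peak_area_fractions(feats, rules).items():
                frac_rows.append({"sample": f.stem, "compound_class": cls,
                                  "peak_area_fraction": frac})
        pd.DataFrame(idx_rows).to_csv(outdir / "metabolome_indices.csv", index=False)
        pd.DataFrame(frac_rows).to_csv(outdir / "metabolome_classes.csv", index=False)
        log["stages"][stage] = "ok"
    except Exception as exc:
        fail(stage, exc)

    # -- qPCR ------------------------------------------------------------
    stage = "qpcr"
    try:
        plate = qpcr.read_plate(indir / "qpcr_plate.csv")
        curves, results = qpcr.analyze_plate(plate, cfg.replicate_merge)
        pd.DataFrame([
            {"gene": g, "slope": c.slope, "intercept": c.intercept,
             "r_squared": c.r_squared, "efficiency_percent": c.efficiency_percent}
            for g, c in curves.items()
        ]).to_csv(outdir / "qpcr_curves.csv", index=False)
        results.to_csv(outdir / "qpcr_gcn.csv", index=False)
        for g, c in curves.items():
            summary_lines.append(
                f"qPCR {g}: slope={c.slope:.3f}, "
                f"efficiency={c.efficiency_percent:.0f}%, R2={c.r_squared:.3f}")
        log["stages"][stage] = "ok"
    except Exception as exc:
        fail(stage, exc)

    # -- community -------------------------------------------------------
    stage = "community"
    try:
        table = community_mod.read_asv_table(
            indir / "asv_counts.tsv", indir / "asv_taxonomy.tsv",
            indir / "copy_map.csv" if (indir / "copy_map.csv").exists() else None)
        if cfg.filter_before_rarefy:
            table = community_mod.filter_low_prevalence(table, cfg.min_prevalence_samples)
            table = community_mod.rarefy(table, cfg.rarefaction_depth, seed=0)
        else:
            table = community_mod.rarefy(table, cfg.rarefaction_depth, seed=0)
            table = community_mod.filter_low_prevalence(table, cfg.min_prevalence_samples)
        div = community_mod.diversity_table(table)
        div.to_csv(outdir / "diversity.csv")
        fam = community_mod.aggregate_taxa(table, "family", cfg.family_other_threshold)
        fam.to_csv(outdir / "family_abundance.csv")
        log["stages"][stage] = "ok"
    except Exception as exc:
        fail(stage, exc)

    # -- comparisons -----------------------------------------------------
    stage = "stats"
    try:
        comp_rows = []
        for analyte in ("PA", "DOC"):
            res = treatment_anova(series, analyte, scope="pooled")
            comp_rows.append({"analyte": analyte, "scope": res.scope,
                              "F": res.f_statistic, "p": res.p_value})
            p_rep, n_rep = replicate_equivalence(series, analyte, cfg.replicate_test,
                                                 on_unpaired="intersect")
            summary_lines.append(
                f"{analyte}: ANOVA p={res.p_value:.3g}; "
                f"replicate equivalence p={p_rep:.3f} (N={n_rep})")
            comp_rows.append({"analyte": analyte, "scope": "replicate_equivalence",
                              "F": np.nan, "p": p_rep})
        pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)
        log["stages"][stage] = "ok"
    except Exception as exc:
        fail(stage, exc)

    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return log


def report_checksum(outdir) -> str:
    """SHA-256 over the report's CSV/text outputs (rerun-determinism check)."""
    h = hashlib.sha256()
    for f in sorted(Path(outdir).glob("*")):
        if f.suffix in (".csv", ".txt", ".json") and f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()
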