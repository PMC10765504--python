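"""Absolute qPCR quantification of marker genes (amoA, cbbL).

Standards are serial dilutions of a linearised template of known length;
the copy number of a standard follows from its DNA mass:

    copies = DNA(ng) × 6.0221e23 / (length(bp) × 1e9 × 660),

with 660 g mol⁻¹ per base pair.  A standard curve is the OLS regression of
Cq on log10(copies); amplification efficiency E = 10^(−1/slope) − 1
(E = 100% at the perfect-doubling slope −3.3219).  Unknowns are quantified
by inverting the curve and normalised per ng of template DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrPlate",
    "StandardCurve",
    "standard_copies",
    "fit_standard_curve",
    "efficiency_from_slope",
    "quantify_unknowns",
    "normalize_gcn",
    "analyze_plate",
    "read_plate",
]

AVOGADRO = 6.0221e23       # molecules per mole, as used in the GCN formula
BP_MOLAR_MASS = 660.0      # g per mole per base pair

PLATE_COLUMNS = ["well", "gene", "role", "copies", "cq", "dna_ng", "replicate"]


@dataclass
class StandardCurve:
    slope: float        # Cq per log10(copies); < 0 for a valid curve
    intercept: float    # Cq at 1 copy
    r_squared: float
    efficiency: float   # fraction, e.g. 1.19 for 119%
    cq_range: tuple[float, float]  # Cq span of the standards
    valid: bool = True

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


def standard_copies(dna_ng: float, standard_length_bp: float) -> float:
    """Gene copy number of a standard from its DNA mass and template length."""
    if standard_length_bp <= 0:
        raise ValueError("standard length must be > 0 bp")
    if dna_ng < 0:
        raise ValueError("DNA mass must be ≥ 0 ng")
    return dna_ng * AVOGADRO / (standard_length_bp * 1e9 * BP_MOLAR_MASS)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency E = 10^(−1/slope) − 1 (fraction)."""
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(copies, cq) -> StandardCurve:
    """OLS of Cq on log10(copies) over ≥3 distinct copy levels."""
    c = np.asarray(copies, float)
    q = np.asarray(cq, float)
    if np.any(c <= 0):
        raise ValueError("standard copies must be > 0")
    if len(np.unique(c)) < 3:
        raise ValueError(f"need ≥3 distinct copy levels, got {len(np.unique(c))}")
    res = stats.linregress(np.log10(c), q)
    valid = res.slope < 0
    eff = efficiency_from_slope(res.slope) if valid else float("nan")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=eff,
        cq_range=(float(q.min()), float(q.max())),
        valid=valid,
    )


def quantify_unknowns(curve: StandardCurve, cq) -> tuple[np.ndarray, np.ndarray]:
    """Invert the standard curve: copies = 10^((Cq − intercept)/slope).

    Returns (copies, out_of_range) where the flag marks Cq values outside
    the standards' Cq span (quantification beyond the dilution series).
    """
    if not curve.valid:
        raise ValueError("cannot quantify against an invalid standard curve")
    q = np.atleast_1d(np.asarray(cq, float))
    copies = 10.0 ** ((q - curve.intercept) / curve.slope)
    lo, hi = curve.cq_range
    out_of_range = (q < lo) | (q > hi)
    return copies, out_of_range


def normalize_gcn(copies: float, dna_ng: float) -> float:
    """Gene copies per ng of template DNA."""
    if dna_ng <= 0:
        raise ValueError("DNA mass must be > 0 ng for normalisation")
    return copies / dna_ng


@dataclass
class QpcrPlate:
    """One plate: standards, unknowns and negative controls, long format."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing plate column(s): {missing}")
        df = self.data
        bad_role = ~df["role"].isin(["standard", "unknown", "negative"])
        if bad_role.any():
            raise ValueError(f"unknown role(s): {sorted(df.loc[bad_role, 'role'].unique())}")
        std = df[df["role"] == "standard"]
        for gene, g in std.groupby("gene"):
            if g["copies"].nunique() < 3:
                raise ValueError(f"gene {gene}: standards span <3 distinct copy levels")
        meas = df[df["role"] != "negative"]
        if (meas["cq"] <= 0).any():
            raise ValueError("Cq must be > 0 for standards and unknowns")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())


def read_plate(path) -> QpcrPlate:
    return QpcrPlate(pd.read_csv(path))


def analyze_plate(plate: QpcrPlate, merge_replicates: str = "mean_cq"):
    """Fit per-gene standard curves and quantify unknowns.

    Replicate wells of the same (sample, gene) are merged by mean Cq before
    quantification (``merge_replicates='mean_cq'``) or quantified
    individually ('none').  A detected Cq in a negative control raises a
    plate-level warning column, not an error.

    Returns (curves: {gene: StandardCurve}, results: DataFrame).
    """
    df = plate.data
    curves: dict[str, StandardCurve] = {}
    for gene in plate.genes:
        std = df[(df["gene"] == gene) & (df["role"] == "standard")]
        if len(std):
            curves[gene] = fit_standard_curve(std["copies"], std["cq"])

    rows = []
    unk = df[df["role"] == "unknown"]
    if merge_replicates == "mean_cq":
        grouped = unk.groupby(["gene", "replicate"], sort=True).agg(
            cq=("cq", "mean"), dna_ng=("dna_ng", "mean"), n_wells=("cq", "size")
        ).reset_index()
    elif merge_replicates == "none":
        grouped = unk.rename(columns={"well": "replicate_well"}).assign(n_wells=1)[
            ["gene", "replicate", "cq", "dna_ng", "n_wells"]
        ]
    else:
        raise ValueError(f"unknown replicate merge policy {merge_replicates!r}")

    for row in grouped.itertuples(index=False):
        curve = curves.get(row.gene)
        if curve is None:
            continue
        copies, oor = quantify_unknowns(curve, row.cq)
        rows.append({
            "gene": row.gene, "sample": row.replicate,
            "cq": row.cq, "dna_ng": row.dna_ng,
            "copies": float(copies[0]),
            "gcn_per_ng": normalize_gcn(float(copies[0]), row.dna_ng),
            "out_of_range": bool(oor[0]),
            "n_wells": int(row.n_wells),
        })
    results = pd.DataFrame(rows)

    negatives = df[df["role"] == "negative"]
    n_neg_amp = int((negatives["cq"].notna() & (negatives["cq"] > 0)).sum())
    if n_neg_amp:
        import logging
        logging.getLogger(__name__).warning(
            "%d negative-control well(s) show amplification", n_neg_amp
        )
    return curves, results
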