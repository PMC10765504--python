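"""Domain types, table IO, QC flagging and conservative-mixing expectations.

The incubation experiment mixes a whole-seawater inoculum (30% by volume)
with 0.2 µm filtrate (70%) from either the surface or the formerly suboxic
deep layer, giving treatments coded S/S, S/D and D/S
(inoculum source / filtrate source).  All downstream stages consume the
long-format time-series container defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the long-format time-series table
TIMESERIES_COLUMNS = [
    "treatment",
    "bottle",
    "time_days",
    "analyte",
    "value",
    "unit",
    "qc_flag",
]

QC_FLAGS = ("ok", "contaminated", "missing")

#: analytes whose values must be non-negative (concentrations / abundances)
NONNEGATIVE_ANALYTES_DEFAULT = True


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class ValidationError(ValueError):
    """Rows violate the container's invariants."""


@dataclass(frozen=True)
class Treatment:
    """One experimental treatment: an inoculum diluted with 0.2 µm filtrate.

    ``filtrate_fraction`` is the volume fraction of filtrate (0.70 in the
    experiment this package models); the inoculum fraction is its complement.
    """

    code: str
    inoculum_source: str
    filtrate_source: str
    filtrate_fraction: float = 0.70
    incubation_temp: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.filtrate_fraction <= 1.0:
            raise ValueError(
                f"filtrate_fraction must be in [0, 1], got {self.filtrate_fraction}"
            )
        for src in (self.inoculum_source, self.filtrate_source):
            if src not in ("surface", "deep"):
                raise ValueError(f"source must be 'surface' or 'deep', got {src!r}")

    @property
    def inoculum_fraction(self) -> float:
        return 1.0 - self.filtrate_fraction


#: the experiment's three treatments (Table-1 style codes)
DEFAULT_TREATMENTS = {
    "S/S": Treatment("S/S", "surface", "surface"),
    "S/D": Treatment("S/D", "surface", "deep"),
    "D/S": Treatment("D/S", "deep", "surface"),
}


@dataclass(frozen=True)
class MixtureExpectation:
    """Conservative-mixing expectation for a two-end-member dilution."""

    surface_value: float
    deep_value: float
    filtrate_fraction: float
    filtrate_source: str
    expected: float

    def __post_init__(self) -> None:
        lo = min(self.surface_value, self.deep_value)
        hi = max(self.surface_value, self.deep_value)
        # guard against construction with an inconsistent expectation
        if not (lo - 1e-9 <= self.expected <= hi + 1e-9):
            raise ValueError("expected value must lie between the end-members")


@dataclass
class IncubationSeries:
    """Long-format incubation measurements.

    One row per (treatment, bottle, time, analyte) observation.  Invariants:
    strictly increasing times per (treatment, bottle, analyte), non-negative
    values for concentration/abundance analytes, one unit per analyte.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TIMESERIES_COLUMNS))

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)

    # -- convenience accessors -------------------------------------------
    def select(
        self,
        treatment: str | None = None,
        bottle: str | None = None,
        analyte: str | None = None,
        include_flagged: bool = False,
    ) -> pd.DataFrame:
        """Return matching rows; QC-flagged rows excluded unless requested."""
        d = self.data
        if treatment is not None:
            d = d[d["treatment"] == treatment]
        if bottle is not None:
            d = d[d["bottle"] == bottle]
        if analyte is not None:
            d = d[d["analyte"] == analyte]
        if not include_flagged:
            d = d[d["qc_flag"] == "ok"]
        return d.sort_values("time_days").reset_index(drop=True)

    def series(
        self, treatment: str, bottle: str, analyte: str, include_flagged: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) arrays for one bottle's analyte, QC filtered."""
        d = self.select(treatment, bottle, analyte, include_flagged)
        return d["time_days"].to_numpy(float), d["value"].to_numpy(float)

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    def bottles(self, treatment: str) -> list[str]:
        return sorted(self.data.loc[self.data["treatment"] == treatment, "bottle"].unique())

    def copy(self) -> "IncubationSeries":
        out = IncubationSeries.__new__(IncubationSeries)
        out.data = self.data.copy()
        return out


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns and c != "qc_flag"]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    if "qc_flag" not in df.columns:
        df["qc_flag"] = "ok"
    df = df[TIMESERIES_COLUMNS]
    if len(df) == 0:
        return df.reset_index(drop=True)

    df["time_days"] = pd.to_numeric(df["time_days"], errors="raise")
    df["value"] = pd.to_numeric(df["value"], errors="raise")

    bad_flag = ~df["qc_flag"].isin(QC_FLAGS)
    if bad_flag.any():
        raise ValidationError(
            f"unknown qc_flag values: {sorted(df.loc[bad_flag, 'qc_flag'].unique())}"
        )
    if (df["time_days"] < 0).any():
        rows = df.index[df["time_days"] < 0].tolist()
        raise ValidationError(f"negative time_days at rows {rows}")
    neg = df["value"] < 0
    if neg.any():
        rows = df.index[neg].tolist()
        raise ValidationError(f"negative values (concentrations/abundances) at rows {rows}")

    # strictly increasing times per (treatment, bottle, analyte)
    dup = df.duplicated(subset=["treatment", "bottle", "analyte", "time_days"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["treatment", "bottle", "analyte", "time_days"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValidationError(
            "duplicate timepoints for key(s): " + "; ".join(map(str, keys))
        )

    # one unit per analyte
    nunit = df.groupby("analyte")["unit"].nunique()
    mixed = nunit[nunit > 1]
    if len(mixed):
        raise ValidationError(f"analyte(s) with mixed units: {mixed.index.tolist()}")

    return (
        df.sort_values(["treatment", "bottle", "analyte", "time_days"])
        .reset_index(drop=True)
    )


def read_timeseries(path) -> IncubationSeries:
    """Read a long-format incubation CSV/TSV into a validated container.

    The file must carry columns treatment, bottle, time_days, analyte,
    value, unit (qc_flag optional, defaulting to ``ok``).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    return IncubationSeries(df)


def write_timeseries(series: IncubationSeries, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    series.data.to_csv(path, sep=sep, index=False)


def flag_doc_outliers(
    series: IncubationSeries,
    analyte: str = "DOC",
    percentile: float = 90.0,
    min_group_size: int = 5,
    group_by: tuple[str, ...] = ("treatment", "bottle"),
) -> IncubationSeries:
    """Flag suspected contamination: values above a group's upper percentile.

    Within each (treatment, bottle) group of the given analyte, values
    strictly greater than the group's ``percentile`` (linear interpolation
    between closest ranks) are flagged ``contaminated``.  Values are never
    removed, only flagged; groups smaller than ``min_group_size`` are
    skipped with a warning.  The operation is idempotent because flagged
    rows keep their value and the percentile is computed over all rows of
    the group regardless of flag.
    """
    out = series.copy()
    df = out.data
    mask_analyte = df["analyte"] == analyte
    for key, idx in df[mask_analyte].groupby(list(group_by)).groups.items():
        vals = df.loc[idx, "value"].to_numpy(float)
        if len(vals) < min_group_size:
            logger.warning(
                "group %s has %d < %d observations; percentile rule skipped",
                key, len(vals), min_group_size,
            )
            continue
        cut = np.percentile(vals, percentile)  # linear interpolation
        hit = df.loc[idx].index[vals > cut]
        df.loc[hit, "qc_flag"] = "contaminated"
    return out


def expected_mixture_concentration(
    surface_value: float,
    deep_value: float,
    filtrate_fraction: float,
    filtrate_source: str,
) -> MixtureExpectation:
    """Conservative-mixing expectation for a filtrate + inoculum mixture.

    expected = f·(filtrate end-member) + (1 − f)·(inoculum end-member),
    where f is the filtrate volume fraction.
    """
    if not 0.0 <= filtrate_fraction <= 1.0:
        raise ValueError(f"filtrate_fraction must be in [0, 1], got {filtrate_fraction}")
    if not (np.isfinite(surface_value) and np.isfinite(deep_value)):
        raise ValueError("end-member values must be finite")
    if filtrate_source == "deep":
        filt, inoc = deep_value, surface_value
    elif filtrate_source == "surface":
        filt, inoc = surface_value, deep_value
    else:
        raise ValueError(f"filtrate_source must be 'surface' or 'deep', got {filtrate_source!r}")
    expected = filtrate_fraction * filt + (1.0 - filtrate_fraction) * inoc
    return MixtureExpectation(
        surface_value=surface_value,
        deep_value=deep_value,
        filtrate_fraction=filtrate_fraction,
        filtrate_source=filtrate_source,
        expected=expected,
    )
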