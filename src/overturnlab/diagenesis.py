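"""Dissolved-organic-matter diagenesis metrics from amino-acid composition.

Total dissolved hydrolysable amino acids (TDAA) are a freshness tracer for
marine DOM: as material is microbially reworked, the TDAA carbon yield
(TDAA-C as a percent of DOC) drops and the composition drifts away from
fresh planktonic material.  The degradation index (DI) condenses that
compositional drift into one number,

    DI = Σ_i [(var_i − AVG_i) / SD_i] · fac.coef_i ,

where var_i is the molar percentage of amino acid i and AVG_i, SD_i and
fac.coef_i are the mean, standard deviation and first principal-component
factor coefficient of that amino acid over a reference sample set.  Fresh
material scores high; degraded, refractory material scores low (< 1).

The packaged reference table (``data/aa_reference_synthetic.csv``) is a
synthetic stand-in with the conventional sign structure (glycine/serine/
threonine enriched in degraded material, glutamic acid and the hydrophobic
acids enriched in fresh material); swap in a transcription of a published
reference via :class:`AAReference.from_csv` for real-data work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AminoAcidProfile",
    "AAReference",
    "load_default_reference",
    "molar_fractions",
    "tdaa_total",
    "tdaa_carbon",
    "tdaa_yield",
    "degradation_index",
    "degradation_index_from_molpct",
]


@dataclass
class AminoAcidProfile:
    """Per-sample dissolved amino-acid concentrations in nmol AA L⁻¹."""

    sample_id: str
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for aa, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {aa}: {c}")


@dataclass
class AAReference:
    """Reference statistics and carbon counts used by DI and TDAA-C.

    ``mean_molpct``/``sd_molpct`` are mol-percent statistics, ``factor_coef``
    the PC factor coefficient, ``carbon_atoms`` the carbon count of each
    amino acid; ``di_set`` lists the acids entering the DI sum.
    """

    mean_molpct: dict[str, float]
    sd_molpct: dict[str, float]
    factor_coef: dict[str, float]
    carbon_atoms: dict[str, int]
    di_set: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.di_set:
            self.di_set = tuple(self.factor_coef)
        for aa in self.di_set:
            if self.sd_molpct.get(aa, 0.0) <= 0:
                raise ValueError(f"sd_molpct must be > 0 for DI amino acid {aa}")

    @classmethod
    def from_csv(cls, path) -> "AAReference":
        df = pd.read_csv(path, comment="#")
        in_di = df["in_di_set"].astype(bool) if "in_di_set" in df else pd.Series(True, index=df.index)
        return cls(
            mean_molpct=dict(zip(df["amino_acid"], df["mean_molpct"].astype(float))),
            sd_molpct=dict(zip(df["amino_acid"], df["sd_molpct"].astype(float))),
            factor_coef=dict(zip(df["amino_acid"], df["factor_coef"].astype(float))),
            carbon_atoms=dict(zip(df["amino_acid"], df["carbon_atoms"].astype(int))),
            di_set=tuple(df.loc[in_di, "amino_acid"]),
        )


def load_default_reference() -> AAReference:
    """The packaged (synthetic stand-in) reference table."""
    with resources.as_file(
        resources.files("overturnlab.data") / "aa_reference_synthetic.csv"
    ) as p:
        return AAReference.from_csv(p)


def molar_fractions(profile: AminoAcidProfile) -> dict[str, float]:
    """Molar percentage of each amino acid; percentages sum to 100."""
    total = float(sum(profile.concentrations.values()))
    if total <= 0:
        raise ValueError(f"profile {profile.sample_id} has zero total concentration")
    return {aa: 100.0 * c / total for aa, c in profile.concentrations.items()}


def tdaa_total(profile: AminoAcidProfile) -> float:
    """Total dissolved amino acids, nmol AA L⁻¹."""
    return float(sum(profile.concentrations.values()))


def tdaa_carbon(profile: AminoAcidProfile, reference: AAReference) -> float:
    """TDAA in carbon units: Σ_i concentration_i × carbon_atoms_i, nmol C L⁻¹."""
    total = 0.0
    for aa, conc in profile.concentrations.items():
        if aa not in reference.carbon_atoms:
            raise KeyError(f"no carbon count for amino acid {aa!r} in reference")
        total += conc * reference.carbon_atoms[aa]
    return total


def tdaa_yield(tdaa_c_nmol: float, doc_umol: float) -> float:
    """TDAA carbon as a percent of DOC: (nmol C/1000) / µmol C × 100."""
    if doc_umol <= 0:
        raise ValueError(f"DOC must be > 0, got {doc_umol}")
    return (tdaa_c_nmol / 1000.0) / doc_umol * 100.0


def degradation_index_from_molpct(
    molpct: dict[str, float], reference: AAReference
) -> float:
    """DI from a mol-percent vector (acids outside the DI set ignored)."""
    di = 0.0
    for aa in reference.di_set:
        if aa not in molpct:
            raise KeyError(f"DI amino acid {aa!r} missing from profile")
        z = (molpct[aa] - reference.mean_molpct[aa]) / reference.sd_molpct[aa]
        di += z * reference.factor_coef[aa]
    return di


def degradation_index(profile: AminoAcidProfile, reference: AAReference) -> float:
    """Degradation index of a concentration profile.

    Depends only on composition (mol%), so it is invariant to uniform
    rescaling of all concentrations.
    """
    return degradation_index_from_molpct(molar_fractions(profile), reference)


def diagenesis_table(
    profiles: list[AminoAcidProfile],
    doc_by_sample: dict[str, float] | None = None,
    reference: AAReference | None = None,
) -> pd.DataFrame:
    """Per-sample summary: TDAA, TDAA-C, yield (if DOC given) and DI."""
    ref = reference or load_default_reference()
    rows = []
    for p in profiles:
        tdaa_c = tdaa_carbon(p, ref)
        row = {
            "sample_id": p.sample_id,
            "tdaa_nmol_L": tdaa_total(p),
            "tdaa_c_nmol_L": tdaa_c,
            "di": degradation_index(p, ref),
        }
        if doc_by_sample and p.sample_id in doc_by_sample:
            row["tdaa_yield_pct"] = tdaa_yield(tdaa_c, doc_by_sample[p.sample_id])
        rows.append(row)
    return pd.DataFrame(rows)


def read_aa_profiles(path) -> list[AminoAcidProfile]:
    """Read long-format (sample_id, amino_acid, concentration_nmol_L) CSV."""
    df = pd.read_csv(path)
    needed = {"sample_id", "amino_acid", "concentration_nmol_L"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    return [
        AminoAcidProfile(str(sid), dict(zip(g["amino_acid"], g["concentration_nmol_L"])))
        for sid, g in df.groupby("sample_id", sort=True)
    ]
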