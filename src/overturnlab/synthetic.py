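"""Seeded synthetic experiment bundles with the statistical structure the
analysis pipeline assumes.

The generator emulates a 21-day, three-treatment dilution-incubation
experiment (S/S, S/D, D/S: inoculum source / 0.2 µm-filtrate source, 30/70
by volume): logistic prokaryotic growth with an optional initial die-off
in the deep-inoculum treatment, first-order DOC drawdown with a lag and an
optional mid-incubation production pulse, amino-acid composition drifting
away from a reference composition as material degrades, qPCR plates with
10⁶–10¹-copy standard dilution series, formula-bearing mzRT feature tables
spanning the compound-class vocabulary, and treatment-structured ASV
counts with a dominant high-copy-number taxon in the deep inoculum.

Growth trajectories are calibrated deterministically at generation time so
that, before noise, (a) the OLS slope of ln(abundance) over the sampled
days inside the exponential window equals the configured specific growth
rate and (b) twice the logistic half-capacity time, measured from the
window start, equals the configured exponential duration.  The noiseless
bundle is therefore an exact fixed point of the downstream growth
analysis.

Everything is driven by one integer seed through a single
``numpy.random.Generator``; identical (config, seed) pairs give
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import community as _community
from . import core_io, diagenesis, metabolomics, qpcr

__all__ = [
    "GrowthBlock",
    "DocBlock",
    "ProductionPulse",
    "TreatmentConfig",
    "ExperimentConfig",
    "ExperimentBundle",
    "default_config",
    "config_from_dict",
    "noiseless",
    "generate_experiment",
    "write_bundle",
    "read_bundle",
    "bundle_checksum",
]

VERSION = "0.1.0"

SAMPLING_DAYS = (0, 1, 2, 3, 4, 5, 6, 8, 9, 12, 21)
AA_DAYS = (0, 2, 6, 12, 21)
FEATURE_DAYS = (0, 8, 21)
QPCR_DAYS = (0, 6, 12, 21)
ASV_DAYS = (0, 2, 6, 12, 21)


@dataclass
class ProductionPulse:
    start: float        # d
    magnitude: float    # µmol C L⁻¹ at the pulse peak
    duration: float = 3.0


@dataclass
class GrowthBlock:
    initial_abundance: float      # cells L⁻¹ in the bottle at t = 0
    specific_growth_rate: float   # target μ, d⁻¹
    exponential_duration: float   # d (t_stationary − window start)
    carrying_capacity: float | None = None  # derived by calibration if None
    die_off_fraction: float = 0.0           # fraction lost before regrowth
    die_off_duration: float = 0.0           # d

    def __post_init__(self) -> None:
        if self.initial_abundance <= 0:
            raise ValueError("initial_abundance must be > 0")
        if self.specific_growth_rate <= 0 or self.exponential_duration <= 0:
            raise ValueError("growth rate and exponential duration must be > 0")
        if not 0.0 <= self.die_off_fraction < 1.0:
            raise ValueError("die_off_fraction must be in [0, 1)")
        if self.die_off_fraction > 0 and self.die_off_duration <= 0:
            raise ValueError("die_off_duration must be > 0 when die-off is enabled")


@dataclass
class DocBlock:
    initial: float                 # µmol C L⁻¹
    lag: float = 0.0               # d of unchanged DOC
    drawdown_rate: float = 0.5     # initial drawdown, µmol C L⁻¹ d⁻¹
    refractory_floor: float = 70.0  # asymptotic DOC, µmol C L⁻¹
    production_pulse: ProductionPulse | None = None

    def __post_init__(self) -> None:
        if self.initial <= self.refractory_floor:
            raise ValueError("initial DOC must exceed the refractory floor")
        if self.lag < 0 or self.drawdown_rate < 0:
            raise ValueError("lag and drawdown_rate must be ≥ 0")


@dataclass
class TreatmentConfig:
    treatment: core_io.Treatment
    growth: GrowthBlock
    doc: DocBlock
    aa_drift_rate: float = 0.05    # z-units of compositional drift per day
    aa_initial_tdaa: float = 1500.0  # nmol AA L⁻¹ at t = 0
    aa_decline_rate: float = 0.08    # d⁻¹ first-order TDAA decline


@dataclass
class ExperimentConfig:
    treatments: dict[str, TreatmentConfig]
    bottles: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {"S/S": ("A", "B"), "S/D": ("C", "D"), "D/S": ("E", "F")}
    )
    sampling_days: tuple = SAMPLING_DAYS
    noise_sd: dict = field(default_factory=lambda: {"PA": 0.03, "DOC": 1.0})
    aa_noise_frac: float = 0.05
    # qPCR block
    qpcr_slope: float = -2.93          # Cq per log10(copies)
    qpcr_intercept: float = 38.0       # Cq
    qpcr_replicate_sd: float = 0.15    # Cq
    qpcr_standard_levels: tuple = (1e6, 1e5, 1e4, 1e3, 1e2, 1e1)
    # feature-table block
    n_features: int = 300
    magnitude_sigma: float = 1.0       # lognormal sd of peak magnitudes
    unassigned_fraction: float = 0.15  # features without a formula
    # ASV block
    asv_library_size: tuple = (12000, 25000)
    rarefaction_floor: int = 10000
    deep_dominant_family: str = "Chlorobiaceae"
    deep_dominant_fraction: float = 0.75
    copy_map: dict = field(default_factory=lambda: {"Chlorobiaceae": 3})

    def treatment(self, code: str) -> TreatmentConfig:
        return self.treatments[code]

    def validate(self) -> None:
        for code, tc in self.treatments.items():
            if code not in self.bottles:
                raise ValueError(f"no bottles defined for treatment {code}")
            _ = tc.growth, tc.doc  # dataclass __post_init__ already validated
        if self.qpcr_slope >= 0:
            raise ValueError("qpcr_slope must be negative")
        if not 0 <= self.unassigned_fraction < 1:
            raise ValueError("unassigned_fraction must be in [0, 1)")
        lo, hi = self.asv_library_size
        if lo < self.rarefaction_floor:
            raise ValueError("ASV library sizes must be ≥ the rarefaction floor")

    def to_dict(self) -> dict:
        def conv(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: conv(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            return o
        return conv(self)


def config_from_dict(d: dict) -> ExperimentConfig:
    """Rebuild an :class:`ExperimentConfig` from ``to_dict`` output (so a
    bundle manifest suffices to regenerate the bundle bit-for-bit)."""
    treatments = {}
    for code, tc in d["treatments"].items():
        pulse = tc["doc"].get("production_pulse")
        treatments[code] = TreatmentConfig(
            treatment=core_io.Treatment(**tc["treatment"]),
            growth=GrowthBlock(**tc["growth"]),
            doc=DocBlock(**{**tc["doc"],
                            "production_pulse": ProductionPulse(**pulse) if pulse else None}),
            aa_drift_rate=tc["aa_drift_rate"],
            aa_initial_tdaa=tc["aa_initial_tdaa"],
            aa_decline_rate=tc["aa_decline_rate"],
        )
    return ExperimentConfig(
        treatments=treatments,
        bottles={k: tuple(v) for k, v in d["bottles"].items()},
        sampling_days=tuple(d["sampling_days"]),
        noise_sd=dict(d["noise_sd"]),
        aa_noise_frac=d["aa_noise_frac"],
        qpcr_slope=d["qpcr_slope"],
        qpcr_intercept=d["qpcr_intercept"],
        qpcr_replicate_sd=d["qpcr_replicate_sd"],
        qpcr_standard_levels=tuple(d["qpcr_standard_levels"]),
        n_features=d["n_features"],
        magnitude_sigma=d["magnitude_sigma"],
        unassigned_fraction=d["unassigned_fraction"],
        asv_library_size=tuple(d["asv_library_size"]),
        rarefaction_floor=d["rarefaction_floor"],
        deep_dominant_family=d["deep_dominant_family"],
        deep_dominant_fraction=d["deep_dominant_fraction"],
        copy_map=dict(d["copy_map"]),
    )


def default_config() -> ExperimentConfig:
    """The experiment's three treatments with their published kinetics.

    Growth rates 0.03/0.19/0.11 d⁻¹ and exponential durations 10.1/4.9/2.8 d
    for S/S, S/D and D/S; initial abundances are 30% of the source-water
    abundances (17.6e8 surface, 70.0e8 deep cells L⁻¹); DOC starting points
    are conservative-mixing values of the 94.8/110.1 µmol C L⁻¹ end-members;
    D/S carries a 25% initial die-off and a DOC production pulse between
    days 9 and 12.
    """
    surface_pa, deep_pa = 17.6e8, 70.0e8
    surface_doc, deep_doc = 94.8, 110.1
    f = 0.70
    mix = core_io.expected_mixture_concentration
    treatments = {
        "S/S": TreatmentConfig(
            treatment=core_io.DEFAULT_TREATMENTS["S/S"],
            growth=GrowthBlock(0.3 * surface_pa, 0.03, 10.1),
            doc=DocBlock(initial=surface_doc,  # both end-members are surface water
                         lag=2.0, drawdown_rate=0.79, refractory_floor=75.0),
            aa_drift_rate=0.03,
        ),
        "S/D": TreatmentConfig(
            treatment=core_io.DEFAULT_TREATMENTS["S/D"],
            growth=GrowthBlock(0.3 * surface_pa, 0.19, 4.9),
            doc=DocBlock(initial=mix(surface_doc, deep_doc, f, "deep").expected,
                         lag=0.0, drawdown_rate=2.7, refractory_floor=93.0),
            aa_drift_rate=0.06,
        ),
        "D/S": TreatmentConfig(
            treatment=core_io.DEFAULT_TREATMENTS["D/S"],
            growth=GrowthBlock(0.3 * deep_pa, 0.11, 2.8,
                               die_off_fraction=0.25, die_off_duration=1.0),
            doc=DocBlock(initial=mix(surface_doc, deep_doc, f, "surface").expected,
                         lag=0.0, drawdown_rate=0.68, refractory_floor=85.0,
                         production_pulse=ProductionPulse(start=9.0, magnitude=2.0,
                                                          duration=6.0)),
            aa_drift_rate=0.05,
        ),
    }
    return ExperimentConfig(treatments=treatments)


def noiseless(config: ExperimentConfig) -> ExperimentConfig:
    """Copy of a config with every observation-noise term set to zero."""
    cfg = dataclasses.replace(
        config,
        noise_sd={k: 0.0 for k in config.noise_sd},
        aa_noise_frac=0.0,
        qpcr_replicate_sd=0.0,
    )
    return cfg


# ---------------------------------------------------------------------------
# growth-curve calibration


def calibrate_growth(block: GrowthBlock, sampling_days) -> dict:
    """Solve for the logistic rate and capacity matching the configured
    μ and exponential duration on the sampled days.

    With window start t_s (end of any die-off) and duration
    T = t_stationary − t_s, the half-capacity time is t_mid = (T + t_s)/2
    and the capacity ratio is ρ = (K − N_s)/N_s = exp(r·(T − t_s)/2);
    r is found by root-finding so that the OLS ln-slope over sampled days
    in [t_s, t_s + T] equals μ.
    """
    t_s = block.die_off_duration if block.die_off_fraction > 0 else 0.0
    T = block.exponential_duration
    n_s = block.initial_abundance * (1.0 - block.die_off_fraction)
    days = np.asarray([d for d in sampling_days if t_s <= d <= t_s + T], float)
    if len(days) < 3:
        raise ValueError("fewer than 3 sampling days inside the exponential window")
    mu = block.specific_growth_rate

    half = (T - t_s) / 2.0  # t_mid − t_s, so that 2·t_mid − t_s = T
    if half <= 0:
        raise ValueError("exponential_duration must exceed the die-off duration")

    if block.carrying_capacity is not None:
        # explicit K: honour K and the duration rule; μ becomes implied
        rho = (block.carrying_capacity - n_s) / n_s
        if rho <= 0:
            raise ValueError("carrying_capacity must exceed the post-die-off abundance")
        r = math.log(rho) / half
        return {"r": r, "rho": rho, "K": block.carrying_capacity,
                "n_start": n_s, "t_start": t_s}

    def slope_given_r(r: float) -> float:
        rho = math.exp(r * half)
        ln_n = -np.log1p(rho * np.exp(-r * (days - t_s)))  # ln N up to a constant
        return stats.linregress(days, ln_n).slope

    lo, hi = mu * (1.0 + 1e-9), mu * 50.0
    if slope_given_r(hi) < mu:
        raise ValueError("cannot calibrate: target μ unattainable on these days")
    r = optimize.brentq(lambda r: slope_given_r(r) - mu, lo, hi, xtol=1e-13, rtol=1e-15)
    rho = math.exp(r * half)
    return {"r": r, "rho": rho, "K": n_s * (1.0 + rho), "n_start": n_s, "t_start": t_s}


def growth_trajectory(block: GrowthBlock, times, sampling_days=SAMPLING_DAYS) -> np.ndarray:
    """Noiseless abundance trajectory: optional exponential die-off segment,
    then the calibrated logistic."""
    cal = calibrate_growth(block, sampling_days)
    t = np.asarray(times, float)
    out = np.empty_like(t)
    t_s, n_s, K, r, rho = (cal["t_start"], cal["n_start"], cal["K"], cal["r"], cal["rho"])
    if t_s > 0:
        lam = -math.log(1.0 - block.die_off_fraction) / block.die_off_duration
        pre = t < t_s
        out[pre] = block.initial_abundance * np.exp(-lam * t[pre])
    else:
        pre = np.zeros_like(t, bool)
    out[~pre] = K / (1.0 + rho * np.exp(-r * (t[~pre] - t_s)))
    return out


def doc_trajectory(block: DocBlock, times) -> np.ndarray:
    """Noiseless DOC: lag, then first-order decay toward the refractory
    floor (initial slope = drawdown_rate), plus an optional triangular
    production pulse."""
    t = np.asarray(times, float)
    amp = block.initial - block.refractory_floor
    k = block.drawdown_rate / amp
    td = np.clip(t - block.lag, 0.0, None)
    doc = block.refractory_floor + amp * np.exp(-k * td)
    if block.production_pulse is not None:
        p = block.production_pulse
        half = p.duration / 2.0
        tri = np.clip(1.0 - np.abs(t - (p.start + half)) / half, 0.0, None)
        doc = doc + p.magnitude * tri
    return doc


# ---------------------------------------------------------------------------
# formula pool for the feature tables (spanning the class vocabulary)

_FORMULA_POOL = [
    # (formula, base weight) — classes under the default ruleset noted
    ("C16H10", 0.04),    # black carbon
    ("C20H12", 0.03),    # black carbon
    ("C10H8", 0.04),     # condensed hydrocarbons
    ("C8H8O3", 0.06),    # polyphenols
    ("C6H12O6", 0.08),   # sugars
    ("C12H22O11", 0.05),  # sugars
    ("C6H10O5", 0.06),   # carbohydrates
    ("C16H32O2", 0.05),  # saturated fatty acids
    ("C18H34O2", 0.05),  # lipids
    ("C5H11NO2", 0.06),  # proteins
    ("C8H16N2O2", 0.06),  # peptides
    ("C5H11NO2S", 0.04),  # protein maya
    ("C10H18O4", 0.06),  # unsaturated aliphatic compounds
    ("C15H18O7", 0.10),  # CRAM
    ("C10H14O6", 0.08),  # lignin
    ("C12H14O9", 0.08),  # highly unsaturated compounds
    ("C5H9NO4", 0.04),   # heteroatom-rich, unassigned by the default rules
    ("C8H14O4S", 0.02),  # CHOS
]

_MONO_MASS = {"C": 12.0, "H": 1.007825, "N": 14.003074, "O": 15.994915,
              "S": 31.972071, "P": 30.973762}


def _formula_mass(formula: str) -> float:
    counts = metabolomics.parse_formula(formula)
    return sum(_MONO_MASS[el] * n for el, n in counts.items())


# ---------------------------------------------------------------------------
# ASV community templates

_FAMILIES = {
    "Chlorobiaceae": "Bacteria;Chlorobi;Chlorobia;Chlorobiales;Chlorobiaceae",
    "Alteromonadaceae": "Bacteria;Proteobacteria;Gammaproteobacteria;Alteromonadales;Alteromonadaceae",
    "Rhodobacteraceae": "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae",
    "Flavobacteriaceae": "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;Flavobacteriaceae",
    "Pelagibacteraceae": "Bacteria;Proteobacteria;Alphaproteobacteria;Pelagibacterales;Pelagibacteraceae",
    "Cyanobiaceae": "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Cyanobiaceae",
    "Nitrosopumilaceae": "Archaea;Crenarchaeota;Nitrososphaeria;Nitrosopumilales;Nitrosopumilaceae",
    "SAR202": "Bacteria;Chloroflexi;Dehalococcoidia;SAR202_clade;SAR202",
    "Vibrionaceae": "Bacteria;Proteobacteria;Gammaproteobacteria;Vibrionales;Vibrionaceae",
    "Halieaceae": "Bacteria;Proteobacteria;Gammaproteobacteria;Cellvibrionales;Halieaceae",
}

# start/end family weights (day 0 → day 21); surface-like vs deep-like
_SURFACE_W0 = {"Pelagibacteraceae": 0.30, "Cyanobiaceae": 0.20, "Rhodobacteraceae": 0.15,
               "Flavobacteriaceae": 0.15, "Halieaceae": 0.10, "Alteromonadaceae": 0.05,
               "Vibrionaceae": 0.03, "SAR202": 0.01, "Nitrosopumilaceae": 0.01}
_SURFACE_W21 = {"Pelagibacteraceae": 0.15, "Cyanobiaceae": 0.05, "Rhodobacteraceae": 0.20,
                "Flavobacteriaceae": 0.15, "Halieaceae": 0.08, "Alteromonadaceae": 0.20,
                "Vibrionaceae": 0.05, "SAR202": 0.07, "Nitrosopumilaceae": 0.05}


@dataclass
class ExperimentBundle:
    timeseries: core_io.IncubationSeries
    aa_profiles: list[diagenesis.AminoAcidProfile]
    qpcr_plate: qpcr.QpcrPlate
    feature_tables: dict[str, list[metabolomics.FormulaFeature]]
    asv_table: _community.AsvTable
    manifest: dict


def _truncnorm(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Additive Gaussian noise truncated at zero (proper truncated sampling)."""
    if sd <= 0:
        return np.asarray(mean, float)
    mean = np.asarray(mean, float)
    a = (0.0 - mean) / sd
    u = rng.random(mean.shape)
    return stats.truncnorm.ppf(u, a, np.inf, loc=mean, scale=sd)


def generate_experiment(config: ExperimentConfig, seed: int) -> ExperimentBundle:
    """Generate a complete seeded bundle; identical (config, seed) pairs
    yield byte-identical bundles."""
    config.validate()
    rng = np.random.default_rng(seed)
    days = np.asarray(config.sampling_days, float)

    # ---- incubation time series (PA, DOC) ------------------------------
    rows = []
    for code, tc in config.treatments.items():
        pa_true = growth_trajectory(tc.growth, days, config.sampling_days)
        doc_true = doc_trajectory(tc.doc, days)
        for bottle in config.bottles[code]:
            pa_sd = config.noise_sd.get("PA", 0.0)
            if pa_sd > 0:
                pa_obs = pa_true * np.exp(rng.normal(0.0, pa_sd, pa_true.shape)
                                          - 0.5 * pa_sd**2)
            else:
                pa_obs = pa_true
            doc_obs = _truncnorm(rng, doc_true, config.noise_sd.get("DOC", 0.0))
            for d, pa, doc in zip(days, pa_obs, doc_obs):
                rows.append((code, bottle, d, "PA", pa, "cells L-1", "ok"))
                rows.append((code, bottle, d, "DOC", doc, "umol C L-1", "ok"))
    ts = core_io.IncubationSeries(
        pd.DataFrame(rows, columns=core_io.TIMESERIES_COLUMNS)
    )

    # ---- amino-acid profiles -------------------------------------------
    ref = diagenesis.load_default_reference()
    aa_names = list(ref.mean_molpct)
    means = np.array([ref.mean_molpct[a] for a in aa_names])
    sds = np.array([ref.sd_molpct[a] for a in aa_names])
    coefs = np.array([ref.factor_coef[a] for a in aa_names])
    profiles = []
    for code, tc in config.treatments.items():
        for day in AA_DAYS:
            drift = -tc.aa_drift_rate * day  # degradation lowers DI over time
            molpct = means + drift * sds * coefs
            molpct = np.clip(molpct, 0.01, None)
            molpct = 100.0 * molpct / molpct.sum()
            total = tc.aa_initial_tdaa * math.exp(-tc.aa_decline_rate * day)
            conc = total * molpct / 100.0
            if config.aa_noise_frac > 0:
                conc = _truncnorm(rng, conc, config.aa_noise_frac * conc.mean())
            profiles.append(diagenesis.AminoAcidProfile(
                sample_id=f"{code}|day{day}",
                concentrations=dict(zip(aa_names, conc)),
            ))

    # ---- qPCR plate ----------------------------------------------------
    plate_rows = []
    well = 0
    gcn_shapes = {
        # per-ng copies over QPCR_DAYS, per treatment; loosely follows the
        # cbbL rise in D/S and the late amoA rise in S/D
        "cbbL": {"S/S": (9000, 7000, 5000, 4000), "S/D": (9000, 6000, 4000, 3000),
                 "D/S": (150, 2000, 8000, 5000)},
        "amoA": {"S/S": (15, 15, 20, 25), "S/D": (15, 30, 800, 2500),
                 "D/S": (1300, 400, 100, 60)},
    }
    for gene in ("amoA", "cbbL"):
        for level in config.qpcr_standard_levels:
            for rep in ("r1", "r2"):
                cq = (config.qpcr_intercept + config.qpcr_slope * math.log10(level)
                      + (rng.normal(0.0, config.qpcr_replicate_sd)
                         if config.qpcr_replicate_sd > 0 else 0.0))
                plate_rows.append((f"W{well}", gene, "standard", level, cq,
                                   np.nan, f"std_{level:g}_{rep}"))
                well += 1
        for code in config.treatments:
            for day, gcn in zip(QPCR_DAYS, gcn_shapes[gene][code]):
                dna_ng = 20.0
                copies = gcn * dna_ng
                for rep in ("r1", "r2"):
                    cq = (config.qpcr_intercept + config.qpcr_slope * math.log10(copies)
                          + (rng.normal(0.0, config.qpcr_replicate_sd)
                             if config.qpcr_replicate_sd > 0 else 0.0))
                    plate_rows.append((f"W{well}", gene, "unknown", np.nan, cq,
                                       dna_ng, f"{code}|day{day}"))
                    well += 1
        plate_rows.append((f"W{well}", gene, "negative", np.nan, np.nan, np.nan, "NTC"))
        well += 1
    plate = qpcr.QpcrPlate(pd.DataFrame(plate_rows, columns=qpcr.PLATE_COLUMNS))

    # ---- mzRT feature tables -------------------------------------------
    pool_formulas = [f for f, _ in _FORMULA_POOL]
    pool_weights = np.array([w for _, w in _FORMULA_POOL])
    feature_tables: dict[str, list[metabolomics.FormulaFeature]] = {}
    for code in config.treatments:
        for day in FEATURE_DAYS:
            w = pool_weights.copy()
            # mild compositional trend: sugars up, black carbon down with time
            shift = day / 21.0
            for i, (formula, _) in enumerate(_FORMULA_POOL):
                if formula in ("C6H12O6", "C12H22O11"):
                    w[i] *= 1.0 + 0.5 * shift
                if formula in ("C16H10", "C20H12"):
                    w[i] *= 1.0 - 0.5 * shift
            w /= w.sum()
            n_unassigned = int(round(config.n_features * config.unassigned_fraction))
            n_assigned = config.n_features - n_unassigned
            choice = rng.choice(len(pool_formulas), size=n_assigned, p=w)
            feats = []
            for idx in choice:
                formula = pool_formulas[idx]
                mag = float(rng.lognormal(10.0, config.magnitude_sigma))
                mass = _formula_mass(formula)
                counts = metabolomics.parse_formula(formula)
                feats.append(metabolomics.FormulaFeature(
                    mz=mass - 1.007276,  # [M−H]⁻ ion
                    rt=float(rng.uniform(30.0, 1200.0)),
                    magnitude=mag, formula_assigned=True, **counts))
            for _ in range(n_unassigned):
                feats.append(metabolomics.FormulaFeature(
                    mz=float(rng.uniform(100.0, 800.0)),
                    rt=float(rng.uniform(30.0, 1200.0)),
                    magnitude=float(rng.lognormal(9.0, config.magnitude_sigma))))
            feature_tables[f"{code}|day{day}"] = feats

    # ---- ASV table -----------------------------------------------------
    families = list(_FAMILIES)
    asv_ids, taxonomy = [], {}
    per_family = 3
    for fam in families:
        genus = fam[:-4] if fam.endswith("ceae") else fam
        for i in range(per_family):
            asv = f"ASV_{fam}_{i}"
            asv_ids.append(asv)
            taxonomy[asv] = f"{_FAMILIES[fam]};{genus}_{i}"
    split = np.array([0.6, 0.3, 0.1])  # within-family ASV split

    def family_weights(code: str, day: float) -> dict[str, float]:
        f = min(day / 21.0, 1.0)
        w = {fam: (1 - f) * _SURFACE_W0.get(fam, 0.0) + f * _SURFACE_W21.get(fam, 0.0)
             for fam in families}
        if code == "D/S" and day <= 6:
            # deep inoculum: dominant anaerobic family at its configured
            # share at day 0, decaying fast after reoxygenation
            dom = {0: config.deep_dominant_fraction, 1: 0.10, 2: 0.02}.get(day, 0.005)
            rest = {k: v for k, v in w.items() if k != config.deep_dominant_family}
            scale = (1.0 - dom) / sum(rest.values())
            w = {k: v * scale for k, v in rest.items()}
            w[config.deep_dominant_family] = dom
        else:
            w.setdefault(config.deep_dominant_family, 0.0)
            total = sum(w.values())
            w = {k: v / total for k, v in w.items()}
        return w

    count_rows, sample_ids = [], []
    lo, hi = config.asv_library_size
    for code, tc in config.treatments.items():
        for bottle in config.bottles[code]:
            for day in ASV_DAYS:
                w = family_weights(code, day)
                p = np.concatenate([w.get(fam, 0.0) * split for fam in families])
                p = p / p.sum()
                libsize = int(rng.integers(lo, hi + 1))
                count_rows.append(rng.multinomial(libsize, p))
                sample_ids.append(f"{code}|{bottle}|day{day}")
    counts = pd.DataFrame(count_rows, index=sample_ids, columns=asv_ids)
    asv = _community.AsvTable(counts=counts, taxonomy=taxonomy,
                              copy_map=dict(config.copy_map))

    manifest = {
        "generator": "overturnlab.synthetic",
        "version": VERSION,
        "seed": int(seed),
        "config": config.to_dict(),
    }
    return ExperimentBundle(timeseries=ts, aa_profiles=profiles, qpcr_plate=plate,
                            feature_tables=feature_tables, asv_table=asv,
                            manifest=manifest)


# ---------------------------------------------------------------------------
# bundle IO


def write_bundle(bundle: ExperimentBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    core_io.write_timeseries(bundle.timeseries, out / "timeseries.csv")
    aa_rows = [
        {"sample_id": p.sample_id, "amino_acid": aa, "concentration_nmol_L": c}
        for p in bundle.aa_profiles for aa, c in p.concentrations.items()
    ]
    pd.DataFrame(aa_rows).to_csv(out / "aa_profiles.csv", index=False)
    bundle.qpcr_plate.data.to_csv(out / "qpcr_plate.csv", index=False)
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for sample, feats in bundle.feature_tables.items():
        df = pd.DataFrame([
            {"mz": f.mz, "rt": f.rt, "magnitude": f.magnitude,
             "formula": metabolomics.formula_string(f) if f.formula_assigned else ""}
            for f in feats
        ])
        df.to_csv(feat_dir / (sample.replace("/", "-").replace("|", "_") + ".csv"),
                  index=False)
    _community.write_asv_table(bundle.asv_table, out / "asv_counts.tsv",
                               out / "asv_taxonomy.tsv")
    pd.DataFrame(
        [{"taxon": t, "copies": c} for t, c in bundle.asv_table.copy_map.items()]
    ).to_csv(out / "copy_map.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))


def read_bundle(indir) -> ExperimentBundle:
    p = Path(indir)
    ts = core_io.read_timeseries(p / "timeseries.csv")
    profiles = diagenesis.read_aa_profiles(p / "aa_profiles.csv")
    plate = qpcr.read_plate(p / "qpcr_plate.csv")
    feature_tables = {}
    for f in sorted((p / "features").glob("*.csv")):
        sample = f.stem
        # undo the filesystem-safe renaming (code_dayN with '-' for '/')
        sample = sample.replace("_day", "|day").replace("-", "/")
        feature_tables[sample] = metabolomics.read_feature_table(f)
    asv = _community.read_asv_table(p / "asv_counts.tsv", p / "asv_taxonomy.tsv",
                                    p / "copy_map.csv" if (p / "copy_map.csv").exists() else None)
    manifest = json.loads((p / "manifest.json").read_text())
    return ExperimentBundle(ts, profiles, plate, feature_tables, asv, manifest)


def bundle_checksum(bundle: ExperimentBundle) -> str:
    """SHA-256 over a canonical serialisation of every table in the bundle."""
    h = hashlib.sha256()
    h.update(bundle.timeseries.data.to_csv(index=False).encode())
    for p in bundle.aa_profiles:
        h.update(p.sample_id.encode())
        for aa, c in sorted(p.concentrations.items()):
            h.update(f"{aa}:{c!r};".encode())
    h.update(bundle.qpcr_plate.data.to_csv(index=False).encode())
    for sample in sorted(bundle.feature_tables):
        h.update(sample.encode())
        for f in bundle.feature_tables[sample]:
            h.update(f"{f.mz!r},{f.rt!r},{f.magnitude!r},{f.C},{f.H},{f.N},{f.O},{f.S},{f.P}".encode())
    h.update(bundle.asv_table.counts.to_csv().encode())
    h.update(json.dumps(bundle.manifest, sort_keys=True).encode())
    return h.hexdigest()
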