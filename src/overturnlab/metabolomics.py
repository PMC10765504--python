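"""Molecular-formula indices and compound classes for mzRT feature tables.

Untargeted FT-MS of solid-phase-extracted DOM yields mzRT features —
unique (m/z, retention-time) pairs with a peak magnitude — a subset of
which carry an assigned elemental formula CcHhNnOoSsPp.  From the formula
this module derives the double-bond equivalents

    DBE = ½ (2 + 2C − H + N + P),

the modified aromaticity index

    AI_mod = (1 + C − ½O − S − ½(N + P + H)) / (C − ½O − N − S − P),

clamped to 0 for negative numerators or non-positive denominators (the
unmodified AI, with full rather than half oxygen weighting, is available
via ``modified=False``), and van-Krevelen style compound classes from an
ordered, editable rule table over (H/C, O/C, AI, DBE ratios, heteroatom
counts).  Sample-level summaries are magnitude-weighted means of O/C, H/C
and DBE plus CHO/CHON/CHOS formula counts and per-class peak-area
fractions.

The default class boundaries are literature-conventional (e.g. the CRAM
DBE/C, DBE/H, DBE/O windows); they are heuristics, and the rule table is
deliberately exposed so users can substitute their own boundary set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormulaFeature",
    "ClassRule",
    "ClassRuleset",
    "default_ruleset",
    "parse_formula",
    "formula_string",
    "double_bond_equivalents",
    "aromaticity_index",
    "assign_compound_class",
    "magnitude_weighted_indices",
    "element_class_counts",
    "class_peak_area_fractions",
    "read_feature_table",
    "feature_frame",
]

_ELEMENTS = ("C", "H", "N", "O", "S", "P")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class FormulaFeature:
    mz: float = 0.0
    rt: float = 0.0
    magnitude: float = 0.0
    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    P: int = 0
    formula_assigned: bool = False

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be ≥ 0")
        if self.formula_assigned and (self.C < 1 or self.H < 1):
            raise ValueError("an assigned formula needs C ≥ 1 and H ≥ 1")

    @property
    def hc(self) -> float:
        return self.H / self.C

    @property
    def oc(self) -> float:
        return self.O / self.C


def parse_formula(text: str) -> dict[str, int]:
    """Parse 'C6H12O6'-style strings into {element: count} (omitted count = 1)."""
    counts = dict.fromkeys(_ELEMENTS, 0)
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise ValueError(f"unknown element {sym!r} in formula {text!r}")
        counts[sym] += int(num) if num else 1
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def formula_string(feature: FormulaFeature) -> str:
    parts = []
    for el in _ELEMENTS:
        n = getattr(feature, el)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def feature_from_formula(formula: str, magnitude: float = 1.0, mz: float = 0.0,
                         rt: float = 0.0) -> FormulaFeature:
    counts = parse_formula(formula)
    return FormulaFeature(mz=mz, rt=rt, magnitude=magnitude, formula_assigned=True, **counts)


def double_bond_equivalents(feature: FormulaFeature) -> float:
    """DBE = ½(2 + 2C − H + N + P); half-integral values indicate a
    nitrogen-rule parity violation and are returned as-is."""
    if not feature.formula_assigned:
        raise ValueError("feature has no assigned formula")
    return 0.5 * (2 + 2 * feature.C - feature.H + feature.N + feature.P)


def aromaticity_index(feature: FormulaFeature, modified: bool = True) -> float:
    """Aromaticity index; AI_mod (half-weighted oxygen) by default.

    Clamped to 0 when the numerator is negative or the denominator ≤ 0.
    """
    if not feature.formula_assigned:
        raise ValueError("feature has no assigned formula")
    C, H, N, O, S, P = feature.C, feature.H, feature.N, feature.O, feature.S, feature.P
    o_weight = 0.5 if modified else 1.0
    num = 1 + C - o_weight * O - S - 0.5 * (N + P + H)
    den = C - o_weight * O - N - S - P
    if den <= 0 or num < 0:
        return 0.0
    return num / den


@dataclass(frozen=True)
class ClassRule:
    """One ordered classification rule: label plus interval predicates.

    Bounds are inclusive; ``None`` leaves a side open.  ``requires_n`` /
    ``requires_s`` constrain heteroatom presence (True: > 0, False: == 0).
    """

    label: str
    hc: tuple[float | None, float | None] = (None, None)
    oc: tuple[float | None, float | None] = (None, None)
    ai: tuple[float | None, float | None] = (None, None)
    dbe_c: tuple[float | None, float | None] = (None, None)
    dbe_h: tuple[float | None, float | None] = (None, None)
    dbe_o: tuple[float | None, float | None] = (None, None)
    c_min: int | None = None
    requires_n: bool | None = None
    requires_s: bool | None = None

    def matches(self, feature: FormulaFeature, ai: float, dbe: float) -> bool:
        def within(x, lohi):
            lo, hi = lohi
            return (lo is None or x >= lo) and (hi is None or x <= hi)

        if not within(feature.hc, self.hc) or not within(feature.oc, self.oc):
            return False
        if not within(ai, self.ai):
            return False
        if not within(dbe / feature.C, self.dbe_c):
            return False
        if not within(dbe / feature.H, self.dbe_h):
            return False
        if self.dbe_o != (None, None):
            if feature.O == 0 or not within(dbe / feature.O, self.dbe_o):
                return False
        if self.c_min is not None and feature.C < self.c_min:
            return False
        if self.requires_n is not None and (feature.N > 0) != self.requires_n:
            return False
        if self.requires_s is not None and (feature.S > 0) != self.requires_s:
            return False
        return True


@dataclass
class ClassRuleset:
    """Ordered compound-class rules; the first match wins, else 'unassigned'."""

    rules: list[ClassRule] = field(default_factory=list)
    ai_modified: bool = True

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("ruleset must contain at least one rule")
        labels = [r.label for r in self.rules]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate class labels in ruleset")


def default_ruleset(ai_modified: bool = True) -> ClassRuleset:
    """Literature-conventional van-Krevelen / AI boundary set, in priority order."""
    rules = [
        ClassRule("black carbon", ai=(0.67, None), c_min=15),
        ClassRule("condensed hydrocarbons", ai=(0.666, None)),
        ClassRule("polyphenols", ai=(0.5, 0.666)),
        ClassRule("sugars", oc=(1.0, None), hc=(1.5, 2.5), requires_n=False),
        ClassRule("carbohydrates", oc=(0.67, 1.2), hc=(1.5, 2.4), requires_n=False),
        ClassRule("protein maya", hc=(1.5, 2.3), oc=(0.2, 0.67), requires_n=True,
                  requires_s=True),
        ClassRule("proteins", hc=(1.5, 2.3), oc=(0.3, 0.67), requires_n=True),
        ClassRule("peptides", hc=(1.5, 2.3), oc=(0.2, 0.67), requires_n=True),
        ClassRule("saturated fatty acids", hc=(1.8, None), oc=(0.0, 0.35),
                  dbe_c=(None, 0.1), requires_n=False),
        ClassRule("lipids", hc=(1.5, 2.5), oc=(0.0, 0.3), requires_n=False),
        ClassRule("unsaturated aliphatic compounds", hc=(1.5, 2.5), oc=(0.0, 0.67)),
        ClassRule("CRAM", dbe_c=(0.30, 0.68), dbe_h=(0.20, 0.95), dbe_o=(0.77, 1.75)),
        ClassRule("lignin", hc=(0.7, 1.5), oc=(0.1, 0.67), ai=(None, 0.5)),
        ClassRule("highly unsaturated compounds", hc=(None, 1.5), ai=(None, 0.5)),
    ]
    return ClassRuleset(rules=rules, ai_modified=ai_modified)


def assign_compound_class(feature: FormulaFeature,
                          ruleset: ClassRuleset | None = None) -> str:
    """First matching rule's label, or 'unassigned'."""
    rs = ruleset or default_ruleset()
    if not feature.formula_assigned:
        raise ValueError("feature has no assigned formula")
    ai = aromaticity_index(feature, modified=rs.ai_modified)
    dbe = double_bond_equivalents(feature)
    for rule in rs.rules:
        if rule.matches(feature, ai, dbe):
            return rule.label
    return "unassigned"


def magnitude_weighted_indices(features: list[FormulaFeature],
                               classified_only: bool = False,
                               ruleset: ClassRuleset | None = None) -> dict[str, float]:
    """Magnitude-weighted mean O/C, H/C and DBE over assigned formulas.

    Each index is Σ(magnitude·index)/Σ(magnitude); by default all assigned
    formulas contribute, optionally only those receiving a compound class.
    """
    feats = [f for f in features if f.formula_assigned]
    if classified_only:
        rs = ruleset or default_ruleset()
        feats = [f for f in feats if assign_compound_class(f, rs) != "unassigned"]
    if not feats:
        raise ValueError("no formula-assigned features")
    w = np.array([f.magnitude for f in feats], float)
    if w.sum() <= 0:
        raise ValueError("total magnitude is zero")
    oc = np.array([f.oc for f in feats])
    hc = np.array([f.hc for f in feats])
    dbe = np.array([double_bond_equivalents(f) for f in feats])
    return {
        "oc_w": float(np.average(oc, weights=w)),
        "hc_w": float(np.average(hc, weights=w)),
        "dbe_w": float(np.average(dbe, weights=w)),
    }


def element_class_counts(features: list[FormulaFeature]) -> dict[str, int]:
    """Feature/formula counts and the disjoint CHO / CHON / CHOS partition.

    CHO: no N, S or P.  CHON: N without S.  CHOS: S without N.  Formulas
    with both N and S fall outside the three bins and are reported as
    ``n_CHONS``.
    """
    assigned = [f for f in features if f.formula_assigned]
    n_cho = sum(1 for f in assigned if f.N == 0 and f.S == 0 and f.P == 0)
    n_chon = sum(1 for f in assigned if f.N > 0 and f.S == 0)
    n_chos = sum(1 for f in assigned if f.S > 0 and f.N == 0)
    n_chons = sum(1 for f in assigned if f.N > 0 and f.S > 0)
    return {
        "n_features": len(features),
        "n_formulas": len(assigned),
        "n_CHO": n_cho,
        "n_CHON": n_chon,
        "n_CHOS": n_chos,
        "n_CHONS": n_chons,
    }


def class_peak_area_fractions(features: list[FormulaFeature],
                              ruleset: ClassRuleset | None = None) -> dict[str, float]:
    """Per-class share of total peak magnitude over classified features."""
    rs = ruleset or default_ruleset()
    sums: dict[str, float] = {}
    for f in features:
        if not f.formula_assigned:
            continue
        label = assign_compound_class(f, rs)
        if label == "unassigned":
            continue
        sums[label] = sums.get(label, 0.0) + f.magnitude
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("no classified features with positive magnitude")
    return {k: v / total for k, v in sums.items()}


def read_feature_table(path) -> list[FormulaFeature]:
    """Read a per-sample feature CSV: mz, rt, magnitude, formula (may be empty)."""
    df = pd.read_csv(path)
    needed = {"mz", "rt", "magnitude", "formula"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        formula = "" if pd.isna(row.formula) else str(row.formula)
        if formula:
            counts = parse_formula(formula)
            out.append(FormulaFeature(mz=row.mz, rt=row.rt, magnitude=row.magnitude,
                                      formula_assigned=True, **counts))
        else:
            out.append(FormulaFeature(mz=row.mz, rt=row.rt, magnitude=row.magnitude))
    return out


def feature_frame(features: list[FormulaFeature],
                  ruleset: ClassRuleset | None = None) -> pd.DataFrame:
    """Tidy per-feature table with DBE, AI and compound class."""
    rs = ruleset or default_ruleset()
    rows = []
    for f in features:
        row = {"mz": f.mz, "rt": f.rt, "magnitude": f.magnitude,
               "formula": formula_string(f) if f.formula_assigned else ""}
        if f.formula_assigned:
            dbe = double_bond_equivalents(f)
            row.update({
                "oc": f.oc, "hc": f.hc, "dbe": dbe,
                "ai": aromaticity_index(f, modified=rs.ai_modified),
                "compound_class": assign_compound_class(f, rs),
                "parity_flag": dbe != int(dbe),  # nitrogen-rule violation
            })
        rows.append(row)
    return pd.DataFrame(rows)
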