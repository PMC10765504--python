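import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from overturnlab import metabolomics as mb
from overturnlab.metabolomics import (
    FormulaFeature,
    aromaticity_index,
    assign_compound_class,
    class_peak_area_fractions,
    default_ruleset,
    double_bond_equivalents,
    element_class_counts,
    feature_from_formula,
    magnitude_weighted_indices,
    parse_formula,
)


class TestParseFormula:
    def test_glucose(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "N": 0, "O": 6, "S": 0, "P": 0}

    def test_implicit_one(self):
        assert parse_formula("CH4") == {"C": 1, "H": 4, "N": 0, "O": 0, "S": 0, "P": 0}

    def test_unknown_element(self):
        with pytest.raises(ValueError):
            parse_formula("X2Y")

    @given(st.tuples(st.integers(1, 40), st.integers(1, 80), st.integers(0, 4),
                     st.integers(0, 20), st.integers(0, 2), st.integers(0, 2)))
    def test_round_trip_with_formatter(self, counts):
        c, h, n, o, s, p = counts
        f = FormulaFeature(C=c, H=h, N=n, O=o, S=s, P=p, formula_assigned=True)
        assert parse_formula(mb.formula_string(f)) == {
            "C": c, "H": h, "N": n, "O": o, "S": s, "P": p}


class TestDbe:
    @pytest.mark.parametrize("formula,dbe", [
        ("C6H12O6", 1.0),   # (2 + 12 − 12)/2
        ("CH4", 0.0),       # saturated
        ("C6H6", 4.0),      # (2 + 12 − 6)/2
        ("C5H9NO4", 2.0),
    ])
    def test_closed_form(self, formula, dbe):
        assert double_bond_equivalents(feature_from_formula(formula)) == dbe

    def test_unassigned_rejected(self):
        with pytest.raises(ValueError):
            double_bond_equivalents(FormulaFeature(magnitude=1.0))


class TestAromaticityIndex:
    def test_benzene(self):
        assert aromaticity_index(feature_from_formula("C6H6")) == pytest.approx(4 / 6)

    def test_negative_numerator_clamped(self):
        assert aromaticity_index(feature_from_formula("C6H12O6")) == 0.0

    def test_nonpositive_denominator_clamped(self):
        # C − O/2 − N − S − P ≤ 0
        assert aromaticity_index(feature_from_formula("C2H6O4S")) == 0.0

    def test_unmodified_variant_weights_full_oxygen(self):
        f = feature_from_formula("C10H8O2")
        assert aromaticity_index(f, modified=False) < aromaticity_index(f, modified=True)


class TestCompoundClasses:
    def test_benzene_is_condensed_hydrocarbon(self):
        assert assign_compound_class(feature_from_formula("C6H6")) == "condensed hydrocarbons"

    def test_glucose_is_sugar(self):
        assert assign_compound_class(feature_from_formula("C6H12O6")) == "sugars"

    def test_pyrene_is_black_carbon(self):
        assert assign_compound_class(feature_from_formula("C16H10")) == "black carbon"

    def test_no_match_is_unassigned(self):
        assert assign_compound_class(feature_from_formula("C5H9NO4")) == "unassigned"

    def test_generator_pool_spans_many_classes(self, noiseless_bundle):
        sample = next(iter(noiseless_bundle.feature_tables))
        feats = noiseless_bundle.feature_tables[sample]
        classes = {assign_compound_class(f) for f in feats if f.formula_assigned}
        assert {"black carbon", "sugars", "CRAM", "lignin",
                "highly unsaturated compounds"} <= classes

    def test_determinism(self, rng):
        rs = default_ruleset()
        for _ in range(50):
            f = FormulaFeature(C=int(rng.integers(1, 30)), H=int(rng.integers(1, 50)),
                               N=int(rng.integers(0, 3)), O=int(rng.integers(0, 15)),
                               S=int(rng.integers(0, 2)), magnitude=1.0,
                               formula_assigned=True)
            assert assign_compound_class(f, rs) == assign_compound_class(f, rs)


class TestWeightedIndices:
    def test_single_feature_identity(self):
        f = feature_from_formula("C6H12O6", magnitude=5.0)
        idx = magnitude_weighted_indices([f])
        assert idx["oc_w"] == pytest.approx(1.0)
        assert idx["hc_w"] == pytest.approx(2.0)
        assert idx["dbe_w"] == pytest.approx(1.0)

    def test_equal_weights_are_plain_mean(self):
        a = feature_from_formula("C10H10O2", magnitude=2.0)  # O/C 0.2
        b = feature_from_formula("C10H10O6", magnitude=2.0)  # O/C 0.6
        assert magnitude_weighted_indices([a, b])["oc_w"] == pytest.approx(0.4)

    def test_three_to_one_weighting(self):
        a = feature_from_formula("C6H10O2", magnitude=3.0)   # DBE 2
        b = feature_from_formula("C8H6O2", magnitude=1.0)    # DBE 6
        assert magnitude_weighted_indices([a, b])["dbe_w"] == pytest.approx(3.0)

    def test_bounded_by_extremes_and_scale_invariant(self, rng):
        feats = [FormulaFeature(C=int(rng.integers(5, 20)), H=int(rng.integers(4, 40)),
                                O=int(rng.integers(0, 10)),
                                magnitude=float(rng.uniform(0.1, 10)),
                                formula_assigned=True) for _ in range(20)]
        idx = magnitude_weighted_indices(feats)
        dbe = [double_bond_equivalents(f) for f in feats]
        assert min(dbe) <= idx["dbe_w"] <= max(dbe)
        scaled = [FormulaFeature(C=f.C, H=f.H, O=f.O, magnitude=f.magnitude * 7.3,
                                 formula_assigned=True) for f in feats]
        idx2 = magnitude_weighted_indices(scaled)
        for k in idx:
            assert idx[k] == pytest.approx(idx2[k])

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValueError):
            magnitude_weighted_indices([feature_from_formula("CH4", magnitude=0.0)])


class TestElementClassCounts:
    def test_partition_by_heteroatoms(self):
        feats = [feature_from_formula(f) for f in ("C6H12O6", "C5H9NO4", "C2H6OS")]
        c = element_class_counts(feats)
        assert (c["n_CHO"], c["n_CHON"], c["n_CHOS"]) == (1, 1, 1)
        assert c["n_formulas"] == 3

    def test_empty_table(self):
        c = element_class_counts([])
        assert all(v == 0 for v in c.values())

    def test_n_and_s_outside_both_bins(self):
        f = feature_from_formula("C5H11NO2S")
        c = element_class_counts([f])
        assert c["n_CHON"] == 0 and c["n_CHOS"] == 0
        assert c["n_CHONS"] == 1 and c["n_formulas"] == 1

    def test_unassigned_counted_in_features_only(self):
        feats = [feature_from_formula("CH4"), FormulaFeature(magnitude=1.0)]
        c = element_class_counts(feats)
        assert c["n_features"] == 2 and c["n_formulas"] == 1


class TestClassFractions:
    def test_single_class(self):
        feats = [feature_from_formula("C6H12O6", magnitude=m) for m in (1.0, 2.0)]
        assert class_peak_area_fractions(feats) == {"sugars": pytest.approx(1.0)}

    def test_equal_split(self):
        feats = [feature_from_formula("C6H12O6", magnitude=3.0),
                 feature_from_formula("C6H6", magnitude=3.0)]
        fr = class_peak_area_fractions(feats)
        assert fr["sugars"] == pytest.approx(0.5)
        assert fr["condensed hydrocarbons"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, noiseless_bundle):
        for feats in noiseless_bundle.feature_tables.values():
            assert sum(class_peak_area_fractions(feats).values()) == pytest.approx(1.0, abs=1e-12)
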