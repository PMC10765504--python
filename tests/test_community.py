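import math

import numpy as np
import pandas as pd
import pytest

from overturnlab.community import (
    AsvTable,
    aggregate_taxa,
    copy_number_adjust,
    diversity_indices,
    filter_low_prevalence,
    rarefy,
)


def _table(counts: dict, taxonomy=None, copy_map=None, n_samples=None):
    df = pd.DataFrame(counts)
    df.index = [f"s{i}" for i in range(len(df))]
    tax = taxonomy or {a: f"Bacteria;P;C;O;F_{a};G_{a}" for a in df.columns}
    return AsvTable(counts=df, taxonomy=tax, copy_map=copy_map or {})


class TestPrevalenceFilter:
    def test_below_threshold_removed(self):
        t = _table({"a": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                    "b": [1] * 10})
        out = filter_low_prevalence(t, min_samples=4)
        assert list(out.counts.columns) == ["b"]

    def test_exactly_four_samples_retained(self):
        t = _table({"a": [2, 3, 4, 5, 0, 0, 0, 0, 0, 0]})
        out = filter_low_prevalence(t, min_samples=4)
        assert list(out.counts.columns) == ["a"]

    def test_all_zero_removed(self):
        t = _table({"a": [0] * 10, "b": [1] * 10})
        out = filter_low_prevalence(t)
        assert list(out.counts.columns) == ["b"]


class TestRarefy:
    def test_exact_depth(self):
        t = _table({"a": [8000], "b": [4000]})
        out = rarefy(t, depth=10_000, seed=1)
        assert out.counts.sum(axis=1).iloc[0] == 10_000

    def test_shallow_sample_dropped(self):
        t = _table({"a": [8000, 5000], "b": [4000, 4000]})
        out = rarefy(t, depth=10_000, seed=1)
        assert list(out.counts.index) == ["s0"]

    def test_seed_reproducible(self):
        t = _table({"a": [8000], "b": [4000], "c": [3000]})
        r1 = rarefy(t, depth=10_000, seed=7)
        r2 = rarefy(t, depth=10_000, seed=7)
        pd.testing.assert_frame_equal(r1.counts, r2.counts)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            rarefy(_table({"a": [100]}), depth=0)

    def test_never_increases_counts(self):
        t = _table({"a": [9000, 11000], "b": [4000, 2000]})
        out = rarefy(t, depth=10_000, seed=3)
        for s in out.counts.index:
            assert (out.counts.loc[s] <= t.counts.loc[s]).all()

    def test_preserves_expected_proportions(self):
        # hypergeometric subsampling is unbiased: mean rarefied proportion
        # stays within 2 SE of the input proportion over 200 seeds
        t = _table({"a": [6000], "b": [4000], "c": [2000]})
        p_in = 6000 / 12000
        depth = 5000
        props = [rarefy(t, depth, seed=s).counts.iloc[0]["a"] / depth
                 for s in range(200)]
        # SE of the mean of 200 hypergeometric draws
        var_one = p_in * (1 - p_in) / depth * (12000 - depth) / (12000 - 1)
        se = math.sqrt(var_one / 200)
        assert abs(np.mean(props) - p_in) < 2 * se


class TestDiversity:
    def test_uniform_four_taxa(self):
        d = diversity_indices([5, 5, 5, 5])
        assert d["shannon"] == pytest.approx(math.log(4))
        assert d["simpson"] == pytest.approx(0.75)

    def test_single_taxon(self):
        d = diversity_indices([10, 0, 0])
        assert d["shannon"] == 0.0
        assert d["simpson"] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(0, 50, size=12)
        counts[0] = 7  # guarantee non-empty
        d = diversity_indices(counts)
        total = counts.sum()
        sh = -sum((c / total) * math.log(c / total) for c in counts if c > 0)
        si = 1 - sum((c / total) ** 2 for c in counts)
        assert d["shannon"] == pytest.approx(sh)
        assert d["simpson"] == pytest.approx(si)

    def test_uniform_maximises_both(self, rng):
        uniform = diversity_indices([10] * 8)
        for _ in range(20):
            other = rng.integers(1, 100, 8)
            d = diversity_indices(other)
            assert d["shannon"] <= uniform["shannon"] + 1e-12
            assert d["simpson"] <= uniform["simpson"] + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            diversity_indices([0, 0])


class TestAggregateTaxa:
    def test_two_families(self):
        t = _table({"a": [60], "b": [40]},
                   taxonomy={"a": "Bacteria;P;C;O;F1;G1", "b": "Bacteria;P;C;O;F2;G2"})
        rel = aggregate_taxa(t, "family", other_threshold=0.0)
        assert rel.loc["s0", "F1"] == pytest.approx(0.6)
        assert rel.loc["s0", "F2"] == pytest.approx(0.4)

    def test_minor_family_pooled_into_other(self):
        t = _table({"a": [995], "b": [5]},
                   taxonomy={"a": "Bacteria;P;C;O;F1;G1", "b": "Bacteria;P;C;O;F2;G2"})
        rel = aggregate_taxa(t, "family", other_threshold=0.01)
        assert "F2" not in rel.columns
        assert rel.loc["s0", "other"] == pytest.approx(0.005)

    def test_rows_sum_to_one(self, rng):
        counts = {f"a{i}": rng.integers(0, 100, 6) + (1 if i == 0 else 0)
                  for i in range(10)}
        t = _table(counts)
        rel = aggregate_taxa(t, "family")
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_missing_rank_errors(self):
        t = _table({"a": [5]}, taxonomy={"a": "Bacteria"})
        with pytest.raises(ValueError, match="family"):
            aggregate_taxa(t, "family")


class TestCopyNumberAdjust:
    def test_three_copies_divides_75_to_25(self):
        out = copy_number_adjust({"Chlorobiaceae": 75.0}, {"Chlorobiaceae": 3})
        assert out["Chlorobiaceae"] == pytest.approx(25.0)

    def test_renormalized_variant(self):
        out = copy_number_adjust({"Chlorobiaceae": 75.0, "rest": 25.0},
                                 {"Chlorobiaceae": 3}, renormalize=True)
        assert out["Chlorobiaceae"] == pytest.approx(50.0)
        assert out["rest"] == pytest.approx(50.0)

    def test_unit_copies_identity(self):
        fr = {"F1": 30.0, "F2": 70.0}
        assert copy_number_adjust(fr, {}) == pytest.approx(fr)

    def test_copy_below_one_rejected(self):
        with pytest.raises(ValueError):
            copy_number_adjust({"F1": 10.0}, {"F1": 0.5})

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            copy_number_adjust({"F1": 120.0}, {})


class TestGeneratedCommunity:
    def test_deep_inoculum_dominated_by_high_copy_taxon(self, noiseless_bundle):
        t = noiseless_bundle.asv_table
        rel = aggregate_taxa(t, "family", other_threshold=0.0)
        day0 = rel.loc["D/S|E|day0"]
        chl = day0.get("Chlorobiaceae", 0.0)
        assert 0.70 < chl < 0.80  # configured at 75% before multinomial noise
        assert t.copy_map["Chlorobiaceae"] == 3

    def test_libraries_exceed_rarefaction_depth(self, noiseless_bundle):
        totals = noiseless_bundle.asv_table.counts.sum(axis=1)
        assert (totals >= 10_000).all()

    def test_filter_then_rarefy_never_increases(self, noiseless_bundle):
        t = noiseless_bundle.asv_table
        out = rarefy(filter_low_prevalence(t, 4), 10_000, seed=0)
        for s in out.counts.index:
            common = out.counts.columns
            assert (out.counts.loc[s, common] <= t.counts.loc[s, common]).all()
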