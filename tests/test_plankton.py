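import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from brackish.core_io import ValidationError
from brackish.plankton import (ChamberCount, PigmentExtract, cell_density,
                               chlorophyll_a, composition, simpson,
                               station_median)
from conftest import make_table


class TestChlorophyll:
    def test_blank_is_zero(self):
        e = PigmentExtract(0, 0, 0, 0, extract_volume_ml=10,
                           filtered_volume_l=1)
        assert chlorophyll_a(e) == 0.0

    def test_trichromatic_plugin(self):
        e = PigmentExtract(a663=0.1, a645=0.0, a630=0.0, a750=0.0,
                           extract_volume_ml=10, filtered_volume_l=1,
                           path_length_cm=1)
        assert chlorophyll_a(e) == pytest.approx(11.64)

    def test_turbidity_fully_subtracted(self):
        e = PigmentExtract(0.05, 0.05, 0.05, 0.05, extract_volume_ml=10,
                           filtered_volume_l=1)
        assert chlorophyll_a(e) == pytest.approx(0.0)

    def test_negative_floored_with_warning(self):
        e = PigmentExtract(a663=0.0, a645=0.2, a630=0.0, a750=0.0,
                           extract_volume_ml=10, filtered_volume_l=1)
        with pytest.warns(UserWarning):
            assert chlorophyll_a(e) == 0.0

    def test_bad_volume_rejected(self):
        with pytest.raises(ValidationError):
            PigmentExtract(0.1, 0, 0, 0, extract_volume_ml=10,
                           filtered_volume_l=0)


class TestCellDensity:
    def test_zero_cells(self):
        assert cell_density(ChamberCount(0, 10, 0.001, 100)) == 0.0

    def test_dimensional_arithmetic(self):
        density = cell_density(ChamberCount(
            cells_counted=100, fields_counted=10, field_volume_ml=0.001,
            concentration_factor=100))
        assert density == pytest.approx(1.0e5)

    def test_zero_fields_rejected(self):
        with pytest.raises(ValidationError):
            ChamberCount(10, 0, 0.001)


class TestComposition:
    def test_single_phylum_pool(self):
        t = make_table({"Euglena": ("Euglenophyta", 7)})
        assert composition([t]) == {"Euglenophyta": 100.0}

    def test_table3_style_renormalisation(self):
        t = make_table({
            "Spirogyra": ("Chlorophyta", 36), "Coscinodiscus": ("Bacillariophyta", 27),
            "Microcystis": ("Cyanobacteria", 14), "Euglena": ("Euglenophyta", 4),
            "Ceratium": ("Miozoa", 4)})
        pct = composition([t])
        assert pct["Chlorophyta"] == pytest.approx(42.4, abs=0.05)
        assert pct["Bacillariophyta"] == pytest.approx(31.8, abs=0.05)
        assert pct["Cyanobacteria"] == pytest.approx(16.5, abs=0.05)
        assert pct["Euglenophyta"] == pytest.approx(4.7, abs=0.05)
        assert pct["Miozoa"] == pytest.approx(4.7, abs=0.05)

    def test_two_equal_phyla(self):
        t = make_table({"A": ("Chlorophyta", 5), "B": ("Bacillariophyta", 5)})
        assert composition([t]) == {"Chlorophyta": 50.0, "Bacillariophyta": 50.0}

    def test_zero_total_rejected(self):
        t = make_table({"A": ("Chlorophyta", 0)})
        with pytest.raises(ValidationError):
            composition([t])

    def test_mixed_sources_rejected(self):
        a = make_table({"A": ("Chlorophyta", 5)})
        b = make_table({"A": ("Chlorophyta", 5)}, source="gut",
                       sample_id="g", fish_length_cm=20)
        with pytest.raises(ValidationError):
            composition([a, b])

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=6))
    def test_sums_to_100(self, counts):
        t = make_table({f"G{i}": ("Chlorophyta" if i % 2 else "Miozoa", c)
                        for i, c in enumerate(counts)})
        assert sum(composition([t]).values()) == pytest.approx(100.0)


def simpson_pair_oracle(counts):
    """P(two individuals drawn without replacement are conspecific),
    enumerated over every pair of individuals."""
    individuals = [i for i, n in enumerate(counts) for _ in range(n)]
    pairs = list(itertools.combinations(individuals, 2))
    return sum(1 for a, b in pairs if a == b) / len(pairs)


class TestSimpson:
    def test_monoculture(self):
        res = simpson(make_table({"A": ("Chlorophyta", 10)}))
        assert res.d == 1.0
        assert res.reciprocal == 1.0

    def test_all_singletons(self):
        res = simpson(make_table({f"G{i}": ("Chlorophyta", 1) for i in range(5)}))
        assert res.d == 0.0
        assert res.reciprocal is None

    def test_hand_evaluation(self):
        res = simpson(make_table({"A": ("Chlorophyta", 5), "B": ("Miozoa", 5)}))
        assert res.d == pytest.approx(40 / 90)
        assert res.reciprocal == pytest.approx(2.25)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValidationError):
            simpson(make_table({"A": ("Chlorophyta", 1)}))

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 10, size=rng.integers(2, 6))
            if counts.sum() < 2:
                continue
            t = make_table({f"G{i}": ("Chlorophyta", int(c))
                            for i, c in enumerate(counts)})
            assert simpson(t).d == pytest.approx(
                simpson_pair_oracle(counts.tolist()))

    @given(st.lists(st.integers(0, 20), min_size=2, max_size=8)
           .filter(lambda c: sum(c) >= 2))
    def test_invariant_to_zero_rows_and_permutation(self, counts):
        t1 = make_table({f"G{i}": ("Chlorophyta", c) for i, c in enumerate(counts)})
        nonzero = [c for c in counts if c > 0] or counts
        t2 = make_table({f"H{i}": ("Miozoa", c)
                         for i, c in enumerate(sorted(nonzero, reverse=True))})
        if sum(nonzero) >= 2:
            assert simpson(t1).d == pytest.approx(simpson(t2).d)


class TestStationMedian:
    def test_dry_d_reference_stations(self):
        assert station_median([0.17, 0.13, 0.16, 0.37, 0.14]) == pytest.approx(0.16)

    def test_wet_reciprocal_reference_stations(self):
        assert station_median([5.63, 7.75, 3.53, 5.21, 5.12]) == pytest.approx(5.21)

    def test_even_n_convention(self):
        assert station_median([1, 2, 3, 4]) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            station_median([])

    def test_density_ranges_consistent_with_chamber_formula(self):
        # generator default totals interpreted through chamber geometry
        lo = cell_density(ChamberCount(103, 10, 0.001, 1000))
        hi = cell_density(ChamberCount(2151, 10, 0.001, 1000))
        assert lo == pytest.approx(10.3e3)
        assert hi == pytest.approx(215.1e3)
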