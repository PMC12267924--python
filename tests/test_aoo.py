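import numpy as np
import pandas as pd
import pytest

from paradoxflora.aoo import (NATIVE_OK, NATIVE_THREATENED, NATURALIZED,
                              cell_indices, clean_occurrences, occupied_cells,
                              partition_aoo, partition_aoo_all,
                              route_occurrences)
from paradoxflora.config import GridSpec
from paradoxflora.errors import InputError

COUNTRIES = pd.DataFrame([
    {"code": "AA", "lon_min": 0.0, "lat_min": 0.0, "lon_max": 10.0, "lat_max": 10.0},
    {"code": "AB", "lon_min": 10.0, "lat_min": 0.0, "lon_max": 20.0, "lat_max": 10.0},
])


def occ(rows):
    return pd.DataFrame(rows, columns=["scientificName", "decimalLongitude",
                                       "decimalLatitude", "countryCode",
                                       "establishmentMeans"])


class TestCleanOccurrences:
    def test_missing_columns_is_input_error(self):
        with pytest.raises(InputError):
            clean_occurrences(pd.DataFrame({"scientificName": []}), COUNTRIES)

    def test_out_of_range_latitude_dropped(self):
        df = occ([("A sp", 5.0, 91.0, "AA", "native"),
                  ("A sp", 5.0, 5.0, "AA", "native")])
        clean, drops = clean_occurrences(df, COUNTRIES)
        assert len(clean) == 1 and drops["coordinate_range"] == 1

    def test_exact_duplicates_collapse(self):
        df = occ([("A sp", 5.0, 5.0, "AA", "native")] * 2)
        clean, drops = clean_occurrences(df, COUNTRIES)
        assert len(clean) == 1 and drops["duplicate"] == 1

    def test_injected_zero_zero_points(self, rng):
        good = [("A sp", float(x), float(y), "AA", "native")
                for x, y in rng.uniform(1, 9, size=(950, 2))]
        bad = [("A sp", 0.0, 0.0, "AA", "native")] * 50
        clean, drops = clean_occurrences(occ(good + bad), COUNTRIES)
        assert drops["zero_zero"] == 50
        assert len(clean) == len(set((r[1], r[2]) for r in good))

    def test_point_outside_stated_country_dropped(self):
        df = occ([("A sp", 15.0, 5.0, "AA", "native"),    # inside AB, not AA
                  ("A sp", 10.05, 5.0, "AA", "native")])  # within 0.1 deg slack
        clean, drops = clean_occurrences(df, COUNTRIES)
        assert drops["outside_country"] == 1 and len(clean) == 1

    def test_unknown_country_dropped(self):
        df = occ([("A sp", 5.0, 5.0, "ZZ", "native")])
        clean, drops = clean_occurrences(df, COUNTRIES)
        assert drops["unknown_country"] == 1 and len(clean) == 0

    def test_non_numeric_coordinates_dropped(self):
        df = occ([("A sp", "not-a-number", 5.0, "AA", "native"),
                  ("A sp", 5.0, 5.0, "AA", "native")])
        clean, drops = clean_occurrences(df, COUNTRIES)
        assert drops["missing_coordinates"] == 1 and len(clean) == 1


class TestOccupiedCells:
    def test_empty_input(self):
        assert occupied_cells(occ([])) == set()

    def test_points_in_one_cell_collapse(self):
        g = GridSpec()
        # default cell spans lon [-0.1, 0.6) x lat [-0.4, 0.3)
        rows = occ([("A sp", 0.1, 0.0, "AA", "native"),
                    ("A sp", 0.2, 0.1, "AA", "native"),
                    ("A sp", 0.3, 0.2, "AA", "native")])
        assert len(occupied_cells(rows, g)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_point_in_cell_search(self, seed):
        """Vectorized assignment equals an exhaustive double loop over a
        small window of grid cells."""
        g = GridSpec(cell_size_deg=1.0)
        r = np.random.default_rng(seed)
        pts = r.uniform([0, 0], [18, 18], size=(60, 2))  # 18x18-cell window
        rows = occ([("A sp", x, y, "AA", "native") for x, y in pts])
        fast = occupied_cells(rows, g)
        slow = set()
        for ix in range(175, 205):
            for iy in range(85, 115):
                x0 = g.origin[0] + ix * g.cell_size_deg
                y0 = g.origin[1] + iy * g.cell_size_deg
                if any((x0 <= x < x0 + 1) and (y0 <= y < y0 + 1) for x, y in pts):
                    slow.add((ix, iy))
        assert fast == slow

    def test_equatorial_cell_area_near_6000(self):
        g = GridSpec()
        iy = int((0.35 - g.origin[1]) / g.cell_size_deg)  # cell centered near lat 0
        area = float(g.cell_area_km2(iy))
        assert 5800 <= area <= 6200


class TestPartitionAoo:
    STATUSES = pd.DataFrame([
        ("A sp", "AA", "EN"), ("A sp", "AB", "LC")],
        columns=["speciesName", "countryCode", "category"])
    NATS = pd.DataFrame([("A sp", "AB")], columns=["speciesName", "countryCode"])

    def test_all_native_in_threatened_country(self):
        rows = occ([("A sp", 1.0, 1.0, "AA", "native"),
                    ("A sp", 5.0, 5.0, "AA", "native")])
        st = self.STATUSES[self.STATUSES.countryCode == "AA"]
        part = partition_aoo("A sp", rows, st, self.NATS.iloc[:0])
        assert part.pct_native_threatened == 100.0

    def test_no_native_in_threatened_country(self):
        rows = occ([("A sp", 11.0, 1.0, "AB", "native")])
        st = pd.DataFrame([("A sp", "AB", "LC")],
                          columns=["speciesName", "countryCode", "category"])
        part = partition_aoo("A sp", rows, st, self.NATS.iloc[:0])
        assert part.pct_native_threatened == 0.0

    def test_equal_area_cells_give_exact_quarter(self):
        # 4 threatened + 12 ok cells, all in the same grid row -> 25.0%
        g = GridSpec(cell_size_deg=1.0)
        thr = [("A sp", 0.5 + i, 0.5, "AA", "native") for i in range(4)]
        ok = [("A sp", 10.5 + i, 0.5, "AB", "native") for i in range(12)]
        st = pd.DataFrame([("A sp", "AA", "CR"), ("A sp", "AB", "LC")],
                          columns=["speciesName", "countryCode", "category"])
        part = partition_aoo("A sp", occ(thr + ok), st, self.NATS.iloc[:0], grid=g)
        assert len(part.cells_native_threatened) == 4
        assert len(part.cells_native_ok) == 12
        assert part.pct_native_threatened == pytest.approx(25.0)

    def test_unresolved_occurrences_are_excluded(self):
        rows = occ([("A sp", 1.0, 1.0, "AA", "introduced"),  # no such role
                    ("A sp", 11.0, 1.0, "AB", "introduced")])
        part = partition_aoo("A sp", rows, self.STATUSES, self.NATS)
        assert part.n_unresolved == 1
        assert len(part.cells_naturalized) == 1

    def test_zero_native_occurrences_leave_pct_undefined(self):
        rows = occ([("A sp", 11.0, 1.0, "AB", "introduced")])
        part = partition_aoo("A sp", rows, self.STATUSES, self.NATS)
        assert part.pct_native_threatened is None

    def test_monotone_in_occurrences(self):
        base = [("A sp", 1.0, 1.0, "AA", "native")]
        extra = base + [("A sp", 5.0, 5.0, "AA", "native")]
        p0 = partition_aoo("A sp", occ(base), self.STATUSES, self.NATS)
        p1 = partition_aoo("A sp", occ(extra), self.STATUSES, self.NATS)
        assert p1.aoo_native_threatened >= p0.aoo_native_threatened

    def test_row_order_never_matters(self, rng):
        rows = occ([("A sp", float(x), float(y), "AA", "native")
                    for x, y in rng.uniform(0.5, 9.5, size=(40, 2))])
        p0 = partition_aoo("A sp", rows, self.STATUSES, self.NATS)
        p1 = partition_aoo("A sp", rows.sample(frac=1, random_state=0),
                           self.STATUSES, self.NATS)
        assert p0.cells_native_threatened == p1.cells_native_threatened
        assert p0.aoo_native_threatened == p1.aoo_native_threatened

    def test_straddling_cell_counts_in_both_native_partitions(self):
        # same grid cell reached from a threatened and a non-threatened
        # country (cell spans the border at lon 10 with a 20-degree grid)
        g = GridSpec(cell_size_deg=20.0)
        rows = occ([("A sp", 9.9, 5.0, "AA", "native"),
                    ("A sp", 10.1, 5.0, "AB", "native")])
        part = partition_aoo("A sp", rows, self.STATUSES, self.NATS.iloc[:0], grid=g)
        assert part.cells_native_threatened == part.cells_native_ok
        assert part.aoo_native_threatened + part.aoo_native_ok \
            == pytest.approx(2 * part.aoo_native_threatened)

    def test_batch_table_matches_single_species_path(self, rng):
        rows = occ([("A sp", float(x), float(y), "AA", "native")
                    for x, y in rng.uniform(0.5, 9.5, size=(30, 2))]
                   + [("A sp", float(x), float(y), "AB", "introduced")
                      for x, y in rng.uniform([10.5, 0.5], [19.5, 9.5], size=(10, 2))])
        single = partition_aoo("A sp", rows, self.STATUSES, self.NATS)
        batch = partition_aoo_all(rows, self.STATUSES, self.NATS)
        row = batch.set_index("acceptedName").loc["A sp"]
        assert row["aooNativeThreatened"] == pytest.approx(single.aoo_native_threatened)
        assert row["aooNaturalized"] == pytest.approx(single.aoo_naturalized)
        assert row["nCellsNativeThreatened"] == len(single.cells_native_threatened)
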