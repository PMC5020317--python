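"""Cell aggregation, correlations and hotspot rankings."""

import numpy as np
import pandas as pd
import pytest

from citrec.spatial import (
    aggregate_cells,
    cells_to_geojson,
    cross_correlation,
    hotspots,
    taxon_surface,
)


def _records(rows):
    """rows: (recorder_id, monad, informal_group)."""
    return pd.DataFrame(
        {
            "recorder_id": [r[0] for r in rows],
            "monad": [r[1] for r in rows],
            "informal_group": [r[2] for r in rows],
            "precision_m": 1000,
        }
    )


def _oracle_cells(rows):
    """Nested-loop tally, no pandas groupby."""
    out = {}
    for rid, monad, group in rows:
        cell = out.setdefault(monad, {"recs": 0, "vols": set(), "groups": set()})
        cell["recs"] += 1
        cell["vols"].add(rid)
        cell["groups"].add(group)
    return {
        m: (c["recs"], len(c["vols"]), len(c["groups"]), c["recs"] / len(c["vols"]))
        for m, c in out.items()
    }


class TestAggregation:
    def test_productivity_example(self):
        rows = [(f"v{i % 4}", "TQ3280", "bird") for i in range(10)]
        cells = aggregate_cells(_records(rows))
        assert cells.loc["TQ3280", "productivity"] == pytest.approx(2.5)

    def test_informal_group_count(self):
        rows = [("v0", "TQ3280", g) for g in ("bird", "moth", "beetle")]
        cells = aggregate_cells(_records(rows))
        assert cells.loc["TQ3280", "n_informal_groups"] == 3

    def test_matches_nested_loop_oracle_on_random_fixture(self):
        rng = np.random.default_rng(0)
        monads = [f"TQ{c:02d}{r:02d}" for c in range(5) for r in range(5)]
        rows = [
            (
                f"v{rng.integers(0, 20)}",
                monads[rng.integers(0, len(monads))],
                ["bird", "moth", "beetle"][rng.integers(0, 3)],
            )
            for _ in range(500)
        ]
        cells = aggregate_cells(_records(rows))
        oracle = _oracle_cells(rows)
        assert set(cells.index) == set(oracle)
        for m, (recs, vols, groups, prod) in oracle.items():
            row = cells.loc[m]
            assert row["n_records"] == recs
            assert row["n_volunteers"] == vols
            assert row["n_informal_groups"] == groups
            assert row["productivity"] == pytest.approx(prod)
        # accounting identities
        assert cells["n_records"].sum() == len(rows)
        assert np.allclose(
            cells["productivity"] * cells["n_volunteers"], cells["n_records"]
        )
        # per-group columns partition the records in every cell
        group_cols = [c for c in cells.columns if c.startswith("records_")]
        assert np.allclose(cells[group_cols].sum(axis=1), cells["n_records"])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"v{i % 7}", f"TQ0{i % 3}00", "bird") for i in range(40)
        ]
        a = aggregate_cells(_records(rows))
        b = aggregate_cells(_records(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_coarse_records_rejected(self):
        df = _records([("v0", "TQ3280", "bird")])
        df["precision_m"] = 10_000
        with pytest.raises(ValueError, match="coarser than 1 km"):
            aggregate_cells(df)


class TestCrossCorrelation:
    def _cells(self, values, monads=None):
        monads = monads or [f"TQ00{i:02d}" for i in range(len(values))]
        return pd.DataFrame({"productivity": values}, index=pd.Index(monads, name="monad"))

    def test_self_correlation_is_one(self):
        a = self._cells([1.0, 3.0, 2.0, 5.0])
        rho, n, p = cross_correlation(a, a)
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_rank_reversal_is_minus_one(self):
        a = self._cells([1.0, 2.0, 3.0, 4.0])
        b = self._cells([9.0, 7.0, 5.0, 3.0])
        rho, _, _ = cross_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_union_pairing_fills_absent_cells_with_zero(self):
        a = self._cells([1.0, 2.0, 3.0], ["TQ0000", "TQ0001", "TQ0002"])
        b = self._cells([5.0, 1.0], ["TQ0000", "TQ0003"])
        _, n_u, _ = cross_correlation(a, b, pairing="union")
        assert n_u == 4
        with pytest.raises(ValueError, match="paired cells"):
            cross_correlation(a, b, pairing="intersection")

    def test_matches_bruteforce_rank_formula(self):
        rng = np.random.default_rng(2)
        x = rng.permutation(15).astype(float) + 1
        y = rng.permutation(15).astype(float) + 1
        a, b = self._cells(x), self._cells(y)
        rho, n, _ = cross_correlation(a, b)
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        want = 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))
        assert rho == pytest.approx(want)

    def test_too_few_pairs(self):
        a = self._cells([1.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            cross_correlation(a, a)


class TestHotspots:
    def test_dominant_cell_ranks_first(self):
        rows = [("v0", "TQ0000", "bird")] * 50 + [
            ("v1", f"TQ00{i:02d}", "bird") for i in range(1, 6)
        ]
        cells = aggregate_cells(_records(rows))
        top = hotspots(cells, "n_records", top_n=3)
        assert top.loc[0, "monad"] == "TQ0000"

    def test_ties_broken_by_monad_id(self):
        rows = [("v0", "TQ0002", "bird"), ("v1", "TQ0001", "bird")]
        cells = aggregate_cells(_records(rows))
        top = hotspots(cells, "n_records", top_n=2)
        assert top["monad"].tolist() == ["TQ0001", "TQ0002"]

    def test_attribute_join(self):
        rows = [("v0", "TQ0000", "bird"), ("v1", "TQ0001", "bird")]
        cells = aggregate_cells(_records(rows))
        attrs = pd.DataFrame(
            {"bluespace": [True]}, index=pd.Index(["TQ0000"], name="monad")
        )
        top = hotspots(cells, "n_records", top_n=2, attributes=attrs)
        assert top.set_index("monad").loc["TQ0000", "bluespace"] == True

    def test_invalid_top_n(self):
        cells = aggregate_cells(_records([("v0", "TQ0000", "bird")]))
        with pytest.raises(ValueError):
            hotspots(cells, "n_records", top_n=0)


class TestTaxonSurface:
    def test_surfaces_partition_total_records(self):
        rng = np.random.default_rng(3)
        rows = [
            (
                f"v{rng.integers(0, 5)}",
                f"TQ000{rng.integers(0, 4)}",
                ["bird", "moth"][rng.integers(0, 2)],
            )
            for _ in range(100)
        ]
        cells = aggregate_cells(_records(rows))
        total = sum(
            taxon_surface(_records(rows), g)["n_records"].sum()
            for g in ("bird", "moth")
        )
        assert total == cells["n_records"].sum()

    def test_unknown_group_raises(self):
        with pytest.raises(KeyError):
            taxon_surface(_records([("v0", "TQ0000", "bird")]), "fish")


class TestGeoJSON:
    def test_square_polygons_with_properties(self, tmp_path):
        cells = aggregate_cells(_records([("v0", "TQ3280", "bird")]))
        doc = cells_to_geojson(cells[["n_records"]], tmp_path / "cells.geojson")
        feat = doc["features"][0]
        ring = feat["geometry"]["coordinates"][0]
        assert ring[0] == [532000, 180000]
        assert ring[2] == [533000, 181000]
        assert feat["properties"]["n_records"] == 1
        assert (tmp_path / "cells.geojson").exists()
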