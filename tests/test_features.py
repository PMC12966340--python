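"""Feature formulas, standardisation, and the species-data table."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

import prevcommon as pc
from prevcommon.features import FEATURES
from prevcommon.occurrence_io import polygon_cells

TINY_EXPECTED = {"A": 2.0, "IntraDs": 2.0, "InterDs": 0.5,
                 "E": 0.2, "F": 0.2, "HF": 0.1}


def naive_features(rs, species, cfg):
    """Independent direct evaluation of each feature formula (loop oracle)."""
    recs = [r for r in rs.records.itertuples() if r.species == species]
    n_ds = len(cfg.datasets)
    n_units = cfg.n_time_units
    if not recs:
        return {f: 0.0 for f in FEATURES}
    cells = {ds: polygon_cells(poly, cfg.cell_resolution)
             for ds, poly in cfg.datasets}
    by_ds = {}
    for r in recs:
        by_ds.setdefault(r.dataset, []).append(r)
    a = e = f_ = hf = 0.0
    for ds, rows in by_ds.items():
        a += sum(r.count for r in rows) / len(rows)
        e += len({(r.cell_x, r.cell_y) for r in rows}) / cells[ds]
        per_year = {}
        for r in rows:
            per_year[r.time_unit] = per_year.get(r.time_unit, 0) + 1
        f_ += len(per_year) / n_units
        hf += sum(1 for v in per_year.values() if v >= cfg.hf_threshold) / n_units
    n_occ = len(by_ds)
    return {"A": a, "IntraDs": len(recs) / n_ds, "InterDs": n_occ / n_ds,
            "E": e / n_occ, "F": f_ / n_occ, "HF": hf / n_occ}


class TestComputeFeatures:
    def test_tiny_fixture_matches_hand_evaluation(self, tiny_study):
        cfg = tiny_study["config"]
        rs = pc.assign_context(pc.deduplicate(tiny_study["records"]), cfg)
        fv = pc.compute_features(rs, tiny_study["species"], cfg)
        assert fv == pytest.approx(TINY_EXPECTED)

    def test_species_with_no_records_gets_zero_vector(self, tiny_study):
        cfg = tiny_study["config"]
        rs = pc.assign_context(tiny_study["records"], cfg)
        assert pc.compute_features(rs, "Nullius species", cfg) == \
            {f: 0.0 for f in FEATURES}

    def test_saturated_species_has_unit_fractions(self):
        # present in every dataset, every cell, every year with >= Thr records
        cfg = pc.StudyConfig(
            time_start=dt.date(2016, 1, 1), time_end=dt.date(2017, 12, 31),
            cell_resolution=0.01, hf_threshold=2,
            datasets=[("d1", box(0, 0, 0.02, 0.01)),
                      ("d2", box(0.1, 0, 0.12, 0.01))])
        rows = []
        for dsx in (0.0, 0.1):
            for cx in (0.005, 0.015):
                for year in (2016, 2017):
                    for rep in (1, 15):
                        rows.append(("Ubiquitus", dsx + cx, 0.005,
                                     dt.date(year, 1, rep), 1, ""))
        rs = pc.RecordSet(pd.DataFrame(rows, columns=[
            "species", "lon", "lat", "date", "count", "dataset"]))
        rs = pc.assign_context(rs, cfg)
        fv = pc.compute_features(rs, "Ubiquitus", cfg)
        assert fv["InterDs"] == fv["E"] == fv["F"] == fv["HF"] == 1.0

    def test_matches_naive_oracle_on_random_record_sets(self, tiny_study):
        # property check: vectorised implementation == direct formula loops
        cfg = tiny_study["config"]
        rng = np.random.default_rng(7)
        minx = np.array([0.0, 0.2])
        for trial in range(100):
            n = rng.integers(1, 50)
            ds = rng.integers(0, 2, n)
            df = pd.DataFrame({
                "species": rng.choice(["X", "Y"], n),
                "lon": minx[ds] + rng.random(n) * 0.1,
                "lat": rng.random(n) * 0.01,
                "date": [dt.date(int(y), int(m), int(d)) for y, m, d in zip(
                    rng.integers(2016, 2026, n), rng.integers(1, 13, n),
                    rng.integers(1, 29, n))],
                "count": rng.integers(1, 20, n),
                "dataset": "",
            })
            rs = pc.assign_context(pc.RecordSet(df), cfg)
            for sp in ("X", "Y"):
                got = pc.compute_features(rs, sp, cfg)
                want = naive_features(rs, sp, cfg)
                assert got == pytest.approx(want), f"trial {trial} species {sp}"

    def test_hf_never_exceeds_f_and_is_monotone_in_threshold(self, default_sim,
                                                             default_table):
        t = default_table.table
        assert (t["HF"] <= t["F"] + 1e-12).all()
        import dataclasses
        stricter = dataclasses.replace(default_sim["config"],
                                       hf_threshold=default_sim["config"].hf_threshold + 3)
        sp = t["species"].iloc[0]
        lo = pc.compute_features(default_sim["records"], sp, stricter)
        hi = pc.compute_features(default_sim["records"], sp, default_sim["config"])
        assert lo["HF"] <= hi["HF"] + 1e-12

    def test_feature_values_invariant_to_record_order(self, tiny_study):
        cfg = tiny_study["config"]
        rs = pc.assign_context(tiny_study["records"], cfg)
        shuffled = pc.RecordSet(
            rs.records.sample(frac=1, random_state=0).reset_index(drop=True))
        assert pc.compute_features(rs, tiny_study["species"], cfg) == \
            pc.compute_features(shuffled, tiny_study["species"], cfg)

    def test_adding_empty_dataset_only_dilutes_dataset_fractions(self, tiny_study):
        import dataclasses
        cfg = tiny_study["config"]
        rs = pc.assign_context(tiny_study["records"], cfg)
        wider = dataclasses.replace(
            cfg, datasets=cfg.datasets + [("empty", box(0.5, 0, 0.6, 0.01))])
        base = pc.compute_features(rs, tiny_study["species"], cfg)
        more = pc.compute_features(rs, tiny_study["species"], wider)
        assert more["IntraDs"] < base["IntraDs"]
        assert more["InterDs"] < base["InterDs"]
        for f in ("A", "E", "F", "HF"):
            assert more[f] == pytest.approx(base[f])


class TestStandardize:
    def _table(self, values):
        return pc.SpeciesDataTable(pd.DataFrame({
            "species": [f"s{i}" for i in range(len(values))],
            **{f: values if f == "A" else list(np.ones(len(values)))
               for f in FEATURES}}))

    def test_z_scores_use_sample_standard_deviation(self):
        out = pc.standardize(self._table([1.0, 2.0, 3.0]))
        assert list(out.table["z_A"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zeros(self):
        out = pc.standardize(self._table([5.0, 5.0, 5.0]))
        assert list(out.table["z_A"]) == [0.0, 0.0, 0.0]
        assert list(out.table["z_E"]) == [0.0, 0.0, 0.0]

    def test_idempotent_on_the_z_columns(self):
        once = pc.standardize(self._table([1.0, 4.0, 7.0, 9.0]))
        twice = pc.standardize(once)
        np.testing.assert_allclose(once.table["z_A"], twice.table["z_A"])

    def test_single_species_is_an_error(self):
        with pytest.raises(ValueError):
            pc.standardize(self._table([1.0]))


class TestBuildSpeciesTable:
    def test_row_order_follows_species_list(self, tiny_study):
        cfg = tiny_study["config"]
        rs = pc.assign_context(tiny_study["records"], cfg)
        table = pc.build_species_table(
            rs, ["Zzz absent", tiny_study["species"]], cfg)
        assert table.species == ["Zzz absent", tiny_study["species"]]
        assert table.table.iloc[0][list(FEATURES)].tolist() == [0.0] * 6

    def test_duplicate_species_names_rejected(self, tiny_study):
        with pytest.raises(ValueError):
            pc.build_species_table(tiny_study["records"], ["A", "A"],
                                   tiny_study["config"])

    def test_default_fixture_has_one_row_per_species(self, default_table):
        assert len(default_table.table) == 150
        assert default_table.matrix().shape == (150, 6)

    def test_csv_round_trip(self, default_table, tmp_path):
        p = tmp_path / "species_data.csv"
        default_table.to_csv(p)
        back = pc.SpeciesDataTable.from_csv(p)
        np.testing.assert_allclose(back.matrix(), default_table.matrix())
        assert back.species == default_table.species
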