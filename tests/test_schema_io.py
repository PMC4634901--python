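"""Schema reading, validation, round-trips and derived-table persistence."""
import sqlite3
from pathlib import Path

import pandas as pd
import pytest

import trackqc as tq
from trackqc.schema_io import SchemaError, IntegrityError


def write_raw_sqlite(path, images, objects, relationships, table_names=None):
    names = {"image": "image", "object": "object", "relationship": "relationship"}
    names.update(table_names or {})
    with sqlite3.connect(path) as con:
        images.to_sql(names["image"], con, index=False)
        objects.to_sql(names["object"], con, index=False)
        relationships.to_sql(names["relationship"], con, index=False)


class TestReadDataset:
    def test_toy_counts(self, toy_dataset, tmp_path):
        db = tmp_path / "toy.sqlite"
        write_raw_sqlite(db, toy_dataset.images, toy_dataset.objects, toy_dataset.relationships)
        ds = tq.read_dataset(db, "sqlite")
        assert len(ds.images) == 3
        assert len(ds.objects) == 6
        assert len(ds.relationships) == 4
        assert ds.feature_names == ["area"]

    def test_cellprofiler_style_column_aliases(self, toy_dataset, tmp_path):
        objects = toy_dataset.objects.rename(
            columns={"image_index": "ImageNumber", "object_index": "ObjectNumber",
                     "x": "Nuclei_Location_Center_X", "y": "Nuclei_Location_Center_Y"}
        )
        images = toy_dataset.images.rename(columns={"image_index": "ImageNumber"})
        db = tmp_path / "cp.sqlite"
        write_raw_sqlite(db, images, objects, toy_dataset.relationships)
        ds = tq.read_dataset(db, "sqlite")
        assert list(ds.objects["x"]) == list(toy_dataset.objects["x"])

    def test_missing_centroid_column_names_it(self, toy_dataset, tmp_path):
        db = tmp_path / "bad.sqlite"
        write_raw_sqlite(db, toy_dataset.images, toy_dataset.objects.drop(columns=["x"]),
                         toy_dataset.relationships)
        with pytest.raises(SchemaError, match="'x'"):
            tq.read_dataset(db, "sqlite")

    def test_missing_table_names_it(self, toy_dataset, tmp_path):
        db = tmp_path / "bad.sqlite"
        with sqlite3.connect(db) as con:
            toy_dataset.images.to_sql("image", con, index=False)
            toy_dataset.objects.to_sql("object", con, index=False)
        with pytest.raises(SchemaError, match="relationship"):
            tq.read_dataset(db, "sqlite")

    def test_table_name_remapping(self, toy_dataset, tmp_path):
        db = tmp_path / "renamed.sqlite"
        write_raw_sqlite(db, toy_dataset.images, toy_dataset.objects,
                         toy_dataset.relationships,
                         {"image": "per_image", "object": "per_object"})
        ds = tq.read_dataset(db, "sqlite",
                             table_names={"image": "per_image", "object": "per_object"})
        assert len(ds.objects) == 6

    def test_empty_relationship_table_is_valid(self, toy_dataset, tmp_path):
        empty = toy_dataset.relationships.iloc[0:0]
        db = tmp_path / "unlinked.sqlite"
        write_raw_sqlite(db, toy_dataset.images, toy_dataset.objects, empty)
        ds = tq.read_dataset(db, "sqlite")
        assert len(ds.relationships) == 0
        assert tq.validate_dataset(ds) == []

    def test_timepoint_derived_from_image_index_rank(self, toy_dataset, tmp_path):
        images = pd.DataFrame({"image_index": [10, 20, 35]})  # no timepoint column
        db = tmp_path / "ranked.sqlite"
        write_raw_sqlite(db, images,
                         toy_dataset.objects.replace({"image_index": {1: 10, 2: 20, 3: 35}}),
                         toy_dataset.relationships.replace(
                             {"child_image_index": {1: 10, 2: 20, 3: 35},
                              "parent_image_index": {1: 10, 2: 20, 3: 35}}))
        ds = tq.read_dataset(db, "sqlite")
        assert list(ds.images["timepoint"]) == [0, 1, 2]

    def test_referential_violation_raises_with_offenders(self, toy_dataset, tmp_path):
        rel = toy_dataset.relationships.copy()
        rel.loc[0, "parent_object_index"] = 99
        db = tmp_path / "dangling.sqlite"
        write_raw_sqlite(db, toy_dataset.images, toy_dataset.objects, rel)
        with pytest.raises(IntegrityError, match="dangling_reference"):
            tq.read_dataset(db, "sqlite")
        # non-validating read still loads for inspection
        ds = tq.read_dataset(db, "sqlite", validate=False)
        assert len(ds.relationships) == 4


class TestValidateDataset:
    def test_clean_dataset_is_silent(self, toy_dataset):
        assert tq.validate_dataset(toy_dataset) == []

    @pytest.mark.parametrize(
        "mutate, rule",
        [
            (lambda ds: ds.images.__setitem__("image_index", [1, 2, 2]), "image_index_unique"),
            (lambda ds: ds.images.__setitem__("timepoint", [0, -1, 2]), "timepoint_nonnegative"),
            (lambda ds: ds.images.__setitem__("timepoint", [0, 2, 1]), "timepoint_increasing"),
            (lambda ds: ds.objects.__setitem__(
                "object_index", [1, 1, 1, 1, 2, 3]), "object_key_unique"),
            (lambda ds: ds.objects.__setitem__(
                "x", [float("nan"), 8.0, 12.0, 7.0, 13.0, 50.0]), "centroid_finite"),
            (lambda ds: ds.objects.__setitem__(
                "image_index", [1, 2, 2, 3, 3, 9]), "object_image_exists"),
            (lambda ds: ds.relationships.__setitem__(
                "parent_object_index", [1, 1, 1, 99]), "dangling_reference"),
            (lambda ds: ds.relationships.__setitem__(
                "parent_image_index", [1, 1, 3, 3]), "time_order"),
        ],
    )
    def test_each_invariant_is_triggered(self, toy_dataset, mutate, rule):
        mutate(toy_dataset)
        rules = {v.rule for v in tq.validate_dataset(toy_dataset)}
        assert rule in rules

    def test_duplicate_relationship_rows_flagged(self, toy_dataset):
        dup = pd.concat([toy_dataset.relationships, toy_dataset.relationships.iloc[[0]]])
        ds = tq.TrackingDataset(toy_dataset.images, toy_dataset.objects,
                                dup.reset_index(drop=True), toy_dataset.feature_names)
        assert {v.rule for v in tq.validate_dataset(ds)} == {"duplicate_relationship"}

    def test_equal_parent_child_timepoint_violates_time_order(self, toy_dataset):
        rel = toy_dataset.relationships.copy()
        rel.loc[0, ["parent_image_index", "parent_object_index"]] = [2, 2]
        ds = tq.TrackingDataset(toy_dataset.images, toy_dataset.objects, rel,
                                toy_dataset.feature_names)
        assert "time_order" in {v.rule for v in tq.validate_dataset(ds)}


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["sqlite", "csv"])
    def test_toy_round_trip_identity(self, toy_dataset, tmp_path, dialect):
        path = tmp_path / ("db.sqlite" if dialect == "sqlite" else "db")
        tq.write_dataset(toy_dataset, path, dialect)
        again = tq.read_dataset(path, dialect)
        assert toy_dataset.equals(again)

    @pytest.mark.parametrize("dialect", ["sqlite", "csv"])
    def test_feature_column_order_preserved(self, tmp_path, dialect):
        ds, _ = tq.simulate(tq.SimParams(n_initial=3, n_frames=5, division_prob=0,
                                         gap_prob=0, n_features=4, seed=11))
        path = tmp_path / "db"
        tq.write_dataset(ds, path, dialect)
        assert tq.read_dataset(path, dialect).feature_names == ds.feature_names

    @pytest.mark.parametrize("dialect", ["sqlite", "csv"])
    def test_gap_edge_preserved(self, tmp_path, dialect):
        images = pd.DataFrame({"image_index": range(1, 7), "group_index": 0,
                               "timepoint": range(6)})
        objects = pd.DataFrame({"image_index": [3, 6], "object_index": [1, 1],
                                "x": [1.0, 2.0], "y": [1.0, 2.0]})
        rel = pd.DataFrame({"child_image_index": [6], "child_object_index": [1],
                            "parent_image_index": [3], "parent_object_index": [1]})
        ds = tq.TrackingDataset(images, objects, rel, [])
        path = tmp_path / "gap"
        tq.write_dataset(ds, path, dialect)
        back = tq.read_dataset(path, dialect)
        assert back.relationships.astype(int).values.tolist() == [[6, 1, 3, 1]]

    @pytest.mark.parametrize("dialect", ["sqlite", "csv"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulated_round_trip_identity(self, tmp_path, dialect, seed):
        ds, _ = tq.simulate(tq.SimParams(n_initial=6, n_frames=10, division_prob=0.05,
                                         gap_prob=0.05, n_singletons=1, seed=seed))
        path = tmp_path / f"rt{seed}"
        tq.write_dataset(ds, path, dialect)
        assert ds.equals(tq.read_dataset(path, dialect))


class TestDerivedRelationships:
    @pytest.fixture
    def stored(self, tmp_path):
        ds, _ = tq.simulate(tq.SimParams(n_initial=6, n_frames=8, division_prob=0,
                                         gap_prob=0, n_singletons=2, seed=4))
        db = tmp_path / "movie.sqlite"
        tq.write_dataset(ds, db, "sqlite")
        return tq.read_dataset(db, "sqlite"), db

    def test_save_and_retrieve(self, stored):
        ds, db = stored
        edges = ds.relationships.iloc[:10]
        tq.save_derived_relationships(ds, edges, "pruned_v1")
        assert tq.list_derived_relationships(db, "sqlite") == ["pruned_v1"]
        back = tq.read_derived_relationships(db, "pruned_v1", "sqlite")
        assert back.astype(int).values.tolist() == edges.astype(int).values.tolist()

    def test_original_tables_untouched_bytewise(self, stored, tmp_path):
        ds, db = stored
        reference = tmp_path / "ref.sqlite"
        tq.write_dataset(ds, reference, "sqlite")
        tq.save_derived_relationships(ds, ds.relationships.iloc[:5], "v1")
        after = tq.read_dataset(db, "sqlite")
        roundtrip = tmp_path / "after.sqlite"
        tq.write_dataset(after, roundtrip, "sqlite")
        assert reference.read_bytes() == roundtrip.read_bytes()

    def test_name_collision_without_overwrite(self, stored):
        ds, db = stored
        tq.save_derived_relationships(ds, ds.relationships, "twice")
        with pytest.raises(FileExistsError):
            tq.save_derived_relationships(ds, ds.relationships, "twice")
        tq.save_derived_relationships(ds, ds.relationships.iloc[:3], "twice", overwrite=True)
        assert len(tq.read_derived_relationships(db, "twice", "sqlite")) == 3

    def test_invalid_edges_rejected(self, stored):
        ds, db = stored
        bad = ds.relationships.copy()
        bad.loc[bad.index[0], "parent_object_index"] = 999
        with pytest.raises(IntegrityError):
            tq.save_derived_relationships(ds, bad, "bad")

    def test_pruned_edge_count_matches_fixture(self, tmp_path):
        ds, gt = tq.simulate(tq.SimParams(n_initial=6, n_frames=8, division_prob=0,
                                          gap_prob=0, n_singletons=2, seed=4))
        db = tmp_path / "m.sqlite"
        tq.write_dataset(ds, db, "sqlite")
        ds = tq.read_dataset(db, "sqlite")
        g = tq.build_graph(ds)
        pruned, removed = tq.prune_singletons(g, 1)
        assert len(removed) == 2  # the injected spurious detections
        kept = set(pruned.edges)
        edges = ds.relationships[
            [((r.parent_image_index, r.parent_object_index),
              (r.child_image_index, r.child_object_index)) in kept
             for r in ds.relationships.astype(int).itertuples(index=False)]
        ]
        # singletons have no incident edges here, so counts match exactly
        assert len(edges) == len(ds.relationships)
        tq.save_derived_relationships(ds, edges, "pruned")
        assert len(tq.read_derived_relationships(db, "pruned", "sqlite")) == len(edges)

    def test_csv_dialect_derived_tables(self, tmp_path):
        ds, _ = tq.simulate(tq.SimParams(n_initial=4, n_frames=6, division_prob=0,
                                         gap_prob=0, seed=9))
        prefix = tmp_path / "movie"
        tq.write_dataset(ds, prefix, "csv")
        ds = tq.read_dataset(prefix, "csv")
        tq.save_derived_relationships(ds, ds.relationships.iloc[:4], "sub")
        assert tq.list_derived_relationships(prefix, "csv") == ["sub"]
        assert len(tq.read_derived_relationships(prefix, "sub", "csv")) == 4
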