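"""Read, validate and write tracking databases in the three-table schema.

A tracking database consists of

* an **image table** — one row per acquired frame, keyed by an integer
  ``image_index``, with an optional ``group_index`` (field of view / site)
  and a ``timepoint`` ordinal within the group;
* an **object table** — one row per segmented object, keyed by
  ``(image_index, object_index)``, carrying the centroid ``(x, y)`` in
  pixels plus an open-ended set of numeric measurement columns; and
* a **relationship table** — one row per tracked parent→child link,
  referencing the object table at both endpoints.  Splits are one-to-many
  rows, merges many-to-one, and temporal gap closures are links whose
  endpoints are more than one frame apart.

Two storage dialects are supported: a single SQLite file with tables
``image`` / ``object`` / ``relationship`` (names remappable), and a CSV
triplet ``<prefix>_image.csv`` / ``<prefix>_object.csv`` /
``<prefix>_relationships.csv``.  Derived (e.g. pruned) relationship tables
are persisted alongside the originals as ``relationship__<name>`` without
touching the original tables.
"""
from __future__ import annotations

import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SchemaConfig

logger = logging.getLogger(__name__)

IMAGE_KEY_COLUMNS = ["image_index", "group_index", "timepoint"]
OBJECT_KEY_COLUMNS = ["image_index", "object_index", "x", "y"]
RELATIONSHIP_COLUMNS = [
    "child_image_index",
    "child_object_index",
    "parent_image_index",
    "parent_object_index",
]

_DERIVED_PREFIX = "relationship__"
_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")


class SchemaError(ValueError):
    """A required table or column is missing or malformed."""


class IntegrityError(ValueError):
    """Referential or ordering invariants are violated."""


@dataclass(frozen=True)
class Violation:
    """One validation failure: a rule id, a severity and the offending keys."""

    rule: str
    severity: str
    keys: tuple

    def __str__(self) -> str:  # human-readable, used by the CLI
        return f"[{self.severity}] {self.rule}: {self.keys}"


@dataclass
class TrackingDataset:
    """In-memory validated tracking database.

    ``images``, ``objects`` and ``relationships`` are pandas DataFrames in
    canonical column form; ``feature_names`` lists the numeric object
    columns that are neither keys nor centroids, in stable order.
    """

    images: pd.DataFrame
    objects: pd.DataFrame
    relationships: pd.DataFrame
    feature_names: list = field(default_factory=list)
    source: tuple | None = None  # (path, dialect) when read from disk

    def timepoint_map(self) -> dict:
        """image_index -> timepoint."""
        return dict(
            zip(self.images["image_index"].astype(int), self.images["timepoint"].astype(int))
        )

    def group_map(self) -> dict:
        return dict(
            zip(self.images["image_index"].astype(int), self.images["group_index"].astype(int))
        )

    def equals(self, other: "TrackingDataset") -> bool:
        return (
            self.feature_names == other.feature_names
            and self.images.reset_index(drop=True).equals(other.images.reset_index(drop=True))
            and self.objects.reset_index(drop=True).equals(other.objects.reset_index(drop=True))
            and self.relationships.reset_index(drop=True).equals(
                other.relationships.reset_index(drop=True)
            )
        )


# ---------------------------------------------------------------------------
# reading


def _csv_paths(path: Path) -> dict:
    prefix = str(path)
    return {
        "image": Path(prefix + "_image.csv"),
        "object": Path(prefix + "_object.csv"),
        "relationship": Path(prefix + "_relationships.csv"),
    }


def _read_raw_tables(path: Path, dialect: str, table_names: dict) -> dict:
    if dialect == "sqlite":
        if not path.exists():
            raise SchemaError(f"database file not found: {path}")
        with sqlite3.connect(path) as con:
            existing = {
                r[0] for r in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
            }
            out = {}
            for role in ("image", "object", "relationship"):
                tname = table_names[role]
                if tname not in existing:
                    raise SchemaError(f"missing table '{tname}' (role: {role}) in {path}")
                out[role] = pd.read_sql_query(f'SELECT * FROM "{tname}"', con)
        return out
    if dialect == "csv":
        out = {}
        for role, fpath in _csv_paths(path).items():
            if not fpath.exists():
                raise SchemaError(f"missing table file '{fpath}' (role: {role})")
            # round_trip parser: floats printed by to_csv re-read bit-identically
            out[role] = pd.read_csv(fpath, float_precision="round_trip")
        return out
    raise ValueError(f"unknown dialect: {dialect!r} (expected 'sqlite' or 'csv')")


def _normalize_images(df: pd.DataFrame, cfg: SchemaConfig) -> pd.DataFrame:
    col = cfg.resolve_column("image_index", df.columns)
    if col is None:
        raise SchemaError("image table: missing required column 'image_index'")
    out = pd.DataFrame({"image_index": df[col].astype(int)})
    gcol = cfg.resolve_column("group_index", df.columns)
    out["group_index"] = df[gcol].astype(int).values if gcol else 0
    tcol = cfg.resolve_column("timepoint", df.columns)
    if tcol:
        out["timepoint"] = df[tcol].astype(int).values
    else:
        # 0-based rank of image_index within its group
        out["timepoint"] = (
            out.sort_values("image_index").groupby("group_index").cumcount()
        ).reindex(out.index)
    pcol = cfg.resolve_column("image_path", df.columns)
    if pcol:
        out["image_path"] = df[pcol].values
    used = {col, gcol, tcol, pcol} - {None}
    for extra in df.columns:
        if extra not in used and extra not in out.columns:
            out[extra] = df[extra].values
    return out


def _normalize_objects(df: pd.DataFrame, cfg: SchemaConfig):
    resolved = {}
    for canonical in OBJECT_KEY_COLUMNS:
        col = cfg.resolve_column(canonical, df.columns)
        if col is None:
            raise SchemaError(f"object table: missing required column '{canonical}'")
        resolved[canonical] = col
    out = pd.DataFrame(
        {
            "image_index": df[resolved["image_index"]].astype(int),
            "object_index": df[resolved["object_index"]].astype(int),
            "x": df[resolved["x"]].astype(float),
            "y": df[resolved["y"]].astype(float),
        }
    )
    features = []
    for colname in df.columns:
        if colname in resolved.values():
            continue
        if pd.api.types.is_numeric_dtype(df[colname]):
            out[colname] = df[colname].astype(float).values
            features.append(colname)
        else:
            logger.warning("object table: ignoring non-numeric column %r", colname)
    return out, features


def _normalize_relationships(df: pd.DataFrame, cfg: SchemaConfig) -> pd.DataFrame:
    out = {}
    for canonical in RELATIONSHIP_COLUMNS:
        col = cfg.resolve_column(canonical, df.columns)
        if col is None:
            raise SchemaError(f"relationship table: missing required column '{canonical}'")
        out[canonical] = df[col].astype(int)
    return pd.DataFrame(out, columns=RELATIONSHIP_COLUMNS) if len(df) else pd.DataFrame(
        {c: pd.Series([], dtype=int) for c in RELATIONSHIP_COLUMNS}
    )


def read_dataset(
    path,
    dialect: str = "sqlite",
    table_names: dict | None = None,
    config: SchemaConfig | None = None,
    validate: bool = True,
) -> TrackingDataset:
    """Read a tracking database into a :class:`TrackingDataset`.

    Parameters
    ----------
    path : path to the SQLite file, or the CSV triplet prefix.
    dialect : ``"sqlite"`` or ``"csv"``.
    table_names : optional remapping of the three table roles.
    config : column-alias configuration; defaults match CellProfiler exports.
    validate : raise :class:`IntegrityError` on referential violations
        (schema errors always raise).  Set False to inspect broken data.
    """
    cfg = (config or SchemaConfig()).with_tables(table_names)
    raw = _read_raw_tables(Path(path), dialect, cfg.table_names)
    images = _normalize_images(raw["image"], cfg)
    objects, feature_names = _normalize_objects(raw["object"], cfg)
    relationships = _normalize_relationships(raw["relationship"], cfg)
    ds = TrackingDataset(images, objects, relationships, feature_names, (str(path), dialect))
    if validate:
        violations = validate_dataset(ds)
        if violations:
            head = "; ".join(str(v) for v in violations[:10])
            raise IntegrityError(
                f"{len(violations)} schema violation(s); first 10 offending entries: {head}"
            )
    return ds


# ---------------------------------------------------------------------------
# validation


def validate_dataset(ds: TrackingDataset) -> list:
    """Check every schema invariant; returns a list of :class:`Violation`
    (empty = valid).  Violations are reported, never raised, and each is
    logged at WARNING with its rule id."""
    out: list[Violation] = []

    def flag(rule, keys):
        v = Violation(rule, "error", tuple(keys))
        logger.warning("validation violation %s: %s", rule, keys)
        out.append(v)

    img = ds.images
    dup = img[img["image_index"].duplicated(keep=False)]
    for key in sorted(set(dup["image_index"].astype(int))):
        flag("image_index_unique", (key,))
    for key in img.loc[img["timepoint"] < 0, "image_index"].astype(int):
        flag("timepoint_nonnegative", (int(key),))
    for gidx, sub in img.sort_values("image_index").groupby("group_index"):
        tp = sub["timepoint"].to_numpy()
        if len(tp) > 1 and not np.all(np.diff(tp) > 0):
            bad = sub["image_index"].to_numpy()[np.where(np.diff(tp) <= 0)[0] + 1]
            for key in bad:
                flag("timepoint_increasing", (int(gidx), int(key)))

    obj = ds.objects
    dup = obj[obj.duplicated(subset=["image_index", "object_index"], keep=False)]
    for key in sorted(set(map(tuple, dup[["image_index", "object_index"]].astype(int).values))):
        flag("object_key_unique", key)
    nonfinite = obj[~(np.isfinite(obj["x"]) & np.isfinite(obj["y"]))]
    for key in map(tuple, nonfinite[["image_index", "object_index"]].astype(int).values):
        flag("centroid_finite", key)
    known_images = set(img["image_index"].astype(int))
    missing = obj[~obj["image_index"].isin(known_images)]
    for key in map(tuple, missing[["image_index", "object_index"]].astype(int).values):
        flag("object_image_exists", key)

    rel = ds.relationships
    if len(rel):
        obj_keys = set(map(tuple, obj[["image_index", "object_index"]].astype(int).values))
        tp = ds.timepoint_map()
        dup = rel[rel.duplicated(keep=False)]
        for key in sorted(set(map(tuple, dup.astype(int).values))):
            flag("duplicate_relationship", key)
        for row in rel.astype(int).itertuples(index=False):
            child = (row.child_image_index, row.child_object_index)
            parent = (row.parent_image_index, row.parent_object_index)
            if (child not in obj_keys or parent not in obj_keys
                    or parent[0] not in tp or child[0] not in tp):
                flag("dangling_reference", (*parent, *child))
            elif not tp[parent[0]] < tp[child[0]]:
                flag("time_order", (*parent, *child))
    return out


# ---------------------------------------------------------------------------
# writing


def _canonical_object_columns(ds: TrackingDataset) -> pd.DataFrame:
    cols = OBJECT_KEY_COLUMNS + list(ds.feature_names)
    return ds.objects[cols]


def write_dataset(ds: TrackingDataset, path, dialect: str = "sqlite") -> None:
    """Persist a dataset; ``read_dataset`` on the result reproduces it.

    Existing files at ``path`` are replaced (derived relationship tables in
    them are lost — write first, then save derived tables)."""
    path = Path(path)
    objects = _canonical_object_columns(ds)
    if dialect == "sqlite":
        if path.exists():
            path.unlink()
        path.parent.mkdir(parents=True, exist_ok=True)
        with sqlite3.connect(path) as con:
            ds.images.to_sql("image", con, index=False)
            objects.to_sql("object", con, index=False)
            ds.relationships.to_sql("relationship", con, index=False)
        return
    if dialect == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        paths = _csv_paths(path)
        ds.images.to_csv(paths["image"], index=False)
        objects.to_csv(paths["object"], index=False)
        ds.relationships.to_csv(paths["relationship"], index=False)
        return
    raise ValueError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# derived relationship tables


def _check_derived_name(name: str) -> None:
    if not _NAME_RE.match(name):
        raise ValueError(f"derived table name must be alphanumeric/underscore: {name!r}")


def _validate_edges(ds: TrackingDataset, edges: pd.DataFrame) -> None:
    probe = TrackingDataset(ds.images, ds.objects, edges[RELATIONSHIP_COLUMNS], ds.feature_names)
    violations = [v for v in validate_dataset(probe) if v.rule in
                  ("dangling_reference", "time_order", "duplicate_relationship")]
    if violations:
        head = "; ".join(str(v) for v in violations[:10])
        raise IntegrityError(f"derived edges fail integrity checks: {head}")


def save_derived_relationships(
    ds: TrackingDataset,
    edges: pd.DataFrame,
    name: str,
    path=None,
    dialect: str | None = None,
    overwrite: bool = False,
) -> None:
    """Store a derived relationship table (e.g. after singleton pruning)
    alongside the original data for retrieval across sessions.

    ``path``/``dialect`` default to where ``ds`` was read from.  The
    original tables are never modified.  Saving under an existing name
    without ``overwrite`` raises FileExistsError."""
    _check_derived_name(name)
    if path is None or dialect is None:
        if ds.source is None:
            raise ValueError("dataset has no source; pass path and dialect explicitly")
        path, dialect = ds.source
    path = Path(path)
    _validate_edges(ds, edges)
    edges = edges[RELATIONSHIP_COLUMNS].astype(int)
    if dialect == "sqlite":
        table = _DERIVED_PREFIX + name
        with sqlite3.connect(path) as con:
            existing = {
                r[0] for r in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
            }
            if table in existing:
                if not overwrite:
                    raise FileExistsError(f"derived table {name!r} already exists in {path}")
                con.execute(f'DROP TABLE "{table}"')
            edges.to_sql(table, con, index=False)
        return
    if dialect == "csv":
        fpath = Path(str(path) + f"_relationships__{name}.csv")
        if fpath.exists() and not overwrite:
            raise FileExistsError(f"derived table file already exists: {fpath}")
        edges.to_csv(fpath, index=False)
        return
    raise ValueError(f"unknown dialect: {dialect!r}")


def list_derived_relationships(path, dialect: str = "sqlite") -> list:
    """Names of derived relationship tables stored with a database."""
    path = Path(path)
    if dialect == "sqlite":
        with sqlite3.connect(path) as con:
            rows = con.execute(
                "SELECT name FROM sqlite_master WHERE type='table' AND name LIKE ?",
                (_DERIVED_PREFIX + "%",),
            ).fetchall()
        return sorted(r[0][len(_DERIVED_PREFIX):] for r in rows)
    if dialect == "csv":
        pattern = re.compile(
            re.escape(path.name) + r"_relationships__([A-Za-z0-9_]+)\.csv$"
        )
        return sorted(
            m.group(1)
            for f in path.parent.glob(path.name + "_relationships__*.csv")
            if (m := pattern.match(f.name))
        )
    raise ValueError(f"unknown dialect: {dialect!r}")


def read_derived_relationships(path, name: str, dialect: str = "sqlite") -> pd.DataFrame:
    """Retrieve a previously saved derived relationship table."""
    _check_derived_name(name)
    path = Path(path)
    if dialect == "sqlite":
        table = _DERIVED_PREFIX + name
        with sqlite3.connect(path) as con:
            try:
                return pd.read_sql_query(f'SELECT * FROM "{table}"', con)
            except pd.errors.DatabaseError:
                raise SchemaError(f"no derived table {name!r} in {path}")
    if dialect == "csv":
        fpath = Path(str(path) + f"_relationships__{name}.csv")
        if not fpath.exists():
            raise SchemaError(f"no derived table file: {fpath}")
        return pd.read_csv(fpath)
    raise ValueError(f"unknown dialect: {dialect!r}")
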