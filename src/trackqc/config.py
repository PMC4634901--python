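"""Configuration for table names and column aliases.

Tracking databases exported by different tools name their key columns
differently (``ImageNumber`` vs ``image_index``, ``Location_Center_X`` vs
``x`` ...).  Readers resolve columns case-insensitively through the alias
lists below; every entry can be overridden via a JSON config file or a
plain dict.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

DEFAULT_TABLE_NAMES = {
    "image": "image",
    "object": "object",
    "relationship": "relationship",
}

# Alias entries are matched case-insensitively.  Entries starting with
# "contains:" match any column whose lowercase name contains the fragment
# (CellProfiler emits e.g. "Nuclei_Location_Center_X").
DEFAULT_COLUMN_ALIASES = {
    "image_index": ["image_index", "imagenumber", "image_number"],
    "group_index": ["group_index", "group_number", "metadata_site", "site"],
    "timepoint": ["timepoint", "metadata_timepoint", "frame", "t"],
    "image_path": ["image_path", "path_name", "image_pathname", "filename"],
    "object_index": ["object_index", "objectnumber", "object_number"],
    "x": ["x", "contains:location_center_x"],
    "y": ["y", "contains:location_center_y"],
    "child_image_index": ["child_image_index", "image_number1", "first_image_number"],
    "child_object_index": ["child_object_index", "object_number1", "first_object_number"],
    "parent_image_index": ["parent_image_index", "image_number2", "second_image_number"],
    "parent_object_index": ["parent_object_index", "object_number2", "second_object_number"],
}


@dataclass(frozen=True)
class SchemaConfig:
    """Table names and column aliases used when reading a database."""

    table_names: dict = field(default_factory=lambda: dict(DEFAULT_TABLE_NAMES))
    column_aliases: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_ALIASES))

    def with_tables(self, mapping: dict | None) -> "SchemaConfig":
        if not mapping:
            return self
        names = dict(self.table_names)
        names.update(mapping)
        return replace(self, table_names=names)

    def resolve_column(self, canonical: str, columns) -> str | None:
        """Return the actual column name for a canonical key, or None."""
        lower = {c.lower(): c for c in columns}
        for alias in self.column_aliases.get(canonical, [canonical]):
            if alias.startswith("contains:"):
                frag = alias[len("contains:"):]
                for lc, orig in lower.items():
                    if frag in lc:
                        return orig
            elif alias.lower() in lower:
                return lower[alias.lower()]
        return None


def load_config(path: str | Path | None) -> SchemaConfig:
    """Load a SchemaConfig from a JSON file with keys
    ``table_names`` and/or ``column_aliases``; missing keys keep defaults."""
    if path is None:
        return SchemaConfig()
    data = json.loads(Path(path).read_text())
    tables = dict(DEFAULT_TABLE_NAMES)
    tables.update(data.get("table_names", {}))
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    for key, val in data.get("column_aliases", {}).items():
        aliases[key] = list(val)
    return SchemaConfig(table_names=tables, column_aliases=aliases)
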