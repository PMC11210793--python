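"""File-format contracts and metadata joins.

Each arena's worm-position table is written to a *location* CSV whose file
name encodes the keys needed to join it back to the assay metadata:
``<imageID>_<slot>_<wellID>.csv``.  The metadata table (one row per arena)
carries assay date, experimenter, image ID, plate ID, scanner slot, well ID,
compound, strain, humidity and temperature; ``(image_id, slot, well_id)``
must be unique and every location file must resolve to exactly one record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MetadataRecord",
    "MetadataError",
    "encode_location_name",
    "parse_location_name",
    "load_metadata",
    "join_metadata",
]

_NAME_RE = re.compile(r"^(?P<image_id>.+)_(?P<slot>[^_]+)_(?P<well_id>[^_.]+)\.csv$")

METADATA_COLUMNS = [
    "assay_date",
    "experimenter",
    "image_id",
    "plate_id",
    "slot",
    "well_id",
    "compound_id",
    "strain_id",
    "humidity",
    "temperature",
]


class MetadataError(ValueError):
    """Raised on malformed location names or unresolvable metadata joins."""


@dataclass
class MetadataRecord:
    image_id: str
    slot: str
    well_id: str
    compound_id: str
    strain_id: str
    plate_id: str = ""
    assay_date: str = ""
    experimenter: str = ""
    humidity: float | None = None
    temperature: float | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.image_id, self.slot, self.well_id)


def encode_location_name(image_id: str, slot, well_id: str) -> str:
    """``(IMG007, 2, B) -> "IMG007_2_B.csv"``; ids must be path-safe."""
    parts = [str(image_id), str(slot), str(well_id)]
    for p in parts:
        if "/" in p or "\\" in p:
            raise MetadataError(f"id component {p!r} contains a path separator")
        if not p:
            raise MetadataError("id components must be non-empty")
    if "_" in parts[1] or "_" in parts[2]:
        raise MetadataError("slot and well_id may not contain underscores")
    return "_".join(parts) + ".csv"


def parse_location_name(filename: str) -> tuple[str, str, str]:
    """Inverse of :func:`encode_location_name`; round-trip identity holds."""
    m = _NAME_RE.match(filename)
    if not m:
        missing = "well_id" if filename.count("_") < 2 else "pattern"
        raise MetadataError(
            f"cannot parse location file name {filename!r}: missing {missing} "
            "(expected <imageID>_<slot>_<wellID>.csv)"
        )
    return m.group("image_id"), m.group("slot"), m.group("well_id")


def load_metadata(path) -> pd.DataFrame:
    """Read the metadata CSV and validate key uniqueness."""
    df = pd.read_csv(path, dtype=str)
    required = {"image_id", "slot", "well_id", "compound_id", "strain_id"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"metadata is missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["image_id", "slot", "well_id"])
    if dup.any():
        keys = df.loc[dup, ["image_id", "slot", "well_id"]].to_records(index=False)
        raise MetadataError(f"duplicate metadata keys: {list(keys)[:5]}")
    return df


def join_metadata(location_names: list[str], metadata: pd.DataFrame) -> pd.DataFrame:
    """Resolve each location file name to its metadata record.

    Raises :class:`MetadataError` listing every orphaned file (a hard error:
    a screen with untraceable assays is not analyzable).
    """
    keys = [parse_location_name(n) for n in location_names]
    lookup = {
        (r.image_id, r.slot, r.well_id): i
        for i, r in metadata.iterrows()
    }
    orphans = [n for n, k in zip(location_names, keys) if k not in lookup]
    if orphans:
        raise MetadataError(f"location files without metadata: {orphans}")
    rows = [metadata.iloc[lookup[k]] for k in keys]
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.insert(0, "location_file", location_names)
    return out
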