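"""Delimited-text readers and writers for tree-level biomass tables.

The canonical wide format has one row per tree:

    species,dbh_cm,height_m,volume_m3,stem_kg,branches_kg,foliage_kg

with masses in kg and stem volume in m³.  A column map (dict, or YAML/JSON
file) renames arbitrary headers onto these canonical keys.  Stem volume may
be omitted when a long-format segment file (keyed by ``tree_id``) supplies
the five equal-length segments for the sectional volume formula.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import Dataset, StemSegment, TreeRecord, hohenadl_volume

CANONICAL_COLUMNS = (
    "species",
    "dbh_cm",
    "height_m",
    "volume_m3",
    "stem_kg",
    "branches_kg",
    "foliage_kg",
)

SEGMENT_COLUMNS = ("tree_id", "length_m", "mid_diameter_cm")


def load_column_map(source: str | Path | dict | None) -> dict:
    """Column map as a dict, from a dict or a YAML/JSON file path."""
    if source is None:
        return {}
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"non-numeric value {df[col][row]!r} in column {col!r}, row {row}"
        )
    return out


def read_segment_table(path: str | Path, sep: str = ",") -> dict[str, list[StemSegment]]:
    """Long-format segment file -> segments per tree_id."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment file {path} lacks columns {missing}")
    out: dict[str, list[StemSegment]] = {}
    for tree_id, grp in df.groupby("tree_id", sort=False):
        segs = [
            StemSegment(length=float(row.length_m), mid_diameter=float(row.mid_diameter_cm))
            for row in grp.itertuples()
        ]
        out[str(tree_id)] = segs
    return out


def read_tree_table(
    path: str | Path,
    column_map: str | Path | dict | None = None,
    sep: str = ",",
    segments_path: str | Path | None = None,
) -> Dataset:
    """Read a delimited tree table into a :class:`Dataset`.

    Rows lacking both a stem volume and a set of five segments are rejected
    (not fatal) and reported in ``Dataset.rejected`` with their row index.
    Negative masses or volumes and non-numeric cells raise.
    """
    cmap = load_column_map(column_map)
    df = pd.read_csv(path, sep=sep)
    if cmap:
        df = df.rename(columns=cmap)
    missing = [c for c in ("species", "stem_kg", "branches_kg") if c not in df.columns]
    if missing:
        raise ValueError(f"input {path} lacks required columns {missing}")

    segments = read_segment_table(segments_path, sep=sep) if segments_path else {}

    for col in ("dbh_cm", "height_m", "volume_m3", "stem_kg", "branches_kg", "foliage_kg"):
        if col in df.columns:
            df[col] = _numeric(df, col)

    for col in ("stem_kg", "branches_kg", "foliage_kg"):
        if col in df.columns and (df[col].dropna() < 0).any():
            row = int((df[col] < 0).idxmax())
            raise ValueError(f"negative mass in column {col!r}, row {row}")
    if "volume_m3" in df.columns and (df["volume_m3"].dropna() <= 0).any():
        row = int((df["volume_m3"] <= 0).idxmax())
        raise ValueError(
            f"non-positive stem volume {df['volume_m3'][row]} in row {row}"
        )

    records: list[TreeRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        tree_id = str(row["tree_id"]) if "tree_id" in df.columns and pd.notna(row.get("tree_id")) else None
        volume = row.get("volume_m3")
        volume = None if pd.isna(volume) else float(volume)
        if volume is None:
            segs = segments.get(tree_id) if tree_id else None
            if segs is None:
                rejected.append((int(i), "no stem volume and no segments"))
                continue
            volume = hohenadl_volume(segs)
        foliage = row.get("foliage_kg")
        foliage_absent = pd.isna(foliage)
        records.append(
            TreeRecord(
                species=str(row["species"]),
                dbh=float(row.get("dbh_cm", 1.0)) if pd.notna(row.get("dbh_cm")) else 1.0,
                height=float(row.get("height_m", 1.0)) if pd.notna(row.get("height_m")) else 1.0,
                stem_volume=volume,
                w_stem=float(row["stem_kg"]),
                w_branches=float(row["branches_kg"]),
                w_foliage=0.0 if foliage_absent else float(foliage),
                foliage_absent=bool(foliage_absent),
                tree_id=tree_id,
            )
        )
    return Dataset(records, rejected=rejected)


def write_tree_table(dataset: Dataset, path: str | Path, sep: str = ",") -> None:
    """Write the canonical wide table (full float precision, round-trip safe)."""
    df = dataset.to_dataframe()
    df.to_csv(path, sep=sep, index=False)


def write_analysis_pairs(dataset: Dataset, path: str | Path, sep: str = ",") -> None:
    """Write the long-format (species, component, W_Mg, V_m3) table."""
    dataset.analysis_pairs().to_csv(path, sep=sep, index=False)
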