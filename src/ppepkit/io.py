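"""Shared tabular readers/writers with light schema validation.

All tables in this package are plain TSV with a header row. Schemas are
column-name tuples; a missing column is an error naming that column, extra
columns are preserved with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "IDENTIFICATION_SCHEMA",
    "GROUND_TRUTH_SCHEMA",
    "MERGED_SCHEMA",
    "KINETICS_SCHEMA",
    "read_table",
    "write_table",
    "merged_products_to_frame",
    "frame_to_merged_products",
]

IDENTIFICATION_SCHEMA = (
    "sequence", "side", "abundance", "retention_time", "has_biotin", "length",
)
GROUND_TRUTH_SCHEMA = ("sequence", "side", "true_abundance", "mass_key")
MERGED_SCHEMA = (
    "side", "mass_key", "representative", "members", "abundance", "retention_time",
)
KINETICS_SCHEMA = ("label", "replicate", "time_min", "fluorescence")


class SchemaError(ValueError):
    """A table does not match its declared column schema."""


def read_table(path: str | Path, schema: Sequence[str]) -> pd.DataFrame:
    """Read a TSV table and validate it against a column schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in frame.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: extra column(s) {extra} preserved", stacklevel=2)
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, schema: Sequence[str]) -> None:
    """Write a TSV table, validating the schema first.

    Floats are serialised with 10 significant digits so write/read round
    trips are lossless at analysis precision.
    """
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"cannot write {path}: missing column(s) {missing}")
    ordered = list(schema) + [c for c in frame.columns if c not in schema]
    frame[ordered].to_csv(path, sep="\t", index=False, float_format="%.10g")


def merged_products_to_frame(products) -> pd.DataFrame:
    """Serialise MergedProduct records (members are comma-joined)."""
    rows = [
        {
            "side": p.side,
            "mass_key": p.mass_key,
            "representative": p.representative,
            "members": ",".join(p.member_sequences),
            "abundance": p.abundance,
            "retention_time": p.retention_time,
        }
        for p in products
    ]
    return pd.DataFrame(rows, columns=list(MERGED_SCHEMA))


def frame_to_merged_products(frame: pd.DataFrame):
    """Inverse of :func:`merged_products_to_frame`."""
    from .quantify import MergedProduct

    out = []
    for _, row in frame.iterrows():
        out.append(
            MergedProduct(
                side=str(row["side"]),
                mass_key=float(row["mass_key"]),
                member_sequences=tuple(str(row["members"]).split(",")),
                representative=str(row["representative"]),
                abundance=float(row["abundance"]),
                retention_time=float(row["retention_time"]),
            )
        )
    return out
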