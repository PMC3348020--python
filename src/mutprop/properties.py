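"""Amino-acid property tables and min-max normalization.

A property table holds one physicochemical / energetic / conformational scale
per row: a real value for each of the 20 standard amino acids.  Before any
downstream analysis each scale is normalized onto [0, 1],

    P_norm(i) = (P(i) - P_min) / (P_max - P_min),

where the minimum and maximum are taken over the 20 standard residues.  The
normalized scale is the default for all feature construction; raw values stay
available for diagnostics.

The packaged default table (``data/aa_properties_synthetic49.tsv``) is a
*synthetic* stand-in: 49 deterministic pseudo-scales whose names indicate the
property family they emulate (hydrophobicity, volume, helix propensity, ...).
It exists so the pipeline is runnable and testable out of the box; for real
analyses supply your own table (e.g. scales exported from AAindex) in the same
TSV layout: ``id<TAB>description<TAB>A<TAB>C<TAB>...<TAB>Y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from os import PathLike

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePropertyError,
    PropertyLookupError,
    PropertyTableError,
    ResidueLookupError,
)

#: The 20 standard amino acids, one-letter codes, alphabetical.
RESIDUES: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

_RESIDUE_SET = frozenset(RESIDUES)

_DEFAULT_TABLE_RESOURCE = "aa_properties_synthetic49.tsv"


def check_residue(code: str) -> str:
    """Return ``code`` if it is a standard one-letter residue code, else raise.

    Ambiguity codes ('B', 'Z', 'X') and lower case are rejected: min-max
    normalization and property lookup are defined over the 20-letter alphabet
    only.
    """
    if not isinstance(code, str) or code not in _RESIDUE_SET:
        raise ResidueLookupError(
            f"unknown residue code {code!r}; expected one of {''.join(RESIDUES)}"
        )
    return code


def normalize_property(raw_values) -> np.ndarray:
    """Min-max normalize one property scale onto [0, 1].

    Parameters
    ----------
    raw_values
        Sequence of real values (one per residue).  At least two distinct
        values are required.

    Returns
    -------
    numpy.ndarray
        ``(v - min) / (max - min)`` elementwise; the minimum maps to exactly
        0.0 and the maximum to exactly 1.0.

    Raises
    ------
    DegeneratePropertyError
        If all values are equal (the map is undefined); such a property must
        be rejected rather than silently zeroed.
    """
    values = np.asarray(raw_values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise PropertyTableError("a property scale needs at least two values")
    if not np.all(np.isfinite(values)):
        raise PropertyTableError("property scale contains non-finite values")
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise DegeneratePropertyError(
            f"degenerate property: all values equal {vmin!r}; min-max normalization undefined"
        )
    return (values - vmin) / (vmax - vmin)


@dataclass(frozen=True)
class PropertyTable:
    """Raw and normalized values of amino-acid properties for the 20 residues.

    Attributes
    ----------
    raw
        DataFrame indexed by property id, one column per residue (table
        order = input order for properties, alphabetical for residues).
    normalized
        Same shape; every row spans [0, 1] exactly.
    pmin, pmax
        Per-property extrema of the raw scale (over the 20 residues).
    descriptions
        Free-text description per property id.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    pmin: pd.Series
    pmax: pd.Series
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def property_ids(self) -> list[str]:
        return list(self.raw.index)

    @classmethod
    def from_raw(cls, raw: pd.DataFrame, descriptions: dict[str, str] | None = None) -> "PropertyTable":
        """Build a table from raw values, validating and normalizing each row."""
        missing = [r for r in RESIDUES if r not in raw.columns]
        if missing:
            raise PropertyTableError(f"missing residue column(s): {', '.join(missing)}")
        extra = [c for c in raw.columns if c not in _RESIDUE_SET]
        if extra:
            raise PropertyTableError(
                f"non-standard residue column(s): {', '.join(map(str, extra))}"
            )
        if raw.index.has_duplicates:
            dups = sorted(set(raw.index[raw.index.duplicated()]))
            raise PropertyTableError(f"duplicate property id(s): {', '.join(map(str, dups))}")
        raw = raw.loc[:, list(RESIDUES)].copy()
        try:
            raw = raw.astype(float)
        except (TypeError, ValueError) as exc:
            raise PropertyTableError(f"non-numeric property value: {exc}") from exc
        if raw.isna().any().any():
            bad = raw.index[raw.isna().any(axis=1)]
            raise PropertyTableError(f"missing value(s) in property: {', '.join(map(str, bad))}")
        norm_rows = {}
        for pid, row in raw.iterrows():
            try:
                norm_rows[pid] = normalize_property(row.to_numpy())
            except DegeneratePropertyError as exc:
                raise DegeneratePropertyError(f"property {pid!r}: {exc}") from exc
        normalized = pd.DataFrame(norm_rows, index=list(RESIDUES)).T
        normalized.index = raw.index
        return cls(
            raw=raw,
            normalized=normalized,
            pmin=raw.min(axis=1),
            pmax=raw.max(axis=1),
            descriptions=dict(descriptions or {}),
        )

    def get_value(self, property_id: str, residue: str, scale: str = "normalized") -> float:
        """Look up one property value for one residue on the given scale."""
        check_residue(residue)
        frame = self._frame(scale)
        if property_id not in frame.index:
            raise PropertyLookupError(f"unknown property id {property_id!r}")
        return float(frame.at[property_id, residue])

    def values(self, property_id: str, scale: str = "normalized") -> pd.Series:
        """All 20 residue values of one property (residues in alphabetical order)."""
        frame = self._frame(scale)
        if property_id not in frame.index:
            raise PropertyLookupError(f"unknown property id {property_id!r}")
        return frame.loc[property_id]

    def _frame(self, scale: str) -> pd.DataFrame:
        if scale == "normalized":
            return self.normalized
        if scale == "raw":
            return self.raw
        raise ValueError(f"scale must be 'raw' or 'normalized', got {scale!r}")

    def denormalize(self, property_id: str, normalized_values) -> np.ndarray:
        """Invert the min-max map using the stored (pmin, pmax); round-trip aid."""
        lo, hi = float(self.pmin[property_id]), float(self.pmax[property_id])
        return np.asarray(normalized_values, dtype=float) * (hi - lo) + lo


def load_property_table(source: str | PathLike) -> PropertyTable:
    """Load a property table from TSV.

    Expected layout: header ``id<TAB>description<TAB><residue columns>`` with
    all 20 standard one-letter codes present (any order); '.' decimal
    separator; UTF-8.
    """
    try:
        frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise PropertyTableError(f"could not read property table {source!r}: {exc}") from exc
    if "id" not in frame.columns:
        raise PropertyTableError("property table must have an 'id' column")
    descriptions = {}
    if "description" in frame.columns:
        descriptions = dict(zip(frame["id"], frame["description"]))
    value_cols = [c for c in frame.columns if c not in ("id", "description")]
    raw = frame.set_index("id")[value_cols]
    for col in value_cols:
        bad = raw[col][~raw[col].str.match(r"^\s*[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?\s*$")]
        if len(bad):
            raise PropertyTableError(
                f"non-numeric cell in column {col!r}, property {bad.index[0]!r}: {bad.iloc[0]!r}"
            )
    return PropertyTable.from_raw(raw.astype(float), descriptions)


def default_property_table() -> PropertyTable:
    """Load the packaged synthetic 49-property stand-in table."""
    with resources.as_file(resources.files("mutprop.data") / _DEFAULT_TABLE_RESOURCE) as path:
        return load_property_table(path)


def write_property_table(table: PropertyTable, path: str | PathLike) -> None:
    """Write a table's raw values back to the TSV layout read by the loader."""
    out = table.raw.copy()
    out.insert(0, "description", [table.descriptions.get(pid, "") for pid in out.index])
    out.index.name = "id"
    out.to_csv(path, sep="\t")
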