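"""Per-mutant explanatory variables from amino-acid property scales.

Three encodings are supported, all taking property values from a
:class:`~mutprop.properties.PropertyTable` (normalized scale by default):

``delta``
    Mutation-induced property change, ``dP = P(mutant) - P(wild)``.
``seq_window``
    Local-sequence effect: the sum of wild-type property values over the
    (2k+1)-residue window centred on the mutated position, minus the mutant
    residue's value.  Windows are truncated at the sequence termini
    (out-of-range positions contribute nothing), so terminal mutants remain
    usable at every k.
``structural``
    Structure-based effect: the sum of property values over all residues
    whose representative (CA) coordinate lies within a cutoff radius
    (default 8 A) of the mutated residue, minus the mutant residue's value.
    The surrounding sum excludes the central residue itself.

A mutant lacking the context an encoding requires (sequence, structure) is an
error, never a NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import (
    DatasetValidationError,
    FeatureContextError,
    StructureError,
)
from .properties import PropertyTable, check_residue

ENCODINGS: tuple[str, ...] = ("delta", "seq_window", "structural")

LOCATION_CLASSES: tuple[str, ...] = ("TM", "loop", "unknown")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutantRecord:
    """One site-directed point mutant and its experimental response.

    ``response`` is the experimental quantity Y as provided (a signed
    delta-EC50, a cAMP increase, a Ca2+ increase, ...); units are the
    caller's.  ``position`` is 1-based into the receptor sequence.
    """

    receptor_id: str
    position: int
    wild: str
    mutant: str
    response: float
    location_class: str = "unknown"

    def __post_init__(self):
        check_residue(self.wild)
        check_residue(self.mutant)
        if self.wild == self.mutant:
            raise DatasetValidationError(
                f"{self.receptor_id} position {self.position}: wild == mutant ({self.wild})"
            )
        if self.position < 1:
            raise DatasetValidationError(f"position must be >= 1, got {self.position}")
        if self.location_class not in LOCATION_CLASSES:
            raise DatasetValidationError(
                f"location_class must be one of {LOCATION_CLASSES}, got {self.location_class!r}"
            )
        if not np.isfinite(self.response):
            raise DatasetValidationError(
                f"{self.receptor_id} position {self.position}: non-finite response"
            )

    @property
    def name(self) -> str:
        return f"{self.wild}{self.position}{self.mutant}"


@dataclass(frozen=True)
class StructureContext:
    """Representative (CA) coordinates for the residues of one chain.

    Positions are 1-based sequence positions, unique and sorted; one (x, y, z)
    coordinate in Angstrom per residue.
    """

    positions: tuple[int, ...]
    residues: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.positions)
        if coords.shape != (n, 3):
            raise StructureError(f"coords must be ({n}, 3), got {coords.shape}")
        if len(self.residues) != n:
            raise StructureError("positions and residues differ in length")
        if len(set(self.positions)) != n or list(self.positions) != sorted(self.positions):
            raise StructureError("positions must be unique and sorted")
        for r in self.residues:
            check_residue(r)

    def index_of(self, position: int) -> int:
        try:
            return self.positions.index(position)
        except ValueError:
            raise StructureError(f"position {position} absent from structure") from None

    def residue_at(self, position: int) -> str:
        return self.residues[self.index_of(position)]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MutantDataset:
    """A set of mutants sharing a receptor context.

    Optional ``sequence`` (needed for window features) and ``structure``
    (needed for structural features).  When a sequence is attached, each
    record's wild residue must match the sequence at its position.
    """

    records: list[MutantRecord]
    sequence: str | None = None
    structure: StructureContext | None = None
    response_label: str = "response"

    def __post_init__(self):
        if not self.records:
            raise DatasetValidationError("a mutant dataset needs at least one record")
        if self.sequence is not None:
            self.sequence = str(self.sequence).upper()
            bad = []
            for i, rec in enumerate(self.records):
                if rec.position > len(self.sequence):
                    bad.append(f"row {i} ({rec.name}): position beyond sequence length "
                               f"{len(self.sequence)}")
                elif self.sequence[rec.position - 1] != rec.wild:
                    bad.append(
                        f"row {i} ({rec.name}): sequence has "
                        f"{self.sequence[rec.position - 1]!r} at position {rec.position}"
                    )
            if bad:
                raise DatasetValidationError(
                    "wild residue / sequence mismatch: " + "; ".join(bad)
                )
        if self.structure is not None:
            for i, rec in enumerate(self.records):
                if rec.position not in self.structure.positions:
                    raise DatasetValidationError(
                        f"row {i} ({rec.name}): position {rec.position} absent from structure"
                    )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def responses(self) -> np.ndarray:
        return np.array([r.response for r in self.records], dtype=float)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def subset(self, indices: Sequence[int]) -> "MutantDataset":
        return MutantDataset(
            records=[self.records[i] for i in indices],
            sequence=self.sequence,
            structure=self.structure,
            response_label=self.response_label,
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-mutant feature values, one column per (encoding, property) pair.

    ``frame`` is a DataFrame whose columns are flat string ids
    ``"<encoding>:<property_id>"`` (``seq_window`` ids carry the half-window,
    e.g. ``"seq_window(k=2):volume_s01"``); ``columns_meta`` retains the
    structured (encoding, property_id, params) description per column.
    """

    frame: pd.DataFrame
    columns_meta: tuple[tuple, ...]
    scale: str = "normalized"

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def column_ids(self) -> list[str]:
        return list(self.frame.columns)


# ---------------------------------------------------------------------------
# elementary feature operations
# ---------------------------------------------------------------------------

def delta_property(
    table: PropertyTable, property_id: str, wild: str, mutant: str, scale: str = "normalized"
) -> float:
    """Mutation-induced property change ``P(mutant) - P(wild)``.

    Antisymmetric in (wild, mutant); zero for an identity substitution.
    """
    return table.get_value(property_id, mutant, scale) - table.get_value(property_id, wild, scale)


def local_sequence_effect(
    table: PropertyTable,
    property_id: str,
    sequence: str,
    position: int,
    mutant: str,
    k: int,
    scale: str = "normalized",
) -> float:
    """Local-sequence effect: window sum of wild-type values minus the mutant value.

    The window spans positions ``position-k .. position+k`` of the wild-type
    sequence (including the wild residue at the mutated position itself) and
    is truncated at the termini.  With ``k = 0`` this reduces to
    ``P(wild) - P(mutant)``, i.e. the negated delta encoding.
    """
    if k < 0:
        raise ValueError(f"half-window k must be >= 0, got {k}")
    sequence = str(sequence).upper()
    if not 1 <= position <= len(sequence):
        raise DatasetValidationError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    lo = max(1, position - k)
    hi = min(len(sequence), position + k)
    window_sum = sum(
        table.get_value(property_id, sequence[j - 1], scale) for j in range(lo, hi + 1)
    )
    return window_sum - table.get_value(property_id, mutant, scale)


def neighbors_within_radius(
    structure: StructureContext,
    position: int,
    radius: float = 8.0,
    include_self: bool = False,
) -> set[int]:
    """Positions whose representative coordinate lies within ``radius`` A.

    Distance is Euclidean between representative (CA) points; the residue
    itself is excluded unless ``include_self``.  Sequence-adjacent residues
    are included (they are genuine spatial neighbours).
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    i = structure.index_of(position)
    d = cdist(structure.coords[i : i + 1], structure.coords)[0]
    mask = d <= radius
    if not include_self:
        mask[i] = False
    return {structure.positions[j] for j in np.nonzero(mask)[0]}


def surrounding_property_sum(
    table: PropertyTable,
    property_id: str,
    structure: StructureContext,
    position: int,
    radius: float = 8.0,
    scale: str = "normalized",
) -> float:
    """Sum of property values over all residues surrounding ``position``.

    Equivalent to summing, over residue types j, (count of type-j neighbours
    within the radius) times P(j).  No neighbours gives 0.0.
    """
    total = 0.0
    for pos in neighbors_within_radius(structure, position, radius):
        total += table.get_value(property_id, structure.residue_at(pos), scale)
    return total


def structural_effect(
    table: PropertyTable,
    property_id: str,
    structure: StructureContext,
    position: int,
    mutant: str,
    radius: float = 8.0,
    scale: str = "normalized",
) -> float:
    """Structure-based effect: surrounding property sum minus the mutant value.

    Note an identity substitution does not in general give zero: the value is
    the surrounding sum minus P(wild) in that case.
    """
    return surrounding_property_sum(
        table, property_id, structure, position, radius, scale
    ) - table.get_value(property_id, mutant, scale)


# ---------------------------------------------------------------------------
# feature-matrix assembly
# ---------------------------------------------------------------------------

def _encoding_column(encoding: str, property_id: str, k: int) -> str:
    if encoding == "seq_window":
        return f"seq_window(k={k}):{property_id}"
    return f"{encoding}:{property_id}"


def build_feature_matrix(
    table: PropertyTable,
    dataset: MutantDataset,
    encodings: Iterable[str] = ("delta",),
    property_ids: Sequence[str] | None = None,
    k: int = 1,
    radius: float = 8.0,
    scale: str = "normalized",
) -> FeatureMatrix:
    """Assemble the N x (encodings x properties) feature matrix for a dataset.

    Column order is deterministic: encodings in the canonical order
    (delta, seq_window, structural), properties in table order.

    Raises :class:`FeatureContextError` if ``seq_window`` is requested without
    a sequence or ``structural`` without a structure.
    """
    requested = list(encodings)
    unknown = [e for e in requested if e not in ENCODINGS]
    if unknown:
        raise ValueError(f"unknown encoding(s): {unknown}; valid: {ENCODINGS}")
    ordered = [e for e in ENCODINGS if e in requested]
    if "seq_window" in ordered and dataset.sequence is None:
        raise FeatureContextError("seq_window encoding requested but dataset has no sequence")
    if "structural" in ordered and dataset.structure is None:
        raise FeatureContextError("structural encoding requested but dataset has no structure")
    if property_ids is None:
        property_ids = table.property_ids
    else:
        property_ids = list(property_ids)
        order = {p: i for i, p in enumerate(table.property_ids)}
        property_ids = sorted(property_ids, key=lambda p: order[p])

    columns: dict[str, np.ndarray] = {}
    meta: list[tuple] = []
    for encoding in ordered:
        for pid in property_ids:
            vals = np.empty(dataset.n, dtype=float)
            for i, rec in enumerate(dataset.records):
                if encoding == "delta":
                    vals[i] = delta_property(table, pid, rec.wild, rec.mutant, scale)
                elif encoding == "seq_window":
                    vals[i] = local_sequence_effect(
                        table, pid, dataset.sequence, rec.position, rec.mutant, k, scale
                    )
                else:
                    vals[i] = structural_effect(
                        table, pid, dataset.structure, rec.position, rec.mutant, radius, scale
                    )
            params = {"k": k} if encoding == "seq_window" else (
                {"radius": radius} if encoding == "structural" else {}
            )
            columns[_encoding_column(encoding, pid, k)] = vals
            meta.append((encoding, pid, tuple(sorted(params.items()))))
    frame = pd.DataFrame(columns, index=dataset.names)
    return FeatureMatrix(frame=frame, columns_meta=tuple(meta), scale=scale)
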