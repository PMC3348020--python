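"""Shared fixtures: the packaged table and hand-sized toy inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutprop.properties import RESIDUES, PropertyTable, default_property_table


@pytest.fixture(scope="session")
def table49() -> PropertyTable:
    """The packaged synthetic 49-property table."""
    return default_property_table()


def make_toy_table(values: dict[str, dict[str, float]]) -> PropertyTable:
    """A table with prescribed raw values for some residues per property.

    Unspecified residues are filled with evenly spaced values over [0, 1]
    (so normalization is well defined); toy tests read the *raw* scale, where
    the prescribed values hold exactly.
    """
    rows = {}
    for pid, vals in values.items():
        fill = np.linspace(0.0, 1.0, 20)
        row = {res: fill[i] for i, res in enumerate(RESIDUES)}
        row.update(vals)
        rows[pid] = [row[res] for res in RESIDUES]
    raw = pd.DataFrame(rows, index=list(RESIDUES)).T
    return PropertyTable.from_raw(raw)


@pytest.fixture()
def toy_table() -> PropertyTable:
    """One property with the hand-example values G=0.1, A=0.2, K=0.3, V=0.9."""
    return make_toy_table({"prop1": {"G": 0.1, "A": 0.2, "K": 0.3, "V": 0.9}})
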