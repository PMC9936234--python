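"""Inflammatory score: sum of 22 deconvolved immune-cell relative fractions.

The score aggregates the relative fractions, within the leukocyte
compartment, of 22 inflammation-related immune cell types (monocytes,
macrophage states, dendritic, mast, neutrophil/eosinophil, B-cell, T-cell
and NK subsets — the exact panel is :data:`~repclon.io_clonotypes.CELL_TYPES_22`).
Fractions are summed exactly as supplied, with no renormalisation; a missing
cell type is a hard error, never a silent zero.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .io_clonotypes import CELL_TYPES_22


def inflammatory_score(cell_fractions: Mapping[str, float]) -> float:
    """Sum the 22 inflammation-related cell fractions.

    Raises ``ValueError`` naming the first missing cell type, or any value
    outside [0, 1].
    """
    for name in CELL_TYPES_22:
        if name not in cell_fractions:
            raise ValueError(f"missing cell type {name!r} in cell fractions")
        v = cell_fractions[name]
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"cell fraction {name!r} = {v} outside [0, 1]")
    return float(sum(cell_fractions[name] for name in CELL_TYPES_22))


def add_inflammatory_score(metadata_frame: pd.DataFrame) -> pd.DataFrame:
    """Append an ``inflammatory_score`` column to a metadata table."""
    missing = set(CELL_TYPES_22) - set(metadata_frame.columns)
    if missing:
        raise ValueError(f"missing cell type column(s): {sorted(missing)}")
    out = metadata_frame.copy()
    bad = (out[list(CELL_TYPES_22)] < 0).any().any() or (
        out[list(CELL_TYPES_22)] > 1
    ).any().any()
    if bad:
        raise ValueError("cell fraction outside [0, 1]")
    out["inflammatory_score"] = out[list(CELL_TYPES_22)].sum(axis=1)
    return out
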