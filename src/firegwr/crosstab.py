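"""Cross-tabulation of significant slope signs against major anthrome types.

For each sign of the fire-population relationship (positive, negative) the
table gives the share of classified area falling in each of the six major
anthrome types — the land-use fingerprint of where people amplify versus
suppress fire.  Shares are area-weighted by default (latitude-corrected
cell areas); a cell-count basis is available for diagnostics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grid_data import ANTHROME_MAJOR_TYPES

#: the 21 anthrome classes grouped into 6 major types
ANTHROME_TO_MAJOR = {
    "Urban": "DenseSettlement",
    "Dense settlements": "DenseSettlement",
    "Rice villages": "Villages",
    "Irrigated villages": "Villages",
    "Cropped and pastoral villages": "Villages",
    "Pastoral villages": "Villages",
    "Rainfed villages": "Villages",
    "Rainfed mosaic villages": "Villages",
    "Residential irrigated cropland": "Croplands",
    "Residential rainfed mosaic cropland": "Croplands",
    "Populated irrigated cropland": "Croplands",
    "Populated rainfed cropland": "Croplands",
    "Remote croplands": "Croplands",
    "Residential rangelands": "Rangelands",
    "Populated rangelands": "Rangelands",
    "Remote rangelands": "Rangelands",
    "Populated forest": "Forest",
    "Remote forest": "Forest",
    "Wild forest": "Wildlands",
    "Sparse trees": "Wildlands",
    "Barren": "Wildlands",
}
_CODE_TO_NAME = {i + 1: name for i, name in enumerate(ANTHROME_TO_MAJOR)}


def map_anthrome_to_major(anthrome) -> str:
    """Major type of one of the 21 anthrome classes (name or code 1-21)."""
    if isinstance(anthrome, (int, np.integer)):
        if anthrome not in _CODE_TO_NAME:
            raise ValueError(f"unknown anthrome code: {anthrome}")
        anthrome = _CODE_TO_NAME[int(anthrome)]
    if anthrome in ANTHROME_MAJOR_TYPES:  # already a major type
        return anthrome
    if anthrome not in ANTHROME_TO_MAJOR:
        raise ValueError(f"unknown anthrome class: {anthrome!r}")
    return ANTHROME_TO_MAJOR[anthrome]


def crosstab_anthromes(sig_map: pd.DataFrame, cells: pd.DataFrame,
                       basis: str = "area") -> pd.DataFrame:
    """Per-sign anthrome shares of the significantly classified cells.

    Returns a frame indexed by sign ('positive', 'negative') with one
    column per major anthrome type plus 'missing' for unlabelled cells;
    rows sum to 1.  Empty when no cell is significant (with a warning).
    """
    if basis not in ("area", "count"):
        raise ValueError("basis must be 'area' or 'count'")
    if len(sig_map) != len(cells):
        raise ValueError("sig_map and cells must align")
    slope_class = sig_map["slope_class"].to_numpy()
    major = cells["anthrome"].map(
        lambda a: "missing" if pd.isna(a) else map_anthrome_to_major(a)).to_numpy()
    weight = (cells["cell_area"].to_numpy(dtype=float) if basis == "area"
              else np.ones(len(cells)))

    cols = list(ANTHROME_MAJOR_TYPES) + ["missing"]
    rows = {}
    for sign in ("positive", "negative"):
        sel = slope_class == sign
        total = weight[sel].sum()
        if total == 0:
            continue
        rows[sign] = {c: float(weight[sel & (major == c)].sum() / total) for c in cols}
    if not rows:
        warnings.warn("no significant cells: empty cross-tabulation")
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame.from_dict(rows, orient="index")[cols]
    out.index.name = "sign"
    return out
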