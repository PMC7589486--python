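"""Choroidal sublayer arithmetic for EDI-OCT caliper readings.

The subfoveal choroidal thickness (SFCT) spans Bruch's membrane to the outer
margin of the large-vessel (Haller's) layer; the inner choriocapillaris-
Sattler's thickness is the difference SFCT minus Haller.  Thicknesses enter
as adjudicated caliper measurements in micrometres — OCT image segmentation
is out of scope here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def inner_layer_thickness(sfct_um: float, haller_um: float) -> float:
    """Choriocapillaris-Sattler thickness (µm) = SFCT - Haller's layer.

    Raises if either reading is negative or Haller exceeds the total
    choroidal thickness, which indicates inconsistent caliper placement.
    """
    if sfct_um < 0 or haller_um < 0:
        raise ValueError("thicknesses must be non-negative")
    if haller_um > sfct_um:
        raise ValueError(
            f"Haller thickness {haller_um} µm exceeds SFCT {sfct_um} µm: "
            "inconsistent caliper measurements")
    return sfct_um - haller_um


def add_inner_layer(cohort: pd.DataFrame, sfct_col: str = "sfct_um",
                    haller_col: str = "haller_um",
                    out_col: str = "inner_layer_um") -> pd.DataFrame:
    """Append the computed inner-layer column to a cohort table."""
    sfct = cohort[sfct_col].to_numpy(dtype=float)
    haller = cohort[haller_col].to_numpy(dtype=float)
    bad = np.flatnonzero(haller > sfct)
    if bad.size:
        raise ValueError(f"Haller > SFCT at rows {bad.tolist()}")
    out = cohort.copy()
    out[out_col] = sfct - haller
    return out
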