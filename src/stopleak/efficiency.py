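"""Transformation-efficiency computation and positive-control normalization.

Efficiency is colonies recovered per cell subjected to transformation.
Because absolute efficiencies vary strongly between transformation
experiments, each replicate's efficiencies are expressed relative to a
positive-control construct transformed in the same experiment (by default
the control selected for photoautotrophic growth), whose row maps to
exactly 100%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError


def transformation_efficiency(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``efficiency`` column: colonies / cells_plated per row."""
    out = counts.copy()
    out["efficiency"] = out["colonies"].to_numpy(dtype=float) / out[
        "cells_plated"
    ].to_numpy(dtype=float)
    return out


def normalize_to_positive_control(
    records: pd.DataFrame,
    control_construct: str,
    control_selection: str | None = "photoautotrophy",
) -> pd.DataFrame:
    """Fill ``relative_percent`` = 100 * efficiency / control efficiency.

    The control is matched within the same replicate (each transformation
    experiment has its own control plate).  ``control_selection`` narrows
    the control rows to one selection regime; pass None to match on
    construct alone.  If several control rows match, their mean efficiency
    is used.  A missing or zero-efficiency control raises
    :class:`AnalysisError` naming the replicate.
    """
    out = records.copy()
    out["relative_percent"] = np.nan
    for replicate, group in records.groupby("replicate", sort=False):
        mask = group["construct"] == control_construct
        if control_selection is not None:
            mask &= group["selection"] == control_selection
        control = group.loc[mask, "efficiency"]
        if len(control) == 0:
            raise AnalysisError(
                f"replicate {replicate!r}: no control rows for construct "
                f"{control_construct!r}"
            )
        control_eff = float(control.mean())
        if control_eff <= 0:
            raise AnalysisError(
                f"replicate {replicate!r}: control efficiency is {control_eff}"
            )
        idx = group.index
        out.loc[idx, "relative_percent"] = (
            100.0 * records.loc[idx, "efficiency"].to_numpy() / control_eff
        )
    return out
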