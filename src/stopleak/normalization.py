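"""Blank correction, per-cell normalization and control-population scaling.

The measurement model for a screen well is additive in an instrument
baseline (measured by blank wells containing medium only), so the first
step subtracts the per-plate mean blank reading channel by channel.
Zeroed Venus fluorescence is then divided by zeroed absorbance (OD750) or
zeroed chlorophyll fluorescence to correct for the amount of cells in the
well, and finally expressed as a multiple of the mean of a no-reporter
("no Venus") control population screened alongside the samples, so that a
value of 1 means "typical autofluorescence".

Wells whose zeroed denominator is not strictly positive (above a
configurable floor) give unstable or meaningless ratios; they are flagged
invalid and carried through, never silently dropped, so record counts stay
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError

DENOMINATORS = ("od750", "chl")

#: Columns of a transformant record table (one row per annotated sample well).
RECORD_COLUMNS = [
    "construct",
    "strain",
    "replicate",
    "plate_id",
    "well",
    "zeroed_venus",
    "zeroed_denominator",
    "normalized_venus",
    "valid",
]


@dataclass(frozen=True)
class ChlorophyllEstimate:
    """Chlorophyll concentration estimated from a crude-extract absorbance
    difference: ``concentration = 0.11 * (od680 - od770)`` in ug/ul."""

    od680: float
    od770: float
    concentration: float
    warning: str | None = None


#: ug chlorophyll per ul per unit of (OD680 - OD770) absorbance difference.
CHLOROPHYLL_COEFFICIENT = 0.11


def chlorophyll_concentration(od680: float, od770: float) -> ChlorophyllEstimate:
    """Estimate chlorophyll concentration (ug/ul) from crude-extract
    absorbance at 680 nm, corrected by absorbance at 770 nm."""
    od680, od770 = float(od680), float(od770)
    if not (np.isfinite(od680) and np.isfinite(od770)):
        raise ConfigError("chlorophyll_concentration requires finite absorbances")
    conc = CHLOROPHYLL_COEFFICIENT * (od680 - od770)
    warning = None
    if conc < 0:
        warning = "od770 exceeds od680; negative chlorophyll estimate"
    return ChlorophyllEstimate(od680, od770, conc, warning)


def zero_readings(measurements: pd.DataFrame, per_plate: bool = True) -> pd.DataFrame:
    """Subtract blank-well baselines from sample readings.

    For each plate (or globally with ``per_plate=False``) the arithmetic
    mean of the blank wells is computed per channel and subtracted from
    every sample well.  Blank rows are consumed: the returned table
    contains sample wells only, with the three reading columns replaced by
    their zeroed values.

    Raises :class:`ConfigError` if any plate has no blank well.
    """
    channels = ["od750", "venus", "chl"]
    blanks = measurements.loc[measurements["role"] == "blank"]
    samples = measurements.loc[measurements["role"] == "sample"].copy()

    if per_plate:
        plates = measurements["plate_id"].unique()
        missing = [p for p in plates if p not in set(blanks["plate_id"])]
        if missing:
            raise ConfigError(f"no blank wells on plate(s) {missing}")
        means = blanks.groupby("plate_id")[channels].mean()
        baseline = means.reindex(samples["plate_id"]).to_numpy()
    else:
        if len(blanks) == 0:
            raise ConfigError("no blank wells in dataset")
        baseline = blanks[channels].mean().to_numpy()

    samples[channels] = samples[channels].to_numpy() - baseline
    return samples.reset_index(drop=True)


def normalize_per_cell(
    zeroed: pd.DataFrame,
    layout: pd.DataFrame,
    denominator: str = "od750",
    denominator_floor: float = 0.0,
) -> pd.DataFrame:
    """Divide zeroed Venus fluorescence by a zeroed cell-amount proxy.

    ``denominator`` selects absorbance (``"od750"``) or chlorophyll
    fluorescence (``"chl"``).  Wells whose zeroed denominator is <= the
    positivity floor are flagged ``valid=False`` (``normalized_venus`` is
    NaN for them) and are excluded from every downstream population
    statistic, but remain present in the table.

    Returns a transformant-record table (see :data:`RECORD_COLUMNS`).
    """
    if denominator not in DENOMINATORS:
        raise ConfigError(
            f"unknown denominator {denominator!r}; expected one of {DENOMINATORS}"
        )
    merged = layout.merge(zeroed, on=["plate_id", "well"], how="inner")
    records = merged.loc[:, ["construct", "strain", "replicate", "plate_id", "well"]]
    records = records.copy()
    records["zeroed_venus"] = merged["venus"].to_numpy()
    records["zeroed_denominator"] = merged[denominator].to_numpy()
    valid = records["zeroed_denominator"].to_numpy() > denominator_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = records["zeroed_venus"].to_numpy() / records[
            "zeroed_denominator"
        ].to_numpy()
    records["normalized_venus"] = np.where(valid, ratio, np.nan)
    records["valid"] = valid
    return records


def scale_to_control(
    records: pd.DataFrame, control_construct: str, value_col: str = "normalized_venus"
) -> pd.DataFrame:
    """Express normalized fluorescence in multiples of the control mean.

    Within each replicate (the control population is transformed and
    screened alongside the samples of its own batch), every record's value
    is divided by the mean over valid control-construct records, filling
    the ``control_scaled_venus`` column.  By construction the control
    population's scaled mean is exactly 1.

    Raises :class:`AnalysisError` if a replicate has fewer than two valid
    control records or a non-positive control mean.
    """
    out = records.copy()
    out["control_scaled_venus"] = np.nan
    for replicate, group in records.groupby("replicate", sort=False):
        controls = group.loc[
            (group["construct"] == control_construct) & group["valid"], value_col
        ]
        if len(controls) < 2:
            raise AnalysisError(
                f"replicate {replicate!r}: control population "
                f"{control_construct!r} has {len(controls)} valid record(s); "
                "need at least 2"
            )
        mean = float(controls.mean())
        if mean <= 0:
            raise AnalysisError(
                f"replicate {replicate!r}: non-positive control mean {mean}"
            )
        idx = group.index
        out.loc[idx, "control_scaled_venus"] = (
            records.loc[idx, value_col].to_numpy() / mean
        )
    out.loc[~out["valid"], "control_scaled_venus"] = np.nan
    return out
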