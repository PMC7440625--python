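"""Hit calling against a control-population tolerance interval.

A transformant "expresses detectable Venus" when its control-scaled
fluorescence falls outside a 95% interval of the no-reporter control
population.  The interval brackets individual control transformants (a
population/tolerance interval, mean +/- 1.96 sd), not the mean: single
outlying wells are what the screen flags.  An empirical percentile variant
and a one-sided (upper-tail) variant are available; boundary values count
as NOT expressing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigError

INTERVAL_MODES = ("normal", "percentile")
SIDEDNESS = ("two", "upper")


@dataclass(frozen=True)
class DetectionInterval:
    """Detection band on the control-scaled fluorescence scale."""

    lower: float
    upper: float
    control_mean: float
    control_sd: float
    n_control: int


def detection_interval(
    control_values,
    mode: str = "normal",
    sidedness: str = "two",
    level: float = 0.95,
) -> DetectionInterval:
    """Compute the detection band from control-population values.

    ``mode="normal"``: mean +/- z * sample sd, z the two-sided normal
    quantile (1.959964 at the default 95% level); ``mode="percentile"``:
    empirical 2.5/97.5 percentiles.  ``sidedness="upper"`` sets the lower
    bound to -inf and uses the one-sided quantile (1.6449 at 95%).

    Requires at least 3 control values.
    """
    if mode not in INTERVAL_MODES:
        raise ConfigError(f"unknown interval mode {mode!r}")
    if sidedness not in SIDEDNESS:
        raise ConfigError(f"unknown sidedness {sidedness!r}")
    values = np.asarray(control_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise AnalysisError(
            f"detection interval undefined: {values.size} control record(s), need >= 3"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if mode == "normal":
        if sidedness == "two":
            z = stats.norm.ppf(0.5 + level / 2.0)
            lower, upper = mean - z * sd, mean + z * sd
        else:
            z = stats.norm.ppf(level)
            lower, upper = -math.inf, mean + z * sd
    else:
        tail = 100.0 * (1.0 - level) / 2.0
        if sidedness == "two":
            lower = float(np.percentile(values, tail))
            upper = float(np.percentile(values, 100.0 - tail))
        else:
            lower = -math.inf
            upper = float(np.percentile(values, 100.0 * level))
    return DetectionInterval(lower, upper, mean, sd, int(values.size))


def call_expressing(
    records: pd.DataFrame,
    interval: DetectionInterval,
    value_col: str = "control_scaled_venus",
) -> pd.DataFrame:
    """Flag records whose value lies strictly outside the interval.

    Values equal to a bound are not flagged; invalid records are never
    flagged.  Adds a boolean ``expressing`` column.
    """
    out = records.copy()
    v = out[value_col].to_numpy(dtype=float)
    outside = (v < interval.lower) | (v > interval.upper)
    out["expressing"] = outside & out["valid"].to_numpy() & np.isfinite(v)
    return out


def summarize_population(
    records: pd.DataFrame, value_col: str = "control_scaled_venus"
) -> pd.DataFrame:
    """Per (construct, replicate) population summary over valid records.

    Columns: n, mean, sd (sample, n-1 denominator; NaN when n < 2),
    n_expressing, fraction_expressing (NaN when n = 0).  Groups with no
    valid records are emitted with NaN statistics, not dropped.
    """
    rows = []
    for (construct, replicate), group in records.groupby(
        ["construct", "replicate"], sort=True
    ):
        valid = group.loc[group["valid"]]
        n = len(valid)
        values = valid[value_col].to_numpy(dtype=float)
        n_expr = int(valid["expressing"].sum()) if "expressing" in valid else 0
        rows.append(
            {
                "construct": construct,
                "replicate": replicate,
                "n": n,
                "mean": float(values.mean()) if n > 0 else np.nan,
                "sd": float(values.std(ddof=1)) if n > 1 else np.nan,
                "n_expressing": n_expr,
                "fraction_expressing": n_expr / n if n > 0 else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "construct",
            "replicate",
            "n",
            "mean",
            "sd",
            "n_expressing",
            "fraction_expressing",
        ],
    )
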