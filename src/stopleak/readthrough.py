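"""Stop-codon read-through estimation from anchor-rescaled fluorescence.

The central statistic: within each biological replicate, normalized Venus
fluorescence is put on a two-point scale where the mean of the 'stop'
construct population (no read-through product) is 0 and the mean of the
'fusion' construct population (every translation event yields the tagged
protein) is 100.  If per-transformant mRNA expression depends only on the
genomic insertion site — so that the three construct populations share the
same expression distribution — the mean rescaled value of the 'leaky'
construct population estimates the read-through rate in percent directly.
Per-replicate estimates are aggregated as mean +/- standard error across
replicates.

An independent, coarser estimator from immunoblot densitometry (leaky band
intensity as a percentage of the fusion average) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError


@dataclass(frozen=True)
class AnchorScaling:
    """Per-replicate anchor means defining the 0/100 scale."""

    replicate: str
    stop_mean: float
    fusion_mean: float


@dataclass(frozen=True)
class ReadthroughEstimate:
    """Per-replicate leakiness percentages and their aggregate.

    ``se_percent`` is the sample sd (n-1) over replicates divided by
    sqrt(n_replicates); NaN when only one replicate is available.
    """

    per_replicate: tuple[tuple[str, float], ...]
    mean_percent: float
    se_percent: float
    n_replicates: int


def anchor_rescale(
    records: pd.DataFrame,
    stop_construct: str = "stop",
    fusion_construct: str = "fusion",
    value_col: str = "normalized_venus",
) -> tuple[pd.DataFrame, dict[str, AnchorScaling]]:
    """Rescale values so stop mean -> 0 and fusion mean -> 100, per replicate.

    Each replicate uses its own anchor populations (anchors are never
    pooled across replicates).  Both anchors need >= 2 valid records and
    the fusion mean must exceed the stop mean, otherwise the scale is
    undefined and an :class:`AnalysisError` names the replicate.

    Adds a ``rescaled_percent`` column (NaN for invalid records) and
    returns the per-replicate :class:`AnchorScaling`.
    """
    out = records.copy()
    out["rescaled_percent"] = np.nan
    scalings: dict[str, AnchorScaling] = {}
    for replicate, group in records.groupby("replicate", sort=False):
        anchors = {}
        for name, construct in (("stop", stop_construct), ("fusion", fusion_construct)):
            values = group.loc[
                (group["construct"] == construct) & group["valid"], value_col
            ]
            if len(values) < 2:
                raise AnalysisError(
                    f"replicate {replicate!r}: anchor population {construct!r} "
                    f"has {len(values)} valid record(s); need at least 2"
                )
            anchors[name] = float(values.mean())
        stop_mean, fusion_mean = anchors["stop"], anchors["fusion"]
        if fusion_mean <= stop_mean:
            raise AnalysisError(
                f"replicate {replicate!r}: fusion mean {fusion_mean} does not "
                f"exceed stop mean {stop_mean}; rescaling undefined"
            )
        idx = group.index
        out.loc[idx, "rescaled_percent"] = (
            100.0
            * (records.loc[idx, value_col].to_numpy() - stop_mean)
            / (fusion_mean - stop_mean)
        )
        scalings[replicate] = AnchorScaling(replicate, stop_mean, fusion_mean)
    out.loc[~out["valid"], "rescaled_percent"] = np.nan
    return out, scalings


def aggregate_replicates(per_replicate: dict[str, float]) -> ReadthroughEstimate:
    """Aggregate per-replicate leakiness values into mean +/- SE."""
    if not per_replicate:
        raise AnalysisError("no replicates to aggregate")
    values = np.array(list(per_replicate.values()), dtype=float)
    n = values.size
    se = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
    return ReadthroughEstimate(
        per_replicate=tuple(per_replicate.items()),
        mean_percent=float(values.mean()),
        se_percent=se,
        n_replicates=n,
    )


def estimate_readthrough(
    rescaled: pd.DataFrame, leaky_construct: str = "leaky"
) -> ReadthroughEstimate:
    """Estimate read-through percent from anchor-rescaled records.

    The per-replicate leakiness is the mean rescaled value over ALL valid
    leaky-construct records — expressing and non-expressing alike;
    restricting to detection-flagged wells would bias the estimate upward.
    Each replicate needs >= 2 valid leaky records.
    """
    per_replicate: dict[str, float] = {}
    for replicate, group in rescaled.groupby("replicate", sort=False):
        values = group.loc[
            (group["construct"] == leaky_construct) & group["valid"],
            "rescaled_percent",
        ]
        if len(values) < 2:
            raise AnalysisError(
                f"replicate {replicate!r}: leaky population {leaky_construct!r} "
                f"has {len(values)} valid record(s); need at least 2"
            )
        per_replicate[replicate] = float(values.mean())
    return aggregate_replicates(per_replicate)


def estimate_readthrough_from_bands(
    bands: pd.DataFrame,
    fusion_construct: str = "fusion",
    leaky_construct: str = "leaky",
) -> float:
    """Read-through percent from immunoblot band intensities.

    Returns ``100 * mean(leaky intensities) / mean(fusion intensities)``.
    """
    fusion = bands.loc[bands["construct"] == fusion_construct, "intensity"]
    leaky = bands.loc[bands["construct"] == leaky_construct, "intensity"]
    if len(fusion) == 0 or float(fusion.mean()) <= 0:
        raise AnalysisError("fusion bands absent or non-positive mean intensity")
    if len(leaky) == 0:
        raise AnalysisError("no leaky-construct bands")
    return 100.0 * float(leaky.mean()) / float(fusion.mean())
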