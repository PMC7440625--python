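"""End-to-end orchestration of the screen-analysis stages.

Chains blank zeroing -> per-cell normalization -> (control scaling +
detection calling) and/or (anchor rescaling + read-through estimation),
with optional transformation-efficiency and calibration stages, keeping a
stage-by-stage log of record counts so that records in = records out +
records flagged is verifiable at every step.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import detection, normalization, plate_io, readthrough
from .errors import ConfigError
from .readthrough import ReadthroughEstimate


@dataclass
class StageLog:
    """Record conservation at one stage: ``n_in == n_out + n_flagged``.

    ``n_out`` counts records passed downstream as valid; ``n_flagged``
    counts records consumed (blank wells) or flagged invalid (carried in
    the tables, excluded from statistics).
    """

    stage: str
    n_in: int
    n_out: int
    n_flagged: int


@dataclass
class ScreenResult:
    """All tables and statistics produced by one pipeline run."""

    records: pd.DataFrame
    summaries: pd.DataFrame | None = None
    intervals: dict[str, detection.DetectionInterval] = field(default_factory=dict)
    estimate: ReadthroughEstimate | None = None
    anchors: dict[str, readthrough.AnchorScaling] = field(default_factory=dict)
    log: list[StageLog] = field(default_factory=list)

    def summary_json(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "stages": [asdict(entry) for entry in self.log],
        }
        if self.estimate is not None:
            se = self.estimate.se_percent
            out["readthrough"] = {
                "mean_percent": self.estimate.mean_percent,
                "se_percent": None if math.isnan(se) else se,
                "n_replicates": self.estimate.n_replicates,
                "per_replicate": dict(self.estimate.per_replicate),
            }
        if self.summaries is not None:
            out["populations"] = json.loads(
                self.summaries.to_json(orient="records")
            )
        return out


def analyze_screen(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    denominator: str = "od750",
    denominator_floor: float = 0.0,
    per_plate_blanks: bool = True,
    control_construct: str | None = "no_venus",
    stop_construct: str | None = "stop",
    fusion_construct: str | None = "fusion",
    leaky_construct: str | None = "leaky",
    interval_mode: str = "normal",
    sidedness: str = "two",
    level: float = 0.95,
) -> ScreenResult:
    """Run the full analysis on in-memory tables.

    ``control_construct=None`` skips control scaling and detection;
    ``stop_construct``/``fusion_construct``/``leaky_construct=None`` skips
    anchor rescaling and read-through estimation.  At least one of the two
    branches must be enabled.
    """
    log: list[StageLog] = []

    n_in = len(measurements)
    zeroed = normalization.zero_readings(measurements, per_plate=per_plate_blanks)
    log.append(StageLog("zero_readings", n_in, len(zeroed), n_in - len(zeroed)))

    records = normalization.normalize_per_cell(
        zeroed, layout, denominator=denominator, denominator_floor=denominator_floor
    )
    n_invalid = int((~records["valid"]).sum())
    log.append(
        StageLog("normalize_per_cell", len(records), len(records) - n_invalid, n_invalid)
    )

    result = ScreenResult(records=records, log=log)

    if control_construct is not None:
        records = normalization.scale_to_control(records, control_construct)
        log.append(
            StageLog(
                "scale_to_control", len(records), len(records) - n_invalid, n_invalid
            )
        )
        for replicate, group in records.groupby("replicate", sort=False):
            controls = group.loc[
                (group["construct"] == control_construct) & group["valid"],
                "control_scaled_venus",
            ]
            interval = detection.detection_interval(
                controls, mode=interval_mode, sidedness=sidedness, level=level
            )
            result.intervals[replicate] = interval
            idx = group.index
            flagged = detection.call_expressing(records.loc[idx], interval)
            records.loc[idx, "expressing"] = flagged["expressing"]
        records["expressing"] = records["expressing"].astype(bool)
        log.append(
            StageLog(
                "call_expressing", len(records), len(records) - n_invalid, n_invalid
            )
        )
        result.summaries = detection.summarize_population(records)

    do_readthrough = (
        stop_construct is not None
        and fusion_construct is not None
        and leaky_construct is not None
    )
    if do_readthrough:
        records, anchors = readthrough.anchor_rescale(
            records,
            stop_construct=stop_construct,
            fusion_construct=fusion_construct,
        )
        log.append(
            StageLog(
                "anchor_rescale", len(records), len(records) - n_invalid, n_invalid
            )
        )
        result.anchors = anchors
        result.estimate = readthrough.estimate_readthrough(
            records, leaky_construct=leaky_construct
        )
    if control_construct is None and not do_readthrough:
        raise ConfigError(
            "nothing to do: enable control scaling/detection or anchor rescaling"
        )
    result.records = records
    return result


def estimate_from_screen(
    measurements: pd.DataFrame,
    layout: pd.DataFrame,
    denominator: str = "od750",
    stop_construct: str = "stop",
    fusion_construct: str = "fusion",
    leaky_construct: str = "leaky",
) -> ReadthroughEstimate:
    """Shortcut: zeroing -> normalization -> anchor rescale -> estimate."""
    zeroed = normalization.zero_readings(measurements)
    records = normalization.normalize_per_cell(zeroed, layout, denominator=denominator)
    rescaled, _ = readthrough.anchor_rescale(
        records, stop_construct=stop_construct, fusion_construct=fusion_construct
    )
    return readthrough.estimate_readthrough(rescaled, leaky_construct=leaky_construct)


def write_outputs(result: ScreenResult, output_dir: str | Path) -> None:
    """Write per-stage CSVs and the JSON run summary to ``output_dir``.

    Read-through percentages get a companion display column rounded to one
    decimal, the convention used when quoting leakiness percentages.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = result.records.copy()
    if "rescaled_percent" in records:
        records["rescaled_percent_display"] = records["rescaled_percent"].round(1)
    plate_io.write_summary(records, outdir / "records.csv", allow_empty=True)
    if result.summaries is not None:
        plate_io.write_summary(
            result.summaries, outdir / "population_summaries.csv", allow_empty=True
        )
    if result.estimate is not None:
        per_rep = pd.DataFrame(
            result.estimate.per_replicate, columns=["replicate", "leakiness_percent"]
        )
        per_rep["leakiness_percent_display"] = per_rep["leakiness_percent"].round(1)
        plate_io.write_summary(per_rep, outdir / "readthrough_per_replicate.csv")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary_json(), fh, indent=2)
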