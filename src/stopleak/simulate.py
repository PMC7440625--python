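"""Synthetic transformant-screen generator.

Emulates the statistical structure of a microplate fluorescence screen of
algal transformant populations:

* random genomic integration gives log-normal transformant-to-transformant
  expression variation (``log_expression_mean``/``log_expression_sd``);
* a fraction of transformants is completely silenced (expression 0);
* each construct translates the reporter in a fixed fraction ``rho`` of
  translation events (fusion 1, leaky r, stop and no-reporter 0), so the
  reporter signal scales with ``rho * expression``;
* every cell autofluoresces in the reporter channel;
* wells differ in cell density (log-normal), which multiplies all
  cell-derived signals and is read out by absorbance and by the
  chlorophyll channel;
* each channel has an instrument baseline (measured by blank wells) and
  additive Gaussian noise; negative raw readings are permitted.

The generator is bit-deterministic: identical config (including seed)
reproduces the dataset exactly.  Outputs use the ``plate_io`` table
schemas, so every pipeline stage can be exercised without external data,
and a ground-truth table enables parameter-recovery tests.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_CONSTRUCTS: tuple[tuple[str, float], ...] = (
    ("no_venus", 0.0),
    ("stop", 0.0),
    ("leaky", 0.025),  # default encodes a ~2.5% read-through rate
    ("fusion", 1.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic transformant screen.

    Units: densities are in absorbance (OD750) units; gains are instrument
    fluorescence units per OD unit (``venus_gain`` additionally per unit of
    true expression); noise sds and baselines are in the raw units of their
    channel.
    """

    seed: int = 0
    n_replicates: int = 3
    wells_per_construct: int = 96
    n_blanks_per_plate: int = 4
    constructs: tuple[tuple[str, float], ...] = DEFAULT_CONSTRUCTS
    log_expression_mean: float = 0.0
    log_expression_sd: float = 1.0
    silenced_fraction: float = 0.1
    autofluorescence_per_cell: float = 50.0
    venus_gain: float = 2000.0
    chl_gain: float = 1500.0
    density_log_sd: float = 0.25
    blank_venus: float = 100.0
    blank_od750: float = 0.04
    blank_chl: float = 30.0
    noise_sd_venus: float = 20.0
    noise_sd_od750: float = 0.005
    noise_sd_chl: float = 5.0
    strain: str = "T222"

    def validate(self) -> None:
        problems = []
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.wells_per_construct < 2:
            problems.append("wells_per_construct must be >= 2")
        if self.n_blanks_per_plate < 1:
            problems.append("n_blanks_per_plate must be >= 1")
        if len(self.constructs) == 0:
            problems.append("constructs must be non-empty")
        names = [c for c, _ in self.constructs]
        if len(set(names)) != len(names):
            problems.append("construct identifiers must be unique")
        for name, rho in self.constructs:
            if not 0.0 <= rho <= 1.0:
                problems.append(f"translation fraction of {name!r} not in [0, 1]")
        if not 0.0 <= self.silenced_fraction <= 1.0:
            problems.append("silenced_fraction not in [0, 1]")
        for attr in (
            "log_expression_sd",
            "density_log_sd",
            "noise_sd_venus",
            "noise_sd_od750",
            "noise_sd_chl",
        ):
            if getattr(self, attr) < 0:
                problems.append(f"{attr} must be >= 0")
        if problems:
            raise ConfigError("; ".join(problems))


def _well_labels(n: int, n_columns: int = 24) -> list[str]:
    """Row-letter + column-number labels, filling plates row by row.

    Rows run A..Z then AA, AB, ... so plates larger than 96 wells (several
    construct populations screened side by side) still get well-formed
    labels.
    """
    letters = string.ascii_uppercase
    labels = []
    for i in range(n):
        row, col = divmod(i, n_columns)
        name = ""
        row += 1
        while row > 0:
            row, rem = divmod(row - 1, 26)
            name = letters[rem] + name
        labels.append(f"{name}{col + 1}")
    return labels


def simulate_screen(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic screen.

    Each replicate is one plate holding ``n_blanks_per_plate`` blank wells
    followed by ``wells_per_construct`` sample wells per construct.  Per
    sample well *i* with construct translation fraction ``rho``:

    * density ``A_i ~ lognormal(0, density_log_sd)``
    * expression ``E_i = 0`` with probability ``silenced_fraction``, else
      ``lognormal(log_expression_mean, log_expression_sd)``
    * venus  = blank_venus + A_i * (alpha + venus_gain * rho * E_i) + noise
    * od750  = blank_od750 + A_i + noise
    * chl    = blank_chl + chl_gain * A_i + noise

    Blank wells read baseline + noise in every channel.

    Returns ``(measurements, layout, ground_truth)`` in plate_io schemas;
    ground truth has columns plate_id, well, construct, replicate,
    true_expression, silenced, true_density.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    meas_rows, layout_rows, truth_rows = [], [], []
    n_samples = config.wells_per_construct * len(config.constructs)
    for rep_index in range(1, config.n_replicates + 1):
        replicate = f"rep{rep_index}"
        plate_id = f"P{rep_index}"
        labels = _well_labels(config.n_blanks_per_plate + n_samples)
        blank_labels = labels[: config.n_blanks_per_plate]
        sample_labels = labels[config.n_blanks_per_plate :]

        noise = rng.normal(size=(config.n_blanks_per_plate, 3))
        for j, well in enumerate(blank_labels):
            meas_rows.append(
                (
                    plate_id,
                    well,
                    "blank",
                    config.blank_od750 + config.noise_sd_od750 * noise[j, 0],
                    config.blank_venus + config.noise_sd_venus * noise[j, 1],
                    config.blank_chl + config.noise_sd_chl * noise[j, 2],
                )
            )

        cursor = 0
        for construct, rho in config.constructs:
            n = config.wells_per_construct
            wells = sample_labels[cursor : cursor + n]
            cursor += n
            density = rng.lognormal(mean=0.0, sigma=config.density_log_sd, size=n)
            silenced = rng.random(n) < config.silenced_fraction
            expression = rng.lognormal(
                mean=config.log_expression_mean,
                sigma=config.log_expression_sd,
                size=n,
            )
            expression[silenced] = 0.0
            noise = rng.normal(size=(n, 3))
            od750 = config.blank_od750 + density + config.noise_sd_od750 * noise[:, 0]
            venus = (
                config.blank_venus
                + density
                * (
                    config.autofluorescence_per_cell
                    + config.venus_gain * rho * expression
                )
                + config.noise_sd_venus * noise[:, 1]
            )
            chl = (
                config.blank_chl
                + config.chl_gain * density
                + config.noise_sd_chl * noise[:, 2]
            )
            for j, well in enumerate(wells):
                meas_rows.append(
                    (plate_id, well, "sample", od750[j], venus[j], chl[j])
                )
                layout_rows.append(
                    (plate_id, well, construct, config.strain, replicate)
                )
                truth_rows.append(
                    (
                        plate_id,
                        well,
                        construct,
                        replicate,
                        expression[j],
                        bool(silenced[j]),
                        density[j],
                    )
                )

    measurements = pd.DataFrame(
        meas_rows, columns=["plate_id", "well", "role", "od750", "venus", "chl"]
    )
    layout = pd.DataFrame(
        layout_rows, columns=["plate_id", "well", "construct", "strain", "replicate"]
    )
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "plate_id",
            "well",
            "construct",
            "replicate",
            "true_expression",
            "silenced",
            "true_density",
        ],
    )
    return measurements, layout, ground_truth


def simulate_colony_counts(
    rates: dict[str, float],
    cells_plated: int,
    seed: int,
    replicate: str = "rep1",
    selection: str = "antibiotic",
) -> pd.DataFrame:
    """Poisson colony counts for per-construct true efficiencies.

    ``colonies ~ Poisson(rate * cells_plated)`` per construct, reproducible
    under ``seed``.  Returns a table in the colony-count schema.
    """
    if cells_plated <= 0:
        raise ConfigError("cells_plated must be positive")
    if any(rate < 0 for rate in rates.values()):
        raise ConfigError("efficiencies must be >= 0")
    rng = np.random.default_rng(seed)
    rows = [
        (
            replicate,
            construct,
            selection,
            int(rng.poisson(rate * cells_plated)),
            cells_plated,
        )
        for construct, rate in rates.items()
    ]
    return pd.DataFrame(
        rows, columns=["replicate", "construct", "selection", "colonies", "cells_plated"]
    )
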