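# stopleak

Population-level quantification of stop-codon read-through ("leakiness")
and transgene expression from microplate fluorescence screens of
*Chlamydomonas reinhardtii* transformant populations.

## The problem

Nuclear transgenes in Chlamydomonas integrate at random genomic
positions, so individual transformants of the same construct differ in
expression by orders of magnitude and a fraction is silenced entirely.
Single-strain comparisons are therefore confounded by the insertion
site. When a leaky stop codon is placed between a gene and a downstream
fluorescent reporter (Venus), the read-through rate can still be
estimated from *population averages*: assuming the expression
distribution across transformants depends only on the genomic locus,
normalized Venus fluorescence averaged over a population of
leaky-construct transformants, put on a scale where the stop-construct
population mean is 0% and the translational-fusion population mean is
100%, reads out leakiness directly:

```
L = 100 · (mean_leaky − mean_stop) / (mean_fusion − mean_stop)   [% per replicate]
```

with `mean_*` the per-replicate means of blank-zeroed, per-cell
normalized Venus fluorescence, and the final estimate the mean ± SE of
`L` across biological replicates.

The package implements the full pipeline — blank zeroing, per-cell
normalization (OD750 or chlorophyll), scaling to a no-reporter control
population, 95% tolerance-interval detection calling, anchor rescaling
and replicate aggregation — plus transformation-efficiency analysis,
a fluorescence-vs-immunoblot calibration regression, and a synthetic
screen generator with known ground truth so every stage is testable
without external data. See `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate a screen at default conditions (3 replicate plates, 96 wells
per construct for the no-venus / stop / leaky / fusion populations, true
read-through fraction 0.025) and estimate leakiness:

```
$ stopleak simulate --seed 1 --out sim
INFO simulated 1164 wells across 3 plate(s)
$ stopleak readthrough --measurements sim/measurements.csv --layout sim/layout.csv --out rt
INFO read-through 2.76% +/- 0.23 over 3 replicate(s)
$ cat rt/readthrough_per_replicate.csv
replicate,leakiness_percent,leakiness_percent_display
rep1,2.4061611233875544,2.4
rep2,3.1877110527709256,3.2
rep3,2.69831690182259,2.7
```

The three per-replicate values are the mean rescaled fluorescence over
all valid leaky-construct wells of each plate; their mean (2.76%) is the
leakiness estimate and the SE (±0.23) its cross-replicate uncertainty —
one Monte-Carlo draw scattered around the simulated truth of 2.5%. The
same computation is available as a library call:

```python
from stopleak import SimulationConfig, simulate_screen, estimate_from_screen

measurements, layout, truth = simulate_screen(SimulationConfig(seed=1))
est = estimate_from_screen(measurements, layout)
print(est.mean_percent, est.se_percent)   # 2.7640... 0.2279...
```

Other subcommands: `normalize`, `detect` (control scaling + expressing
calls + population summaries), `efficiency` (colony counts → relative
transformation efficiencies), `calibrate` (fluorescence–band-intensity
OLS and detection-limit inversion), and `run` (everything, from a YAML
config). All inputs are plain CSV in the schemas documented in
`stopleak.plate_io`; exit codes are 0 (ok), 2 (schema/config), 3
(statistic undefined), 4 (I/O).

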