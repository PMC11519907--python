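# cytoshell

Dual-frequency impedance cytometry toolkit for discriminating
**microplastics from phytoplankton** in high-conductivity (seawater-like)
media, in the 1.5–10 μm size range.

Impedance cytometers measure the complex electrical impedance of single
particles as they transit microelectrodes. In a conductive medium the low
frequency (1 MHz) signal reports particle **volume**, while the high
frequency (500 MHz) signal probes **internal electrical composition**:
membranous cells and solid plastics produce distinct high-frequency
phases. `cytoshell` implements the full computational chain around this
idea:

- **Forward dielectric model** — the complex Clausius–Mossotti (CM)
  factor `f_CM = (ε*_p − ε*_m)/(ε*_p + 2ε*_m)` of homogeneous beads and
  shelled cells, with `ε* = ε_r ε₀ − jσ/ω`. Cells are modelled as a
  cytoplasm core containing lipid vesicles (Maxwell–Garnett mixing)
  wrapped in a plasma membrane and an organic scale layer, collapsed
  shell-by-shell to an equivalent homogeneous sphere
  (`ε_eq = ε_sh (γ³ + 2G)/(γ³ − G)`).
- **Spectrum fitting** — population-averaged current spectra are
  referenced to a calibration bead and fitted by minimising the mean
  squared error with a bounded, derivative-free **compass (pattern)
  search**; dielectric relaxations are extracted from the imaginary-part
  peak or the maximum real-part gradient.
- **Event classification** — electrical diameter (cube root of the 1 MHz
  real signal, bead-calibrated) and baseline-subtracted 500 MHz phase
  feed a **KNN classifier** (k = 11, standardized Euclidean metric,
  n = 3000 training vectors per class), with a limit of detection of
  1.5 μm. Per-class concentrations and **recovery rates**
  (100 × classified / true concentration) quantify accuracy; a binary
  (microplastic vs pooled-biological) mode is included.
- **Synthetic instrument** — seeded generators for monoculture and mixed
  event tables (lognormal sizes, diameter-dependent phase noise,
  coliving-bacteria contamination, bead spike-ins, Poisson arrivals),
  noisy population spectra, and simplified nine-electrode multipeak
  waveforms with matched-filter event detection and velocity estimation.

## Worked example

```python
from cytoshell import (
    FrequencyGrid, cm_spectrum, relaxation_frequency,
    isochrysis_galbana, seawater_medium,
    default_experiment_config, run_mixed_culture_experiment,
)

# dielectric relaxation of the fitted I. galbana double-shell model
grid = FrequencyGrid.log_spaced(250e3, 550e6, 200)
spectrum = cm_spectrum(isochrysis_galbana(), seawater_medium(), grid)
print(f"Im-peak relaxation: {relaxation_frequency(spectrum) / 1e6:.0f} MHz")

# full synthetic mixed-culture experiment (5 classes, n=3000, k=11)
result = run_mixed_culture_experiment(default_experiment_config())
for label, rec in result.recovery.items():
    print(f"{label:14s} recovery {rec:6.1f} %")
```

prints (seeds 1/2, the package defaults):

```
Im-peak relaxation: 518 MHz
microplastic   recovery   99.7 %
i_galbana      recovery   99.9 %
c_vulgaris     recovery   98.2 %
p_purpureum    recovery  100.0 %
synechococcus  recovery  159.8 %
```

All classes except the smallest recover their true concentration within
a few percent. *Synechococcus* is systematically **over**-estimated: most
of its population lies below the 1.5 μm detection limit, and coliving
bacteria carried in from the other (non-axenic) cultures are
misclassified into it — the same failure mode seen on real instruments.
The 518 MHz figure is the global in-band imaginary-part maximum of the
default cell model; see `docs/methods.md` for why this quantity is
strongly radius-dependent.

The same experiments are scriptable from a shell:

```bash
cytoshell run-mixed --seed 1 --out out/          # five-class experiment
cytoshell run-binary --seed 1 --out out/         # microplastic vs biological
cytoshell simulate --seed 1 --out out/tables/    # just the event tables
cytoshell fit-spectrum --spectrum s.csv --spec fit.json --out result.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch each run: the recovered inner-core and
scale-layer permittivities of a noiseless double-shell spectrum fit
(compass search initialised at 1.3× the generating values), the
imaginary-peak relaxation frequency of the default cell model on a
200-point log grid, and the worst-case recovery deviation of the full
mixed-culture experiment over all classes except the smallest. Results
are written as JSON keyed by target id.
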