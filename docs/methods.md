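# Methods

## Dielectric forward model

A particle in a medium of complex permittivity `ε*_m` polarises according
to the Clausius–Mossotti factor

    f_CM(ω) = (ε*_p − ε*_m) / (ε*_p + 2 ε*_m),
    ε* = ε_r ε₀ − j σ / ω            (e^{+jωt} sign convention)

with `Re f_CM ∈ [−1/2, 1]` for passive materials. The sign convention is a
package-wide choice (loss appears as a negative imaginary part of `ε*`,
and interfacial relaxations appear as positive peaks of `Im f_CM`); all
formulas and tests assume it consistently.

Cells are concentric-sphere composites reduced to an equivalent
homogeneous sphere in two steps:

1. **Core mixing.** The cytoplasm host with a volume fraction `φ` of
   spherical lipid inclusions is homogenised with Maxwell–Garnett:
   `ε_mix = ε_host (1 + 2φF)/(1 − φF)`, `F = (ε_inc − ε_host)/(ε_inc + 2ε_host)`.
   This is exact at `φ ∈ {0, 1}` and appropriate for dilute, roughly
   spherical vesicles; it is *not* symmetric in host/inclusion, so the
   host must be the connected phase (cytoplasm).
2. **Shell collapse.** Each layer (membrane, then scale layer) is
   absorbed innermost-first via
   `ε_eq = ε_sh (γ³ + 2G)/(γ³ − G)`, `γ = r_out/r_in`,
   `G = (ε_in − ε_sh)/(ε_in + 2ε_sh)`.
   Collapsing a layer split into same-material sub-layers is an exact
   identity (tested to 1e−10 relative), so layer bookkeeping cannot
   change the result.

For a homogeneous sphere the resulting `f_CM(ω)` is exactly a single
Debye relaxation with the Maxwell–Wagner time constant
`τ = ε₀(ε_p + 2ε_m)/(σ_p + 2σ_m)`; this closed form is the independent
oracle for both the spectrum code and the relaxation extractor.

### Default parameter set

The default cell model is the fitted *Isochrysis galbana* double-shell
parameterisation: inner-core host ε_r 63, σ 1.12 S/m with 20% lipid
inclusions; membrane ε_r 6, σ 5×10⁻⁴ S/m, 5 nm; scale layer ε_r 13,
σ 9.9×10⁻³ S/m, 100 nm. The membrane permittivity and both thicknesses
are fixed (literature/SEM values); the rest are the fitted quantities.

Values that the source data do not pin down, chosen once here:

- **Cell radius 2.5 μm** (configurable): a mid-range size for this
  species; the fit never constrains it because the bead-referenced
  spectrum retains an unknown volume-ratio scale.
- **Lipid phase ε_r 2.2, σ 10⁻⁶ S/m**: oil-like, essentially lossless.
- **Medium ε_r 78, σ 2.9 S/m**: seawater-like f/2 culture medium; the
  conductivity is the measured value, the permittivity is water's.
- **Core-parameter reading**: the core values are interpreted as the
  cytoplasm *host* with lipid mixed in at 20%. The alternative reading
  (values describing the already-mixed core) is available by setting
  `lipid_fraction=0`.

### Relaxation frequencies — a known discrepancy

With this parameter set and radius 2.5 μm the model has **two**
interfacial relaxations: a membrane–medium charging relaxation near
72 MHz and a core–medium relaxation near 520 MHz. The in-band
(250 kHz–550 MHz) global maximum of `Im f_CM` therefore sits at
≈518 MHz. Neither peak falls near the nominal 250 MHz first-relaxation
figure quoted for this cell type, and no plausible radius moves the
membrane relaxation there (it scales as 1/r; r ≈ 0.7 μm would be
required). The single-shell limit of the code reproduces the classical
`f_c = 1/(2π r C_m (ρ_i + ρ_m/2))` membrane-charging result, so this is a
property of the parameter set, not an implementation artifact. The
acceptance check on this quantity is accordingly expected to fail and is
documented as radius-sensitive; the package reports the computed value
honestly rather than tuning the radius into the pass band.

`relaxation_frequency` refines the grid extremum with a 3-point
quadratic fit in log₁₀(f) (the `imag_peak` method interpolates `Im`
directly; `real_max_gradient` interpolates `d Re/d log f`), and raises on
flat or monotone spectra and on grids shorter than 10 points.

## Spectrum normalisation and fitting

Population spectra are referenced to a calibration bead:
`observed(f) = f_CM,bead(f_ref) · I_cell(f)/I_bead(f_ref)`. The bead's CM
factor is known from its material, so the reference removes electronics
gain and drift but leaves a cell/bead volume ratio; a multiplicative
nuisance `scale` (default bounds 0.1–10) absorbs it during fitting.

The objective is the mean over frequencies of squared real plus squared
imaginary residuals. Minimisation uses a bounded **compass search**:
poll ±one step per coordinate (step = fraction of that coordinate's box
range, initial 0.25), accept the first improving move, halve the step
after a full failed poll, stop when the step fraction drops below
`tolerance` (default 10⁻⁶) or the evaluation budget (default 20 000) is
spent. Accepted objective values are non-increasing by construction; the
poll order is randomly permuted per iteration from the fit seed. Free
parameter bounds default to generating value ×/÷10.

Identifiability: with a free scale, only the spectral *shape* is
informative. The noiseless self-consistency tests recover
(σ_core, ε_core, ε_scale, scale) to better than 1% from a 30% perturbed
start; with 1% complex noise the median of repeated fits stays within
10%.

## Event features and classification

- **Electrical diameter**: `d = d_bead · (S₁ₘₕz / median bead signal)^{1/3}`,
  anchored to 2 μm bead spike-ins. The median makes the calibration
  robust to stray particles inside the bead gate and maps the median
  bead to exactly the nominal diameter.
- **HF phase**: four-quadrant angle of the 500 MHz vector minus the
  run-level median bead phase (beads double as the phase reference).
- **LOD**: events with electrical diameter below 1.5 μm are discarded;
  the boundary is inclusive (d ≥ 1.5 kept).
- **KNN**: exhaustive standardized-Euclidean neighbours (axes scaled by
  the pooled-library standard deviation), unweighted majority vote over
  k = 11; a vote tie goes to the class of the nearest neighbour among the
  tied classes. Neighbour search is delegated to scikit-learn; the vote,
  tie-break, and metric scaling are owned here and verified against a
  brute-force oracle. `select_k` picks k by seeded stratified K-fold
  misclassification loss (ties → smallest k).
- **Gating**: in synthetic tables, calibration beads are identified by
  ground-truth label (standing in for manual scatter-plot gating); for
  unlabeled tables a rectangular gate (1.8–2.2 μm, top phase quartile)
  is provided. Beads are excluded from classification and from truth.
- **Recovery**: `100 × classified concentration / true concentration` per
  class, with concentration = count / (flow rate × duration / 60).
  Truth is *realized* (from generated labels), counted over events that
  pass the same LOD filter the classifier sees. This mirrors practice —
  "known" concentrations are themselves measured on the instrument — and
  is what makes the smallest-class contamination bias visible: most
  sub-LOD cells never enter either count, while bacteria that survive
  the filter are misassigned into the smallest class.

## Synthetic world

Defaults state one fixed scenario (all configurable, none tuned):
five stocks at 500 particles/μL mixed at equal volumetric ratio
(→ 100 /μL each), beads at 100 /μL in monocultures and 200 /μL in the
mixture, 30 μL/min flow, 120–150 s runs. Class layout: microplastic mix
(median 3 μm, GSD 1.45, standing in for 2/3/5/8 μm beads, phase offset
0.30 rad), *I. galbana* 5 μm / 0.05 rad, *C. vulgaris* 3.5 μm / 0.08 rad,
*P. purpureum* 6 μm / 0.03 rad, *Synechococcus* 1.2 μm / 0.10 rad
(mostly below the LOD by design), plus coliving bacteria
(1.3 μm / 0.09 rad) at 10% of each phytoplankton class's events.
Phase noise follows `sd = 0.2 rad·μm³ / d³` — inverse-volume, from
signal-amplitude reasoning — which reproduces the characteristic fan-out
of phase distributions below ~2 μm. Size-signal noise is 5%
multiplicative. Arrivals are Poisson; timestamps are sorted uniforms
(equivalent to a Poisson process conditioned on the count).

What a green pipeline test does **not** establish: the generator draws
classes from clean parametric families with class-independent noise laws;
real data add silt, bubbles, coincidences, gain drift, and species whose
phase offsets were never measured here. The monoculture run for the
smallest class is lengthened ×6 so that 3000 above-LOD training vectors
exist — a statement about the simulator, not about instrument time.

The waveform module is deliberately simplified: nine alternating-polarity
Gaussian lobes (σ 50 μs) at 50 μm electrode pitch, 230 kS/s sampling, no
position-dependent gain. Detection uses a velocity-insensitive envelope
statistic (single-lobe matched-filter magnitude averaged over one transit
span; an alternating-polarity full-template filter collapses under
lobe-spacing mismatch), thresholded at 5 robust noise units estimated
from the envelope's lower quantiles (P50, P50−P16). Velocity is
electrode pitch / median lobe spacing with sub-sample quadratic peak
refinement; amplitude is the least-squares template scale at the
estimated velocity. Closed loop at SNR 10 over 500 events: 100%
single-event detection, amplitude bias below 0.1%.

## Numerical choices and edge cases

- Quadratic peak interpolation is clipped to the bracketing grid
  interval; edge extrema raise "no relaxation found".
- `mg_mixture` endpoints (`φ = 0, 1`) are exact identities; `φ` outside
  [0, 1] raises.
- Non-positive 1 MHz signals and zero HF vectors mark events invalid
  (NaN features, dropped by extraction) rather than raising.
- Compass search clips polls to the box; moves that clip to the current
  point are skipped without spending evaluations.
- Event tables round-trip through CSV with `%.12g` formatting
  (lossless to ~1e−9 relative); metadata travel in `# key=value` header
  comments.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give byte-identical tables.

## Known limitations

- No electrode-geometry or field modelling; signal amplitude is an ideal
  volume law. No electrical double layer, no temperature dependence.
- Fits report point estimates and final MSE only — no uncertainty
  quantification, no global-optimum guarantee.
- Concentrations assume no coincidence losses.
- Recovery of the smallest class is reported with the caveat that counts
  at the detection limit are inherently unreliable; the pipeline flags
  its bias direction rather than promising an accurate number.
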