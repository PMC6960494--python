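# Methods

## The physical model

The simulator models a differential inductive reader for magnetic
lateral-flow assays.  A strip carrying superparamagnetic nanoparticle
reporters is dragged between a pair of congruent rectangular pickup
loops — a sense coil and a counter-wound reference coil in series — while
an alternating excitation field magnetizes the reporters.  Any imbalance
of magnetic material between the two coils induces a net voltage; an
empty or balanced strip reads exactly zero.

The chain is linear end to end:

1. **Induced moment.**  In the unsaturated regime a reporter of volume V
   and volume susceptibility χ in a local field H acquires the moment
   m = χ·V·H.  Saturation and the nonlinear multi-frequency excitation
   used by related instruments are deliberately not modelled; every
   downstream quantity is therefore strictly linear in χ, V and the drive
   amplitude.

2. **Flux coupling.**  The normal flux a z-moment dipole threads through
   a rectangular loop of half-extents t (scan axis) and h, at
   perpendicular standoff p, has the closed form built from the corner
   primitive

   φ(a, b, p) = (μ₀ m_z / 4π) · a·b·(a² + b² + 2p²) /
                [ (a² + p²)(b² + p²) √(a² + b² + p²) ],

   the flux through [0,a]×[0,b] of the coil plane.  A centered dipole's
   full-coil flux is 4·φ(t, h, p); off-center dipoles use four signed
   corner terms (inclusion–exclusion).  The square root in the last
   denominator factor is required dimensionally (flux must scale as
   μ₀·m/length) and is confirmed against adaptive 2-D quadrature of the
   dipole field to ~1e-13 relative over a wide (t, h, p) range; the
   quadrature path (`rect_flux_quadrature`) stays available as an
   independent oracle and as the only route for non-z moments.
   The geometry-only shape factor α(t, h, p) = φ_z/m_z falls off as p⁻³
   far from the coil and vanishes (slowly, as 1/extent) as the loop
   grows — the net dipole flux through an infinite plane is zero.

3. **Faraday readout.**  For a sinusoidal drive Hₐ(t) = H₀ sin(2πft) the
   induced amplitude is 2πf·α·χ·V·H₀ ("physical" convention).  A
   "datasheet" convention (f·α·χ·V·H₀, without the 2π of
   differentiation) is also exposed because instrument quick-reference
   formulas sometimes quote it; every `SignalResult` records which
   convention produced it.  Since only
   amplitudes are reported, the sign convention of −dφ/dt is immaterial.

4. **Differential detection.**  The detector voltage is the sense-coil
   sum minus the reference-coil sum over all dipoles.  Congruent coils
   make the null exact: mirror-balanced loadings cancel to ~1e-15
   relative (pure floating-point residue).  The default reference coil
   sits 10 mm from the sense coil along the scan axis; its pickup of a
   test line under the sense coil is computed (not assumed) to be
   < 0.1% (`reference_coupling_ratio`, ≈ 2.5e-4 for the default
   geometry).

## Device defaults and units

Internal units are SI throughout; file formats use mm and µV (the
working units of the instrument), and the bead-counting arithmetic uses
emu, emu/g, g/cm³ and mm³ exactly as magnetometers state them (1 emu =
1e-3 A·m²).

| parameter | default | why |
|---|---|---|
| pickup loop | 2t = 0.25 mm × 2h = 10 mm | the microfabricated pickup trace footprint |
| coil plane standoff | 0.3 mm above the strip bottom | the chip gap; a 0.2 mm strip passes beneath, so p ∈ [0.1, 0.3] mm per dipole |
| excitation trace | 10 × 1 × 0.035 mm | the PCB drive trace |
| drive frequency f | 90 MHz | the RF drive used with the prototype |
| drive field H₀ | 2.4×10⁴ A/m (~300 Oe) | see below |
| reporter | V = 4.2e-12 mm³, χ = 0.17, Ms = 40 emu/g, ρ = 2.0 g/cm³ | 200 nm polymer-shelled iron-oxide beads |
| scan | 1 mm/s, one sample / 10 ms | the profiling procedure (10 µm per sample) |
| noise | 1 µV rms additive white Gaussian | the detector noise floor |

The true excitation current is not known for the physical device (the
drive is specified as a voltage, and its analytic model is reported to
overestimate the measured signal), so H₀ is a free configuration
parameter.  The default of 2.4×10⁴ A/m is the field scale this class of
inductive sensors drives reporters at; it keeps the linear-moment
assumption comfortable (M/Msat ≈ 5% for χ = 0.17) and places a
10⁷-reporter test line at ≈ 18 µV peak, on the tens-of-µV working scale
the instrument reports.  Absolute voltage agreement with the physical
device is explicitly not a goal — every quantification path is
calibration-based, so H₀ cancels.

Drive modes: `uniform` (default) applies H₀ ẑ at every reporter,
matching the analytic model, which uses only the normal flux component.
`biot_savart` evaluates the excitation-trace field at each reporter by
summing exact finite-segment fields over an 8×8 filament discretization
of the trace cross-section (convergence is a test: 16 vs 32 filaments
differ by < 0.1% beyond one trace-width).

## The virtual strip generator

The generator emulates the *spatial* content of a developed LFA strip:
printed lines of known reporter count (uniform or Gaussian lateral
profile) plus an optional Poisson background of nonspecifically trapped
reporters.  Two representations:

- **sampled** — every reporter an explicit dipole, positions drawn
  uniformly in the line volume (exact requested counts, bitwise
  reproducible per seed); practical to ~1e5 reporters;
- **homogenized** — the line volume tiled by a deterministic grid of
  equivalent dipoles carrying fractional weights, the same treatment a
  field solver applies when a line holds ~1e7 reporters.  Default pitch
  (50 µm × 0.5 mm × 20 µm along x, y, z) is fine where the coil response
  varies (x, and z where coupling falls as p⁻³) and coarse along the
  long coil axis; halving the pitch moves the simulated peak by < 0.1%
  (tested at 0.5%).

What the generator does **not** emulate: capillary transport, binding
kinetics, line-shape irregularity, reporter polydispersity, and the
assay-level run-to-run loading variability (~12 µV in the real
instrument, attributed to the assay rather than the detector; an
optional multiplicative loading jitter exists but defaults to off).
Passing tests therefore demonstrate the fidelity of the *transducer*
model and the correctness of the quantification chain, not wet-lab
assay performance.

## Scan profiles and peak calling

A scan records the differential amplitude every 10 ms at 1 mm/s; profile
position q means strip coordinate q is over the sense-coil center.
Because a 1 mm line is wider than the 0.25 mm coil, the noise-free
response is twin-lobed (dipoles just outside the coil footprint thread
negative return flux); its tails are slightly negative for the same
reason, so the baseline is legitimately nonzero.

`extract_peak` is deliberately simple and declared rather than inferred
from any instrument convention: baseline = median of samples outside the
line window (or the outermost 25% of the scan); peak = max of the
5-sample moving-average-smoothed profile minus baseline; SNR = peak over
a MAD-based noise estimate from the baseline region.  The moving average
uses edge renormalization so constants are preserved exactly; an
all-flat profile returns peak 0 with SNR 0.

Taking a maximum over a noisy profile carries a small positive bias
(extreme-value statistics of the smoothed noise, ~2–3% at an 18 µV peak
with 1 µV noise).  The quantification chain is therefore calibrated the
way a real assay is: known-count strips are scanned under the *same*
noise as the unknowns and fed to `calibrate_voltage_to_count`
(zero-intercept least squares — zero beads give zero differential signal
by construction), so the shared bias cancels in the ratio.  With that
design, 20 seeded full-membrane scans at N = 10⁷ recover the count
within 5% in 20/20 runs (the packaged acceptance run reports the
realized numbers).

## Quantification

- **Bead counting.**  N = MT/(Ms·ρ·V), computed in emu, g and cm³
  exactly as magnetometers state the quantities (SI entry points convert
  first).  With the default reporter, one bead saturates at
  Ms·ρ·V = 3.36e-13 emu; the N → MT → N round trip is exact.
- **Susceptibility.**  Least-squares slope of M vs H restricted to
  |M| ≤ 0.3 × the saturation plateau (mean |M| over the top decile of
  |H|), averaged over branches when the loop is labelled.  Exact for a
  linear loop; recovers the initial slope of a Langevin-shaped loop
  within ~3% (the fit window reaches ξ ≈ 1 where the Langevin curve has
  already softened — tightening `fit_fraction` trades bias for noise).
- **Dose response.**  Molecule counts from concentration, sample volume
  and molar mass (molar mass is a *required* input: none is assumed, and
  a wrong default would silently corrupt every ratio); molecules-per-bead
  is an exact quotient; the table flags whether the ratio is
  nondecreasing in concentration.

## Numerical and design notes

- Quadrature oracle: `scipy.integrate.dblquad` at epsrel 1e-10; the
  closed form agrees to ~1e-13 even at extreme aspect ratios (t/p = 200).
- The closed form rejects non-z moments (> 1e-12 of the moment
  magnitude) rather than silently dropping transverse components.
- Standoff p ≤ 0 (dipole in the coil plane) is an error everywhere.
- Scans are evaluated by broadcasting the corner primitive over
  (samples × dipoles), chunked to bound memory; a full 46 mm membrane at
  10 µm sampling against ~1200 equivalent dipoles takes ~2 s.
- Problem sizes in the tests (6–46 mm strips, 10⁶–10⁷ reporters
  homogenized, 20-seed recovery runs) are chosen to exercise the exact
  study conditions of the scan procedure while keeping a full suite run
  around a minute.
- Determinism: every stochastic step (strip sampling, background Poisson
  draw, scan noise) flows from an explicit integer seed through
  `numpy.random.default_rng`; identical seeds give bitwise-identical
  strips and profiles, which the CLI inherits.

## Known limitations

- No eddy currents, skin effect, frequency-dependent permeability,
  coil self/mutual inductance or drive-chain impedance: the drive is an
  ideal field, the pickup an ideal flux integrator.
- Reporter saturation is not modelled; at fields approaching the
  reporters' saturation the linear moment (and hence every linearity
  property) overestimates the true signal.
- The homogenized line ignores reporter-scale granularity; at counts
  below ~10⁴ use sampled mode.
- Peak calling assumes a single dominant line inside the window;
  overlapping lines closer than the coil response width are not
  deconvolved.
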