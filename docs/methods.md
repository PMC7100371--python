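# Methods

## Kinetic model

The simulator and the analysis share one physical picture. UV excitation
of [peptide, Ag]⁺ triggers electron transfer to silver; the transient
[radical peptide⁺•, Ag⁰] complex loses neutral Ag with time constant τ₁,
and the resulting radical cation converts to its distonic form (proton
moved from the tryptophan radical to histidine) with time constant τ₂.
Sequential first-order kinetics give, with populations normalized to the
pump-generated pool,

    complex(t)  = exp(−t/τ₁)
    radical(t)  = τ₂/(τ₂−τ₁) · (exp(−t/τ₂) − exp(−t/τ₁))
    distonic(t) = 1 − complex − radical

with the degenerate τ₁ = τ₂ case handled by the (t/τ)·exp(−t/τ) limit
(triggered below a relative τ difference of 1e−9). These closed forms are
checked against direct numerical integration of the rate equations
(`scipy.integrate.solve_ivp`, rtol 1e−11) in the tests.

The probe fragments the radical with probability `probe_yield_radical`
and the distonic ion with the smaller `probe_yield_distonic`; the
metastable complex contributes no probe fragments (the probe sees a
different chromophore while Ag is still bound), which reproduces the
observed growth of the fragmentation ratio over the first microseconds.
For t ≫ τ₁ the expected corrected FRR reduces exactly to the fitted
model: offset = `probe_yield_radical`, amplitude = difference of the two
yields, plus a non-zero end level because the distonic ion still absorbs.

## Synthetic data: what it emulates, what it does not

Each rendered spectrum contains centroid sticks for: the surviving
parent at M; silver-free loss channels at M−129 / M−185 (Cα–Cβ indole
loss and Trp-containing C-terminus loss) or, for His-free systems, the
complementary charged fragments at m/z 130 / 186; and pump-induced
silver-containing fragments as a ¹⁰⁷Ag/¹⁰⁹Ag doublet (spacing 1.9997 Th,
abundance ratio 48.161/51.839 = 0.929). Pump-induced silver-free
fragments feed the same loss channels at a fixed ratio α_true to the
silver-containing ones — exactly the background the α correction must
remove. Channel intensities are independent Poisson draws (ion-counting
statistics; the doublet is thinned into its isotopologues, which is
equivalent to a Poisson total binomially split).

Defaults encode the experiment's design: 200 log-spaced delays from
50 ns to 20 ms plus 5 negative controls, 120 repeats per delay, parent
M = 755 Th. Values the experiment does not pin down were fixed once at
realistic magnitudes: τ₁ = 200 ns (the metastable-complex lifetime is a
free parameter of order several hundred ns), τ₂ = 825 μs (a mid-range
penta-alanine-like system), n0 = 2000 counts, probe yields 0.25/0.10
(matching a ~0.25 → 0.10 FRR decay), α_true = 0.4, mean pump Ag fragment
count 500, and 65% of silver-free intensity in the 129-loss channel.

Not emulated: profile peak shapes, ¹³C satellites (the classifier keys
on the Δ2 doublet; a ¹³C-like +2 satellite at ratio ~0.2 is rejected by
the ratio band), m/z calibration drift, detector saturation, shot-to-shot
laser fluctuations, and any wavelength dependence. Passing recovery
tests therefore demonstrate the statistical machinery — calibration,
correction, fitting, bootstrap, censoring — under the assumed counting
noise, not robustness to instrumental artefacts absent from the model.

Per-spectrum random streams are keyed `(seed, delay index, repeat)` via
`numpy.random.SeedSequence`, so datasets are bit-reproducible and
enlarging the repeat count leaves earlier spectra unchanged.

## Fragment classification and quantification

A peak is silver-containing iff a partner centroid lies within ±0.3 Th
of the Ag isotope spacing above it and the high/low intensity ratio is
within ±35% of 0.929. The tolerances balance Poisson scatter of the
ratio (relative σ ≈ √(1/I₁₀₇ + 1/I₁₀₉), ~9% at 500 counts) against
rejecting isotopic satellites; tests verify ≥99% correct classification
at 1000-count channels. All species are treated as singly charged.
Windows whose pattern cannot be classified are assigned silver-free with
a warning (strict mode raises); integration windows are inclusive
±0.5 Th sticks, suited to unit-resolution ion-trap centroids, and
overlapping windows are a configuration error.

## α calibration and FRR

α is the pooled ratio ΣIF/ΣIF_Ag over all negative-delay spectra of an
experiment (ratio of sums is less biased than a mean of per-spectrum
ratios at low counts), with a Poisson-propagated standard error
√(ΣIF + α²ΣIF_Ag)/ΣIF_Ag. FRR is computed per spectrum; the corrected
numerator IF − α·IF_Ag is floored at zero (FRR is a population fraction;
the unfloored variant is available for bias studies), then averaged per
delay with the standard deviation of the mean over repeats. Per-spectrum
averaging, rather than a ratio of per-delay summed intensities, is the
default; the per-delay FRR of all-identical repeats reports an exact
zero SEM.

## Decay fitting, bootstrap, censoring

Points with delay > 30 μs (excluding the complex-dissociation transient)
enter a bounded trust-region least squares (`scipy.optimize.least_squares`,
analytic Jacobian) of offset − amplitude·(1−exp(−t/τ₂)), weighted 1/SEM²
(unit weights if any SEM is zero), with bounds offset ∈ [0,1],
amplitude ∈ [−0.5,1], τ₂ ∈ [1 μs, 1 s] and starting values
(first-point FRR, first−last, median delay) — robust on log-spaced
grids. At least 4 qualifying points are required.

Uncertainty: parametric bootstrap, redrawing each per-delay mean from
Normal(mean, SEM) and refitting (default 10⁴ draws, seeded); the
reported parameters are the mean of the draws and σ their standard
deviation. A nonparametric variant resamples the stored per-spectrum FRR
values per delay instead. Fits with >20% non-converged draws are flagged
unreliable.

Censoring: a fit is reported as the lower bound "τ₂ > 5000 μs" when the
fitted τ₂ exceeds 5 ms or the amplitude is not resolved at 2σ — decays
flatter than that cannot be distinguished from no decay within the 20 ms
window.

Replicates measured on different days are fitted independently and only
then combined: weighted mean Σ(τᵢ/σᵢ²)/Σ(1/σᵢ²) with combined
σ = (Σ1/σᵢ²)^−1/2. The combined mean lies in the convex hull of the
replicates and the combined σ never exceeds the smallest replicate σ.
Reports and plots use 2σ error bars (95.4% window); tables are in μs,
internal units SI seconds.

## Ion mobility

Arrival times regress linearly on 1/V (slope L²/K, intercept the
non-drift time t0); a non-positive slope is a data error. The
Mason–Schamp relation converts K to a cross section,
Ω = (3q/16N)·√(2π/(μk_BT))·1/K, with N from the stated pressure and
temperature and μ the ion–buffer reduced mass; reduced mobility is
referenced to 760 Torr / 273.15 K. "Room temperature" defaults to 298 K
and is configurable, as is t0 handling. The reported CCS uncertainty
adds a 2% systematic floor in quadrature to the regression error.
Published absolute CCS values for specific peptides are documentation
context only — reproducing them needs the raw arrival times.

## Problem sizes and numerical choices in the test/acceptance suites

Recovery studies use 60 delays × 40 repeats with 5 controls and a few
hundred bootstrap draws per fit — enough delays to constrain a 800 μs
decay inside the 30 μs–20 ms window and enough draws to estimate σ_boot
to ~5% — keeping a 100-run coverage study to about a minute. The
full-size schedule (200 × 120, 10⁴ draws) remains the library default.
Exact-identity tests assert at 1e−12; closed-form vs ODE agreement at
1e−8 (the integrator's accuracy, not the closed form's, is limiting);
published-table aggregation at 1% (replicate σ are published rounded to
integers, which propagates ~1% into the weighted means).

## Known limitations

- The α correction assumes the probe creates no silver-containing
  fragments; violations (e.g. probe absorption by the intact complex)
  would bias FRR at short delays only.
- Flooring the corrected numerator introduces a small positive bias in
  FRR at delays where the true value is near zero; the unfloored option
  exists for sensitivity analysis.
- Mono-exponential fitting deliberately ignores the sub-30 μs transient;
  systems with τ₂ approaching τ₁ would need the full two-step model.
- The bootstrap treats per-delay means as independent Gaussians; with
  120 repeats the CLT makes this excellent, but very low repeat counts
  would call for the nonparametric mode.
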