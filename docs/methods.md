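# Methods

## Scope and data model

The package analyzes two kinds of measurements from lysolipid-gated
channel experiments: continuous-wave X-band EPR spectra of nitroxide
spin-labeled protein (first-derivative signal on a uniform magnetic-field
grid, mT) and fluorescence dequenching traces of calcein-loaded
proteoliposomes (intensity vs time, s).  All field axes are mT internally;
inputs in gauss must be converted by the caller (1 G = 0.1 mT).  Spectra
are functions of field only and are never resampled implicitly: mismatched
grids are an error, not a resampling trigger.

## Spectral statistics

With S(B) the absorption spectrum (single integral of the recorded
derivative), the mobility parameters are

    B_F    = ∫ B S(B) dB / ∫ S(B) dB
    ⟨ΔB²⟩  = ∫ (B − B_F)² S(B) dB / ∫ S(B) dB
    ΔH⁻¹   = 1 / ΔH_pp

and the spin–spin interaction proxy is the difference of second moments of
a dipolar-broadened (maximally labeled) and a non-broadened (minimally
labeled) spectrum, Δ⟨ΔB²⟩ = ⟨ΔB_I²⟩ − ⟨ΔB_N²⟩, each about its own first
moment.  Because a unit-area convolution adds its own variance to a
lineshape, Δ⟨ΔB²⟩ of an ideal pair equals the second moment of the
broadening kernel — the property the test suite verifies numerically.
Values are computed in mT² and reported alongside in T² (1 mT² = 10⁻⁶ T²),
the customary tabulation scale.  Negative differences are physically
anomalous (an incompletely closed reference, or noise); they are flagged
with a warning and never clamped.

### Moment windows

Moments are integrated over a window with no tail extrapolation — the only
defensible convention for Lorentzian-tailed lines, whose infinite-window
second moment diverges; the window used is recorded in every result, and
the documented window dependence (a Lorentzian's ⟨ΔB²⟩ grows roughly
linearly with the window) is regression-tested rather than hidden.

Direct calls to `first_moment` / `second_moment` / `delta_second_moment`
default to the full recorded sweep.  The pipeline (`mobility_result`,
`build_series`) defaults to the spectrum's *signal support*: the
contiguous span where the smoothed derivative envelope exceeds 2% of its
maximum (and a noise floor estimated from the envelope's lower quartile),
padded by 2 mT.  The reason is statistical: integrating white noise twice
across a 33 mT sweep produces a random walk whose contribution to
⟨ΔB²⟩ — weighted by (B−B_F)² — swamps the signal's own variance.  Within a
window the absorption is re-anchored to zero at both ends (a Brownian
bridge for the noise, a no-op for a clean spectrum).  Δ⟨ΔB²⟩ pairs share a
single window (the union of the two supports) so truncation affects both
moments alike.

Even so, the double integration sets a precision floor: at a realistic
signal-to-noise of ~300 the per-pair Δ⟨ΔB²⟩ of the default simulated
system fluctuates by a few hundred ×10⁻¹⁰ T².  Tabulated experimental
values with ±20×10⁻¹⁰ T² uncertainties imply narrower sweeps and very high
SNR; the generator's defaults do not reproduce that precision, and the
package reports its scatter rather than smoothing it away.

### Central linewidth

ΔH_pp is the field separation between the global derivative maximum inside
a central search window (default: the middle third of the sweep) and the
minimum that follows it; both extrema are refined by three-point parabolic
interpolation, giving sub-grid accuracy (2σ for Gaussian lines, 2Γ/√3 for
Lorentzian, verified to within a grid step).

### Quantitation

C_samp = N_samp·C_ref/N_ref compares baseline-corrected double integrals
of identically acquired spectra (the caller attests comparability; a
100 mM reference probe solution is the conventional standard), and
SLE = C_samp/C_prot.  Values above 1 are allowed with a warning.  Double
integrals carry the same random-walk noise discussed above (≈2% sd at 1%
peak noise over the signal support), which bounds single-shot quantitation
accuracy.

## Preprocessing

Baseline correction fits a polynomial (default order 1, the bench-top
standard; configurable 0–3) to the outer `edge_fraction` (default 0.1 per
side) of the derivative sweep, subtracts it, then applies a second-stage
constant so the absorption returns exactly to zero at the high-field end.
Diagnostics flag (a) a pre-correction absorption endpoint above 2% of the
absorption maximum — an under-modelled baseline — and (b) edge-region RMS
above 5% of the peak — hyperfine wings intruding into the fit region.
Correction is idempotent to <0.1% on the double integral.  Integration is
trapezoidal throughout on the uniform grid; no spline resampling.
Normalization is by spin count (matching double integrals) or by
central-line peak-to-peak amplitude; both are pure rescalings and never
change a moment.

## The forward model (synthetic data)

The simulated absorption is a three-line nitrogen hyperfine triplet at
B0 − a_N, B0, B0 + a_N (default B0 = 335 mT, a_N = 1.6 mT on a 33 mT,
1024-point sweep — plausible for the stated 9.41 GHz microwave frequency)
with per-line derivative peak-to-peak widths, plus an optional broad
Gaussian "immobile" component at B0.  This two-component superposition is
a deliberate stand-in for slow-motional physics: it reproduces the
markers the analysis quantifies (broad wings that shrink and vanish as
mobility rises) without a stochastic-Liouville simulation, and nothing in
the analysis depends on the markers' exact shape.  The recorded signal is
the analytic field derivative of all components, convolved with the
dipolar kernel where applicable, plus a polynomial baseline and white
Gaussian noise whose sd scales as 1/√scans (16 scans for maximally,
25 for minimally labeled acquisitions).

### Dipolar broadening

A pair of labels at distance r adds a powder (Pake) broadening with
splitting d(r) = C_dd/r³, using the standard nitroxide-pair constant
C_dd = 52.04 MHz·nm³ converted to field units at 28.03 MHz/mT (g ≈ 2.006);
both constants are overridable.  The kernel integrates the orientation
distribution exactly per field bin (the half-pattern CDF is closed-form),
is symmetrized over the two transitions, sums to one, and has second
moment d²/5 — hence the r⁻⁶ scaling of Δ⟨ΔB²⟩.  A `gaussian` variant with
the same root second moment is available.  Beyond a 2.5 nm cutoff the
kernel is a single-bin identity (unresolvable at grid resolution);
`labeled_fraction` < 1 mixes in an identity component for partially
labeled neighbors.  Center-bin mass lumping biases the discrete kernel's
second moment by O(h²/12); at the default grid this is <0.1% of the
closed-state kernel moment.

### Titration ground truth

Per concentration c the spectrum is the mixture
(1−f(c))·closed + f(c)·open of unit-spin state spectra — so the spin count
is constant across the series, as for aliquots of one labeled stock.  The
open fraction is the cubic smoothstep f = 3x² − 2x³, x = min(c/c_sat, 1):
monotone, exactly saturated at c_sat (default 30 mol%), with its largest
increment in the interval containing the half-activation point.  The
maximal-labeling condition convolves each state with its state-appropriate
kernel (defaults r = 1.2 nm closed, 2.0 nm open — the closed-state
distance is a free parameter of the simulator, not a structural claim);
the minimal condition applies none.  Default noise is 0.3% of each
spectrum's derivative peak at 16 scans (SNR ≈ 330, a typical bench-top
accumulation) and the default baseline drift is linear at ~10% of peak
across the sweep.  All generators are bit-reproducible from their seed.

## Titration analysis

`build_series` runs preprocessing and moments over a manifest, pairs
maximal/minimal spectra at exactly matching concentrations for Δ⟨ΔB²⟩ (no
interpolation; unpaired concentrations warn and are omitted), and computes
per labeling condition a *mixing coordinate*: the least-squares
decomposition of each spectrum on the span of the lowest- and
highest-concentration spectra, reported as b/(a+b).  For a two-state
titration this coordinate is exactly linear in the open fraction,
scale-invariant, and far more precise than any doubly integrated
statistic; an errors-in-variables correction (subtracting m·σ̂² from the
Gram diagonal, with σ̂ from the signal-free edges) removes the attenuation
the endpoint spectra's own noise would otherwise cause.  It is the default
statistic for saturation detection.  ΔH⁻¹ is deliberately not used for
saturation: the central-line extrema are dominated by the narrow open
component well before full opening, so ΔH⁻¹ flattens early.

`saturation_point` returns the smallest concentration from which the
statistic's tail (≥2 points) has total spread ≤ tolerance (default 10% of
the statistic's full range, standing in for an unavailable
replicate-derived error).  Spread (max−min) rather than deviation-from-mean
is used because the latter certifies the final two points of any strictly
monotone series at the default tolerance — a spurious plateau.  A constant
series saturates at its first concentration; a series with no qualifying
tail returns none.

`interaction_trend` localizes the largest drop between consecutive
Δ⟨ΔB²⟩ values and classifies values under a threshold (default
20×10⁻¹⁰ T²) as negligible interaction.  `reversibility_score` compares
spin-normalized derivative spectra (what overlay figures show; mode
deliberate) as RMS(difference)/RMS(reference) over the reference's signal
support — full-sweep RMS would depend arbitrarily on how much empty
baseline the acquisition window contains.  Scores: 0 identical; the
default simulated BSA-reverted spectrum at 1% noise scores ≈0.03 versus
≈12 for the open state.

## Release-trace analysis

%Release = 100·(I−I₀)/(I₁₀₀−I₀); I₀ defaults to the first sample and I₁₀₀
to the median of the final 10% of post-lysis samples (the lysis marker is
the one experimental annotation the analyzer consumes — the experimenter
knows when detergent was added).  Out-of-range values from noise are
flagged, passed through, never clipped.

The model: release rises as 1 − exp(−kΔt) from its current level after
every LPC addition, holds after BSA, and jumps to 100% at lysis.  The
default ground truth is a three-cycle experiment at sub-saturating doses
(k = 0.004 s⁻¹, ~3 min per LPC follow and ~1 min per BSA follow); a fully
opening dose corresponds to k = 0.015 s⁻¹, which plateaus within ~5
minutes.  A single rate constant cannot produce visible steps in *every*
cycle of a long experiment at the full-dose rate — release saturates in
the first cycle — which is why the repeated-cycle default uses the slower
rate.

Segmentation classifies samples by rolling least-squares slope of the
%-release curve (window 10 s) against a threshold (default 5% of the
maximum rolling slope — the data's own scale, since no absolute threshold
is defensible), cleans flips shorter than half a window, and refines each
boundary by a local two-segment piecewise-linear fit, which recovers
noiseless change points to the sample.  Rate estimation fits
log(1 − R/R∞) vs t by weighted least squares with weights ∝ (1 − R/R∞)
(the delta-method inverse-variance weighting; unweighted log fits are
badly degraded by near-asymptote points), excluding points within 2% of
R∞ = 100% (overridable).  Plateau time is the first time release stays
within 1 percentage point of its final pre-lysis value.  The arrest
latency implied by "release stops immediately" is a detection parameter
(two samples at default settings), not a biological claim.

## What a green test does and does not establish

The generator states a world of Gaussian/Lorentzian hyperfine lines,
pairwise effective dipolar broadening, exact two-state mixing, white
noise, and ideal exponential efflux.  Green tests certify the estimators
against that world's ground truth and against closed-form/brute-force
oracles — they do not certify slow-motional lineshape physics, five-spin
ring geometry, inter-label distance extraction (invalid at partial
labeling), field-modulation distortion (an approximate pseudo-modulation
hook exists but is off by default), photobleaching, or inner-filter
effects, all of which are out of scope.  Printed experimental tables of
Δ⟨ΔB²⟩ from undeposited spectra cannot be regenerated; what the package
reproduces is the structure of the analysis: the saturating mobility
curves, the sharp spin–spin drop before saturation, reversibility, and
arrestable multi-cycle efflux.
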