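# spinflux

Quantitative analysis of reversible ion-channel gating followed by
site-directed spin-label EPR and liposome dye-efflux assays — with a
synthetic-data generator so the entire pipeline can be exercised and
validated without instrument data.

The motivating experiment: the bacterial mechanosensitive channel MscL,
reconstituted into liposomes and spin-labeled at a pore residue, is opened
stepwise by titrating the lysolipid LPC into the bilayer and closed again
by extracting the LPC with BSA.  Channel opening shows up in the cw-EPR
spectra as increased label mobility (narrower lines) and reduced spin–spin
interaction between labels on neighboring subunits; in parallel,
calcein-loaded liposomes report pore opening as dye efflux that BSA
arrests.  This package implements the statistics that turn those raw
signals into numbers.

## What it computes

For a first-derivative cw-EPR spectrum integrated to its absorption S(B):

* first moment ``B_F = ∫B·S(B)dB / ∫S(B)dB`` and second moment
  ``⟨ΔB²⟩ = ∫(B−B_F)²·S(B)dB / ∫S(B)dB`` — the overall spectral width, a
  robust inverse-mobility measure;
* inverse central linewidth ``ΔH⁻¹ = 1/ΔH_pp`` of the m_I = 0 hyperfine
  line — larger for more mobile labels;
* spin quantitation ``C_samp = N_samp·C_ref/N_ref`` from double integrals
  against a reference probe, and labeling efficiency
  ``SLE = C_samp/C_prot``;
* the spin–spin interaction proxy
  ``Δ⟨ΔB²⟩ = ⟨ΔB_I²⟩ − ⟨ΔB_N²⟩`` between maximally labeled
  (dipolar-broadened) and minimally labeled (non-interacting) samples;
* dose–response assembly over an LPC titration: mobility curves, the
  saturation concentration, the interval of the sharpest Δ⟨ΔB²⟩ drop, and
  a reversibility score comparing BSA-reverted spectra to the closed state;
* for fluorescence dequenching traces:
  ``%Release = 100·(I−I₀)/(I₁₀₀−I₀)``, segmentation into open/arrested
  intervals, first-order efflux rate constants, and plateau times.

The generator simulates nitroxide triplet spectra (motion-dependent
linewidths, an immobile component, Pake dipolar broadening with a
d = C_dd/r³ splitting, baseline drift, scan-scaled noise), full
closed↔open titration series with a saturating open fraction, and
exponential-release traces arrested by BSA events — all with known ground
truth and bit-reproducible seeding.

## Worked example

```sh
spinflux simulate --preset titration --seed 1 --out sim/
spinflux titrate --manifest sim/manifest.csv --out results/
```

or equivalently, the end-to-end driver:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints (seed 1):

```
titration:
  saturation detected at 30.0 mol% (ground truth 30.0 mol%)
  delta second moment at    0 mol%:   2496.5 x 1e-10 T2
  delta second moment at   10 mol%:   2186.7 x 1e-10 T2
  delta second moment at   20 mol%:    810.9 x 1e-10 T2
  delta second moment at   30 mol%:   -670.4 x 1e-10 T2
  delta second moment at   40 mol%:   1241.9 x 1e-10 T2
  delta second moment at   50 mol%:    129.4 x 1e-10 T2
  largest drop over (20.0, 30.0) mol%
release trace:
  6 segments, change points at [12.5, 188.0, 252.0, 428.5, 486.5] s (events at [10.0, 190.0, 250.0, 430.0, 490.0] s)
  open-segment rates [0.0040162907552933605, 0.004017222302377066, 0.0040988625950898645] s^-1 (true 0.004 s^-1)
  final pre-lysis release 88.8 %
reversibility:
  closed vs BSA-reverted score 0.0260
  closed vs open score        11.7134
```

Reading it: the mobility statistics flatten at 30 mol% LPC — the channel
is fully open there and more lysolipid changes nothing.  Δ⟨ΔB²⟩ is large
while the channel is closed (labels on adjacent subunits are within
dipolar range), collapses sharpest between 20 and 30 mol%, and scatters
around small values past saturation (the per-spectrum statistical
uncertainty of this moment difference is a few hundred ×10⁻¹⁰ T² at the
simulated signal-to-noise; a negative value is reported, flagged, never
clamped).  The release trace segments into three open/arrested cycles
whose change points land within a sample or two of the scheduled LPC/BSA
additions, with the efflux rate recovered in each cycle.  The
reversibility score of a BSA-reverted spectrum is ~0.03 — spectroscopically
indistinguishable from closed — versus ~12 for the open channel.

`scripts/acceptance.py` regenerates everything from scratch at the given
seed: it simulates the titration, writes and re-reads the spectra through
the native file format, runs the full analysis chain, and does the same
for the release trace and the reversibility comparison.

## Library layout

| module                 | contents |
| ---------------------- | -------- |
| `spinflux.io`          | native spectrum file dialect, manifests, validation |
| `spinflux.synth`       | lineshape/dipolar/titration/release generators |
| `spinflux.preprocess`  | baseline correction, integration, normalization |
| `spinflux.moments`     | moments, Δ⟨ΔB²⟩, linewidths, quantitation, SLE |
| `spinflux.flux`        | % release, cycle segmentation, rate fitting |
| `spinflux.titration`   | dose–response assembly, saturation, trends |
| `spinflux.cli`         | `spinflux simulate / analyze-spectra / titrate / flux` |

See `docs/methods.md` for the models, parameter defaults, numerical
choices and known limitations.
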