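# Methods

This note documents the physical and numerical model behind `qmrisim`:
what is simulated, which conventions are fixed, which design choices were
genuinely open, and what the synthetic experiments do and do not
demonstrate about real acquisitions.

## Sequence model and `.seq` dialect

A sequence is an ordered list of blocks, each holding at most one RF
pulse, one trapezoidal gradient per axis, one ADC window and an optional
pure delay. All RF/ADC/delay times live on a 1 µs raster, gradient ramp
segments on a 10 µs raster, quantized round-half-up at construction.
Units follow the Pulseq convention: RF amplitude in Hz (γB1), gradients
in Hz/m (γG), file times in integer microseconds (ADC dwell in
nanoseconds).

Files are written in a Pulseq-1.2-style section layout ([VERSION],
[DEFINITIONS], [BLOCKS], [RF], [TRAP], [ADC], [DELAYS], [SHAPES]).
Two dialect notes:

* a `[DEFINITIONS]` section records FOV, matrix, slice geometry and the
  nominal TR/TE/TI — without the FOV the phase-encode line of each
  readout could not be re-derived from gradient areas on read-back;
* RF table rows carry a trailing `use` code (excitation / refocusing /
  inversion). The reader accepts rows without it and falls back to a
  flip-angle-and-order heuristic.

Shapes are written uncompressed; the reader also decodes the Pulseq
run-length-compressed derivative encoding. Only symmetric pulses (block,
Hamming-apodized sinc, selectable per protocol) are generated, so the
pulse center is always duration/2 and need not be serialized. Write →
read → write is byte-identical, which the tests enforce for every preset.

## Timing auditor

TE, TI, TR and echo spacing are *measured* from the event timeline, never
copied from metadata: TE from excitation center to the ADC temporal
center, TI from inversion center to the next excitation of the same
slice, TR between successive same-slice excitations. For echo trains the
reported TE belongs to the echo that acquires the k-space center line
when that echo index is unique (the effective TE of a banded TSE);
variable-TE trains revisit the center line at every echo, and the tie is
broken toward the ADC nearest after the last refocusing pulse, i.e. the
final echo. The auditor also reports the full per-train echo-time list,
which is what the acceptance script uses.

## Protocols

Four preset families reproduce the standard validation experiments:
qualitative multi-slice IRSE (250 mm FOV, 256 matrix, 11 slices, TR 2 s,
TE 12 ms, TI 150 ms), qualitative multi-slice TSE (TR 3 s, effective TE
50 ms, 4 echoes), a 10-TI IRSE T1-mapping set (TR 4.5 s, TE 10 ms, TI =
50, 75, 100, 125, 150, 250, 1000, 1500, 2000, 3000 ms) and a 23-echo
variable-TE multi-echo TSE for T2 mapping (TE = 7…161 ms spaced 7 ms).
Low-resolution simulation presets use TR 4.5 s, TI 200 ms, TE 10 ms.
A `scale` factor shrinks only the matrix (and phantom raster); all timing
is preserved.

Open choices, resolved as follows:

* **TSE echo spacing.** Only the effective TE and echo count are printed
  for the qualitative TSE; the echo spacing is set to TE/center_echo with
  center_echo = 2 by default (ESP 25 ms), keeping the k-space-center echo
  at the nominal TE — the standard banded-TSE convention. Both knobs are
  parameters.
* **Phase-encode order.** Banded ("centric-banded") assignment: k-space
  splits into ETL contiguous bands; the band containing the center line
  (index N/2, 0-based) is acquired at the center echo, the rest by cyclic
  rotation. The multi-echo T2-mapping variant instead acquires *one* line
  at *every* echo per excitation, so each echo index assembles a complete
  k-space at its own TE.
* **Slice handling.** Slices are excited sequentially within each TR in a
  seeded random order (the order and seed are recorded); slice selection
  is encoded as RF frequency offsets against a z-gradient, but the
  simulator treats slices as ideal, independent 2D planes — adequate for
  single-slice-plane phantoms, silent about cross-talk.
* **CPMG.** Refocusing pulses are applied with a π/2 phase relative to
  excitation so echo trains are phase-stable; the per-echo phase-encode
  blip/rewind bookkeeping accounts for the phase conjugation of every
  refocusing pulse (including the self-sustaining readout prephaser).
* **Readout calibration.** The frequency-encode amplitude satisfies
  Δk = 1/FOV per dwell; ADC samples sit at delay + j·dwell so the
  sample j = N/2 coincides exactly with the ADC temporal center, where
  the spin echo and the gradient echo are aligned.

## Simulator

Hard-pulse approximation: the full rotation happens instantaneously at
the pulse center, with no relaxation during RF. Between events the
evolution is piecewise closed-form (exponential relaxation; gradient
phase from exact trapezoid areas), so the closed-form spin-echo
steady-state solutions are reproduced to machine precision rather than to
an ODE tolerance. Refocusing and inversion pulses are full physical
rotations — in particular a refocusing pulse inverts the longitudinal
magnetization that recovered since excitation, so the exact IR spin-echo
steady state is

    S ∝ | 1 − 2·e^(−TI/T1) − e^(−TR/T1) + 2·e^(−(TR−TE/2)/T1) | · e^(−TE/T2)

which differs from the common fitting form (1 − 2e^(−TI/T1) + e^(−TR/T1))
by a term of order e^(−TR/T1); for the protocols here the difference is
below 5·10⁻⁴ of the equilibrium signal, far under the noise floor of any
real acquisition, and the fitting form is retained for mapping.

Ideal spoiling zeroes the transverse magnetization immediately before
every excitation — the closed-form counterpart of crusher gradients, and
a definition that remains unambiguous in interleaved multi-slice
timelines. Steady-state preparation prepends dummy TR cycles with the
ADCs removed (two by default in the experiment runner; the oracle tests
use ten, giving transients below 10⁻⁶).

Off-resonance, B1 inhomogeneity, diffusion, flow and intra-voxel
dephasing (T2*) are not modeled. One isochromat per voxel: with
relaxation nearly constant across a readout, the simulated k-space is
then the exact discrete Fourier transform of the PD map, which the
encoding-oracle tests exploit (< 0.01% at 16×16, < 2% required at 64×64).

## Phantoms

* **Grid phantom:** uniform-relaxation disk (radius 0.46·FOV) crossed by
  zero-PD lines every `period` voxels — a resolution target.
* **Sphere planes:** ten disjoint spheres (radius 20 mm; one center,
  three at 52 mm, six at 92 mm) in a 115 mm disk of background material
  (PD 0.2, T1 3 s, T2 1 s — water-like), with T1 = 0.05…2.0 s on the T1
  plane and T2 = 0.02…0.3 s on the T2 plane, bracketing the protocols'
  TI/TE ranges. These are *synthetic stand-ins* for the calibrated sphere
  arrays of commercial system phantoms, whose certified values are not
  reproduced here; the 20 mm radius keeps each sphere ≳2.5 voxels at the
  32×32 desk scale so that eroded interior ROIs exist at all. Passing
  recovery tests therefore demonstrate pipeline correctness
  (self-consistency of simulation, reconstruction and fitting), not
  agreement with any physical phantom.

Coordinates are FOV-centered with a half-voxel offset (voxel (0,0) top
left; x right, y up). The reconstruction realizes the half-voxel offset
as k-space phase ramps, so reconstructed images overlay the phantom
raster exactly — the convention every oracle test depends on.

## Reconstruction

Readouts are regrouped by (slice, contrast), splitting by echo index when
phase-encode lines repeat (variable-TE data); duplicated or missing lines
raise errors naming the lines. Apodization multiplies k-space with the
n-point 2D Hamming window (0.54 − 0.46·cos 2πk/(n−1)); it defaults on for
quantitative mapping data and off for qualitative imaging. The centered
inverse FFT convention (k-space center and image DC at index n/2, row
direction carrying decreasing y) is fixed and tested against a
brute-force DFT. Channels combine by sum of squares; the image set is
normalized jointly by its single global maximum so inter-contrast ratios
survive normalization — a requirement for fitting signal equations to
normalized images.

## Mapping

Bounded trust-region least squares (T1, T2 ∈ [1 ms, 10 s]; A ≥ 0; B
free; cost tolerance 1e-10, ≤ 800 function evaluations). The IR model is
fitted in magnitude form — reconstruction outputs magnitudes and no
polarity restoration is attempted. The magnitude kink creates local
minima when the null point TI = T1·ln 2 falls between sampled TIs, so the
fitter multi-starts from every TI-implied null candidate and keeps the
lowest cost; the T2 initializer comes from a log-linear regression of
S − min S. Convergence excludes fits pinned at the parameter bounds;
degenerate inputs (zero or constant signal) return non-converged results
rather than raising. ROI statistics use converged voxels only, with
sphere ROIs derived by eroding each sphere by one voxel — a programmatic
replacement for manual interior ROI selection, recorded as a divergence
from interactive practice.

Known limitation: multi-echo TSE T2 under imperfect refocusing would be
biased by stimulated echoes; with the ideal 180° pulses simulated here
the echo-train decay is purely e^(−TE/T2), so this bias is not exercised.
At low SNR the information content of the 3-parameter exponential fit
bounds what any fitter can do — e.g. at image SNR 50 the per-voxel
Cramér–Rao bound for T2 = 0.3 s sampled at TE ≤ 161 ms is ≈ 40%, so
per-sphere medians over the handful of interior voxels available at the
32×32 desk scale scatter by tens of percent for the longest spheres.
The test suite states this expectation explicitly rather than averaging
it away.

## Metrics and RF power

PSNR is 10·log₁₀(R²/MSE) on [0,1]-normalized images, with identical
images reported as a 300 dB sentinel instead of infinity. SSIM uses the
original publication's constants (Gaussian window σ = 1.5, C1 = 0.0001,
C2 = 0.0009 for R = 1) via scikit-image. RF power is reported as the
time-averaged |B1|² (Hz²) plus duty cycle — deliberately *relative*
units; absolute SAR in W/kg requires an electromagnetic body model that
is out of scope, and only the conventional 70 kg reference mass is
book-kept.

## Problem sizes

The default test and acceptance runs use 32×32 matrices (64×64 for the
encoding oracle), the full 10-TI and 23-echo contrast sets, and the full
11-slice qualitative IRSE; native 128/256-matrix sequences are generated
and round-tripped in full but only simulated at desk scale. These sizes
were chosen so a complete validation pass runs on a laptop-class machine
in a couple of minutes while every contrast dimension stays at its
protocol value.
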