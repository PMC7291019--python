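# Methods

This note records the models the package implements, the defaults it
ships, and the reasoning behind choices that were genuinely open.

## Decay model and reconvolution fitting

The donor emission of a well is modelled as a mixture of exponentials,
F(t) = Σᵢ xᵢ exp(−t/τᵢ) with Σxᵢ = 1, observed through the instrument
response function (IRF). The screening readout is the amplitude-weighted
mean lifetime τ = Σ xᵢτᵢ; FRET efficiency follows from donor lifetimes with
and without acceptor, E = 1 − τ_DA/τ_D. Amplitude normalisation to Σxᵢ = 1
is this package's convention; fits estimate unnormalised component
amplitudes and report fractions.

Fitting is by *reconvolution*: the model — not the data — is convolved with
the IRF and adjusted by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective). Deconvolving the
data would amplify noise; reconvolution is the numerically stable standard.
For the two supported IRF shapes the convolution is evaluated in closed
form: a delta IRF reduces to the bare exponential, and a Gaussian IRF gives
the exponentially modified Gaussian, computed through `erfcx` on the early-
time branch and the plain `erfc` form at late times so that neither branch
overflows for small lifetimes. Closed-form evaluation is what lets the
model agree with an independent analytic oracle to better than 1e−6 and
keeps per-well fits fast (~15 ms).

Fit details: amplitudes bounded ≥ 0, lifetimes bounded to [0.02, 30] ns, a
constant baseline fitted by default (real detectors have offsets).
Initialisation is automatic — baseline from the 5th percentile, total
amplitude from the background-subtracted peak, lifetime scale from a
log-linear fit to the decay tail; two-component fits start at (1.3, 0.45)×
that scale. Components are reported in descending amplitude order, and a
stalled optimiser sets `converged=False` rather than raising. Degenerate
(zero-dynamic-range) waveforms are rejected with an error.

## Synthetic data: what it emulates and what it does not

The simulator is the package's source of inputs and defines its operating
conditions:

* **Time base**: 0–50 ns in 0.25 ns steps (200 points); Gaussian IRF,
  FWHM 1.0 ns, centred at 10 ns. Instrument vendors do not publish these
  figures for fast direct-waveform-recording readers; a 1 ns FWHM is
  typical of microchip-laser/PMT chains and, being Gaussian, analytically
  checkable. The grid covers the default 2.5 ns longest lifetime 16-fold;
  simulation refuses grids covering less than 5× the longest lifetime.
* **Donor decay**: bi-exponential, x = (0.6, 0.4), τ = (2.5, 1.25) ns,
  mean 2.0 ns — the ~2 ns regime of GFP-family donors.
* **Two channels**: Ch2 is a fixed spectral fraction (0.43) of the Ch1
  decay model. In the noiseless, contaminant-free case the integrated
  Ch2/Ch1 ratio equals that fraction exactly, for any lifetime — which is
  precisely why ratio deviations isolate compound fluorescence. The ~40 ns
  electronic delay some instruments insert in the second channel is a
  cabling artifact and is not modelled; both channels share one time axis.
* **Noise**: additive Gaussian with σ = √(expected counts) per sample (the
  Gaussian limit of Poisson counting noise; exact Poisson and fixed-σ
  Gaussian are also available). The default per-well integrated intensity
  of 1e6 counts was calibrated so the SD of fitted mean lifetimes across
  vehicle wells is ≈ 6.6 ps, inside the ≤ 10 ps precision envelope the
  pipeline assumes of the instrument. No photon-level TCSPC simulation, no
  polarisation, no well-position (edge/drift) effects — so passing tests
  demonstrate the statistics of the pipeline, not robustness to spatial
  plate artifacts.
* **Plates**: 1536-well (32 × 48, vehicle controls in columns 1, 2, 47,
  48) or 384-well (16 × 24, controls in columns 1, 2, 23, 24); optional
  tool-compound columns carved from the control columns (default planted
  effect −150 ps, a saturating FRET-increasing inhibitor). Planted effects
  are per-well: a lifetime shift (all components shifted equally, so the
  mean shifts by exactly Δτ) or a fluorescent contaminant — an added
  exponential with its own lifetime and independent per-channel intensity
  fractions, the minimal model that perturbs both the fitted lifetime and
  the channel ratio. Ground truth is retained in the plate map for scoring
  recall/precision.
* **Functional assays**: Hill-shaped activity curves in pCa
  (activity = lower + (upper−lower)/(1 + 10^{n_H(pCa−pCa50)})) or molar
  concentration; Ca-uptake traces as exponential approach to a floor with
  initial slope −rate. Canonical conditions ship as constants: control
  pCa50 6.62 and fusion pCa50 6.38 (n_H = 2.0, 8 replicates on a 13-point
  pCa grid from 7.8 to 5.0), with per-point noise SDs (0.155 and 0.115 of
  the activity span) chosen so the refitted midpoint standard errors land
  on the assay's reported precision (~0.04 and ~0.03 pCa units); and a
  7.5 nM-midpoint lifetime CRC over 9 log-spaced doses (0.1–316 nM,
  triplicate, 8 ps response noise). The Hill coefficient 2.0 reflects
  typical calcium-pump cooperativity; the sources state none.

## Triage statistics

Order of operations: fit → flag → hit-select → counter-screen → rZ′.

* **Flagging**: percent difference of a well's integrated Ch2/Ch1 ratio
  from the DMSO mean, two-sided, flagged when strictly beyond 3 × SD of the
  DMSO percent differences. Plain SD (not MAD) is used for the flag and hit
  thresholds — the screen's stated rule — while MAD enters only rZ′.
  Intensities are trapezoidal integrals of the full window; a peak-ratio
  option exists. On null plates the flag fires at the two-sided Gaussian
  rate (~0.27%, slightly inflated by threshold estimation from 128 control
  wells).
* **Hit selection**: |τ_well − median(τ_DMSO)| > k·SD(τ_DMSO) for
  k ∈ {3, 5, 7}, restricted to unflagged compound wells; the direction
  (lifetime decrease = FRET increase) is recorded. The median is used as
  the centre, consistent with the robust philosophy of rZ′; ties at the
  threshold are not hits (strict inequality, "more than"). Hit sets are
  nested by construction: 7 SD ⊆ 5 SD ⊆ 3 SD.
* **Counter-screen**: a hit passes only if its shift on the linker-only
  biosensor stays strictly within 3 linker-DMSO SDs; hits absent from the
  linker plate are reported `untested`, never `pass`.
* **Robust Z′**: computed on per-well mean lifetimes (the directly measured
  quantity; equivalent to FRET units up to the monotone E(τ) map when τ_D
  is a plate constant). rZ′ = 0.5 corresponds to 12 pooled SDs of
  separation for equal-noise Gaussian controls; equal medians raise a
  zero-dynamic-range error. rZ′ is invariant under common affine rescaling
  of both populations.
* Wells on repeated reads of the same plate are treated as independent
  plates; no cross-read combination rule is imposed. Reproducibility across
  repeated screens is left to the caller (a majority rule is the natural
  choice and is not hard-coded).

## Dose-response and rates

The default Hill fit is four-parameter (midpoint, n_H, both plateaus free —
real curves have nonzero baselines); a fixed-floor three-parameter variant
exists. Concentration-mode fits run in log10(x) for conditioning and
convert back (delta method for the EC50 SE). The pCa-mode sigmoid is
oriented so activity rises as free calcium rises (pCa falls); fitting in
one mode and converting matches the other mode to 1e−6 on noiseless data.
A non-saturation diagnostic (`saturated=False`) is set when the upper
plateau's SE exceeds the plateau estimate — the midpoint then extrapolates
beyond the data. Biphasic (bell-shaped) responses are *not* modelled: the
fit warns on non-monotonicity beyond noise and the caller may fit the
rising limb only. pCa50 shifts are differences of midpoints with SEs
combined in quadrature.

Uptake initial rates are minus the slope of a linear fit over the first 20%
of the trace (configurable); ATPase rates convert −dA340/dt through the
NADH extinction coefficient (6220 M⁻¹cm⁻¹) and a 0.55 cm default path
length (200 µL in a 96-well plate), with basal (calcium-free) activity
subtracted by plain arithmetic.

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.default_rng` seeds; identical
  config + seed reproduces plates and result tables byte-for-byte. Plate
  wells consume draws from a single per-plate generator in well order.
* The exGaussian branch switch is at z = 0 of the scaled-erfc argument;
  both branches agree there to machine precision.
* `mad` of fewer than two values and empty inputs are errors, as are
  all-constant DMSO populations wherever an SD threshold is needed.
* Simulated-plate screens fit ~15 ms/well single-threaded; a full 1536-well
  plate triages in under a minute. Pipeline-level tests use 384-well plates
  or single 1536-well fixtures to keep the suite quick.

## Known limitations

* Only Gaussian and delta IRFs; no measured-IRF import (a tabulated IRF
  would need a discrete-convolution path with its own accuracy analysis).
* One- and two-component fits only; no global (linked-lifetime) analysis
  across wells, no phasor analysis, no FLIM images.
* The simulator's well-to-well variation is purely shot noise — no
  dispensing volume error, evaporation gradients, or edge effects.
* Free-calcium speciation (EGTA buffering) is out of scope; pCa values are
  taken as given.
* Channel centre wavelengths are metadata only; the package does not model
  emission spectra.
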