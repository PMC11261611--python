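# Methods

`tonguechip` simulates and analyses taste-receptor array experiments in a
microfluidic flow cell: an array of reverse-transfected receptor spots
(each co-expressing the Twitch2B FRET calcium sensor) is exposed to loop-
injected tastant samples in a constant buffer flow, and imaged in two
interleaved fluorescence channels (CFP donor, YFP acceptor).  The package
has two halves: a synthetic data generator that emulates the platform's
raw output, and the analysis pipeline that turns two-channel traces into
the platform's metrics — iRatio peak responses, onset and Δfwhm
lingering, Hill EC50/EC10 estimates, and mixed-model blocking contrasts.

## Flow-cell exposure model

The sample loop converts a valve switch into a rectangular concentration
pulse of duration `injection_volume / flow_rate` (the *theoretical
exposure*; 300 µL at 300 µL/min gives 60 s).  Transport to and through
the cell disperses the pulse; we model this with a tanks-in-series
(Erlang) kernel — `n_tanks` well-mixed stages whose total mean residence
time is `cell_volume / flow_rate` — optionally mixed with a slow
exponential "dead-zone" tail (`tailing_fraction`, `tailing_tau`) that
makes wash-out shallower than wash-in, as dye measurements show.  The
exposure profile is the pulse convolved with the normalised kernel,
clipped at 1 (relative concentration).  Defaults: `n_tanks = 3`,
`dt = 0.5 s` (0.1 s for calibration-grade fwhm), washout window of five
mean residence times.

Because the system is linear and the pulse reaches plateau for all
standard conditions, the peak's full width at half maximum equals the
plug duration — which is why the measured dye fwhm tracks the theoretical
exposure across the calibration grid.  Peak metrics use linearly
interpolated half-maximum crossings (first upward, last downward) and
central-difference derivatives in percent of peak per second.

The model deliberately excludes Taylor–Aris dispersion and any
position-resolved transport; the several-second spread of arrival times
across the array is represented as a per-spot delay in the generator.
The known shortfall of nominal 1 mL loops is available as an
`effective_loop_volume` override but is not applied by default.

## Receptor response model

Per spot, receptor occupancy is a Hill function of the local ligand
concentration `c(t)` (the exposure profile shifted by the spot's arrival
delay, times the sample dose): `o = Σ_ligands a·c^h / (c^h + (EC50·S)^h)`,
capped at 1, where `S = 1 + Σ [antagonist]/Ki` is the competitive-shift
factor.  Mixtures therefore combine agonists additively at the occupancy
level, and antagonists act purely through the EC50 shift — at `[I] = Ki`
and `h = 1` the effective EC50 doubles.

The calcium signal is occupancy passed through a linear
activation/decay chain plus one nonlinearity:

1. *adaptation*: a low-passed copy of occupancy (time constant
   `adapt_tau`) is subtracted with weight `adapt_weight`, making the
   response to a sustained stimulus transient.  IP3-driven calcium
   release behaves this way: prolonged receptor occupation does not hold
   cytosolic calcium at its peak.  Without this term a saturating dose
   pins occupancy at its ceiling for the whole exposure and the response
   peak can only occur at wash-out, which contradicts the near-
   instantaneous peak the platform records for high-dose advantame.
2. *activation rate limit*: a first-order filter with rate `k_act`.
3. *decay kernel*: convolution with the normalised mixture
   `(1−w)·Exp(k_dec) + w·Exp(1/linger_tau)` — a fast decay plus a slow
   "lingering" pool with weight `w = linger_weight`.

Repeated near-saturating exposures (dose above 0.8× the dose giving 95 %
occupancy) multiply the amplitude by `desens_factor` per prior strong
exposure — the desensitization seen when saturating injections repeat.

Channels are rendered as `YFP = B_Y (1 + α·s) (1 + ε)` and
`CFP = B_C (1 − β·s) (1 + ε′)` with independent multiplicative Gaussian
noise of CV 1 % per frame, baselines 1000 a.u., α = β = 0.15, and YFP
sampled half a frame after CFP (interleaved acquisition).  High-osmolarity
samples subtract a non-specific "dip" term `γ·(osmolarity/100 mM)·c(t)`
from the signal of every cell-bearing spot; a fluorescein injection adds
a purely optical bump to the acceptor channel of every spot (the exposure
reference), while the fixed-ratio sensor-control (YC) spots receive
optical artifacts identically in both channels, so their ratio is flat.

## Calibrated constants

The platform's papers print metrics, not raw traces, so the per-sweetener
kinetic constants (`k_act`, `k_dec`, `linger_weight`, `linger_tau`,
`adapt_weight`, `adapt_tau`) and the cyclamate inhibition constants for
TAS2R8/31/43 cannot be read off data.  `scripts/calibrate_presets.py`
derives them once: a coarse grid plus shrinking random search and a
Nelder-Mead polish minimise, on the *noiseless* end-to-end pipeline, the
squared error of (onset, Δfwhm) at the maximal dose against the published
values, with secondary penalties that keep the apparent EC50 of the
simulated dose series on the published midpoint, the peak response above
the 1 % noise detection floor, and the noisy-median estimate consistent
with the noiseless value (curve shapes whose metrics are only
well-defined without noise — broad maxima, shelves grazing the half-
maximum line — are thereby rejected, the published value itself always
being matched noiselessly).  Cyclamate Ki
values are then solved by bisection so the noiseless blocking
percentages match the published 33/48/92 % reductions.  The resulting
constants are frozen in `presets.py`; they are study conditions, not
user-facing knobs.

## Analysis pipeline

*QC*: spots with fewer than 15 fluorescent pixels are dropped, then any
receptor group left with fewer than 5 replicates (both thresholds
strict).  *Ratio*: each channel is smoothed (3-point moving average) and
linearly interpolated onto a common 1 s grid; the ratio is
acceptor/donor so calcium rises give upward peaks.  *iRatio*: per
injection, the window is the valve time plus the exposure duration plus
120 s (truncated at the next injection); the baseline is the mean over
the 10 s before the window; the response is the window maximum minus
baseline, floored at zero.  *Reference correction*: the deviation of a
non-responding reference group's mean trace (umami preferred, mock as
fallback) from its baseline is subtracted from a target trace, removing
the shared osmotic dip while preserving the receptor-specific peak;
correction is subtractive because the dip superposes additively on the
specific signal.

*Kinetics*: the response curve is the umami-corrected mean trace of the
receptor group around the agonist injection; the reference curve is the
uncorrected mean trace of all cell-bearing spots around the fluorescein
injection (the dye signal is common to all spots, so correcting it away
would be self-defeating, and the wide average minimises reference noise).
Both are synchronised so the valve sits at T = 50 s, lightly smoothed
(5 s moving average) and normalised to 0–100 %.  Onset is the peak-time
difference between response and reference, with the peak time taken as
the centroid of the samples within 5 % of the maximum: a raw
first-sample-attaining-the-maximum rule is biased several seconds late
and highly variable under 1 % channel noise whenever the top is broad,
whereas the centroid treats the near-maximum band symmetrically and
averages enough samples to be stable.  An
onset-90 variant (first crossing of 90 %) is available.  Δfwhm lingering
is the response fwhm minus the reference fwhm (interpolated crossings of
the fixed 50 % line; an optional debounce for spurious re-crossings is
off by default because it clips genuinely shallow lingering tails),
reported as "none" when not positive.  Slope metrics are derivative extrema in %/s, also
expressed relative to the reference.

*Dose-response*: four-parameter logistic fitted by least squares in
log10-dose, initialised at (min, max, geometric-mean dose, slope 1) with
EC50 bounded a decade beyond the tested range and slope in (0, 10].  The
default fit uses per-spot responses so parameter uncertainty reflects
spot variance.  For recovery on the presets the fit instead uses one
response per dose read off the umami-corrected mean trace — the
procedure the platform documents — because per-spot window maxima carry
a max-of-noise floor (≈0.02 ratio units at 1 % channel noise) that
distorts sub-threshold doses; with only five such points the fitted top
and EC50 trade off along a ridge, so the top is capped at 1.25× the
largest observed response (the assumption that the highest tested dose
reaches ≥80 % of saturation).  EC10, the proposed taste-threshold
analog, is the closed-form inverse `EC50·(f/(1−f))^(1/h)` at f = 0.1.
No correction is applied for the sequential-exposure desensitization
bias of ascending series (an injection-order covariate could be added,
but the published estimates carry the same bias).

*Contrasts*: per receptor group, log iRatio (floored at 1e−4 before the
log, with floored counts logged) is modelled with injection as a fixed
effect and spot as a random intercept, fitted by REML
(statsmodels MixedLM); singular fits fall back to ordinary least squares
with a logged notice.  Treatment-versus-control contrasts are
differences of injection coefficients, exponentiated, with Wald 95 %
intervals; an estimate is significant when its interval excludes 1.  The
blocking percentage is `100·(E_pure − E_mix)/(E_pure − 1)` clipped to
[0, 100]: the reduction of the *excess* multiplicative effect, which
correctly reports 100 % when the mixture effect returns to 1.  No
multiple-testing correction is applied across receptors.

## What the generator does and does not emulate

The generator reproduces the statistical structure the analysis relies
on: replicate spots with QC failures, arrival-time spread, interleaved
channel sampling, multiplicative channel noise, osmotic dips, optical
dye references, desensitization, and competitive antagonism.  It does
not emulate image-level segmentation noise, spatial crosstalk between
neighbouring spots, slow baseline drift, transfection-efficiency
variation between arrays (a single amplitude per receptor stands in for
the gene-dose optimisation), or mechanistic IP3/PLCβ2 signalling.
Passing recovery tests therefore shows the pipeline is correct and
well-conditioned under the platform's nominal noise model, not that it
is robust to every artifact of real imaging data.

## Numerical choices and degenerate inputs

Half-maximum crossings are linearly interpolated; flat profiles raise
explicit no-peak errors; zero-dynamic-range curves raise degenerate-curve
errors rather than dividing by zero; non-positive intensities name the
spot and time; an empty post-QC array raises an all-filtered error.
Simulation grids: dt = 0.5 s for traces (0.1 s where calibration-grade
fwhm is needed), channel frames every 2 s, analysis grid 1 s.  Problem
sizes in tests and the acceptance script (20 simulated arrays per
stochastic quantity, 500 null datasets for CI coverage, 5–15 replicate
spots per receptor) were chosen to keep each recovery's median stable
while a full run stays comfortably within a coffee break on one CPU.

## Known limitations

* Onset and Δfwhm at the high advantame dose are measured at the
  precision limit of the assay model: a response that peaks with the dye
  (onset ~5 s) yet lingers 39 s necessarily has a broad near-maximum
  region, so at 1 % channel noise the median over 20 simulated arrays
  still scatters by ±2–3 s around the noiseless value — the same order
  as the ±2 s the platform quotes for single onset measurements.

* The aspartame preset misses its published kinetics by a few seconds
  (onset 16 vs 18 s, Δfwhm ~15 vs 12 s): under the flow model's
  saturation widening, no bounded kinetic solution hits both exactly.
  Aspartame is not used by any recovery check; the constants are the
  calibration optimum.
* The synthetic dye peak is ~62 s wide versus the platform's 68–69 s;
  relative metrics (onset, Δfwhm) are insensitive to this, and a heavier
  dead-zone tail would make saturated responses unrealistically wide.
* EC50 recovery at 1 % noise is accurate to ~10 % (median over 20
  arrays), limited by the max-statistic noise floor and the five-point
  design, not by the fitter.
* Absolute iRatio scales are arbitrary; only relative and kinetic
  quantities are calibrated.
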