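# Methods

## The loss model

A tonically firing neuron is modeled as a renewal process whose
interspike intervals (ISIs) are Gamma-distributed with shape `a`
(dimensionless) and scale `b` (seconds); the mean ISI is `mu = a*b` and
the mean rate `r = 1/mu`. The parametrization is shape/SCALE (`b`
multiplies); this is stated loudly in the code because libraries differ.
The shape controls firing regularity: `a = 1` is the memoryless limit,
larger `a` is more clock-like. The reference cell is a tonically active
interneuron with `r = 1.12` Hz; only the mean rate of such cells is
typically reported, so the default shape `a = 2` is a modeling choice —
regular, non-exponential tonic firing with a unimodal ISI histogram — and
is configurable everywhere. In the regimes of interest (mean ISI much
longer than the stimulation period) the loss is insensitive to the shape,
which the rate-independence checks confirm.

Periodic stimulation at `f_st` with a blanking window `t_b = pw + t_m`
zeroes the signal in the windows `[k*t_st + phase, k*t_st + phase + t_b)`.
Measuring time from the previous spike, the probability that the next
spike lands in a blanked window is the sum of the ISI mass inside each
window, truncated at the 99.95th ISI percentile `x_9995`:

* blanked-bin count `n_b = floor(x_9995 / t_st)`;
* window onsets `x_n = n*t_st + phase` for `n = -1 .. n_b`, where the
  `n = -1` window (clipped at zero) is the blank already in progress at
  the previous spike — it contributes only when `phase + t_b > t_st` and
  is what makes the exact-tiling case `t_b = t_st` lose everything at
  every phase;
* windows are half-open so adjacent windows never double-count;
* the `<= 0.05%` tail mass beyond `x_9995` counts as detectable;
* `fully_blanked` is the strict condition `n_b * t_b > x_9995`; exact
  tiling (`t_b = t_st`) is deliberately not flagged, by the floor
  identity `n_b * t_st <= x_9995`. When the flag is set the loss is
  floored at 0.9995 so the detectable probability respects the
  truncation bound. Protocols with `t_b > t_st` are accepted (sweep
  grids cross that boundary) and reported fully blanked rather than
  rejected.

The spike-to-stimulus phase is unobservable, so the headline quantity is
the arithmetic mean of the phase-locked loss over phases uniformly spaced
on `[0, t_st)`; 64 phases are used by default (the change from 64 to 128
is below 1e-4 in all tested regimes). In the broad-ISI limit
(`mu >= 20 t_st`) the phase-averaged loss equals the blanking duty cycle
`min(1, t_b * f_st)` within 0.01.

Numerics: the ISI distribution functions delegate to the regularized
incomplete gamma function (`scipy.special.gammainc` / `gammaincinv`);
percentiles are therefore exact inverses rather than root-finding
approximations, and the interval mass is validated against brute-force
trapezoidal integration at 1e-7. `fit_isi` is the profile-likelihood MLE
with the location pinned at zero (`scipy.stats.gamma.fit(..., floc=0)`),
which solves the digamma equation in the shape and preserves the sample
mean exactly; it requires at least 10 strictly positive samples with
nonzero variance.

## The synthetic ground truth

The generator emulates cell-attached-quality recordings of one tonic
neuron during stimulation:

* **Spike trains** — i.i.d. Gamma ISI draws accumulated from zero; all
  randomness flows through one `numpy` Generator per call, seeded
  explicitly, so trains and traces are byte-identical across reruns.
* **Traces** — Gaussian noise (default SD 0.05 of the spike amplitude,
  i.e. SNR 20) plus a biphasic spike template (Hann-windowed sine period,
  width 1.5 ms, sharp negative deflection then shallower rebound, unit
  amplitude) at every spike time, sampled at 20 kHz.
* **Artifacts** — at every stimulus onset `k*t_st`: a biphasic
  rectangular pulse (65 us default) evaluated on the coarse sample grid —
  which reproduces the aliased, non-rectangular artifact shapes seen when
  digitizing rectangular pulses — plus an exponential capacitive tail
  (amplitude 3x the spike, tau 0.5 ms). No published values exist for the
  artifact amplitude or decay constant; these defaults are package
  decisions chosen to put the artifact clearly above the spike without
  saturation.
* **Blanking** — samples whose time falls in a blanking window are set to
  exactly zero; everything else is bit-identical. The stimulus train is
  strictly periodic from t = 0 and the `phase` parameter shifts the
  blanking comb only (trigger-to-blank alignment), not the artifact.

Train-level loss uses the peak-in-window rule (spike peak time inside a
blanked interval), mirroring the analytic ISI-bin nullification; the
stricter trace-level notion (detector misses a partially clipped
waveform) is measured by the detector. Both are reported by the
experiment layer.

What the generator does **not** emulate: bursting or history-dependent
firing, stimulation-evoked rate changes, electrode drift, multi-unit
activity, amplifier recovery transients, or non-Gaussian noise. Passing
tests therefore demonstrate correctness of the loss accounting under the
stated renewal model, not detector performance on arbitrary real
recordings.

## The detector

Calibration (artifact-free baseline, >= 10 s, >= 5 events): noise level
as robust scale (MAD x 1.4826); amplitude threshold `k = 5` times that;
template as the mean of aligned, edge-detrended, peak-normalized events;
slope bands `[1 - tol, 1 + tol]` (tol = 0.5) around the median
peak-to-trough secant slopes of the rise (snippet start to negative peak)
and fall (negative peak to the template's rebound position). No numeric
thresholds are published for this class of detector; these defaults are
conventional and all exposed as parameters.

Detection on contaminated traces proceeds per overlapping analysis
window (50 ms, 50% overlap by default; results are invariant to the
overlap because candidate minimality is evaluated on the full trace):

1. runs of four or more exactly-zero samples are marked as blanked
   (hardware blanking writes identical zeros; noise never does);
2. isolated impulsive samples — the aliased stimulus pulse digitizes to
   one or two extreme samples — are clamped to their 3-point rolling
   median when they deviate by more than 8x the noise level
   (impulse-noise rejection, not artifact subtraction);
3. candidates are negative-going extrema whose *prominence* over the
   local baseline exceeds the amplitude threshold, so a spike riding an
   artifact decay tail is still found while a baseline step fabricates
   nothing;
4. each candidate (with a +/-2-sample alignment search) is scored by a
   robust matched-subspace fit `snippet ~ alpha*template + nuisance`:
   the worst ~10% of samples are excluded and the fit repeated; the
   shape score is the partial correlation of the template given the
   nuisance, `sqrt(1 - RSS_full/RSS_nuisance)` — the template must
   explain variance the nuisance cannot;
5. the plain nuisance is an orthonormal cubic polynomial basis. If the
   snippet contains a jump too large to be spike slope (3x the fitted
   spike's steepest sample-to-sample step, with an 8x-noise floor), the
   fit is repeated with one-sided step/ramp/parabola columns anchored at
   the jump so an artifact onset and its decay can be absorbed; if that
   is ambiguous (the one-sided basis can absorb a spike rebound too) the
   template is validated on the uncontaminated side of the jump alone,
   provided that side carries at least 40% of the template energy;
6. accepted events must clear the amplitude threshold and both slope
   bands (slopes from the nuisance-subtracted snippet, normalized by the
   fitted amplitude), and candidates whose feature-bearing template span
   (|template| >= 10% of peak) overlaps a blanked zero-run are rejected
   as clipped — blanked spikes are not detected, which is the loss
   mechanism under study;
7. events within one template width are merged, keeping the deepest.

Scoring against ground truth matches detections to true spike times
one-to-one within half a template width; loss = 1 - recall. Ground-truth
events within one template width of the trace edges are excluded as not
fully observable. With no detections and no truth events both recall and
precision are defined as 1.

Measured behavior under the default conditions: on artifact-free traces
at SNR 20, recall = precision = 1 across seeds; with artifacts but no
blanking, residual loss is a few percent (direct spike-pulse collisions)
with precision 1; on blanked traces the realized loss exceeds the
peak-in-window prediction by a clipping excess bounded by
(template width) x f_st, as partially clipped waveforms fail validation.

## Experiment layer

`run_experiment` emulates the study paradigm per replicate seed: 100 s
artifact-free baseline, 100 s stimulated phase with artifacts, blanking
(default phase policy "fixed" at 0 — the blank starts at the stimulus
trigger, as hardware does; "averaged" and "random-per-run" are options),
detector calibration on the baseline, detection on both phases, and
scoring. Triplicate cells are emulated as three independent seeds of the
same ISI model; the inter-run rest period of the wet-lab protocol has no
effect in a stationary simulation and is not modeled. Sub-seeds for
train and noise generation are spawned from the replicate seed via
`numpy.random.SeedSequence`, keeping every replicate independent and
reproducible. The report attaches the analytic phase-averaged loss and
the duty-cycle reference, and flags agreement within three binomial
standard errors of the pooled spike count plus the clipping bound.

Figures (loss heat surfaces with overlay lines at the 1.12 Hz reference
rate and the common 2 ms window) are optional artifacts; all quantitative
outputs are CSV/JSON.

## Problem sizes

The analytic figures use 64 phases and 1 Hz frequency steps. Monte-Carlo
validation uses 50 seeds of 10^4 s trains for the train-level oracle and
10-20 seeds of 100 s traces for the detector-level checks; binomial
standard errors at those counts set the stated tolerances.

## Known limitations

* The shape of the reference cell's ISI distribution is not identifiable
  from its published mean rate; the default `a = 2` is a choice, and
  exact reproduction of a specific fitted ISI histogram is out of reach.
* The loss model treats consecutive ISIs independently (renewal); serial
  ISI correlations would perturb the phase-averaging argument, though not
  the broad-ISI duty-cycle limit.
* The detector's contamination handling is tuned to the synthetic
  artifact family (aliased pulse + exponential tail); real artifact
  morphologies vary and may require adjusting the nuisance model.
* Blanked-interval identification via exact-zero runs assumes the
  recording chain writes true zeros during blanking, which is how
  blanking hardware behaves but would not hold for, e.g., dithered ADCs.
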