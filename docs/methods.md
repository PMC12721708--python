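# Methods

This note documents the models, conventions and numerical choices behind
`caplast`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic tests do and do not
establish about real data.

## Forward model of the synthetic generator

A session is a set of ROIs × trials × frames sampled at a fixed frame rate
(default 30.98 Hz, 620-frame = 20 s trials, one stimulus per trial at frame
155). Per trial the latent calcium signal follows an AR(1) recursion

    c[t] = γ · c[t−1] + s[t],        0 < γ < 1,

driven by non-negative impulses `s`: spontaneous events from per-frame
Poisson thinning of a rate (default 0.1 events/s — sparse activity typical
of L2/3 pyramidal neurons with GCaMP6f), plus at most one stimulus-locked
evoked event per trial (probability 0.8, latency 50 ms with uniform ±30 ms
jitter rounded to the nearest frame). Event amplitudes are
N(0.5, 0.1²) ΔF/F clipped at zero; post-induction evoked amplitudes are
multiplied by the *plasticity factor*, the ground truth of the plasticity
stage. Fluorescence is read out as

    F[t] = baseline_f · (1 + c[t]) + ε[t],   ε ~ N(0, noise_sd²),

so `noise_sd/baseline_f` is the ΔF/F-scale noise (defaults 2/100 = 0.02;
the recovery tests use 10/100 = 0.1, i.e. evoked SNR 5). γ defaults to
0.92, matching an indicator decay constant of roughly 400 ms at 30.98 Hz
via γ = exp(−1/(τ·rate)).

One master seed feeds three independent substreams (event placement +
amplitudes, latency jitter, readout noise), so changing the noise level
never moves an event. Identical configuration + seed gives bit-identical
arrays.

What the generator deliberately does **not** emulate: pixel-level movies
and neuropil contamination, bleaching, biophysical indicator nonlinearity
(saturating ΔF/F-per-spike), bursting statistics, and slow drifts of the
baseline. Tests passing on this generator therefore establish correctness
of the *computations* under the model the analysis itself assumes — not
robustness to every artifact of real recordings.

Secondary generators produce binary movement traces from explicit
(start, end) bouts, reflectance stacks in which pixels inside an
activation disc darken by a fractional depth from stimulus onset, and
membrane-potential sweeps carrying one double-exponential EPSP normalized
to a stated peak amplitude.

## ΔF/F recipes

*S1*: the scalar 1st percentile of a caller-supplied neuropil-free
background trace is subtracted from all trials; isolated artifact frames
are replaced by the mean of their two neighbours; the concatenated session
trace is smoothed with a 51-point order-1 Savitzky–Golay filter;
F0 is the 1st percentile of the smoothed trace and ΔF/F = (smoothed−F0)/F0.
F0 < 0 (possible after background subtraction) inverts the signal, so such
ROIs are rejected rather than analysed; F0 = 0 is an error, not a
rejection. F0 is computed per session — the most natural reading of a
single smoothed session trace; a per-trial variant would change F0 only
marginally for stationary baselines.

*Cerebellar*: per trial, F0 is the 20th percentile of the raw trial trace;
ΔF/F is smoothed with a centered 5-frame moving average and the mean of
the 5 pre-stimulus frames is subtracted from the whole trial, making the
pre-stimulus baseline exactly zero.

An order-1 Savitzky–Golay filter on a symmetric window is identical to a
centered moving average, so both smoothers share one implementation. Edge
handling is *shrink-fit*: the half-window shrinks symmetrically near the
boundaries (the fit window stays centered), which keeps constants and
straight lines fixed points everywhere but leaves the outermost frames
essentially unsmoothed — see "trial-edge frames" below.

**Percentile convention.** All percentiles use midpoint-anchored linear
interpolation (order statistic k at probability (k−0.5)/n), i.e. numpy's
`method="hazen"` and MATLAB's `prctile`. A sort-based oracle pins this in
the tests; other conventions differ by O(1/n) and would silently shift F0
and σ.

**σ and SNR.** σ is the 1st percentile of sample SDs over all 5 s windows
(round(5·rate) = 155 frames at 30.98 Hz) at stride 1 — the most inclusive
reading of "every 5 s period", and a *baseline* noise estimate by
construction (the 1st percentile selects the quietest windows). SNR is
P95 of all ΔF/F samples divided by σ. On pure Gaussian ΔF/F, SNR ≈ 1.645
(the standard normal 95th percentile), which the tests verify by
simulation.

**Rigid motion correction** registers each frame to the mean image (or a
given template) by the integer shift maximizing normalized whole-frame
circular cross-correlation within a search radius, ties broken toward zero
shift; frames are translated back by the negative shift. Normalization
makes the estimate invariant to per-frame intensity scaling. No subpixel
refinement is attempted.

## Event inference

`oasis_ar1` solves

    min_c ‖c − y‖²   s.t.   s[t] = c[t] − γ·c[t−1] ∈ {0} ∪ [s_min, ∞)

by pool-adjacent-violators segment merging (the online active-set method
for the AR(1) kernel): pools are merged whenever the jump into the next
pool falls short of s_min, and each constrained segment decays exactly by
γ per frame. With s_min = 0 this is the exact non-negative solution; the
test suite checks it against explicit non-negative least squares on the
lower-triangular impulse-response design matrix (identical supports,
residual gap < 1e−6 on noiseless instances). The event threshold is
interpreted as a **minimum inferred event amplitude** (s_min = 3σ) rather
than a ΔF/F crossing; no additional sparsity penalty is used. A transient
may carry several consecutive event frames — event count then scales with
transient amplitude — but all per-frame counts downstream are binarized,
so a trial-frame contributes at most one event to P^event.

γ can be supplied (the synthetic tests pass the generator's value),
derived from a decay constant, or estimated from data by the
lag-2/lag-1 autocovariance ratio pooled within trials — lag 0 is inflated
by white readout noise, lags 1 and 2 are not, so their ratio is
noise-robust. Estimates are clipped to (0.5, 0.999); white noise pegs the
estimate at the lower bound.

**Trial-edge frames.** Two boundary effects put spurious supra-threshold
events at trial edges: the shrink-fit smoother leaves the outermost frames
unsmoothed (their noise SD is √window larger than the interior on which σ
was calibrated), and the deconvolution's final pool has no forward
evidence to average over. On event-free sessions this reliably planted
"events" on the last trial frame across trials — a structured artifact
that P^event then amplified into a spurious window at the trial end.
`exclude_edge_frames` clears events within the smoothing half-window
(pipeline default 2 frames) of both trial edges; it is detector hygiene,
not a data-dependent tuning, and costs at most 4/620 of uniformly placed
events.

## P^event and the evoked window

P^event[f] is the fraction of trials with at least one binary event at
frame f; its mean and SD are taken over **all** frames of the trial-time
axis (including pre-stimulus frames — no exclusion is applied, matching
the plain reading of averaging across frames). The evoked window is the
longest run of consecutive frames with P^event above mean + 3·SD, among
runs clipped at stimulus onset (earliest on ties). Clipping rather than
requiring the run to *start* at onset matters: centered smoothing is
acausal and drags the rising edge of a strong evoked run a frame before
the stimulus, and a strict start-at-onset rule would then discard the
evoked run entirely — precisely when the response is strongest. Purely
pre-stimulus runs are still discarded. Durations convert to ms by
round(n/rate·1000): 12 frames at 30.98 Hz is the 387 ms window, a single
frame is 32 ms.

`min_run` (default 1) sets the minimum admissible run length. A known
limitation, stated plainly: on sessions with *no* evoked signal but rare
noise- or coincidence-driven events, a mean + 3·SD threshold is exceeded
by isolated single frames in most finite rasters (a binomial-tail ×
600-frames effect), so with `min_run=1` such sessions can yield spurious
1–2-frame "windows". On literal pure-noise sessions the 3σ-thresholded
raster is empty and no window is ever found; for spontaneously active
null sessions, `min_run=2` (or larger) is the mitigation, at the price of
rejecting genuine single-frame windows.

Responsive trials are those with ≥1 binary event inside the window; a
neuron is responsive iff it has any; *persistent cells* — the unit of all
pre/post comparisons — are the set intersection of responders across the
two conditions.

## Plasticity quantification

Per neuron and epoch, the responsive trials are averaged frame-wise and
the response is summarized over a post-stimulus window: AUC = window mean
× window duration in seconds (reported in ΔF/F·s; by construction exactly
proportional to the mean), amplitude = window max. Window presets:
0–700 ms (default), 650–850 ms (late phase), 0–1750 ms (prolonged
responses). In-window frames are those with
start_ms ≤ (f − onset)/rate·1000 < end_ms (half-open, 0-based). Epochs are
up to 50 min of trials before and 60 min after induction; 10-min binned
trajectories average trials within cells per half-open bin, then across
cells, with empty bins reported missing rather than zero. Animal-level
statistics divide each animal's condition mean by its baseline mean
(animals with zero baseline excluded) and run a one-sample t-test against
1; zero-variance ratio sets are flagged undefined rather than tested.

The recovered post/pre ratio carries a small bias toward 1 from
non-scaling background (spontaneous events falling inside the window);
with the default conditions it stays well inside ±0.05 of the true factor,
and the acceptance checks recover factors 0.7/1.0/1.5 within ±0.1 over 40
neurons through the full pipeline.

## Behavior

Raw video reduces to a per-frame frame-difference energy series; a
threshold (no universal value exists — it depends on camera and scene, so
it is a required parameter) yields a binary movement trace, frame 0
defined non-moving. A trial is *rest* iff no moving frame lies within
±round(0.4·rate) frames of stimulus onset, inclusive at both ends ("at
least 400 ms" read as a closed bound); all others are *active*; trials
whose guard window leaves the trial are flagged unclassifiable. Video and
imaging are assumed sample-synchronous at the same frame rate.

## Intrinsic-signal mapping

Stacks are Gaussian-smoothed (σ default 1 px, configurable — 0 disables)
and downsampled 4× by block means (deterministic, unlike striding); masks
downsample by majority vote. Per trial, R0 is the mean of the 1 s
(30-frame at 30 Hz) pre-stimulus period; post-stimulus frames are averaged
in three 200 ms bins starting 400 ms after onset, each expressed as
(bin − R0)/R0, and summed — a noiseless disc of depth d therefore reads
−3d. ΔR/R is invariant to global illumination scaling by construction.
The trial-averaged image (≥30 trials) is zeroed outside the
cranial-window mask, z-scored over **in-mask pixels only** (zeroed
outside pixels would dilute the statistics with an arbitrary constant),
thresholded at z < −1.5 (reflectance *decreases* mark activation), median
filtered with a 5×5 neighbourhood (binarize-then-filter-then-count
ordering), and the surviving pixel count is normalized by the mask area.
On pure noise the pre-filter activation fraction approaches the Gaussian
tail Φ(−1.5) ≈ 6.7%, and median filtering strictly removes isolated
pixels; both are checked by simulation.

## EPSP metrics

Amplitude is the maximum of the post-pulse segment minus the mean of the
20 ms pre-pulse baseline; latency is the delay from pulse onset to the
first sample where the baseline-subtracted voltage exceeds 10% of that
amplitude. Non-positive amplitudes leave the latency undefined and
flagged.

## Statistical test selection

Each sample is first tested for normality with the Lilliefors test
(statsmodels implementation; p-values from its published small-sample
table) at α = 0.05; constant samples are degenerate and treated as
non-normal; n < 4 cannot be assessed and falls back to the non-parametric
branch with a warning. The decision table is total: paired → paired t
(both normal) or Wilcoxon signed-rank; unpaired → Student t (normal,
equal variances by a two-sided F-ratio test at α = 0.05), Welch t
(normal, unequal variances), or Wilcoxon rank-sum; categorical →
chi-squared without continuity correction; factorial → fixed-effects
two-way ANOVA with interaction (balanced designs; the interaction term is
the reported statistic). Identical paired samples sit at the null centre
(statistic 0, p = 1) by convention. Significance labels: * p<0.05,
** p<0.01, *** p<0.001. Simulation shows the full gated procedure holds
its type-I error within [0.03, 0.07] at nominal 0.05 on Gaussian nulls.

## Problem sizes and determinism

The test and acceptance workloads use deliberately compact sessions —
typically 5 ROIs × 20 trials × 620 frames for detection checks, 40
neurons × 80 trials for plasticity recovery, 1500 simulated cohorts for
the null calibration, 2000 replicates for the type-I calibration — sizes
at which every stochastic check is stable across seeds while the whole
suite runs in minutes. All randomness flows from explicit seeds through
`numpy.random.default_rng`/`SeedSequence`; the end-to-end pipeline writes
a manifest with per-stage SHA-256 checksums, which are identical across
reruns of the same configuration.

## Known limitations

- The generator's realism limits (listed above) bound what green tests
  imply about real recordings; in particular the S1 recipe's 51-point
  smoothing materially widens transients at ~31 Hz, so event *timing*
  checks run on the gentler cerebellar recipe or on ideally normalized
  traces.
- σ underestimates the in-band SD of smoothed, correlated noise by
  design (it is a baseline estimate); with `min_run=1` this can admit
  rare spurious 1–2-frame windows on event-free but spontaneously active
  sessions (see above).
- Motion correction is integer-pixel and circular (np.roll); large shifts
  wrap content at the edges and should be cropped downstream.
- Two-way ANOVA is implemented for balanced designs only; unbalanced
  designs and mixed models are out of scope, as is multiple-comparison
  correction.
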