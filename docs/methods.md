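# Methods

This note documents the models, parameter choices and numerical decisions
behind `ieegflow`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Phase transfer entropy

For phase series φx (driver) and φy (target) of length M and delay τ, PTE
is the plug-in conditional mutual information
I(φy(t+τ); φx(t) | φy(t)) computed from a single joint histogram of
(φy(t+τ), φy(t), φx(t)) over the M − τ valid samples.

Numerical decisions:

- **Bin edges** are fixed to equal-width bins on [−π, π) for every axis.
  Phases live on a known circle; fixed edges make histograms comparable
  across trials and pairs, unlike data-adaptive ranges. The right edge π
  maps into the last bin.
- **Zero-count cells** are skipped (0·log 0 := 0). All marginals are
  computed from the same joint table, which guarantees non-negativity of
  the plug-in estimate up to float rounding (~1e−16). There is no bias
  correction; all scientific claims the package supports are *comparisons*
  of PTE between directions or conditions, for which the plug-in bias
  largely cancels.
- **Logarithm base**: natural log (nats). The base cancels in every
  supported comparison.
- **Delay heuristic** τ = round(2M/M±), floored at 1, where M± counts sign
  changes between consecutive phase samples summed over the two series of
  the analysed pair. For a clean oscillation the phase changes sign twice
  per cycle (one zero crossing, one ±π wrap), so τ lands near half the
  dominant period. "Across channels" is interpreted as the pair's two
  series, not all recorded channels — the heuristic is stated in terms of
  the analysed series, and a global count would make τ depend on unrelated
  electrodes. With no sign change at all (constant-sign phases) the
  fallback is τ = 1 with a warning.
- **Bin-count heuristic**: the expression 3.49·STD·M^(−1/3) (STD = mean of
  the two phase standard deviations) is dimensionally a bin *width* —
  Scott's rule. Read as a bin count it yields values below 2 for any
  realistic M (uniform phases at M = 1000 give ≈ 0.63) and would have to be
  clamped to a degenerate 2-bin histogram. The default therefore treats it
  as Scott's width h and uses ceil(2π/h) bins; an `as_printed` mode
  (round, clamped to ≥ 2) is available behind a switch for comparison.
- τ and the bin count are evaluated **per trial per pair** from that
  trial's phases; trials are the analysis unit and their PTEs are averaged
  afterwards.
- Trials shorter than 4τ are skipped with a warning (too few valid samples
  for a meaningful triple histogram).

**Net outflow** of a node is aggregate outgoing PTE minus aggregate
incoming PTE over the analysed node set. The default aggregates by *mean*
over a node's pairs so that regions with more electrodes are not
mechanically inflated; a *sum* mode exists, under which net outflow is
exactly conservative (sums to zero over any closed node set) and which the
tests use as an invariant. No directed-PTE normalisation (dPTE) is
applied: the supported comparisons are between raw directional PTEs.

## Phase-locking value

PLV = |mean(e^{i(φx−φy)})| per trial, averaged across trials. For
independent phase series the finite-sample null mean is the Rayleigh
expectation √π/(2√M), which the tests verify by simulation.

## Signal conditioning

Order: resample (500 Hz) → bipolar montage → line-noise band-stops →
per-channel z-score → band filter → epoch. The pipeline driver enforces
this order.

- **Filters**: fourth-order Butterworth, applied forward and backward
  (`sosfiltfilt`), so the net phase response is zero and the effective
  attenuation order doubles. "Fourth-order" names the one-pass design.
  Band-stops at 57–63, 117–123, 177–183 Hz; stops above Nyquist are
  skipped. Band edges must lie below Nyquist or the call errors.
- **Resampling** uses polyphase anti-aliased resampling
  (`scipy.signal.resample_poly`); upsampling is refused. Event onsets are
  stored in seconds and are unchanged by resampling.
- **Bipolar montage**: within each contact group, adjacent differences
  c_i − c_{i+1} named "A-B"; the virtual channel inherits the *first*
  contact's region label (coordinate-based midpoint assignment is out of
  scope). Single-contact groups emit nothing (logged).
- **Epoch conventions**: half-open sample windows, onset sample =
  floor(onset·fs). Encoding epochs are [onset, onset+L) with L = 1.6 s
  (verbal free recall tasks), 4 s (paired associates), 5 s (water maze).
  Recall epochs are the 1.6 s *preceding* vocal onset for verbal tasks and
  5 s navigation epochs for the water maze. Rest epochs are consecutive
  non-overlapping windows of the encoding length cut from the pre-task
  rest span, matched in count to the encoding trials; a too-short span
  yields fewer epochs with a warning. Trials extending outside the
  recording are dropped with a warning, and epoch counts are conserved
  (kept + dropped = matched events).
- **Stationarity check**: `ar_spectral_radius` fits an AR(p) model by OLS
  (default order 10 — the order is a free choice; 10 comfortably captures
  short-range dependence at 500 Hz) and returns the companion-matrix
  spectral radius. Values near 1 indicate unit-root nonstationarity, the
  motivation for using phase-based rather than autoregressive directed
  measures on these signals.

## High-gamma power

80–160 Hz is split into eight 10 Hz sub-bands to counteract 1/f power
decay. Per sub-band: zero-phase band-pass → Hilbert envelope → divide by
that band's own mean envelope, ×100. The across-band mean is the power
time course; its pre-baseline across-time mean is exactly 100 per band and
the measure is exactly invariant to signal scale.

- **Normalisation scope** is per epoch and per channel (each trial is an
  independent analysis unit, trial values being averaged afterwards). The
  normalising mean includes the filter edge transients of the epoch; for
  band-free synthetic inputs these transients can dominate a leakage
  band's mean, which is why validation uses inputs with genuine power in
  every sub-band.
- **Near-zero band guard**: a band whose mean envelope is below
  1e−12 × signal RMS is excluded from the across-band mean with a warning
  (avoids 0/0 on band-free inputs).
- **Edge handling**: the first and last 50 ms of each epoch are replaced
  by the nearest interior value before smoothing, suppressing Hilbert edge
  artifacts.
- **Smoothing**: sliding means over 0.2 s windows at 90 % overlap
  (step = win·(1−overlap), count = floor((n−win)/step)+1, timestamps at
  window centres).
- **Baselines**: encoding epochs are corrected by subtracting the mean of
  the windows lying entirely in the 0.2 s before stimulus onset (epochs
  must be cut with pre-anchor padding). Recall windows end at vocal onset
  and have no pre-stimulus period; they — and rest-matched contrasts — are
  corrected against the matched rest series' per-channel grand mean, and
  the output is flagged `baseline="rest"`.
- **Window-wise contrasts** run the mixed-model condition contrast in
  every window after averaging trials per (subject, channel), then apply
  Benjamini–Hochberg correction across windows.

## Group statistics

- **Normalising transform**: ordered-quantile (rank-based inverse normal),
  value → Φ⁻¹((rank−0.5)/n) with average ranks on ties. It is
  deterministic, exactly order-preserving, and the recommended default of
  auto-selecting normalisation toolkits.
- **Mixed model**: `value ~ condition + (1|subject)` fit by REML
  (statsmodels MixedLM). The 1-df condition effect is reported as
  F = t², with a two-sided p on df2 = n − 2 (statsmodels provides no
  Satterthwaite denominator df; with the sample sizes this package
  targets, the difference is negligible, and the null rejection rate is
  verified at ~5 % by simulation). Trial averaging precedes modelling.
  With a single subject the model is unidentifiable and the contrast falls
  back to a fixed-effects ANOVA with a warning; singular fits likewise.
- **Effect size**: Cohen's d = 2t/√df2 (the mixed-model d-score
  convention). Internal consistency: F(1, 264) = 59.36 gives
  d = 0.948 ≈ 0.95.
- **Bayes factors**: BF₁₀ ≈ exp((BIC₀ − BIC₁)/2) from maximum-likelihood
  fits of the condition model against the intercept-only model, both
  retaining subject intercepts. The BIC approximation implies a
  unit-information prior; magnitudes are therefore comparable *within*
  this implementation, not to default-prior Bayes factor packages. The
  replication ratio BF(joint)/BF(original) uses the conventional ≥ 3
  ("replicated") and ≥ 100 ("decisive") thresholds.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
iEEG biophysics:

- **Background**: per-contact 1/f^α Gaussian noise (α = 1, amplitude 1
  a.u.) — matches broadband field-potential spectra without claiming a
  generative model.
- **Oscillations**: per-region band-limited Gaussian noise (default
  8–12 Hz, amplitude 1 a.u., i.e. oscillation SNR ≈ 1 against the
  background — a realistic regime for alpha-band field potentials).
- **Directed coupling**: the target's oscillation is
  (1−s)·own + s·source(t−lag) — a delayed mixture rather than explicit
  phase equations, giving an unambiguous ground-truth direction and lag in
  samples. During the pre-task rest span the mixture weight is scaled by
  `rest_factor` (default 0.5) so task-vs-rest contrasts are testable.
- **Contacts**: each probe's contacts pick up the region's latent
  components with alternating gains (1.0, 0.4, …) plus private background
  noise, emulating distance-dependent pickup of a local source; adjacent-
  contact differences therefore retain the latent signal while common-mode
  components cancel.
- **High gamma**: a per-region 80–160 Hz component (amplitude 0.5)
  whose envelope is multiplied by 1 ± magnitude inside event-locked
  windows.
- **Task templates**: 1.6 s word presentations with 0.8–1.2 s ISIs (free
  recall; the categorized variant uses 0.75–1.0 s), 4 s pairs with
  1.75–2.0 s ISIs, 5 s water-maze epochs; a pre-task rest span at least as
  long as the summed encoding epochs; a 20 s post-encoding delay; recall
  events for a task-typical fraction of items (25–48 %).
- All draws come from one seeded `numpy` generator passed explicitly;
  identical configs give bit-identical sessions.

What the generator does **not** emulate: non-Gaussian and nonstationary
iEEG statistics, cross-frequency coupling, volume-conduction geometry,
artifacts, or behaviour beyond a recalled flag. Passing ground-truth
recovery tests therefore demonstrates estimator correctness under the
assumed statistical structure, not performance on real recordings.

## Validation problem sizes

The test suite and acceptance script size their simulations for stable
statistics on a single CPU: 20 sessions for direction recovery, 30
replicates per coupling strength for monotonicity, 200 replicates for null
sign calibration and PLV nulls, 1000 simulated datasets for type-I
calibration of the contrast, and 100 true-replication plus 200
null-replication runs for the Bayes factor ratio. The acceptance script
uses 12 sessions per task with two probes per region, which gives 16
channel pairs per region pair and stable group-level contrasts.

## Known limitations

- Plug-in PTE is biased upward for small M; only directional and
  condition *differences* should be interpreted.
- The BIC-based Bayes factors are not numerically comparable to
  default-prior implementations.
- The denominator df convention (n − 2) is anti-conservative for very
  small subject counts; with < 10 subjects, treat p-values as indicative.
- Recall-epoch baselines use matched rest (no pre-stimulus exists before
  vocal onset), so encoding and recall power are corrected against
  different references — comparisons across those two conditions inherit
  that asymmetry.
- EDF writing is not supported (HDF5 + TSV is the native format); EDF
  reading requires the optional `mne` dependency.
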