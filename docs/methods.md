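# Methods

`srmeeg` implements the analysis chain used to study self-referential
processing with EEG: evoked alpha-band time-frequency power,
phase-lag-index (PLI) functional connectivity, graph-theoretic network
topology, and the accompanying behavioural scores and statistics — all
of it exercised against a synthetic cohort generator with known ground
truth. This note documents the models, the conventions where several
were possible, the generator's assumptions, and the problem sizes used
by the heavier validation runs.

## Study design being modelled

Two groups (healthy controls and patients, 18 per group) perform a
self-referential memory (SRM) encoding task under three conditions —
judging adjectives about *self*, about an *other* person, or about a
*physical* property — with 70 trials per condition. EEG is recorded
from 59 scalp channels at 500 Hz and segmented from −300 to +800 ms
around stimulus onset. Later recognition yields hits (out of
`n_old = 70` studied items) and false alarms (out of `n_new = 100`
lures) per condition:

* recognition score = hit rate − false-alarm rate, in [−1, 1];
* SRM bias = recognition(self) − recognition(other). Positive values
  indicate the self-referential memory advantage that healthy
  participants typically show.

## Preprocessing

* **Band-pass**: zero-phase forward–backward Butterworth, order 4 per
  direction. Zero phase is mandatory because instantaneous Hilbert
  phases downstream must not be biased by filter delay. The broad
  analysis band is 0.1–30 Hz; the connectivity band is alpha, 8–13 Hz.
  A forward–backward IIR band-pass is not exactly idempotent on
  broadband input (a second pass re-attenuates the transition bands by
  a few percent of RMS); on in-band content it is a no-op to filter
  tolerance, which is the property the phase pipeline relies on.
* **Re-referencing**: averaged mastoids (`M1`/`M2`), which are then
  dropped from the analysis montage.
* **Segmentation**: epochs span `[onset − 300 ms, onset + 800 ms)`;
  with `fs = 500` Hz that is exactly 550 samples with stimulus onset at
  sample 150. All windows in the package are half-open `[start, end)`
  in milliseconds.
* **Spectral distortion |dP|**: per channel, the sum over the 0.1–30 Hz
  grid of the absolute difference between trial-averaged Welch PSDs
  (1 s windows, or the full epoch when shorter) of a raw recording and
  an artifact-cleaned reconstruction. It is zero iff the spectra are
  identical, symmetric in its arguments, and is provided as a
  quality-control metric for any user-supplied cleaning step; the
  package does not itself perform ICA.

## Evoked power

Evoked (phase-locked) power is the squared magnitude of the complex
Morlet transform of the **across-trial average** waveform — average
first, then transform — so activity whose phase varies across trials
cancels roughly as 1/N before squaring. The wavelet family has a fixed
centre-frequency to spectral-bandwidth ratio f0/σ_f = 7 on a 0.1–30 Hz
grid in 0.5 Hz steps, σ_t = 1/(2π σ_f). Wavelets are L2 (unit-energy)
normalised, which makes power scale exactly quadratically with signal
amplitude (a convention chosen so that scaling tests are exact; the
absolute scale of power is arbitrary but consistent).

A wavelet at 0.1 Hz is ~11 s wide — far beyond a 1.1 s epoch — so every
time–frequency cell within 2σ_t of an epoch edge is computed but
flagged invalid, and **every** aggregate (band/window means, the
statistics built on them) uses valid cells only. Low-frequency rows of
the default grid are therefore entirely masked by design; a band ×
window selection that is fully masked raises rather than silently
returning rubbish, and the pipeline records such cells as missing. No
baseline correction is applied to power; raw evoked power is compared
across groups.

The headline measure is mean alpha (8–13 Hz) evoked power in the
100–300 ms post-stimulus window, per channel or averaged over channels.

## PLI connectivity

Alpha-filtered epochs are Hilbert-transformed; the first and last
100 ms of each epoch (50 samples at 500 Hz) are discarded as transform
edge distortion. For electrodes i, j and time t, across N trials:

    PLI_ij(t) = | (1/N) Σ_n sign(Δφ_ij(t, n)) |

with Δφ wrapped to (−π, π] **before** the sign. Conventions that
matter:

* `sign(0) = 0`: an exactly zero-lag (common-source / volume-conducted)
  mixture contributes nothing, so PLI is exactly 0 on noise-free
  scaled-copy channels. This is the property that makes PLI robust to
  volume conduction.
* Wrapping before the sign keeps the statistic independent of
  accumulated cycles; swapping the channel order leaves PLI unchanged.
* Windowed matrices (e.g. the 100–300 ms active window, the −200–0 ms
  baseline) average the PLI time course over valid samples only.

Edge significance follows the study convention: an
*independent*-samples t-test between per-subject active-window and
baseline-window PLI values per edge, displayed at raw p < 0.001 with
Bonferroni-adjusted p also reported. A paired variant is available
behind a flag (`paired=True`); it is statistically the more natural
choice for a within-subject contrast, but the independent form is the
default for fidelity to the original analysis.

## Network topology

Each subject × condition PLI matrix is binarized by proportional
(global) sparsity thresholding: at sparsity S, the strongest
`round(S · n(n−1)/2)` edges are kept (ties broken by fixed
lexicographic pair order so results are deterministic), giving every
subject the same edge count. The sweep runs S = 0.10 … 0.50 in steps
of 0.05, and each metric is summarised by its trapezoidal AUC over the
sweep — the per-subject scalar used in group statistics.

Distances are unweighted shortest paths (per-source BFS). The metric
conventions differ deliberately:

* global efficiency uses 1/∞ = 0 for disconnected pairs (always
  defined, in [0, 1]);
* characteristic path length averages only the finite distances over
  connected pairs and reports how many pairs were excluded;
* nodal efficiency is the per-node mean inverse distance, so
  mean(E_nodal) = E_glob holds exactly under these conventions.

A consequence worth knowing: at sparse thresholds a graph consisting of
one strong clique plus isolated nodes measures a *short*
characteristic path length (only within-clique pairs are connected), so
the direction of group differences in CPL is not determined by the
planted connectivity deficit; the global-efficiency contrast is the
reliable topological readout of the planted effect (see below).

## Statistics

* Mixed-design ANOVA (group between subjects, condition within) from
  classical split-plot sums of squares, no sphericity correction:
  F_group = MS_group/MS_subj(group) with df (g−1, N−g); condition and
  interaction are tested against MS_error with df (c−1, (c−1)(N−g)) and
  ((g−1)(c−1), (c−1)(N−g)). For N = 36 and c = 3 the interaction df are
  (2, 68); reports of such designs sometimes print (2, 34) instead —
  this implementation always reports the classical df.
* Independent t-tests use the pooled-variance (Student) form,
  df = n_a + n_b − 2 (df = 34 for 18 + 18).
* Pearson correlation with t-based two-tailed p; simple linear
  regression by least squares with the F-test of the slope and
  R² = r² exactly.
* Bonferroni correction is `min(1, p·m)` with m = the number of
  electrodes (topographic maps) or edges (connectivity maps).

## Synthetic cohort generator

Real recordings for this paradigm are not publicly deposited, so the
generator produces cohorts with the statistical structure the analysis
assumes, each effect planted with a known size:

* **Background**: per-channel, per-trial 1/f (pink, exponent 1) noise,
  RMS-calibrated to 10 µV by default — realistic spectra so band
  filters are meaningfully exercised.
* **Evoked alpha burst**: Gaussian-windowed 10 Hz sinusoid centred in
  the 100–300 ms window (σ = 50 ms), phase fixed across trials per
  subject × condition × channel so it survives trial averaging.
  Default amplitudes: 2.0 µV everywhere except the patient self
  condition at 1.4 µV — a 30 % planted amplitude deficit, i.e. the
  group × condition interaction. A `phase_jitter` parameter (uniform
  ±J per trial) demonstrates evoked-power cancellation; at J = π the
  evoked response vanishes up to 1/N residue.
* **Subject heterogeneity**: a per-subject amplitude trait multiplies
  evoked *power* linearly with coefficient of variation
  `alpha_amp_cv = 0.35` (shared across conditions, so within-subject
  contrasts are unaffected); recognition probabilities get a shared
  memory trait (`mem_sd = 0.10`) and a self-condition bias latent
  (`bias_sd = 0.28`, consistent with a bias SD of ~0.3 implied by a
  reported SE of 0.08 at n = 18).
* **Planted connectivity**: every edge of a posterior clique (the tail
  of the anterior→posterior channel list; all pairs among
  `max(2, min(8, n_channels // 3))` channels) receives a shared 10 Hz
  source with a flat envelope across the active window (20 ms cosine
  ramps). The second channel is delayed by 25 ms (a quarter cycle,
  Δφ = π/2) on a `coupling_consistency` fraction of trials and advanced
  on the rest; lag signs are i.i.d. Bernoulli(p) per trial, so the
  planted single-edge PLI is exactly E|2·Binomial(N, p)/N − 1|.
  Defaults: controls p = 0.85 in all conditions; patients 0.60 / 0.70 /
  0.75 (self / other / physical) — the planted connectivity deficit.
* **Exactly non-phase-locked coupling**: source phases are drawn
  antithetically *within each lag-sign class* (each phase reused once
  with a π offset), so the coupling's trial average cancels exactly (up
  to one unpaired trial per odd-sized class) and contributes nothing to
  evoked power, cleanly separating the two planted effects. Adding π to
  both channels leaves Δφ untouched, so the PLI statistics are those of
  the binomial model.
* **What the clique does to measurements**: with several coupled edges
  sharing channels, the other edges' sources act as in-band
  interference for any one edge, attenuating its *measured* PLI well
  below the single-edge binomial value (≈0.18 rather than 0.70 at
  p = 0.85 with default amplitudes) while remaining monotone in p.
  Group contrasts and the network-topology effect are driven by this
  attenuated but ordered signal; quantitative consistency recovery is
  therefore validated on a single-edge, low-noise configuration where
  the binomial formula holds cleanly.
* **Network consequence**: weaker patient coupling lets uniformly
  scattered noise edges displace clique edges under proportional
  thresholding, moving patient graphs toward uniform random graphs —
  *raising* their global efficiency. That positive patient-minus-control
  global-efficiency contrast is the planted network effect recorded in
  the ground truth; the CPL direction is recorded as indeterminate for
  the convention reason given above.
* **Behaviour**: hits ~ Binomial(70, p_hit), false alarms ~
  Binomial(100, p_fa) per condition. Default hit probabilities give
  expected recognition ≈ 0.49/0.35/0.35 (controls self/other/physical)
  and ≈ 0.36/0.33/0.35 (patients) at p_fa = 0.15 — a self-referential
  advantage in controls only. Reaction times are drawn per condition
  (self 999 ± 159 ms, other 1033 ± 196 ms, physical 631 ± 101 ms).
* **Planted power–bias correlation**: `power_bias_corr` (default 0.6
  in patients, 0 in controls) targets the correlation between the
  *observables* — measured evoked alpha power and measured SRM bias.
  The binomial sampling noise of the recognition counts attenuates any
  latent correlation by the exactly computable factor
  `bias_sd / sqrt(bias_sd² + v_binom)`; the generator disattenuates the
  latent correlation by this factor (capped at 0.97). The EEG-side
  attenuation depends on the measurement pipeline and is not corrected;
  configurations that exercise correlation recovery should provide
  enough evoked-response SNR that it stays within a few percent (the
  validation configuration uses 2.0 µV bursts over 16 channels at 5 µV
  noise RMS, where it does).
* **Volume-conduction fixture**: optionally, both channels of listed
  edges receive the same zero-lag source with power-of-two gains —
  power-of-two so the channels stay bit-exactly proportional through
  any linear processing, making the PLI's exact-zero property testable
  in floating point.
* **Determinism**: everything derives from one integer seed.
  Per-subject streams come from `SeedSequence(seed, spawn_key=…)` and a
  CRC of the subject label, so subjects regenerate identically in any
  order, and a cohort regenerated with the same configuration is
  bit-identical.

What the generator does **not** emulate: ocular/muscle artifacts (the
|dP| metric accepts real cleaned data but synthetic data are
artifact-free), volume-conducted mixing beyond the explicit fixture,
scalp topography (channel labels are positional only), non-stationary
background dynamics, and realistic between-channel covariance. Tests
passing on these cohorts validate the estimators and their statistical
calibration — not claims about any real clinical population.

## Problem sizes used by the validation runs

Chosen once, as the package's own study conditions, and fixed:

* **Consistency recovery**: 2 channels, one coupled edge, 70 trials,
  fs = 250 Hz, noise RMS 2 µV, 200 seeds per planted p ∈ {0.6, 0.75,
  0.9, 1.0}; the mean estimated PLI must sit within 3 Monte-Carlo SE of
  the binomial expectation.
* **Null calibration**: all group/condition cells equal with
  `burst_amp = 0` and chance coupling — the only null under which the
  active-vs-baseline edge test is genuinely null, since any
  phase-locked burst creates a real active/baseline difference; 500
  cohort draws at 8 subjects/group, 8 channels, 20 trials, fs = 250.
  Rejection rates at α = 0.05 must lie in [0.03, 0.08].
* **Contrast recovery**: 18 + 18 subjects and 70 trials (the study
  scale), 16 channels at fs = 250 with a 5-channel posterior clique;
  50 cohort seeds; interaction, self-condition PLI difference and the
  positive global-efficiency contrast must each be detected in ≥ 80 %
  of seeds.
* **Correlation recovery**: 500 patient-group cohorts of n = 18 at the
  high-SNR configuration above; mean recovered r within 0.1 of 0.6 and
  mean R² within 0.1 of 0.36.

`scripts/acceptance.py` recomputes one study-regime cohort, a 50-seed
correlation regime and a 150-draw calibration run from a single
command-line seed and writes the resulting numbers to JSON.

## Known limitations

* The mixed ANOVA assumes a balanced within-subject design and applies
  no sphericity correction (by design, matching the analysis it
  reproduces); with three conditions and small n, condition/interaction
  p-values are mildly liberal under strong non-sphericity.
* The independent-samples form of the active-vs-baseline edge test
  ignores the within-subject pairing; the paired variant is provided
  but not default.
* Proportional thresholding fixes edge count, so group differences in
  overall PLI level are expressed only through topology; with a single
  planted clique the CPL direction is convention-dependent (above).
* Measured clique-edge PLI is attenuated by inter-edge interference;
  treat `expected_coupled_pli` in the ground truth as the single-edge
  value, not the in-clique measurement.
* EDF export requires the optional `edfio` backend; the `.npz` + JSON
  container is the supported fixture format.
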