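# Methods

This note documents the models, numerical choices and limitations behind
`vims_hrv`, in the spirit of a package reference rather than a study report.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## The generative heartbeat model (IPFM)

Beat times are generated by integral pulse frequency modulation: the
instantaneous rate

    r(t) = (1 + a_lf sin(2π f_lf t) + a_hf sin(2π f_hf t) + b(t)) / mean_rr

is integrated and a beat emitted at every integer crossing of the integral
(linear interpolation on a 64 Hz grid; beat-time error is O(dt²) ≈ 0.1 ms).
IPFM was chosen because band-limited modulation of the rate maps directly
onto RR-spectral band power, which is the quantity the whole analysis
estimates. The broadband term `b(t)` is white noise low-pass filtered below
0.4 Hz (4th-order Butterworth, forward-backward) and rescaled to
`broadband_sd`, keeping its power inside the analyzed range. The stability
invariant `a_lf + a_hf + 3·broadband_sd < 1` keeps the rate positive.

Defaults: `mean_rr` 0.85 s, `f_lf` 0.10 Hz, `f_hf` 0.25 Hz, `a_lf` 0.04,
`a_hf` 0.08, `broadband_sd` 0.012. These give a resting-like tachogram with
HF (respiratory) dominance at baseline — HF n.u. ≈ 77 — which is on the
vagally-dominant side of typical resting values; the source study reports
no absolute baseline magnitudes, so the defaults aim at qualitative, not
quantitative, fidelity.

## Study-level simulation

A cohort is a two-condition crossover: per participant, one sham and one
stimulation session (order randomized, balanced), each 300 s baseline +
≤ 1200 s nauseogenic section + 300 s recovery. Condition effects enter as
per-(section, condition) modulation amplitudes; the defaults shift the
nauseogenic section to `a_lf × 1.5, a_hf × 0.5` under sham and
`a_lf × 1.1, a_hf × 0.9` under stimulation. Between-participant structure:
`mean_rr ~ N(0.85, 0.06)`, a log-normal amplitude factor (σ = 0.15) shared
across a participant's sessions, respiratory frequency `N(0.25, 0.015)` Hz,
LF frequency `N(0.10, 0.008)` Hz, and a latent "tolerance" trait that both
delays nausea ratings (+2 min/SD) and raises HF amplitude (σ = 0.15 on the
log scale), inducing the positive latency–HF association the association
battery probes.

Nausea-rating latencies are drawn from truncated normals with the
published per-condition means/SDs (minutes to mild/moderate/strong;
stimulation later than sham), made non-decreasing in time. Latencies for
ratings ≥ 2 are truncated at 5.5 min because the epoching rule anchors a
5-min window immediately before the maximum-rating trigger; an earlier
moderate rating would be incompatible with the session layout the epoch
rules assume. Given a strong rating, a premature stop occurs with
probability 0.30 (sham) / 0.15 (stimulation) shortly after.

MSAQ items use a latent-normal model: participant trait + item noise
(σ = 0.8), a post-session latent shift (sham 1.5, stimulation 0.5 on the
1–9 scale), rounded and clipped to 1–9. This is the simplest ordinal model
with a controllable effect size; it applies the shift uniformly across
items, so category subscores all move together (real data show
category-specific profiles).

**What the generator does not emulate:** respiration as a signal (HF
modulation is tonal, not a wandering narrowband process), ectopic beats and
arrhythmia, multi-lead morphology, drift/motion artifacts beyond white
noise, order-of-magnitude between-subject power heterogeneity, and any
EEG. Passing tests therefore demonstrate correctness of the machinery
under idealized autonomic structure, not robustness to real-world ECG
pathology.

## Preprocessing

Pan–Tompkins runs at the canonical parameterization (5–15 Hz bandpass,
five-point derivative, squaring, 150 ms integration, adaptive signal/noise
thresholds with 1.66·RR search-back, 200 ms refractory, 360 ms T-wave slope
check). All filtering is forward-backward (zero phase), so the R fiducial
is refined as the bandpassed-signal maximum near the integrator peak. On
synthetic records the detector reaches ≥ 99.5% sensitivity/PPV clean and
≥ 98% at 10 dB SNR (the acceptance suite measures this); the only
systematic miss is a template truncated by the record edge.

RR artifact handling is automated (a package cannot rely on visual
inspection): an interval deviating > 20% from the median of its
11-interval neighborhood, or outside 300–2000 ms, is flagged; flagged
intervals are excluded from spectral estimation but retained for audit.

Epoch windows are half-open `[start, end)` in seconds from session start.
The nauseogenic epoch ends at recovery onset (full section or premature
stop) or at the *first* trigger of the maximum rating when that maximum is
≥ 2; a window that would cross into baseline raises an error rather than
silently shortening.

## Spectral estimation

The Lomb–Scargle periodogram is computed on the mean-centred, unflagged
(beat-time, RR) pairs — gaps from flagged intervals are simply left out,
which is precisely the estimator's advantage on irregular data. Grid: from
1/duration to 0.40 Hz at spacing 1/(4·duration) (oversampling 4), with the
0.40 Hz edge appended. The raw periodogram is rescaled so its trapezoidal
integral equals the series variance, making band integrals variance
contributions in ms²; variance above 0.40 Hz is small for tachograms but
folds into the analyzed range under this normalization. Band edges are
0.04 / 0.15 / 0.40 Hz; the VLF band is bounded below by 1/duration. The
normalized-unit denominator `Total − VLF` is computed as `LF + HF`
(identical by construction, immune to cancellation), which also makes
`LF n.u. + HF n.u. = 100` exact.

## Time-frequency estimation

RR is resampled at 4 Hz with a not-a-knot cubic spline (the classic
'spline' interpolant), mean-centred, optionally onto a fixed grid so maps
align across sessions (samples outside the beat span are edge-held; they
fall inside the excluded edge region). The SPWVD uses the analytic signal
and separable smoothing: Hamming time window of 15 s and Hamming lag window
of 31 s (both odd-length at 4 Hz, overridable), chosen to resolve the
0.04 Hz band structure while suppressing cross-terms (measured: mid-band
cross-term energy < 1% of auto-terms for a two-tone input, vs > 100%
unsmoothed). Frequency axis: zero-padded FFT over lag, 256 bins up to
0.5 Hz by default. The output is scaled so the full-frequency integral per
time equals the time-smoothed instantaneous power |z(t)|², giving ms²/Hz.
Edges are reflect-padded for the time convolution, and all columns within
the combined half-window span of either end are flagged and excluded from
statistics — SPWVD edge artifacts are systematic, not exchangeable.
Contrasts are element-wise differences ("X vs Y" = X − Y) on identical
axes.

## Permutation inference

Both procedures are two-tailed at α = 0.05 with 1000 permutations by
default and operate on edge-excluded, band-cropped (0.04–0.40 Hz) maps.

*Pixel-based (participant level).* The null pools the minimum and maximum
of each permuted difference map; thresholds are the α/2 and 1−α/2
percentiles of the pooled extremes, using the outward order-statistic
convention so each tail stays valid. Because the pooled 97.5th percentile
is approximately the 95th percentile of the per-permutation maxima, the
procedure controls each *tail* at ≈ α (the calibration test verifies both
tails), so its two-sided family-wise rate is bounded by ≈ 2α — a property
of the pooled-extremes construction itself. With one map per condition the
exchange unit is a sign flip of time-column blocks (block length = the
time-smoothing window) of the difference map, preserving within-block
autocorrelation; note that a strong sustained effect then contaminates the
null extremes, so the participant-level test is sensitive mainly to
*time-localized* deviations. With paired map sets the exchange is a
within-pair sign flip.

*Cluster-based (cohort level).* The paired difference maps are
z-transformed pixelwise against the sign-flip permutation distribution
using its exact group moments (mean 0, SD √(Σᵢdᵢ²)/n) — identical
standardization for observed and permuted maps makes the test exact under
exchangeability (an empirical mean/SD from the same finite permutation set
biases the observed z upward; we measured a family-wise rate of ~0.12
before switching). Pixels with |z| ≥ z₀.₉₇₅ = 1.96 form 8-connected
clusters (positive and negative labelled separately; 4-connectivity
available); the cluster statistic is the mean z; cluster p-values are
exceedance proportions of the permutation distribution of the maximum
|cluster mean| with the +1 correction, so every p is an achievable
multiple of 1/(n_perm + 1).

**A power caveat worth stating plainly.** The mean-z cluster statistic is
bounded by √n (2.9–3.7 for n = 14) because the permutation SD at an
effect pixel contains the effect itself, and the null distribution of the
maximum cluster-mean of a smooth z-field concentrates near 2.5–2.6 almost
regardless of the data. Sustained band-limited effects under realistic
between-participant amplitude variability therefore yield observed cluster
means near the null's 95th percentile, and detection is marginal — the
acceptance suite measures ≈ 48% replicate-level power for the planted HF
suppression at n = 14, while the corresponding spectral paired tests detect
the same effect in 100% of replicates. A cluster-*mass* statistic would
reward spatial extent, but the mean-z statistic is the procedure this
package implements by design.

## Behavioral statistics

MSAQ scoring: total = Σ items/(9·16)·100; category = within-category
percentage under the shipped 4/5/3/4 item map
(`src/vims_hrv/data/msaq_items.csv`, editable). Condition comparisons use
the one-tailed Wilcoxon signed-rank (alternative: stimulation < sham),
exact for n ≤ 25, zeros discarded and counted, with Shapiro–Wilk reported
alongside; all-zero differences are flagged degenerate with p = 1. Paired
t-tests take explicit directions (defaults: nausea HF↓ LF↑ vs baseline;
stimulation LF↓ HF↑ vs sham); zero-variance differences are flagged, with
p = 0.5 at zero mean and a tiny/unit p under a forced direction. The
order-effect check is a one-way fixed-effect F (df₁ = 1) between order
groups; for two groups it equals the squared pooled t (tested). The MSAQ
regression regresses the tES−sham delta difference on the sham delta
(sign configurable). No multiplicity correction is applied across MSAQ
scales, matching the analysis this package mirrors.

## Pipeline, sizes and determinism

`run_study_analysis` chains generation/reading → filtering → detection →
RR → epochs → spectral metrics → paired tests → SPWVD contrasts →
pixel/cluster permutation tests → MSAQ scoring and tests → associations →
order test, with per-participant crash isolation (a failing participant is
excluded and logged). Everything is driven by one `StudyConfig`
(YAML-serializable; the defaults are the analysis preset) and a single
seed; identical (config, seed) runs write byte-identical tables.

Replicate-level checks in the test suite use scaled problem sizes chosen
for tight feedback loops: calibration cohorts use 64 frequency bins and a
4-sample time hop (the statistics' validity does not depend on map
resolution), power runs use the default 256 bins, and the fixture dataset
uses 3 participants with 60/240/60 s sections and 60 s epochs. The
acceptance script runs the full 14-participant, full-duration,
1000-permutation analysis from ECG.

## Known limitations

- EDF/BDF writing pads the final partial record with zeros (duration is
  rounded up to a whole second on read); reading uses `mne`.
- The Lomb–Scargle normalization folds the (small) above-0.4 Hz tachogram
  variance into the analyzed range.
- The participant-level pixel test is insensitive to sustained effects by
  construction (see above); the cohort cluster test carries the mean-z
  power caveat.
- The generator's idealizations listed above bound what green tests imply
  about real recordings.
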