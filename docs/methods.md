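# Methods

This note records the scientific and numerical choices behind `epivmd`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Analysis unit

All features are computed on 2 s non-overlapping windows ("epochs") of two
bipolar 10–20 channels (defaults FZCZ, CZPZ). Epoch *i* covers samples
`[i·fs·d, (i+1)·fs·d)`; a trailing partial window is dropped. When seizure
annotations are supplied, an epoch is labeled epileptic iff its midpoint
lies inside an annotated interval — boundary epochs get the class that
covers the majority of their span, and the rule is unambiguous.

## Outlier cleaning (Pauta criterion)

Mean and standard deviation are computed per epoch (population sd; at
N = 512 the distinction from the sample sd is negligible, and the 3σ rule
is classically stated with population moments). Samples with
`|x − mean| > k·sd` (strict inequality, default k = 3) are replaced by the
median of the *original* epoch — the median is robust to the outliers it
replaces, so no exclusion or re-estimation pass is needed, and none is
performed. A zero-spread epoch returns an empty outlier set rather than an
error.

## Nonuniform amplitude transform

```
y = x                                   |x| ≤ knee   (80 µV)
y = sign(x)·(pivot + 10·log10(|x|−pivot))   |x| > knee   (pivot 70 µV)
```

This is the unique odd-symmetric, exactly continuous reading of the
piecewise identity/log map (70 + 10·log10(80 − 70) = 80). Both knee and
pivot are exposed so other readings can be reproduced. The transform feeds
**only** the entropy branch: log-compressing amplitudes would shift VMD
center frequencies and distort the phase branch, whose motivation is
spectral, not amplitude-based.

## Sample entropy and its adjustment

Templates of length m and m+1 are compared under the Chebyshev distance
with strict tolerance r; self-matches are excluded and both dimensions use
the same N−m templates (the classical Richman–Moorman convention — the
ratio `B^{m+1}/B^m` is insensitive to the common normalization constant).
Defaults m = 2, r = 0.2·sd, the standard convention; the tolerance is
resolved **once per epoch** and reused for the 8 within-epoch segments so
that segment values are comparable — a segment-local r would change the
meaning of the inter-segment trend. If either match count is zero (likely
on 64-sample segments) the estimator returns the finite cap
`−ln(2/((N−m)(N−m−1)))` — the largest value resolvable with that many
template pairs — keeping the trend detector total.

Trend rule: the segment series triggers the ascending (descending) flag
iff some three *consecutive* steps each rise (fall) by ≥ 20 % of the
step's starting value; a step starting at zero never qualifies; longer
runs still count once (the flags are binary). The adjusted entropy is
`SampEn + µ·α − µ·β`. The published example table that motivates the rule
labels its flag columns transposed relative to the rule text; the
implementation follows the rule text, and the tests assert that every
printed flag is reproduced under that documented transposition. One
printed row arithmetically triggers *both* directions even though only one
flag is printed; the tests assert reproduction of printed flags, not
absence of unprinted ones.

µ is the absolute difference of the channel's class-mean sample entropies
(the printed source means disagree between table and text about which
class is larger for CZPZ; the absolute difference, 0.05, is consistent
with both). A per-channel calibration CSV ships with the package;
`ChannelEntropyStats` supports re-estimation from user data.

## Variational mode decomposition

Standard ADMM solution of the constrained variational problem: per
iteration, each mode's positive-frequency spectrum is updated by a Wiener
filter centered on its current frequency with bandwidth weight α, the
center frequency moves to the mode's power-weighted mean frequency, and
(when the dual step τ > 0) a Lagrangian dual ascent enforces
reconstruction. Convergence is declared when the summed relative change of
the mode spectra falls below `tol`; hitting `max_iter` returns the current
state flagged unconverged rather than raising. Epochs are mirror-extended
by half their length at each end and cropped after inversion, suppressing
boundary ringing on short windows. Modes are returned sorted by ascending
center frequency (in Hz), which defines "corresponding IMFs" across
channels.

Defaults: α = 20000, τ = 0, tol = 1e-7, max_iter = 500, deterministic
**log-spaced** initial center frequencies. These two defaults deserve
explanation. EEG rhythms are organized roughly logarithmically in
frequency (delta through gamma); a linearly uniform initialization leaves
the low-frequency bands unclaimed — modes initialized above ~50 Hz sit on
broadband noise and never find delta/theta content — while a geometric
spread over (0, fs/2) tracks the actual band layout. Similarly, a filter
bandwidth weight of α = 2000 at fs = 256 corresponds to a half-width of
several Hz, which cannot separate oscillations at 1 and 2.5 Hz on a 2 s
window at all; α = 20000 resolves the low bands while remaining broad
enough to lock onto tones. Linear-uniform, zero and seeded-random
initializations remain available as options. Exact reconstruction
(residual < 1e-6) requires letting the dual variable saturate: τ = 1 with
tol ≈ 1e-13 (~10⁴ cheap iterations, well under a second); τ ≳ 5 diverges.

### Mode-count selection

For each candidate K (ascending) the center frequencies are averaged
rank-wise across epochs; a candidate passes if every adjacent pair
satisfies `(f[i+1] − f[i]) / f[i+1] ≥ 0.1` (the threshold quantifies
"obviously different" and is exposed as a parameter). The scan **stops at
the first failing candidate** and returns the largest K seen before it:
once an extra mode crowds an existing band, over-decomposition has set in,
and rank-averaging across epochs can make spacing spuriously re-open at
even larger K (the crowding lands at slightly different ranks per epoch),
so candidates beyond the first collapse are not trusted. If the smallest
candidate already fails, it is returned with a `RuntimeWarning`.

## Phase synchronization

Instantaneous phase is the angle of the analytic signal (Hilbert
transform), well defined per narrowband IMF; 5 % of samples are trimmed at
each edge (exposed parameter) because Hilbert edge ringing is not
negligible on 2 s windows. The synchronization index is the mean resultant
length of the per-sample phase differences; only 1:1 locking is
implemented. The five features pair IMF1…IMF5 rank-to-rank across the two
channels; the highest-frequency mode is excluded as noise-dominated. A
plain-text channel→region lookup (forehead, left/right temporal,
occipital, hippocampus) ships as editable configuration.

## Classification

Random forest with 900 trees and 5 candidate variables per split (values
selected by grid search in the source study; the grid
{300, 600, 900, 1200} × {2, 3, 5, 7} can be re-run inside the training
folds only). Stratified 10-fold cross-validation with seeded shuffling;
per-fold confusion counts are pooled and accuracy, sensitivity
(epileptic recall) and specificity recomputed from the pooled counts. The
trainer never rebalances silently — class counts are echoed in the report,
and an explicit balanced-subsampling helper is provided. Every report
embeds the fold assignments, the resolved configuration and the seed.

## Synthetic generator

The generator emulates exactly the structure the pipeline exploits, with
defaults frozen as the package's study conditions:

* fs 256 Hz, 2 s epochs; six narrowband oscillators log-spaced over
  1–100 Hz, amplitude 6 µV except a 3× dominant band at 15.85 Hz
  (resting-EEG dominant rhythm); each band's phase is a carrier plus a
  random walk with step 0.3·sqrt(f/f₀) rad/√s (faster rhythms are less
  phase-stable, which keeps high-frequency lines wider);
* cross-channel coupling c ∈ [0, 1]: each band's phase perturbation —
  both the slow walk *and* the constant per-channel offset — is a mixture
  of a shared and a private component in proportion c : (1−c), so c = 1
  makes the channels' phase tracks identical (γ = 1 by construction even
  under mode mixing) and c = 0 leaves them independent;
* ictal component: a 2.5 Hz (delta) spike-wave rhythm, placed on the
  second band center so it reinforces an existing mode rather than
  spawning a stray line, under a ramp-then-plateau envelope covering
  50–80 % of the epoch with peak amplitude 90 µV, generated once and added
  to both channels (a single deep source projects coherently onto both
  bipolar derivations). The ramp reflects that seizure activity evolves
  rather than switching on. The envelope keeps extremes bounded below 3σ
  of the burst-inflated epoch spread — mirroring the observation that
  high-amplitude ictal activity *submerges* small outliers — while
  engaging the 80 µV transform knee (≈ 8 % of ictal samples exceed it);
* pink (1/f power) Gaussian background noise, sd 2 µV, independent across
  channels; deletion-style missing-data corruption (gap-closing, since
  dropped samples shorten the series; zero-filling is available for
  comparison but injects artificial spectral content);
* class parameters: epileptic c = 0.9, tail 90 µV; nonepileptic c = 0.5,
  tail 0.

What the generator does **not** emulate: physiological spike-wave
morphology, inter-patient variability, artifacts with structure (eye
blinks, muscle), non-stationary background, or volume-conduction mixing
beyond the shared-source idealization. Passing benchmarks on it
demonstrates that the pipeline recovers the structure it assumes — not
clinical-grade performance; the published corpus-scale accuracies require
the real recordings.

## Missing-data robustness protocol

For each replication, a mixed-class epoch set is generated; each feature
is computed on the complete epochs and on corrupted copies at each missing
proportion, and the Pearson correlation between complete and corrupted
feature series (across epochs) is recorded, then averaged over
replications. The comparison partner for the adjusted entropy is the
*traditional* feature — sample entropy of the band-pass **denoised**
signal (zero-phase Butterworth 0.5–35 Hz, the classical clinical EEG
filter; `preprocess.bandpass_denoise`). That is the claim under test: a
full-information feature degrades more gracefully than one computed after
denoising has discarded content. Computed on the *same unfiltered* signal,
plain and adjusted entropy are nearly identical in robustness (differences
of order 1e-4 in correlation) because the adjustment flags are rare — in
the source calibration they fire on ~4 % and ~3 % of windows — so no
dominance should be expected or is claimed for that comparison.

## Numerical details and degenerate inputs

* Entropy: inputs shorter than m+2 raise; constant vectors return 0 under
  an absolute tolerance and raise under a relative one (sd = 0).
* VMD: epochs shorter than 32 samples and K > N/4 raise; the zero signal
  is a fixed point (zero modes, zero residual, converged).
* Phase: all-zero signals raise (undefined phase); series must have equal
  length for γ.
* Amplitude invariance: with relative tolerance, entropy is exactly
  scale-invariant; tests use power-of-two scales to keep floating-point
  comparisons bit-exact.
* Seeding: every stochastic component takes a `numpy` Generator or an
  integer seed; dataset generation splits the master seed into one
  independent stream per epoch pair, so datasets are reproducible and
  order-insensitive.

## Problem sizes used by the shipped checks

The test suite and acceptance script run entirely on synthetic data at
desk scale, chosen as the smallest sizes at which each property is stable:
oracle equivalence on 200 inputs of N ≤ 200; mode-count selection on 20
epochs; the classification benchmark at 100 epochs per class under
10-fold CV; the robustness protocol with 30 epochs × 20 replications over
missing proportions 0.05–0.3.

## Known limitations

* The two fixed hippocampal channels are not always the most informative
  pair for a given patient; adaptive channel selection is out of scope.
* Epoch-level detection only — no event-level onset aggregation.
* The calibration table transcribes published channel means; users should
  recalibrate µ on their own data when montages or populations differ.
* VMD mode identity across channels relies on rank matching after
  ascending-frequency sort; when two modes of one channel exchange
  spectral content (crowded spectra), the pairing can momentarily
  misalign, which depresses the affected γ.
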