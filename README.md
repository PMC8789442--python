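# epivmd

Epoch-level seizure detection from two-channel scalp EEG **without a
denoising stage**. Denoising filters (band-pass, ICA) discard signal along
with noise; `epivmd` instead works on the full noisy recording and uses
features designed to be robust to noise:

* **Pauta (3σ) outlier cleaning** — per 2 s analysis window, samples with
  `|x − mean| > 3·sd` are replaced by the window median.
* **Nonuniform amplitude transform** — identity for `|x| ≤ 80` µV,
  `sign(x)·(70 + 10·log10(|x| − 70))` above; continuous at the knee and
  odd-symmetric, it compresses extreme amplitudes and widens the relative
  ictal/interictal contrast.
* **Adjusted sample entropy** — SampEn (Chebyshev templates, m = 2,
  r = 0.2·sd, self-matches excluded) plus a channel-specific correction:
  the window is split into 8 segments and, when the per-segment entropies
  rise (or fall) by ≥ 20 % on three consecutive steps, the channel factor µ
  is added (or subtracted):
  `SampEn_imp = SampEn + µ·α − µ·β`, with µ = |mean entropy (ictal) −
  mean entropy (interictal)| for that channel (shipped calibration: e.g.
  µ = 0.05 for CZPZ, 0.13 for FZCZ).
* **Variational mode decomposition (VMD)** — ADMM with Wiener-filter mode
  updates and power-weighted center-frequency updates splits each channel
  into K narrowband modes (IMFs); K is chosen by *center-frequency
  observation*: increase K until the rank-averaged center frequencies
  crowd below a relative spacing of 0.1.
* **Phase synchronization index (PSI)** — per rank-matched IMF pair of the
  two channels, `γ = sqrt(⟨cos Δθ⟩² + ⟨sin Δθ⟩²)` with Δθ the difference
  of Hilbert instantaneous phases; γ = 1 is perfect locking.
* **Random forest** (900 trees, 5 candidate variables per split) on the
  7-feature vector `[SampEn_imp(FZCZ), SampEn_imp(CZPZ), γ₁…γ₅]`,
  evaluated with seeded stratified 10-fold cross-validation and reported
  as accuracy / sensitivity / specificity (epileptic = positive class).

The package reads EDF recordings (e.g. the CHB-MIT scalp EEG corpus,
bipolar 10–20 montage, channels FZ-CZ and CZ-PZ) and also ships a seeded
two-channel surrogate generator so that every stage is testable and
benchmarkable without any download.

## Worked example

```python
from epivmd import GenConfig, PipelineConfig, generate_dataset, run_pipeline

data = generate_dataset(20, GenConfig(seed=7))        # 40 labeled epoch pairs
report, features = run_pipeline(data, PipelineConfig(seed=7))
print(report.accuracy, report.sensitivity, report.specificity)
```

prints

```
accuracy    1.0
sensitivity 1.0
specificity 1.0
```

and the feature table makes the mechanism visible — ictal epochs carry a
sustained high-amplitude rhythm (lower adjusted entropy) and stronger
cross-channel phase locking:

```
              sampen_imp_FZCZ  psi_1  psi_5
epileptic               0.975  0.964  0.938
nonepileptic            1.715  0.951  0.858
```

On the default synthetic benchmark the classes are deliberately well
separated, so accuracy saturates; with class parameters equalized the same
pipeline drops to chance (≈ 0.5), confirming there is no leakage.

The same flow from the shell:

```bash
epivmd simulate --n-per-class 20 --seed 7 --out dataset.csv
epivmd extract-features --dataset dataset.csv --seed 7 --out features.csv
epivmd train --features features.csv --out report.json
epivmd select-k --n-epochs 20 --seed 1          # prints the chosen K
epivmd robustness --out robustness.csv          # missing-data protocol
```

For real data replace the first two steps with
`epivmd extract-features --edf recording.edf --annotations seizures.txt`
where `seizures.txt` lists one `start_seconds end_seconds` interval per
line.

## Layout

| module | contents |
| --- | --- |
| `epivmd.preprocess` | `Epoch`, Pauta outlier handling, nonuniform transform, band-pass baseline |
| `epivmd.entropy` | sample entropy, segment entropies, trend flags, adjustment factor, calibration IO |
| `epivmd.vmd` | VMD (ADMM), rank-averaged center frequencies, mode-count selection |
| `epivmd.phase_sync` | Hilbert phase, PSI, IMF-pair PSI, channel→region map |
| `epivmd.features_model` | 7-feature assembly, ANOVA screening, random-forest CV, report/feature IO |
| `epivmd.synthetic_data` | surrogate generator, missing-data corruption, robustness protocol |
| `epivmd.pipeline` / `epivmd.cli` | EDF ingestion, epoching, orchestration, `epivmd` command |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
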