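# ecgsqa — signal-quality assessment for wearable single-lead ECG

Wearable ECG recorders produce long ambulatory recordings in which much
of the signal is unusable: electrodes detach, muscles fire, cables
move. Before any rhythm or morphology analysis, each 10-second segment
must be graded — **A** (all waveforms legible, diagnostic quality),
**B** (QRS visible, heart rate measurable), **C** (discard). `ecgsqa`
implements a complete three-grade quality-assessment pipeline for
researchers and device engineers working with single-lead wearable
ECG:

1. **Pre-assessment** — cheap rules reject lead-off segments (constant
   voltage over > 80 % of the window) and pure noise (spectral-purity
   index `MPSQI = ∫₀⁴⁰ p(f) df / ∫₀^Nyq p(f) df < 0.30`);
2. **Wavelet scattering features** — a three-layer Morlet scattering
   network
   `S0 = x∗φ_I`, `S1[i] = |x∗ψ1ᵢ|∗φ_I`, `S2[i,j] = ||x∗ψ1ᵢ|∗ψ2ⱼ|∗φ_I`
   with invariance scale `I = 2 s` and quality factors `Q = (8, 1)`,
   producing an 81 × 20 translation-invariant, deformation-stable
   feature matrix per 2,500-sample segment (41 first-order wavelets,
   7 second-order, 39 admissible order-2 paths);
3. **Classification** — a bidirectional LSTM reads the 20 time frames
   as a sequence and outputs grade probabilities; k-fold
   cross-validation reports per-class sensitivity (Se), precision
   (+P), F1, macro-F1 (mF1) and overall accuracy (mACC);
4. **Synthetic data** — clean P-QRS-T ECG and four ambulatory noise
   classes (baseline wander, muscle artifact, electrode motion,
   Gaussian-augmented baseline wander) mixed at exact SNR: +10 dB
   defines grade B, −10 dB grade C — so the full pipeline runs and is
   tested without any database downloads;
5. **Streaming** — a 10-s frame / 1-s hop sliding assessor grades long
   records in real-time style.

## Worked example

```python
import ecgsqa as e

bank = e.build_filter_bank()                      # default: fs 250, I = 2 s, Q = (8, 1)
print("filters:", bank.n_first_order, bank.n_second_order, "paths:", bank.n_paths)

rec = e.synth_ecg(duration_s=10.0, fs=250.0, heart_rate_bpm=72.0, seed=7)
seg = e.segment(rec)[0]                           # min-max normalized 10-s window
res = e.preassess(seg)
print("verdict:", res.verdict.value, " MPSQI = %.3f" % res.mpsqi)

fm = e.scattering_transform(seg, bank)
print("feature matrix:", fm.shape)

noisy = e.add_noise(rec, e.synth_noise(e.NoiseSpec("em", -10.0, seed=8)), -10.0)
print("measured SNR = %.3f dB" % e.measured_snr_db(rec, noisy))

cm = e.ConfusionMatrix3([[1578, 37, 1], [23, 1597, 8], [2, 8, 1645]])
print(e.metrics(cm).table())
```

Output:

```
filters: 41 7 paths: 81
verdict: PASS  MPSQI = 0.998
feature matrix: (81, 20)
measured SNR = -10.000 dB
 class      Se%      +P%      F1%
     A    97.65    98.44    98.04
     B    98.10    97.26    97.68
     C    99.40    99.46    99.43
mF1 = 98.38%   mACC = 98.39%
```

The filter counts are the default network's geometry; the clean
synthetic beat passes pre-assessment with 99.8 % of its power in the
ECG band; the electrode-motion mixture lands at exactly the requested
−10 dB; and the metric table is the full per-class suite for a 3 × 3
confusion matrix of a held-out test set (rows actual, columns
predicted).

An end-to-end experiment — 300 synthetic segments per grade, scattering
features, 3-fold cross-validated Bi-LSTM — reaches mACC ≈ 98 % and runs
in about a minute on one CPU:

```python
data = e.build_dataset(300, seed=17)              # A clean, B +10 dB, C -10 dB
feats = e.transform_batch([d.segment for d in data], bank)
cfg = e.ClassifierConfig.desk(max_epochs=40, hidden_units=32,
                              batch_size=64, seed=17, standardize=True)
folds, mean = e.crossvalidate(feats, [d.label for d in data], k=3, config=cfg, seed=17)
print("mACC = %.2f%%" % mean.macc)
```

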