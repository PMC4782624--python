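# pcgkit

Noise-robust cardiac status recognition from phonocardiogram (PCG)
recordings.

Auscultation — listening to S1/S2 heart sounds and the murmurs between
them — degrades badly in noisy clinical environments, and visual
inspection of waveforms or spectrograms becomes unreliable below roughly
10 dB SNR. `pcgkit` implements an automated alternative for engineers and
researchers working on heart-sound screening: it quantifies the
*structural irregularity* of the signal, a property that survives noise
far better than its visual appearance, and classifies recordings as
normal or abnormal with a support vector machine.

## Method

The pipeline has five stages:

1. **Amplitude normalization.** Each recording (16-bit PCM mono WAV,
   nominally 8 kHz) is scaled by its peak so amplitudes lie in ±1,
   removing subject- and sensor-dependent gain.
2. **Fractal-dimension profile.** The Katz fractal dimension

   `FD = log10(n) / (log10(n) + log10(d/L))`

   is computed over a sliding window of `M = 0.05·fs` samples with 99 %
   overlap, where `L` is the curve length of the windowed waveform, `d`
   its maximal extent from the window's first point, and `n = M − 1`.
   S1/S2 transients raise FD above the quiet-interval baseline.
3. **Cardiac cycle extraction.** Events are contiguous runs of the FD
   profile above `mean + k_σ·std`; the shorter inter-event gap (systole)
   identifies S1 vs S2, and each S1-to-next-S1 span becomes one cycle with
   duration `C_d = d_S1 + d_sys + d_S2 + d_dia`.
4. **Irregularity index.** Sample entropy
   `SampEn(m, r, N) = −ln(C^{m+1}(r) / C^m(r))` — the negative log
   conditional probability that templates matching for `m` points within
   tolerance `r` (Chebyshev distance, self-matches excluded) still match
   at `m + 1` — is computed per cycle and averaged. Regular (normal)
   heart sounds score low; murmurs and turbulence score high. Defaults:
   `m = 2`, `r = 0.2` absolute on the normalized signal.
5. **Classification.** A soft-margin kernel SVM (dual problem
   `max Σα_j − ½ΣΣ α_j α_k d_j d_k K(y_j, y_k)` s.t. `Σ d_j α_j = 0`,
   `0 ≤ α_j ≤ Γ`) separates normal (−1) from abnormal (+1); performance
   is reported as sensitivity, specificity and accuracy from the
   TP/TN/FP/FN confusion counts.

A synthetic PCG generator (Gaussian-envelope S1/S2 bursts, band-limited
murmur noise, exact ground-truth annotations) and an SNR-exact noise
injector (white Gaussian or lung-sound interference) make the whole
pipeline testable and let it run the full robustness protocol — clean,
10, 5, 0 and −5 dB — without clinical data.

## Worked example

```python
import pcgkit as pk

# a 6 s normal recording and a pansystolic-murmur recording
normal, _ = pk.generate(pk.SynthSpec(duration_s=6.0, seed=1))
abnormal, _ = pk.generate(
    pk.SynthSpec(duration_s=6.0, murmur=pk.MurmurSpec("pansystolic"), seed=2)
)

for sig in (normal, abnormal):
    fv = pk.extract_feature(sig)
    print(f"{sig.label:>8}: SampEn = {fv.sampen:.4f} over {fv.n_cycles_used} cycles")

noisy = pk.add_noise(normal, pk.NoiseSpec(snr_db=0.0, seed=3))
print(f"  0 dB  : SampEn = {pk.extract_feature(noisy).sampen:.4f}")
```

prints

```
  normal: SampEn = 0.0045 over 5 cycles
abnormal: SampEn = 0.0336 over 2 cycles
  0 dB  : SampEn = 0.2411
```

The murmur raises the irregularity index of the clean abnormal record by
roughly an order of magnitude over the clean normal one, and heavy noise
(0 dB) drives even a normal record's index upward — which is exactly the
degradation the SVM stage has to absorb. The same stages are available
from the shell:

```bash
pcgkit simulate --n-normal 10 --n-abnormal 10 --out corpus/
pcgkit corrupt --input corpus/normal_000.wav --out noisy.wav --snr 0 --seed 7
pcgkit entropy --input corpus/ --manifest corpus/manifest.csv --out features.csv
pcgkit noise-study --n-normal 30 --n-abnormal 30 --out study/
```

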