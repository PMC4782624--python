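# Methods

This note documents the models, conventions and numerical choices behind
`pcgkit`, the reasoning where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Signal model and pipeline order

A phonocardiogram is modeled as a sequence of cardiac cycles, each the
concatenation S1 → systole → S2 → diastole, with optional murmur energy
inside the systolic and/or diastolic interval. All stages operate on the
peak-normalized waveform (division by the global maximum absolute
amplitude), and normalization always precedes feature computation: both
the Katz fractal dimension and the absolute entropy tolerance are
amplitude-convention-sensitive, so fixing the scale first is what makes
their values comparable across recordings. Per-window gain normalization
was considered and rejected — it would distort the relative S1/S2/murmur
amplitudes the downstream stages rely on.

## Katz fractal dimension

`katz_fd` treats a window as the planar curve through `(i, s_i)` with
**unit abscissa spacing** and returns
`log10(n) / (log10(n) + log10(d/L))`. Katz's measure is
convention-sensitive (rescaling either axis changes it), so the
convention is fixed and documented rather than left implicit; it follows
that FD is *not* invariant under amplitude scaling, and the test suite
asserts only ordering properties on same-scale (normalized) inputs.
Numerical choices:

- A constant window has no extent (`d = 0`) and returns 1.0 by
  convention.
- `d ≤ L` always (each point's chord is no longer than the path to it),
  so FD ≥ 1; when `d/L ≥ 1 − 1e−12` the window is treated as an exact
  straight line and FD is returned as exactly 1.0, absorbing the few-ulp
  difference between a summed path length and its chord.
- The window is `M = floor(0.05·fs)` samples (400 at 8 kHz) with 99 %
  overlap, giving hop `max(1, M − floor(0.99·M))` = 4 samples at 8 kHz.
  Trailing samples short of a full window are discarded so every FD value
  is a true M-sample statistic.

At 8 kHz with ±1 amplitudes the per-step ordinate increments are ≪ 1, so
FD values live in a narrow band just above 1; the S1/S2 contrast is still
reliable because the detection threshold is relative to the profile's own
mean and spread.

## Event detection and cycle assembly

Heart-sound events are contiguous runs of FD-profile windows at or above
`mean + k_σ·std` (default `k_σ = 0.5`). Runs closer than `merge_gap_s`
(30 ms) are merged **before** events shorter than `min_event_s` (40 ms)
are dropped — merging first prevents a burst fragmented by a single
sub-threshold dip from being deleted piecewise. Window indices map back
to samples via the window start indices; an event spans first-window
start to last-window start plus the window length.

S1/S2 disambiguation uses the physiological rule that systole is shorter
than diastole: each adjacent pair of inter-event gaps votes for the
parity of the S1 events, and the majority fixes the labeling, making it
robust to one missed or spurious event. With fewer than three events the
alternation cannot be anchored and all events stay unlabeled.

All intervals are half-open `[start, end)` in 0-based sample
coordinates; durations are `(end − start)/fs`. Each consecutive S1 pair
with exactly one S2 between them yields one cycle, so the four sub-span
durations sum to the S1-to-next-S1 span *exactly* at sample resolution —
an invariant the tests assert. A trailing S1 without a successor closes
no cycle; malformed spans (doubled or missing events) are skipped rather
than guessed at.

## Sample entropy

`SampEn(m, r, N) = −ln(C^{m+1}/C^m)` with Chebyshev template distance,
`d ≤ r` matching (closed inequality — documented because strict vs closed
changes counts at exact ties) and self-matches excluded. Both conditional
probabilities are computed over the same template range `i ∈ [1, N−m]`,
which guarantees `C^{m+1} ≤ C^m` by template nesting and hence
SampEn ≥ 0 whenever defined. If no pair matches at dimension m+1 (or m),
the conditional probability is undefined: the implementation returns an
`inf` sentinel with a warning, and per-record aggregation excludes such
cycles from the mean rather than imputing a value.

Two independent implementations exist: a compiled sorted-sweep pair
counter (numba; the templates are sorted by first component so the inner
loop terminates early) with an exact KD-tree fallback, and a brute-force
double-loop reference that follows the defining equations literally. The
test suite holds them equal to 1e−12 over hundreds of seeded series.

**Tolerance convention.** The defaults are `m = 2` and `r = 0.2` used as
an **absolute** tolerance on the ±1-normalized signal, with
`r_mode="std_relative"` (`r·std(segment)`, the classical choice for raw
physiological series) available as an option. The absolute default is
deliberate: with a std-relative tolerance the ratio between r and the
noise amplitude is fixed by the SNR alone, so under additive noise the
entropy of *every* record saturates at the white-noise ceiling as soon as
the noise exceeds the (shrinking) tolerance, and class contrast collapses
already at mild noise levels. An absolute tolerance on the normalized
signal instead acts as a genuine noise filter: perturbations below r are
invisible, the index rises gradually as the noise amplitude approaches r,
and the normal/abnormal contrast degrades gracefully across the SNR
ladder — the behavior the classification stage depends on. The two modes
agree on clean, fixed-scale inputs up to the choice of scale.

**Aggregation.** The per-record feature is the mean per-cycle SampEn over
all complete extracted cycles (`n_cycles_used` records how many), with a
whole-record escape hatch (`whole_record=True`). When segmentation finds
no usable cycle — under heavy noise the FD peaks can be buried — the
study pipeline falls back to whole-record SampEn and logs the fallback,
so no record is silently dropped and no class can empty out.

## Noise injection

SNR is defined over whole-record mean power,
`10·log10(P_signal/P_noise)`, the conventional reading when no other
definition is given; the scaling is exact by construction and verified to
0.1 dB. Gaussian noise comes from a seeded generator; lung-sound
interference is tiled to the record length with a 10 ms crossfade at each
seam to avoid click transients, then scaled identically. The corrupted
signal is *not* re-normalized by the injector — the analysis stages
re-normalize themselves, so the perturbation genuinely reaches them.

## Classifier

The soft-margin kernel SVM is solved in its dual form by libsvm's SMO
(via scikit-learn), but the fitted model re-exposes the multipliers α_j,
targets d_j, support vectors and bias b, and *verifies* the dual
constraints (Σ d_j α_j = 0 within 1e−6, 0 ≤ α_j ≤ Γ) after every fit, so
the optimization problem being solved is explicit and testable (including
dual-vs-primal equality for the linear kernel). Defaults: RBF kernel with
the bandwidth set by the median heuristic on pairwise training distances
(`gamma = 1/(2·median²)` — scale-free, which matters for a 1-D feature of
varying spread), box constraint Γ = 1. Abnormal is encoded +1 and is the
"positive" class of the confusion bookkeeping; a decision value of
exactly zero maps to abnormal, the fail-safe direction for screening.
Percentages are sensitivity TP/(TP+FN), specificity TN/(TN+FP) and
accuracy (TP+TN)/total, each ×100, reported to two decimals.

## Synthetic data generator

The generator emulates: S1 as a Gaussian-envelope 60 Hz burst (0.10 s,
amplitude 1), S2 as a 90 Hz burst (0.08 s, amplitude 0.8), a systolic
fraction of 0.35 (S1 onset → S2 onset), per-cycle length jitter ±2 %,
murmurs as seeded band-limited Gaussian noise (150–400 Hz, std 0.35
relative to the S1 peak — a clearly audible murmur still quieter than the
valve sounds) placed in the systolic interval, the diastolic interval, or
pan-systolically, and a seeded sensor/ambient noise floor of std 0.005:
real auscultation recordings never contain exact digital silence. Heart
rates are drawn per subject (default 55–95 bpm) and every record carries
sample-exact ground-truth annotations. The floor value sits where the
FD event detector's relative threshold still separates bursts from
baseline across 50–120 bpm; a much larger floor compresses the FD
profile's spread at low heart rates and produces spurious events.

What the generator does **not** emulate: recorded S1/S2 morphology and
split sounds, S3/S4, respiration-modulated heart rate and amplitude,
frequency-dependent chest-wall filtering, real hospital noise (only
stationary Gaussian noise and looped interference), and the diversity of
real murmur spectra. Passing tests on this corpus therefore demonstrate
the *mechanics* of the pipeline — exact cycle recovery, correct entropy
arithmetic, the direction and monotonicity of the noise response, the
shape of the accuracy degradation — not clinical performance. Absolute
entropy values and accuracies on real recordings depend on data that is
not available, and are out of scope; only orderings and trends are
claimed.

## Problem sizes

The bundled validation uses corpora small enough for a single CPU:
per-seed corpora of 3+3 records (3.5 s) over 20 seeds for the entropy
noise trend, 10+10 records (4 s) over 10 seeds for the accuracy shape,
and a 60+60-record, 6 s study in `scripts/acceptance.py`. These sizes are
the package's own choice of test scale; the generator's signal parameters
are identical at every scale.

## Known limitations

- The FD event detector assumes murmurs quieter than S1/S2; a murmur
  bridging S1→S2 merges their FD runs into one event, which costs cycles
  (the entropy feature is unaffected, but per-cycle counts drop for
  murmur records).
- Under heavy noise (≤ 0 dB) segmentation degrades to near-arbitrary
  spans; the entropy feature then measures the composite signal rather
  than true cycles, which is precisely why the whole-record fallback is
  acceptable there.
- Katz FD under the unit-spacing convention compresses toward 1 at high
  sampling rates; the detector works with relative thresholds, but
  absolute FD values should not be compared across sampling rates.
- The classifier is a single-feature SVM; it inherits the feature's
  saturation at deeply negative SNR, where sensitivity/specificity drift
  toward chance.
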