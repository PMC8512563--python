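# Methods

This note records the models, parameter choices and numerical decisions
behind `carotidprint`, and what the synthetic experiments do and do not
demonstrate.

## Synthetic carotid sound model (`vascsim`)

Real carotid auscultation data are rarely shareable, so the package
ships a generator whose output exercises every downstream stage and
carries exact ground truth.

**Cycle timing.** RR intervals are drawn per beat from
`Normal(60/hr_mean, hr_sd/hr_mean · 60/hr_mean)` seconds, truncated
below at half the mean. Systole lasts `0.30 + 0.10·(RR − 1)` s (clipped
to [0.18, 0.45] s — systole varies much less than diastole), S1 and S2
have per-user fixed durations drawn from [0.09, 0.13] s and
[0.07, 0.10] s, and diastole absorbs the remainder (≥ 0.10 s). A
recording starts with a partial diastole so leading fragments are
realistic.

**Heart sounds.** S1 and S2 are Gaussian-windowed multi-tone bursts
(window σ = duration/6) whose 2–3 component frequencies are drawn per
user from 100–150 Hz (S1) and 110–170 Hz (S2) and jittered ±12 % per
burst. The burst peak is renormalized to its target amplitude (S1 ≈ 1,
S2 ≈ 0.55, ±10 % per beat) so random component phases cannot cancel a
heart sound. The jitter spreads burst energy in frequency, as in real
transients, and keeps any single spectral line from dominating a
recording's periodogram. Placing the bursts above 100 Hz keeps the
transient band disjoint from the murmur signature band below, which is
what makes the amplitude-based S1/S2 screening rule and the
murmur-band separability property simultaneously satisfiable.

**Murmur (the biometric signature).** Continuous white noise is
band-pass filtered (2nd-order Butterworth) into a user-specific band
inside 4–100 Hz, scaled to an RMS gain of 0.08–0.13 relative to the S1
peak, and boosted ×1.4 during systole (smoothed 30 ms) — flow sound
peaks with systolic velocity. Band centres for an `n`-user cohort are
geometrically spaced by `min(separation, available_span/(n−1))` octaves
inside [4, 100] Hz: the requested octave spacing is honoured whenever
the cohort fits, and gracefully compressed otherwise (seven users at
separation 0.8 need more octaves than the band holds). Band half-widths
are 0.15–0.25 octaves.

**Degraded recordings** attenuate S2 to 0.04 — below the murmur floor —
emulating recordings whose S2 events cannot be recognized. The default
degraded fraction is 9/890 ≈ 1 %.

**Devices and sides.** The four device "clones" differ by a fixed gain
(0, +2, −2, +1 dB) and a first-order low-pass at 6–7.5 kHz; the right
side multiplies the murmur gain by a per-user factor in [0.92, 0.99].
Both effects are deliberately small.

**What the generator does not model:** breathing or motion artifacts
(recordings are taken under apnea), arterial pathology (stenosis
bruits), sensor contact variation, within-user drift over weeks, or any
hemodynamic physics. Passing results on this cohort demonstrate that
the pipeline's stages are correct and mutually consistent — not that
real carotid sounds reach the same identification accuracy.

## Quality screening (`audio_quality`)

The screen automates a visual criterion — "are S1 and S2 events
recognizable?" — so its parameters are declared, not estimated. The
envelope is |Hilbert| of the 25–400 Hz band-passed signal, smoothed
50 ms. Peaks need at least 15 % of the envelope maximum in height, 5 %
in prominence, and 0.15 s separation; the separation must stay below
the ~0.3 s S1→S2 spacing or a murmur spike can evict a true S2 peak.
A peak that dominates its ±0.55-beat-period neighbourhood is an S1
candidate. S2 candidates are non-S1 peaks 0.1–0.7 periods after an S1
with ≥ 15 % of that S1's prominence; because a genuine S2 recurs at a
nearly constant phase while murmur transients scatter, only candidates
within 0.06 periods of the cohort-median S1→S2 offset are accepted. A
recording passes when both S1 and S2 counts reach 70 % of the expected
cycle count (duration / autocorrelation beat period). On a 280-recording
sweep over four cohort seeds this yields 2.7 % false rejection of clean
recordings and 100 % rejection of degraded ones.

## Morse-wavelet CWT (`cwt_spectral`)

The analysis wavelet is the generalized Morse family,
`Ψ(ω) ∝ ω^β e^(−ω^γ)` for ω > 0, with γ = 3 (perfectly symmetric
member) and β = 20 so the time-bandwidth product γβ = 60. Its peak is
at `ω_p = (β/γ)^(1/γ)`. Each pseudo-frequency on a geometric grid
(default 10 voices per octave, 200 Hz down to 1 Hz — all reported
carotid structure sits below 100 Hz; the full band to fs/2 is available
by argument) gets a filter sampled in the frequency domain,
peak-normalized to 2 so a unit tone yields a unit-magnitude ridge; the
transform is inverse FFTs of the filtered spectrum. The signal is
symmetrically padded by three time-domain standard deviations of the
slowest wavelet (≈ 3·√(βγ)/(2π f_min) seconds) to keep edge energy out
of the analysis window. Magnitude is stored linearly; log compression
happens only at rendering. Double precision is the default (the
linearity property is tested at 1e−9 relative); the batch pipeline opts
into single precision for a ~2× speed/memory win at ~1e−7 accuracy.

## HSMM segmentation (`hs_segmentation`)

Four envelope features at 50 Hz from the 25–400 Hz band-passed signal,
computed at an intermediate 1 kHz rate: homomorphic envelope (exp of
8 Hz low-passed log |Hilbert|), Hilbert envelope, a Morlet wavelet
envelope at 130 Hz pseudo-frequency, and mean spectrogram power in
90–200 Hz (the last two track the burst band). Each is min-max scaled
per recording, which makes segmentation exactly amplitude-invariant.

Emissions are one-vs-rest logistic regressions per state (deterministic
lbfgs fits), normalized across states per frame. Durations are Gaussian
pmfs on run lengths estimated from labelled interior runs; at decode
time the systole and diastole means are rescaled so their sum matches
the estimated heart rate's cycle length minus the S1/S2 means —
duration generalization over heart rate. The duration search is capped
at 2× the mean.

Decoding is an extended Viterbi over run lengths with deterministic
cyclic transitions (S1→systole→S2→diastole). The path score semantics —
interior runs charged their duration pmf, the first and last
(truncated) runs charged the survival tail, uniform initial state —
are stated in the module docstring, and the decoder is property-tested
against exhaustive path enumeration on random toy problems. Ties break
toward the earlier state in cycle order and the shorter final run, so
decoding is deterministic. Heart rate comes from the homomorphic
envelope's autocorrelation peak in the 0.43–1.5 s lag range (40–140
bpm); peaks need 0.35 prominence — periodic envelopes score above
≈ 0.5, noise-only autocorrelations below ≈ 0.25 — otherwise a 70 bpm
prior is used with a warning.

Trained on 14 labelled synthetic recordings (2 per user), held-out
frame accuracy is ≈ 0.95 across users.

## Fingerprints and cycle images (`fingerprint`)

Cycles (diastole onset → S2 end) slice the CWT magnitude in time; each
slice is resized to 16,000 columns with nearest-neighbour indexing
(`src = floor((j+0.5)·w_in/w_out)`), the only interpolation used
anywhere. Fingerprints are pixel-wise means over a user/side's cycles.
For the classifier, a cycle is log-compressed (`log1p(m/ε)` with ε =
1e−3 of the cycle's own maximum, making images amplitude-invariant),
min-max normalized per image, mapped through a fixed analytic 256-entry
heat-style RGB lookup table (black→red→yellow→white; generated in code,
so no palette file and bit-stable output), and nearest-neighbour
resized to 134×134×3 in [0, 1]. The three image channels are what the
first conv layer's 896 parameters require.

## CNN and evaluation protocol (`identify_cnn`, `metrics_report`)

Architecture: 134×134×3 input → [3×3 conv, 32 filters, valid, ReLU →
2×2 max-pool] ×3 → dense 128 (ReLU) → dense n_classes (softmax);
feature maps 132→66→64→32→30→15, flatten 7200; parameter counts 896,
9248, 9248, 921,728, 903. Training: Adam (lr 0.001, β₁ 0.9, β₂ 0.999,
ε 1e−7), categorical cross-entropy, batch 32, 10 epochs, per-epoch
shuffling; Glorot-uniform initialization. Activation, optimizer,
pooling and padding choices are the standard conventions that produce
exactly these shapes and counts.

The network runs directly on NumPy (single-threaded BLAS GEMMs,
float32): the first conv uses an im2col patch matrix filled by wide row
copies, deeper convs use k² shifted strided-view matmuls, and ReLU is
fused into pooling. Large scratch buffers are pooled between optimizer
steps. Everything is seeded through `SeedSequence`, so a fixed seed
reproduces confusion matrices bit-exactly on CPU.

Evaluation is stratified k-fold cross-validation with reshuffled
repetitions (default 5×10 = 50 runs; the packaged experiment uses 5×2 =
10 runs), a fresh model per run. Splitting is over cycle images, so
cycles from one recording can appear in both train and test folds; that
matches the sample-level protocol the pipeline emulates, and is the
optimistic reading — a grouped-by-recording split would be stricter.
Metrics: per class one-vs-rest TP/TN/FP/FN, SEN, SPE, PRE, F1 and
accuracy; the headline accuracy of a run is trace/total (the only
single-number multiclass reading); aggregation is mean ± sample sd over
runs, formatted as `(xx.xx±y.yy)%`. Undefined 0/0 ratios surface as
NaN, never as 0. Note that the mean one-vs-rest accuracy relates to
trace/total as `(C−2)/C + (2/C)·trace/total` for any C-class matrix —
they are equal only for C = 2 or a perfect classifier — which is why
both are reported explicitly.

## Packaged experiment scale

The default experiment simulates 7 users × 10 left-side recordings
(plus 2 per user, held out, to train the HSMM), screens them, caps the
per-user cycle count at 80 (every user retains ≥ 80 of typically
100–140 extracted cycles) and cross-validates 5-fold × 2 repetitions.
These sizes keep the complete run — simulation through 10 CNN
trainings — at roughly a quarter hour on one CPU while preserving the
protocol's structure; all of them are ordinary config fields
(`SimParams`, `FingerprintParams`, `CvPlan`) for larger studies.

## Known limitations

- The cohort is synthetic; accuracy numbers characterize the pipeline,
  not real-world biometric performance (see the generator's non-goals).
- The HSMM is trained on generator ground truth; on real data it would
  need labelled recordings or a pretrained segmentation model.
- Quality screening assumes S1 louder than S2 in the 25–400 Hz
  envelope and a quasi-periodic beat; arrhythmias would defeat the
  phase-consistency rule.
- The CNN implementation is CPU-only by design; wall-clock scales
  linearly with images × epochs × runs.
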