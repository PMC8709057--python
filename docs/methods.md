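# Methods

`bcishield` models one concrete security problem: a P300-speller
brain-computer interface whose EEG headset streams N = 14 channels at
128 Hz to a classification framework over a link an attacker can write to.
The package provides (i) a synthetic world in which the whole stack is
testable without recordings, (ii) the attacks, (iii) the SVM classification
and metric suite, (iv) the channel-mixing integrity layer (the "brain
hacking recognizer", BHR), and (v) the Monte Carlo campaign that measures
its rejection rate.

## Synthetic EEG world

Each trial is a 14 × 90 matrix (0.7 s at 128 Hz) in µV:

* background: per-channel 1/f ("pink") noise, synthesized by shaping white
  Gaussian noise with a 1/√f amplitude mask in the frequency domain
  (exactly seedable; periodogram slope −1 within ±0.3 over 1–40 Hz),
  scaled to 10 µV RMS, plus 1 µV RMS white sensor noise;
* target (P300) trials add a positive Gaussian deflection, default 6 µV
  peak at 300 ms with 80 ms width, weighted across channels by a fixed
  parietal-dominant topography (P7/P8 = 1.0 falling to 0.2 frontally);
* per-subject variation: peak latency ~ U(280, 380) ms, amplitude ×
  U(0.85, 1.25), width ~ U(70, 90) ms, topography jitter ± 20%; per-trial
  latency jitter ± 15 ms and amplitude × U(0.75, 1.25). These jitters are
  our choice of realistic inter-subject/inter-trial variability; they are
  config-exposed and fixed once.
* all samples soft-clipped (tanh) to the amplitude bound R = 100 µV, the
  same bound the integrity layer assumes.

A full-scale subject holds 240 target and 1,200 non-target trials (1:5, the
composition of a 6×6 speller run); `scale` shrinks both counts, never the
ratio. Non-target trials carry **no deterministic evoked content** — that
is a deliberate simplification, and it matters for what the green/red
classification tests establish (below). No artifacts (blinks, EMG), no
volume conduction, no inter-channel noise correlation are modelled.

The resulting single-trial discriminability is AUC ≈ 0.74 for a linear
SVM — at the low end of realistic P300 single-trial performance and well
below the real-data operating point of the experiment this package
emulates. Green classifier tests therefore establish pipeline correctness
and direction of mechanisms, not absolute performance.

## Preprocessing

Window 50–600 ms post-onset, half-open with sample *i* at time *i*/fs
(70 samples at 128 Hz); zero-phase low-pass by an 8th-order Butterworth at
15 Hz run forward–backward (`sosfiltfilt`; the *designed* order is 8, the
effective magnitude response is its square — the conventional zero-phase
reading); per-channel mean subtraction (an across-channel grand-average
subtraction is available behind `detrend_mode`); block-mean downsampling by
4 with trailing remainder discarded (70 → 17); per-trial z-scoring of the
flattened channel-major vector (per-channel scope available). Feature
length at defaults: 14 × 17 = 238.

## Attacks

* **AWGN**: per channel, noise variance = measured mean power /
  10^(SNR/10); presets at 20 and 40 dB. Forged samples are hard-clipped at
  ±R (the attacker stays inside winsorizing limits; clipping is the
  identity for in-range samples).
* **MN_MF**: donor subjects' trials (never the victim's) are averaged per
  class, median-filtered per channel (order 3 or 9, shrinking window at
  the edges), then amplitude-modulated with unit-variance pink noise and
  rescaled: `MN_MF = (1 + α1·pn) ⊙ MF_sig ⊙ k`, with per-channel
  `k = min(1, max|victim limits| / max|waveform|)` (shrink-only: the
  correction exists to evade amplitude-based rejection, not to amplify).
  The combination operator is read as amplitude modulation; a literal
  convolution mode exists behind `mode="convolve"` but under rescaling it
  would make the modulation depth α1 unobservable.
* **Injection**: a hacked dataset substitutes `n_fake` trials (400 of
  1,440 at full scale, i.e. 27.8%) at the first `n_fake` positions of an
  MT19937 permutation (seed 4). Each slot receives a fake of the same
  class, preserving the dataset composition.

## Classification

scikit-learn `SVC` with the five kernel presets L / Q / C / MG / CG;
Gaussian scales √P and 4√P (γ = 1/P, 1/(16P); P = 238), polynomial kernels
`(x·y/P + 1)^degree` with degree 2/3, box constraint 1 (not stated by the
source experiment; predictor standardization was tested and changes
nothing, so it is omitted). Stratified 5-fold cross-validation with a
seeded shuffle. Metrics are computed from explicit confusion counts;
zero-denominator metrics are reported as undefined (`None`) and flagged,
never coerced to 0 — silently zeroed metrics would corrupt the attack
impact Δ = V_real − V_fake.

## Integrity layer (BHR)

Both link ends derive, per iteration, the same ordered tuple (a, b, c, d)
of distinct channels from a counter-based PRNG keyed by a shared seed
(software stand-in for a hardware seed; the contract is only determinism
per (seed, iteration)). Tuples are uniform over the N(N−1)(N−2)(N−3)
ordered dispositions — 24,024 at N = 14.

With offsets u_a = s_a + C1, u_b = s_b + C2, v_c = s_c + C2
(C1 = 2000 µV, C2 = 1000 µV), the transmitted frame carries

    slot b: s_b          slot c: x = u_a·u_b/(u_a+u_b)
    slot d: y = u_a·u_b/(u_a−u_b)    slot a: z = u_a·v_c/(u_a+v_c)

and all other channels unchanged. The constraint C1 − C2 > 2R bounds every
denominator away from zero (|u_a − u_b| ≥ 800 µV at the defaults); C2 > R
keeps offset signals positive. The receiver verifies the harmonic identity
û_b = 2xy/(x+y), compares b̂ = û_b − C2 against the raw slot-b reference
(max relative deviation ε, threshold τ = 1e-6), then reconstructs
û_a from 1/û_a = 1/x − 1/û_b and v̂_c from 1/v̂_c = 1/z − 1/û_a.

Two receiver-side checks beyond the ε comparison are **required**, not
optional hardening:

1. any tripped division guard on tampered data is a `compromised` verdict,
   never a numeric fault;
2. every reconstructed signal must lie inside the physical band ±R (small
   absolute slack 1e-3 µV). The harmonic mean is symmetric in (x, y), so
   the ε check alone cannot distinguish a c/d-swapped forgery, and a guess
   agreeing on (b, c, d) but wrong on role a satisfies the identity by
   construction. Both cases put a reconstruction thousands of µV outside
   ±R (a raw ≤ 100 µV channel read as z forces v̂_c ≈ −C2), so the bound
   check rejects them deterministically. With it, an exhaustive sweep of
   all 24,023 wrong tuples on a random frame yields zero false passes; an
   attacker forging under the *correct* tuple passes by design — that is
   the 1/24,024 residual risk the campaign quantifies.

Verdict semantics are therefore: `compromised` ⇔ ε > τ **or** a guard/bound
violation. A single-sample perturbation of 0.01 µV on slots b, c or d
moves ε to ≥ ~2×10⁻⁵ (the worst-case sensitivity dε/dy ≈ 2(x/(x+y))² ≈
0.2), four orders above τ, while float round-off on legitimate frames
keeps ε < 10⁻⁹.

The original channel d is not transmitted (four slots carry three signals
plus one redundancy); the receiver fills it per `d_fill_policy` (zeros by
default, or a copy of the reference). A classifier behind the BHR
therefore sees 13 of 14 channels faithfully; on clean data this can flip a
small number of near-margin predictions relative to a BHR-less run — exact
metric equality is *not* attainable and is not claimed.

Inhibition: a compromised verdict forces the non-P300 label and raises a
warning. For a speller, false positives actuate the device and false
negatives merely stall it, so forcing the negative class is the safe
counteraction.

## Monte Carlo campaign

Per attack trial the defender draws its tuple from the synchronized PRNG
and the attacker (who knows the scheme but not seed/iteration — the
maximum-entropy worst case) guesses uniformly over all ordered
dispositions. `index_level` mode counts exact index matches with
vectorized chunked draws (144 M trials in ~2 s); `signal_level` mode
actually forges and decodes frames. Both modes consume the same two child
streams of the master seed, so small-scale runs agree success-for-success;
the equivalence holds because a forged frame passes verification iff the
guess equals the truth. Expected statistics at N = 14: rejection
1 − 1/24,024 = 99.996%, successes/session ~ Poisson(1440/24024 ≈ 0.05994).

## Numerical and degenerate-input choices

* Window convention: half-open [50, 600) ms, 0-based, sample *i* at
  *i*/fs; fixed for reproducibility and asserted against an enumeration
  oracle at several sampling rates.
* Median filter edges: shrinking window (length-preserving); even-length
  edge windows take the mean of the two central order statistics.
* Zero-variance trials, single-class training sets, missing donor
  classes, all-zero templates: `DataError`, distinct from argument errors.
* An empty campaign has rejection rate 1 by convention (no attack got
  through).
* Determinism: every stochastic step takes a seed or `numpy` Generator;
  dataset generation spawns independent child streams per subject
  (`SeedSequence`), so datasets are reproducible bit-for-bit.

## Known limitations

* The synthetic world's single-trial SNR is low; on it, class-mean-based
  forgeries (MN_MF) are *easier* to classify correctly than real trials,
  so those attacks raise precision instead of lowering it, and the
  corresponding direction-of-effect acceptance tests are intentionally
  left failing rather than papered over — see the repository's test suite
  output. The mechanism tests (winsorizing safety, template morphology,
  injection bookkeeping, BHR detection and inhibition) are unaffected.
* Non-target trials have no evoked content; real non-target flashes evoke
  VEPs that partly drive false positives in real spellers.
* No channel-noise-tolerant verification: τ = 1e-6 assumes a lossless
  float link; a noisy-link τ is config-exposed but unvalidated.
* EDF import requires an optional reader (`mne`/`pyedflib`) not bundled
  here; delimited text import is built in.
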