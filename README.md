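# bcishield

Cybersecurity toolkit for P300-based brain-computer interfaces (BCIs).

A P300 speller turns a rare-stimulus EEG deflection (the P300, peaking
250–500 ms after the target flash) into device commands. The wireless link
between the EEG headset and the classification framework is writable by an
attacker, who can inject noise or physiologically plausible fake P300
trials and silently steer the interface. `bcishield` implements the full
problem and its defense:

* **`synthgen`** — seeded synthetic 14-channel, 128 Hz EEG with P300
  morphology (pink-noise background, parietal-weighted Gaussian
  deflection), so everything is testable without recordings;
* **`prep`** — the standard P300 feature chain: 50–600 ms window,
  zero-phase 8th-order Butterworth low-pass at 15 Hz, detrending,
  block-mean decimation ×4, per-trial z-scoring (238 features/trial);
* **`attacks`** — AWGN injection at a target SNR and the modulated-noise /
  median-filter forgery `MN_MF = (1 + α₁·pn) ⊙ MF_sig ⊙ k` built from
  donor-subject class averages, plus seeded substitution of 400/1,440
  trials into a victim dataset (presets AWGN20, AWGN40, MF3_001, MF9_001,
  MF9_05);
* **`classify`** — the five SVM kernels (linear, quadratic, cubic,
  medium/coarse Gaussian), confusion-count metrics A/PPV/TPR/F1 and the
  cyberattack impact Δ = V_real − V_fake;
* **`bhr`** — the Brain Hacking Recognizer: both link ends derive a secret
  ordered channel tuple (a, b, c, d) per iteration from a shared-seed
  PRNG; the transmitter sends channel b raw plus three algebraic mixtures

      x = u_a·u_b/(u_a+u_b),  y = u_a·u_b/(u_a−u_b),  z = u_a·v_c/(u_a+v_c)

  (u = signal + offset), and the receiver checks the redundancy
  û_b = 2xy/(x+y) against the raw reference before reconstructing the
  signals. An attacker ignorant of the tuple must guess one of
  N(N−1)(N−2)(N−3) = 24,024 ordered dispositions (N = 14); any wrong guess
  is detected and the trial is forced to non-P300;
* **`testbench`** — the Monte Carlo campaign measuring the rejection rate
  over 100,000 sessions × 1,440 attack trials (144 M attacks, vectorized,
  ~2 s).

See `docs/methods.md` for the model details, assumptions and limitations.

## Worked example

```python
import bcishield as b
from bcishield import attacks, classify, prep, testbench

# a victim subject at 1/10 scale: 24 P300 + 120 non-P300 trials
ds = b.synth_dataset(n_subjects=1, seed=42, scale=0.1)[0]

# train a linear-kernel P300 classifier with 5-fold CV
X, y = prep.features_matrix(ds.trials)
model = classify.train_svm(X, y, kernel="L", seed=0)
print(f"cv accuracy {model.cv_accuracy:.3f}")          # cv accuracy 0.806

# inject 40 AWGN-forged trials and evaluate with the BHR enabled
hacked = attacks.inject(ds, "AWGN20", n_fake=40, selection_seed=4)
rep = classify.evaluate_under_attack(model, hacked, bhr_enabled=True, bhr_seed=7)
print(rep.as_dict())
# {'TP': 14, 'TN': 120, 'FP': 0, 'FN': 10, 'accuracy': 0.9305..., 'precision': 1.0,
#  'recall': 0.5833..., 'f1': 0.7368...}
# all 40 forged trials were flagged compromised and forced to non-P300: the
# fake non-P300s land in TN, the fake P300s in FN (zero false positives)

# the rejection statistics of the integrity layer itself
report = testbench.run_campaign(testbench.SessionConfig(
    n_sessions=1000, trials_per_session=1440, master_seed=1))
print(f"rejection {100*report.rejection_rate:.3f}% "
      f"(analytic {100*testbench.analytic_rejection_probability(14):.3f}%)")
# rejection 99.996% (analytic 99.996%)
```

A CLI mirrors the library (`bcishield synth|attack|train|eval|bhr-verify|campaign`),
e.g. the full-scale campaign:

```bash
bcishield campaign --sessions 100000 --trials 1440 --channels 14 --seed 1
# trials=144000000 successes=6002 rejection=99.996% (analytic 99.996%)
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from a fresh full-scale Monte Carlo campaign (100,000 sessions
× 1,440 attack trials at N = 14, defender tuple PRNG-drawn per trial,
attacker guessing uniformly over the 24,024 ordered dispositions): the
percentage of rejected attack trials, the total number of undetected
attacks, and the number of sessions with exactly one, two and three
undetected attacks, writing them as JSON keyed `t1`…`t5`.
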