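# wmv1 — working-memory content coding in V1 spike data

`wmv1` is a tested, reusable pipeline for asking whether — and how — primary
visual cortex carries the *content* of visual working memory during the delay
period of a delayed match-to-sample (DMTS) task. It implements the three core
spike-train analyses that question needs, plus everything around them:

- **Content-modulation index (CMI).** For each electrode,
  `CMI = (FR_h − FR_l) / (FR_h + FR_l)`, where `FR_h` and `FR_l` are the mean
  firing rates of the highest- and lowest-firing memory-content conditions
  (the *h/l pair*). The designation can be frozen in one dataset or epoch and
  applied as minuend/subtrahend in another, so a negative CMI reports a
  ranking reversal; a 20-fold × 200-iteration cross-validation with held-out
  designation removes the selection bias that self-designation introduces.
- **Cross-temporal Poisson-independent decoding (PID).** Trials are averaged
  into 20-trial batches, windowed on a sliding 200-ms grid, and content is
  decoded by `log L(θ) = Σᵢ nᵢ log fᵢ(θ) − Σᵢ fᵢ(θ)` with tuning `fᵢ(θ)`
  taken from a training window and activity `nᵢ` from a test window; the
  second term is the bias correction. Training in every window and testing
  in every other yields a train × test accuracy matrix against a
  label-permutation null — the tool for asking whether the delay period
  reuses the stimulus-period code.
- **Jitter-corrected cross-correlogram (CCG) connectivity.** Per unit pair
  and condition, `CCG(τ) = Σᵢ Σₜ r_j(t−τ) r_k(t) / √(N_j N_k)` on binary
  1-ms bins, corrected by subtracting the correlogram expected under 25-ms
  interval jitter; a pair is functionally connected when the corrected peak
  over 1–20-ms lags exceeds 7 SDs of the ±20–40-ms flanks. Pairs are
  categorised as stimulus-only / delay-only / both.

No public recording accompanies this problem, so the package ships a
first-class **synthetic DMTS-session generator** (`wmv1.simulate`): 4 content
conditions, 200-ms tuned cue responses, an exponentially decaying
off-response, a 700–1700-ms delay with weak content modulation at
near-spontaneous rates whose condition ranking is drawn *independently* of
the stimulus ranking, a configurable fraction of incorrect trials with
attenuated delay modulation, and injectable pairwise lagged synchrony. Every
analysis stage is validated against this ground truth.

Supporting stages: MUA threshold-crossing detection (4.5 robust SDs on the
1000-Hz high-passed trace), modified-z artifact-trial rejection (|z| ≤ 2.5),
channel retention by evoked SNR ≥ 5, receptive-field mapping by 2-D Gaussian
fit (r² > 0.6), early/late training-stage definition, antagonistic cue–probe
pairing, a linear-SVM cross-task harness, and a PCA projection of CMI time
courses. Sessions travel as an HDF5 container with a mirrored CSV trial
table (`wmv1.pipeline_io`).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
sessions and write their tables under `results/`:

```bash
python analysis/01_simulate_sessions.py
python analysis/03_cmi_by_task.py
```

```
  trial_set  mean_cmi      sem  n_electrodes
    correct  0.202445 0.004718             8
  incorrect  0.016432 0.021929             8
   fixation  0.000578 0.005530             8
spontaneous -0.007184 0.019679             8
```

Delay-period content modulation is present on correct memory trials and
collapses on incorrect trials and in the no-memory fixation control, with
the spontaneous-window baseline at zero — the signature of memory-specific
content coding. Decoding shows the complementary population-level story:

```bash
python analysis/04_cross_temporal_decoding.py
```

```
chance = 0.25
stimulus-window on-diagonal accuracy: 1.000
delay-window on-diagonal accuracy:    0.842
stimulus-trained, delay-tested:       0.250
```

Content is decodable within the stimulus period and within the delay, but a
decoder trained on stimulus-period activity performs at chance in the delay:
the two epochs use different codes, as the generator's independent rankings
dictate. `analysis/05_functional_connectivity.py` recovers the injected
3-ms-lag synchrony in exactly the epoch it was injected into, and
`analysis/06_association_learning.py` shows the CMI sign reversal and
|ΔCMI| convergence that frozen early-stage designation makes visible.

A CLI mirrors the stages for shell use:
`wmv1 simulate|preprocess|cmi|decode|ccg|association|run` (see `wmv1 --help`).

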