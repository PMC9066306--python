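# equivnoise

Equivalent-noise psychophysics for global motion and orientation processing:
a tested, reusable implementation of the full analysis pipeline used to
compare perceptual integration between cohorts of children (e.g. dyslexic
vs. typically developing readers) — from trial-by-trial 2AFC simulation
through adaptive threshold estimation to the rank-based and Bayesian group
statistics.

## The problem and the model

In a motion- or orientation-averaging task, an observer judges whether 100
elements (moving dots or Gabor patches) point on average left or right of
vertical.  External noise is injected by drawing element
directions/orientations from a Gaussian with standard deviation σ_ext.
Discrimination thresholds σ_obs (the offset supporting 84% correct) obey the
equivalent-noise observation equation

    σ_obs² = (σ_int² + σ_ext²) / n_samp

where **σ_int** is the internal noise corrupting each element's estimate and
**n_samp** is the effective number of elements pooled.  The efficient
two-point method measures just two thresholds per observer:

* the **no-noise threshold** — the mean offset at 84% correct with σ_ext = 0;
* the **maximum tolerable noise (MTN)** — the σ_ext at 84% correct with the
  mean offset fixed (±45° motion, ±22.5° orientation);

and converts MTN to sampling through a Monte-Carlo-calibrated transform

    n_samp = exp(A·MTN² + B·MTN + C)

(motion: A = 0.0001, B = 0.0357, C = −1.8093; orientation: A = 0.0006,
B = 0.0652, C = −1.6843), with internal noise then σ_int² = σ_obs² · n_samp.
A companion coherence task (proportion of signal elements at 84% correct)
is carried alongside.

Thresholds come from **QUEST** Bayesian adaptive staircases (75 trials each,
Weibull slope 3.5, lapse 0.01, prior SD 2 log10 units, posterior-mean
threshold), embedded in sessions with interleaved staircases and 15 easy
catch trials (165 trials per averaging task, 90 per coherence task),
criterion practice phases, and the screening rules that exclude inattentive
or at-ceiling participants.

The package contains six parts:

| module | role |
| --- | --- |
| `equivnoise.psychometric` | Weibull psychometric function, QUEST engine |
| `equivnoise.tasks` | session structure, stimulus sampling, exclusion rules |
| `equivnoise.observer_sim` | generative observers and synthetic cohorts |
| `equivnoise.en_model` | two-point decomposition + transform re-calibration |
| `equivnoise.stats` | Mann–Whitney + rank-biserial, JZS and rank Bayes factors, Quade rank ANCOVA, partial rank correlations, power analysis |
| `equivnoise.io` / `equivnoise.cli` | CSV/YAML schemas, run manifests, `equivnoise` command line |

## Worked example

Simulate one observer with known parameters through the full four-task
procedure and decompose their thresholds:

```python
from equivnoise.observer_sim import ObserverParams, run_participant
from equivnoise.en_model import fit_participant

observer = {
    "motion": ObserverParams(sigma_int=8.0, n_samp=3, lapse=0.01),
    "orientation": ObserverParams(sigma_int=5.0, n_samp=3, lapse=0.01),
}
result = run_participant(observer, seed=42, participant_id="demo")
thr = result.thresholds
est = fit_participant(thr["motion_avg"]["no_noise"],
                      thr["motion_avg"]["high_noise"], "motion")
```

which prints (via the obvious format strings):

```
motion no-noise threshold: 4.84 deg
motion MTN:                62.20 deg
motion coherence:          0.432
estimated n_samp:          2.22 (true 3)
estimated sigma_int:       7.22 deg (true 8)
```

The no-noise threshold sits near the closed-form prediction
z(0.84)·σ_int/√n_samp ≈ 4.59°, and the decomposition recovers the generative
parameters to within the precision a single 75-trial staircase affords.

The same pipeline runs from the shell:

```sh
equivnoise simulate-cohort --seed 7 --out-dir runs/demo
equivnoise fit-thresholds  --trials runs/demo/trial_logs.csv --out-dir runs/demo
equivnoise fit-en          --thresholds runs/demo/thresholds.csv --out-dir runs/demo
equivnoise compare-groups  --cohort runs/demo/cohort.csv --seed 7 --out-dir runs/demo
equivnoise report          --out-dir runs/demo
```

`simulate-cohort` draws a 48 + 48 synthetic cohort by default and
`compare-groups` emits the six pre-registered hypothesis rows (H1–H6:
coherence threshold, sampling and internal noise, per modality) with W, p,
rank-biserial, BF₁₀ and its evidence band, plus an age-controlled Quade
ANCOVA table.

## Documentation

`docs/methods.md` describes the generative model and its assumptions, the
staircase and calibration design choices, what the synthetic cohorts do and
do not emulate, and known limitations.
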