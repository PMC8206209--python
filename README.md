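# reflexmri

Tools for measuring stretch-evoked long-latency reflexes (LLRs) during
fMRI: EMG motion-artifact removal by adaptive noise cancellation, reflex
quantification, agreement statistics, parametric BOLD modeling, and
test-retest reliability of activation maps — with a synthetic-data layer
so every stage can be exercised and validated without access to scanner
recordings.

## The problem

Long-latency reflexes are muscle responses arising 50–100 ms after a
sudden joint perturbation, partly mediated by brainstem pathways.
Studying their neural substrates requires recording EMG *inside* an MRI
scanner while a robot perturbs the wrist — but sub-millimeter electrode
motion in the static field induces artifacts several times larger than
the reflex itself, in the same frequency band. The measurement strategy
this package implements:

- Perturbations are timed to the **silent window** after each fMRI
  volume (225 ms with no gradient/RF activity), and the 200 ms of EMG
  starting at perturbation onset is analysed.
- A **co-located reference electrode** records the motion artifact
  alone. Because the interference passes through two different channels,
  the reference `r` and the true artifact `w` are *nonlinearly* related,
  so plain subtraction is not enough.
- An **ANFIS adaptive noise canceller** (first-order Takagi–Sugeno fuzzy
  system, hybrid least-squares/backpropagation training with
  cross-validated epoch selection) learns `ŵ = f(r, ṙ, θ)` per trial and
  recovers the clean EMG as `x̂ = y − ŵ`.

Three pipelines are provided for comparison: `STD` (`x̂ = y`), `SUB`
(`x̂ = y − r`) and `ANC` (`x̂ = y − f(r)`). After band-pass filtering
(4th-order Butterworth, 20–250 Hz), rectification, low-pass envelope
extraction (60 Hz) and normalization by the isometric-contraction level,
the LLR amplitude is the envelope area over the long-latency window:

```
H = ∫₅₀¹⁰⁰ EMG(t) dt        (t in ms, normalized-EMG·ms)
```

Downstream, H values feed

- **agreement statistics** between in-scanner and reference sessions:
  paired Bland–Altman bias and 95% limits of agreement (LoA) with
  t-based confidence intervals, the Jaccard index of LoA intervals with
  a parametric bootstrap, per-trial z-scores against a reference
  session, and Bartlett variance tests;
- a **voxelwise GLM** of BOLD series,
  `y = β_FCR·H*_FCR + β_ECU·H*_ECU + β₀ + β_R·R`, where each `H*` column
  convolves 50 ms boxcars (placed 50 ms after perturbation onset, height
  H̃) with a double-gamma HRF — either the standard kernel (peak 6 s) or
  a brainstem-specific kernel (peak 4.5 s) — plus one-sided t contrasts,
  uncorrected-p / Bonferroni thresholding and cluster-extent cuts;
- **test-retest reliability**: Sørensen–Dice overlap of thresholded
  maps, `S = 2V_o/(V₁+V₂)`, and the two-session consistency intraclass
  correlation `ICC(3,1) = (BMS − EMS)/(BMS + EMS)` at participant
  (voxels as targets) and group (subjects as targets) level.

## Worked example

```python
import numpy as np
import reflexmri as rm
from reflexmri.emg_sim import EmgSimParams, generate_session_recording
from reflexmri.emg import process_session, LlrTable

protocol = rm.generate_protocol(rm.ProtocolSpec(seed=1))
recordings, truth = generate_session_recording(
    protocol, EmgSimParams(), np.random.default_rng(2)
)
rows = process_session(recordings, "P01", "IN1", seed=3)
table = LlrTable.from_rows(rows)
print(table.means().query("filter == 'ANC' and direction == 'stretch'")
      [["muscle", "velocity", "H_mean"]])
```

prints the per-velocity mean LLR amplitudes recovered by the adaptive
canceller for the stretched muscle:

```
   muscle  velocity     H_mean
0     ECU    -200.0  19.184756
1     ECU    -125.0  12.548182
2     ECU     -50.0   5.010505
9     FCR      50.0   6.429621
10    FCR     125.0  10.092062
11    FCR     200.0  21.034438
```

H grows roughly linearly with perturbation speed (the generator's
stretch response is `0.1 · |v|` normalized-EMG·ms on top of a ~2.5
background contribution), and the canceller recovers it in the presence
of motion artifacts whose in-band amplitude is five times the reflex.

On the same session the mean absolute error against the artifact-free
ground truth orders the pipelines as the method predicts — ANC ≈ 2.4,
SUB ≈ 4.0, STD ≈ 11.0 normalized-EMG·ms (see
`reflexmri.experiment.ranking_study`).

## Command line

```bash
reflexmri simulate -c run.yaml -o out/   # recordings + BOLD phantom + truth
reflexmri emg      -c run.yaml -o out/   # H tables for STD / SUB / ANC
reflexmri validate -c run.yaml -t out/llr_all.tsv -o out/   # agreement report
reflexmri glm      -c run.yaml -o out/   # t-maps, thresholding, Dice/ICC
```

All stages draw their randomness from one root seed through named
substreams and write provenance manifests, so reruns are byte-identical.

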