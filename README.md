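# tcrstrong

Tools for quantifying T cell receptor (TCR) signal strength and for testing
whether a strong-TCR-signal gene signature stratifies patient outcomes under
anti-PD1 immune checkpoint blockade.

The package has two halves:

* **Reporter side (mouse).** A simulator of fluorescent *Timer* reporter
  kinetics. A Timer protein is translated in a blue form and matures
  irreversibly into a long-lived red form, so a T cell's position in
  blue–red space encodes the history of its NFAT-driven TCR signaling:

  ```
  dB/dt = s(t) − λ_B·B          λ_B = ln2 / 4 h   (blue half-life)
  dR/dt = λ_B·B − λ_R·R         λ_R = ln2 / 120 h (red half-life)
  ```

  with `s(t)` the transcription rate while a cell is actively signaling.
  Cells are quadrant-gated into signal loci — *new* (Blue⁺Red⁻),
  *persistent* (Blue⁺Red⁺), *arrested* (Blue⁻Red⁺) — and summarized by the
  Timer angle θ = atan2(red, blue) ∈ [0°, 90°]. Activation is digital: dose
  sets the *probability* that a cell activates (a Hill function), while
  every activated cell follows identical kinetics. Dose/re-challenge
  protocols include activation-threshold recalibration by the priming dose
  and checkpoint-blockade multipliers that lower the re-activation
  threshold and strengthen the re-activation signal.

* **Patient side (human).** Geometric-mean gene-signature scores on
  expression data, the four-way differential-expression intersection that
  derives the **TCR.strong** signature (*TNFRSF4, ICOS, IRF8, TNIP3,
  STAT4*), and survival stratification. FPKM is converted to TPM by column
  normalization (×10⁶) plus a 0.01 offset, counts to CPM likewise; the
  score is `exp(mean(ln TPM))` over the signature genes. On-therapy scores
  are split at the cohort median into High/Low, compared by Mann-Whitney U
  between responders (CR/PR/SD) and non-responders (PD), and the strata
  compared by Kaplan-Meier curves with a Mantel-Cox log-rank test. A
  seeded synthetic-cohort generator produces paired pre/on expression with
  responder-specific signature lifts and exponential survival whose
  log-hazard is linear in the standardized log score.

## Worked example

```python
from tcrstrong import (SynthCohortConfig, mannwhitney_u, stratified_survival)
from tcrstrong.cohort_synth import generate_cohort

cohort = generate_cohort(SynthCohortConfig(beta=-0.5), seed=1)
scores = cohort["scores_on"]                      # on-therapy TCR.strong
resp = cohort["truth"].set_index("patient_id")["is_responder"]
mw = mannwhitney_u(scores[resp.reindex(scores.index)],
                   scores[~resp.reindex(scores.index)])
print(f"U={mw.statistic:.0f}, p={mw.p_two_sided:.2e}")
res = stratified_survival(cohort["metadata"], scores, endpoint="PFS")
print(res.summary().to_string(index=False))
print(f"log-rank chi2={res.logrank.statistic:.2f}, p={res.logrank.p_two_sided:.4f}")
```

prints

```
U=625, p=1.33e-09
stratum  n  median_survival
   High 25       291.556044
    Low 25       107.630309
log-rank chi2=12.72, p=0.0004
```

i.e. with a one-log2-unit responder lift of the signature genes and a
protective hazard slope (β = −0.5 per SD of log score), responders'
on-therapy TCR.strong scores separate cleanly from non-responders', and the
score-High half of the cohort progresses markedly later than the score-Low
half (median progression-free survival 292 vs 108 days).

On the reporter side, a strong (80 µg) priming dose arrests most cells
against an 8 µg re-challenge:

```python
from tcrstrong import StimulationProtocol, TimerKinetics, simulate_flow_sample, rechallenge_summary
prot = StimulationProtocol(doses=((0.0, 80.0), (24.0, 8.0)))
ev = simulate_flow_sample(3000, prot, TimerKinetics(), t_obs_h=28.0, seed=1)
print(rechallenge_summary(ev))
# {'responders': 0.078, 'arrested_nonresponders': 0.876, 'active': 0.119}
```

## Command line

The same stages are exposed as a CLI driven by a YAML config; each command
writes TSV/CSV/JSON outputs plus a manifest recording the seed and input
checksums:

```sh
tcrstrong simulate-timer  -c config.yaml -o out/timer
tcrstrong synth-cohort    -c config.yaml -o out/cohort
tcrstrong score           -c config.yaml -o out/scores --expression out/cohort/expression_on.tsv --unit FPKM
tcrstrong derive-signature -c config.yaml -o out/derived
tcrstrong stratify        -c config.yaml -o out/strat --scores out/scores/scores.tsv --metadata out/cohort/metadata.tsv
tcrstrong report out/timer out/strat -o out/report.json
```

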