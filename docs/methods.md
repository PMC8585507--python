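# Methods

## Timer reporter kinetics

The fluorescent Timer reporter is modelled as a linear two-compartment
system. Blue protein is produced at rate `s(t)` (a.u./h) while a cell's
NFAT–reporter pathway is transcribing and matures into red with rate
constant λ_B = ln2 / `blue_half_life_h`; red decays with
λ_R = ln2 / `red_half_life_h`:

```
dB/dt = s(t) − λ_B·B,   dR/dt = λ_B·B − λ_R·R,   B(0) = R(0) = 0.
```

**All blue loss is maturation into red** — there is no separate immature-
protein degradation channel. One parameter then reproduces the 4 h blue
half-life while keeping the model identifiable, and total protein is
conserved when red decay is switched off (`red_half_life_h = inf` is
supported for that check). Defaults: blue 4 h, red 120 h, transcription
rate 100 a.u./h.

The solver advances the exact piecewise closed form across segments of
constant `s`; numerical error is rounding-level, and the test suite checks
it against an independent fourth-order Runge-Kutta integration at step
0.01 h. Degenerate limits (λ_R = 0, λ_R → λ_B) use their analytic limits.

## Digital activation and stimulation protocols

Antigen dose controls the *probability* of activation, not the kinetics of
activated cells: each cell activates per dose as an independent Bernoulli
draw with the Hill probability `p = d^n / (d^n + EC50_eff^n)` (defaults
EC50 = 8 µg, n = 1, chosen so the 0.8 / 8 / 80 µg dose ladder spans
activation probabilities ≈ 0.1 / 0.5 / 0.9). Every activated cell turns
transcription on for `signal_duration_h` (default 6 h — short enough that
active, Blue⁺ signaling has decayed to near-zero 24 h after a single dose
while matured red persists).

Re-challenge doses see an effective EC50 of
`EC50 × (1 + κ·priming_dose/EC50) × blockade_ec50_mult` for cells that
activated at priming, with κ = 1 by default and the fold reset to 1 when
the re-challenge comes more than 72 h after priming. The linear-in-dose,
reversible form is this package's own parameterization: the threshold
shift is dose-dependent and decays with time, but no mechanistic equation
is imposed. Checkpoint blockade enters as two knobs applied to
re-challenge stimulation only: `blockade_ec50_mult ≤ 1` (lowered
activation threshold → more responders) and `blockade_rate_mult ≥ 1`
(stronger transcription in re-activated cells → higher blue).

## Measurement model and Tocky quantification

Measured fluorescence is `raw × LogNormal(cv)` (mean-one multiplicative
noise with coefficient of variation `noise_cv`) plus additive Gaussian
background truncated at zero. The background SD is tied to the same knob
(`noise_cv × background mean`): with `noise_cv = 0` the whole measurement
is deterministic, and whenever any noise is present the unstimulated
controls have the nonzero variance the normalization needs. Default
`noise_cv` = 0.05, backgrounds 2 a.u.

Channel normalization subtracts the control mean, scales by the 99th
percentile of the Timer-positive events' subtracted values, multiplies by
100 and clips to [0, 100]. The scale is computed within the Timer-positive
population (not per-channel positives) so that a channel whose signal sits
near its gate is not normalized by a handful of tail events.
Timer-positivity defaults to exceeding control mean + 3 SD on either
channel. These constants are this package's choices; the original
Timer-angle algorithm's constants live in prior work and are not restated
here.

Signal loci are quadrant gates on raw fluorescence. In
`simulate_flow_sample` the default gates sit at 10 % of the blue plateau
(s/λ_B) and 20 % of the total red yield (s × signal duration) above
background; at these gates an activated cell reads *new* at 4 h,
*persistent* while transcription is on and red has matured, and *arrested*
once blue has decayed — with positivity at background + 3 SD every cell
with trace matured red would read Red⁺ and the locus trajectory would
collapse. The Timer angle is `atan2(red_norm, blue_norm)` in degrees,
undefined (error) when both normalized channels are zero; the mean angle
is an arithmetic mean over Timer-positive events.

Per-cell random streams are derived from `(seed, stream, cell_index)`
via numpy's seed-sequence mechanism, so enlarging a sample never
reshuffles the cells already drawn. Because the per-sample 99th-percentile
scale depends on sample composition, *normalized* values may shift when
cells are added; raw values, gating and loci do not.

What the simulator does not emulate: instrument spillover/compensation,
cell-to-cell kinetic heterogeneity (the digital rule is exact by
construction), co-reporters, TCR-affinity effects, and FCS binary files
(events are plain CSV).

## Expression units and signature scores

FPKM → TPM divides each gene's FPKM by the sample's total FPKM, multiplies
by 10⁶, **then** adds the 0.01 offset; counts → CPM likewise. Because the
offset follows the ratio step, scores are exactly invariant to per-sample
rescaling of the input — adding the offset before normalizing would break
this, which is why the order is fixed. Column sums run over all genes
present in the input matrix.

A signature score is the geometric mean `exp(mean(ln x))` of the signature
genes' TPM/CPM values (natural log internally; any base is equivalent).
Built-ins: TCR.strong = {TNFRSF4, ICOS, IRF8, TNIP3, STAT4} and
T.activation = {NR4A1, CD69, IL2RA, TNFRSF9}, with CD25 treated as an
alias of the canonical symbol IL2RA. Missing signature genes are a hard
error; `allow_missing=True` opts in to scoring the intersection for
datasets where a gene is undetectable.

## Signature derivation

DEG sets are thresholded with strict inequalities (`log2fc > lfc_min`,
`padj < padj_max`; boundary values excluded). Presets: human contrasts
0.5 / 0.1; the mouse strong-vs-weak 4 h contrast 1 / 0.05; the mouse
anti-PD1 contrast padj < 0.05 only. Only up-regulated sets feed the
classifier; down-thresholds exist but are unused in derivation.

Mouse symbols map to human through a static table (explicit overrides
plus title-case → uppercase); Riken/Gm-style identifiers are reported as
unmapped rather than silently dropped. A static table was chosen over a
live ortholog query for reproducibility.

Every gene in the responder set is labelled by its membership pattern in
the other three sets (groups I–VI; genes outside the responder set are
always unassigned, and every gene gets exactly one label). The derived
signature is the union of groups I and II, sorted; an empty union is an
error pointing at the thresholds.

## Survival statistics

Responder = CR/PR/SD, non-responder = PD, NE/missing excluded from all
patient analyses (the pipeline lists exclusions in its manifest).
Median-split uses the midpoint-of-order-statistics median; scores strictly
above the median are High, ties go Low (configurable via `high_rule`,
and a precomputed whole-cohort median can be reused for subgroup curves —
the default for subgroups is reuse). Stratification uses on-therapy
scores only; pre-therapy records contribute only to the paired
pre/on change analysis.

Kaplan-Meier estimation and the Mantel-Cox log-rank test (two-sided via
χ² with 1 df) are computed with lifelines; the tests check them against a
hand product-limit computation, hand Mantel-Cox arithmetic and a
label-permutation reference. Mann-Whitney U gives 0.5 credit for ties and
switches between an exact-enumeration p (min(n, m) ≤ 8 and tie-free — the
regime of the small patient subgroups this pipeline targets) and a
tie-corrected normal approximation. The approximation deliberately omits
the continuity correction so identical samples give exactly p = 1.

## Synthetic cohorts

Expression is log-normal: per-gene baseline log2 FPKM ~
Normal(4, 2), per-observation Normal(0, 0.25) noise, 1,000 background
genes plus the nine signature/comparator genes. On-therapy responders
receive +1 log2 unit on the five TCR.strong genes; the T-activation genes
carry a separate, default-zero effect so the "TCR.strong separates but
T activation does not" scenario holds by construction. No count-level
simulation is attempted since the scored pipeline consumes FPKM/CPM, and
no attempt is made to match real cohorts' gene-level means or dispersions.
Cohort sizes default to 25 responders / 25 non-responders with a 40/60
ipilimumab-naive / ipilimumab-progressed mix, the scale of published
anti-PD1 melanoma cohorts. The effect size is a calibration choice, not
an estimate — the source cohorts report test results, not effect sizes.

Survival is exponential for analytic transparency:
`h_i = h0 · exp(β·z_i)` with `z_i` the standardized ln score,
`h0 = ln2 / 180 days`, administrative censoring at 1,095 days, and
β = −0.5 per SD by default (protective). PFS and OS are independent draws
from the same hazard.

DEG fixture tables place member genes strictly inside each contrast's
inclusion region and non-members strictly outside, with a 0.05 margin on
every threshold, so thresholding round-trips the memberships exactly. The
margin is infeasible for the mouse anti-PD1 preset (padj < 0.05 leaves no
room for a 0.05 padj margin) — that raises `MarginError`; the synthetic
four-contrast fixtures therefore default to the human preset everywhere.

## Problem sizes and determinism

All randomness flows from one master seed; generators are numpy
`default_rng` with derived seed sequences, and identical (config, seed)
give byte-identical outputs. The validation suite uses: 5,000 cells per
flow sample for the dose-invariance check (Monte-Carlo error well under
1°), 1,000 null cohorts of 25 patients/arm for log-rank calibration
(±2 % band around 5 %), 100 random membership patterns for DEG round
trips, 150-patient cohorts for hazard-sign recovery, and full enumeration
(≤ C(16,8) assignments) for the Mann-Whitney exact path.

## Known limitations

* The reporter model is deterministic per activation pattern; real cells
  show kinetic heterogeneity, so population variance here comes only from
  measurement noise and the digital activation draw.
* Normalized channels are a per-sample statistic; cross-sample angle
  comparisons assume comparable sample composition.
* The recalibration fold is a phenomenological stand-in with an assumed
  linear dose dependence and a hard 72 h reset.
* The synthetic cohorts cannot validate gene-level realism (dispersion,
  correlation structure, tumor purity); passing tests demonstrate the
  statistical machinery, not biological effect sizes.
* No Cox modelling, no multiple-testing correction across endpoints, no
  enrichment analysis, no differential-expression estimation — DEG tables
  are consumed, not fitted.
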