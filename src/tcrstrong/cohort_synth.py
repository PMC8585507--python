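"""Synthetic patient cohorts for the human-side scoring/survival pipeline.

Emulates the statistical structure of paired pre-/on-therapy melanoma
biopsy cohorts under anti-PD1 therapy: log-normal FPKM expression, a
responder-specific on-therapy lift of the TCR.strong signature genes (with
an independent, default-zero lift of the T-activation genes so the
"TCR.strong separates but T activation does not" scenario holds by
construction), and exponential progression-free / overall survival whose
log-hazard is linear in the standardized log signature score.  DEG fixture
tables with prescribed four-set memberships feed the signature-derivation
classifier.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scoring import ExpressionMatrix, TCR_STRONG, T_ACTIVATION, fpkm_to_tpm, signature_score
from .signature_sets import DEGThresholds, HUMAN_PRESET

__all__ = [
    "SynthCohortConfig",
    "generate_expression",
    "generate_survival",
    "generate_cohort",
    "generate_deg_tables",
    "MarginError",
    "CONTRASTS",
]

CONTRASTS = ("res", "ot", "strong4h", "pd1")

LN2 = np.log(2.0)


class MarginError(ValueError):
    """The requested DEG margin is infeasible for the given thresholds."""


@dataclass(frozen=True)
class SynthCohortConfig:
    """Generating conditions for one synthetic cohort.

    Sizes default to the scale of published anti-PD1 melanoma cohorts
    (tens of patients per response arm, roughly balanced ipilimumab-naive /
    ipilimumab-progressed subgroups).  The on-therapy responder lift of one
    log2 unit doubles the TCR.strong score; survival is exponential with a
    protective log-hazard slope per SD of log score.
    """

    n_responders: int = 25
    n_nonresponders: int = 25
    cohort_labels: tuple[str, ...] = ("ipi_naive", "ipi_progressed")
    cohort_proportions: tuple[float, ...] = (0.4, 0.6)
    n_background_genes: int = 1000
    baseline_log2_fpkm_mean: float = 4.0
    baseline_log2_fpkm_sd: float = 2.0
    signature_effect_log2fc: float = 1.0
    t_activation_effect_log2fc: float = 0.0
    noise_sd: float = 0.25
    baseline_median_survival_days: float = 180.0
    beta: float = -0.5
    censor_days: float = 1095.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("each response arm needs at least one patient")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.baseline_log2_fpkm_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.censor_days > 0:
            raise ValueError("censor_days must be > 0")
        if len(self.cohort_labels) != len(self.cohort_proportions):
            raise ValueError("cohort labels and proportions must align")
        if abs(sum(self.cohort_proportions) - 1.0) > 1e-9:
            raise ValueError("cohort proportions must sum to 1")


def _gene_symbols(config: SynthCohortConfig) -> list[str]:
    signature = list(TCR_STRONG.genes) + list(T_ACTIVATION.genes)
    background = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    clash = set(signature) & set(background)
    if clash:
        raise ValueError(f"background symbols collide with signature genes: {clash}")
    return signature + background


def generate_expression(
    config: SynthCohortConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate paired pre/on FPKM matrices, patient metadata and truth.

    Per gene, a baseline log2 FPKM level is drawn from
    Normal(baseline_log2_fpkm_mean, baseline_log2_fpkm_sd); each
    observation adds Normal(0, noise_sd) noise, and on-therapy responders
    add ``signature_effect_log2fc`` on the five TCR.strong genes (and the
    separate T-activation effect on its four genes).

    Returns (pre matrix, on matrix, metadata, truth).  Metadata has one row
    per patient per timepoint (patient_id, cohort, timepoint, bor, and
    empty survival columns to be filled by :func:`generate_survival`).
    """
    rng = np.random.default_rng(config.seed if seed is None else int(seed))
    genes = _gene_symbols(config)
    n_pat = config.n_responders + config.n_nonresponders
    patients = [f"P{i:04d}" for i in range(1, n_pat + 1)]
    responder = np.array([True] * config.n_responders + [False] * config.n_nonresponders)

    cohorts = rng.choice(
        config.cohort_labels, size=n_pat, p=np.asarray(config.cohort_proportions)
    )
    # best overall response codes within each arm
    bor = np.where(
        responder,
        rng.choice(["CR", "PR", "SD"], size=n_pat, p=[0.15, 0.5, 0.35]),
        "PD",
    )

    base = rng.normal(
        config.baseline_log2_fpkm_mean, config.baseline_log2_fpkm_sd, size=len(genes)
    )
    sig_idx = np.array([g in TCR_STRONG.genes for g in genes])
    act_idx = np.array([g in T_ACTIVATION.genes for g in genes])

    def _draw(timepoint: str) -> pd.DataFrame:
        log2 = (
            base[:, None]
            + rng.normal(0.0, config.noise_sd, size=(len(genes), n_pat))
        )
        if timepoint == "on":
            lift = np.zeros((len(genes), n_pat))
            lift[np.ix_(sig_idx, responder)] = config.signature_effect_log2fc
            lift[np.ix_(act_idx, responder)] += config.t_activation_effect_log2fc
            log2 = log2 + lift
        cols = [f"{p}_{timepoint}" for p in patients]
        return pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"), columns=cols)

    pre = ExpressionMatrix(_draw("pre"), "FPKM")
    on = ExpressionMatrix(_draw("on"), "FPKM")

    meta = pd.DataFrame(
        [
            {
                "patient_id": p,
                "cohort": c,
                "timepoint": tp,
                "bor": b,
                "pfs_days": np.nan,
                "pfs_event": pd.NA,
                "os_days": np.nan,
                "os_event": pd.NA,
            }
            for p, c, b in zip(patients, cohorts, bor)
            for tp in ("pre", "on")
        ]
    )
    truth = pd.DataFrame(
        {
            "patient_id": patients,
            "is_responder": responder,
            "signature_lift_log2": np.where(responder, config.signature_effect_log2fc, 0.0),
        }
    )
    return pre, on, meta, truth


def generate_survival(
    config: SynthCohortConfig, scores: pd.Series, seed: int | None = None
) -> pd.DataFrame:
    """Draw PFS/OS outcomes with log-hazard linear in the log score.

    h_i = h0 * exp(beta * z_i) with z_i the standardized ln(score) and
    h0 = ln 2 / baseline_median_survival_days; event times are exponential
    with administrative censoring at ``censor_days``.  Negative beta makes
    a high score protective.
    """
    sc = scores.astype(float)
    if not np.all(np.isfinite(sc)) or np.any(sc <= 0):
        raise ValueError("scores must be finite and positive")
    rng = np.random.default_rng(config.seed + 1 if seed is None else int(seed))
    ln = np.log(sc.to_numpy())
    sd = ln.std(ddof=0)
    z = (ln - ln.mean()) / sd if sd > 0 else np.zeros_like(ln)
    h0 = LN2 / config.baseline_median_survival_days
    hazard = h0 * np.exp(config.beta * z)
    out = {"patient_id": list(sc.index), "true_hazard": hazard}
    for ep in ("pfs", "os"):
        t = rng.exponential(1.0 / hazard)
        event = t <= config.censor_days
        out[f"{ep}_days"] = np.minimum(t, config.censor_days)
        out[f"{ep}_event"] = event
    return pd.DataFrame(out)


def generate_cohort(
    config: SynthCohortConfig, seed: int | None = None
) -> dict[str, object]:
    """Full cohort: expression -> TPM -> scores -> survival -> metadata.

    Convenience composition used by the pipeline and the validation runs.
    Survival is linked to the on-therapy TCR.strong score.  Returns a dict
    with keys ``pre``, ``on`` (FPKM matrices), ``metadata`` (PatientRecord
    rows with survival filled in and per-timepoint scores), ``scores_on``,
    ``scores_pre`` (Series by patient) and ``truth``.
    """
    seed = config.seed if seed is None else int(seed)
    pre, on, meta, truth = generate_expression(config, seed)

    def _scores(m: ExpressionMatrix, suffix: str) -> pd.Series:
        tab = signature_score(fpkm_to_tpm(m), TCR_STRONG)
        idx = [s.removesuffix(f"_{suffix}") for s in tab["sample_id"]]
        return pd.Series(tab["score"].to_numpy(), index=idx, name="score")

    scores_pre = _scores(pre, "pre")
    scores_on = _scores(on, "on")
    surv = generate_survival(config, scores_on, seed + 1).set_index("patient_id")

    meta = meta.copy()
    for col in ("pfs_days", "os_days"):
        meta[col] = meta["patient_id"].map(surv[col]).astype(float)
    for col in ("pfs_event", "os_event"):
        meta[col] = meta["patient_id"].map(surv[col]).astype(bool)
    meta["score"] = np.where(
        meta["timepoint"] == "pre",
        meta["patient_id"].map(scores_pre),
        meta["patient_id"].map(scores_on),
    )
    truth = truth.merge(
        surv["true_hazard"].rename("true_hazard"), left_on="patient_id", right_index=True
    )
    return {
        "pre": pre,
        "on": on,
        "metadata": meta,
        "scores_pre": scores_pre,
        "scores_on": scores_on,
        "truth": truth,
    }


def generate_deg_tables(
    memberships: dict[str, set[str]],
    thresholds: dict[str, DEGThresholds] | None = None,
    seed: int = 0,
    margin: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Emit four DEG tables realising prescribed set memberships.

    ``memberships`` maps gene -> subset of {'res', 'ot', 'strong4h',
    'pd1'}.  Member genes receive (log2fc, padj) strictly inside each
    contrast's inclusion region with at least ``margin`` to spare on every
    threshold; non-members land strictly outside on both axes.  Thresholding
    the emitted tables therefore round-trips the memberships exactly.

    Raises :class:`MarginError` when a contrast's padj threshold cannot
    accommodate the margin (padj_max <= margin).
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    thresholds = dict(thresholds or {})
    for c in CONTRASTS:
        thresholds.setdefault(c, HUMAN_PRESET)
    bad = [c for c in memberships.values() if not c <= set(CONTRASTS)]
    if bad:
        raise ValueError(f"unknown contrast names in memberships: {bad}")
    rng = np.random.default_rng(seed)
    genes = sorted(memberships)
    tables: dict[str, pd.DataFrame] = {}
    for contrast in CONTRASTS:
        thr = thresholds[contrast]
        if thr.padj_max <= margin:
            raise MarginError(
                f"margin {margin} infeasible for contrast {contrast!r} "
                f"(padj_max = {thr.padj_max})"
            )
        rows = []
        for g in genes:
            member = contrast in memberships[g]
            if member:
                lfc = thr.lfc_min + margin + rng.uniform(0.0, 1.0)
                padj = rng.uniform(0.0, thr.padj_max - margin)
            else:
                lfc = thr.lfc_min - margin - rng.uniform(0.0, 1.0)
                padj = rng.uniform(
                    min(1.0, thr.padj_max + margin), 1.0
                )
            rows.append({"gene": g, "log2fc": lfc, "padj": padj})
        tables[contrast] = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])
    return tables
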