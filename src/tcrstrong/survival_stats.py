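"""Response classification, median-split stratification and survival tests.

Patients are classified from best overall response (CR/PR/SD -> responder,
PD -> non-responder, NE or missing -> excluded), signature scores are split
at the cohort median into "High" (> median) and "Low" (<= median) strata,
and the strata are compared with the Kaplan-Meier product-limit estimator
and the Mantel-Cox log-rank test.  Score distributions between groups are
compared with the Mann-Whitney U test (exact enumeration for small
tie-free samples, tie-corrected normal approximation otherwise), and paired
pre-/on-therapy score changes are summarised per response group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "TestResult",
    "KMCurve",
    "classify_response",
    "median_split",
    "km_estimate",
    "logrank_test",
    "mannwhitney_u",
    "paired_change",
    "PairedChange",
    "stratified_survival",
    "StratifiedSurvival",
]

RESPONDER_CODES = {"CR", "PR", "SD"}
NONRESPONDER_CODES = {"PD"}
EXCLUDED_CODES = {"NE", "missing", ""}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_sided <= 1:
            raise ValueError("p value must lie in [0, 1]")


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve: S(t) = prod_{t_j <= t} (1 - d_j/n_j)."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_risk: np.ndarray  # number at risk just before each event time

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(s < 0) or np.any(s > 1) or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival must be non-increasing within [0, 1]")

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self, group: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.times, "survival": self.survival, "n_risk": self.n_risk}
        )
        if group is not None:
            df.insert(0, "group", group)
        return df


def classify_response(bor: str) -> str:
    """Map best-overall-response codes to responder / nonresponder / excluded."""
    code = "missing" if bor is None or (isinstance(bor, float) and np.isnan(bor)) else str(bor)
    if code in RESPONDER_CODES:
        return "responder"
    if code in NONRESPONDER_CODES:
        return "nonresponder"
    if code in EXCLUDED_CODES:
        return "excluded"
    raise ValueError(f"unknown best-overall-response code: {bor!r}")


def median_split(
    scores: pd.Series,
    median: float | None = None,
    high_rule: str = "strict",
) -> tuple[pd.Series, float]:
    """Split scores at the median into High / Low labels.

    The median is the midpoint of the order statistics (mean of the middle
    two for even n).  With the default tie rule, score > median -> High and
    score <= median -> Low; ``high_rule='inclusive'`` puts ties High
    instead.  A precomputed ``median`` (e.g. a whole-cohort median reused
    for a subgroup) may be supplied.

    Returns (labels, median used).
    """
    if len(scores) < 2 and median is None:
        raise ValueError("need at least two scores to median-split")
    if high_rule not in ("strict", "inclusive"):
        raise ValueError("high_rule must be 'strict' or 'inclusive'")
    med = float(np.median(scores.to_numpy(dtype=float))) if median is None else float(median)
    if high_rule == "strict":
        high = scores > med
    else:
        high = scores >= med
    labels = pd.Series(np.where(high, "High", "Low"), index=scores.index, name="stratum")
    if scores.nunique() == 1 and median is None:
        warnings.warn("all scores identical; every sample labelled Low", stacklevel=2)
    return labels, med


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate from event/censoring times and event flags."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    times_out = ev.index.to_numpy(dtype=float)
    return KMCurve(
        times=times_out,
        survival=np.array([float(surv.loc[x]) for x in ev.index]),
        n_risk=ev["at_risk"].to_numpy(dtype=float),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-sided Mantel-Cox log-rank test (chi-square, 1 df)."""
    ta, tb = np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float)
    ea, eb = np.asarray(events_a, dtype=bool), np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if int(ea.sum()) + int(eb.sum()) == 0:
        raise ValueError("log-rank test undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(
        statistic=float(res.test_statistic),
        p_two_sided=float(res.p_value),
        n_a=int(ta.size),
        n_b=int(tb.size),
    )


def mannwhitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test with the cohort-scale switching rule.

    U counts wins of ``a`` over ``b`` with 0.5 credit for ties
    (U_a + U_b = n*m).  The p value is by exact enumeration when
    min(n, m) <= 8 and the pooled data are tie-free, and by the
    tie-corrected normal approximation otherwise (no continuity
    correction, so identical samples give exactly p = 1).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # fully tied data: U is exactly nm/2 and the normal statistic is 0/0
        return TestResult(
            statistic=x.size * y.size / 2.0,
            p_two_sided=1.0,
            n_a=int(x.size),
            n_b=int(y.size),
        )
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_two_sided=min(1.0, float(res.pvalue)),
        n_a=int(x.size),
        n_b=int(y.size),
    )


@dataclass(frozen=True)
class PairedChange:
    """Per-patient on-minus-pre score deltas grouped by response status."""

    deltas: pd.DataFrame  # patient_id, response, score_pre, score_on, delta
    summary: pd.DataFrame  # response -> n, mean_delta, se_delta
    unmatched: tuple[str, ...]  # patients lacking one of the two timepoints


def paired_change(records: pd.DataFrame) -> PairedChange:
    """Compute paired pre/on-therapy score changes per patient.

    ``records`` needs columns patient_id, timepoint ('pre'/'on'), bor and
    score.  Patients without both timepoints are reported in ``unmatched``
    and excluded; duplicate timepoint rows for one patient are an error.
    """
    dup = records.duplicated(subset=["patient_id", "timepoint"])
    if dup.any():
        bad = sorted(records.loc[dup, "patient_id"].unique())
        raise ValueError(f"duplicate timepoint records for patient(s): {bad}")
    wide = records.pivot(index="patient_id", columns="timepoint", values="score")
    for tp in ("pre", "on"):
        if tp not in wide.columns:
            wide[tp] = np.nan
    matched = wide.dropna(subset=["pre", "on"])
    unmatched = tuple(sorted(set(wide.index) - set(matched.index)))
    bor = records.drop_duplicates("patient_id").set_index("patient_id")["bor"]
    deltas = pd.DataFrame(
        {
            "patient_id": matched.index,
            "response": [classify_response(bor.get(p)) for p in matched.index],
            "score_pre": matched["pre"].to_numpy(),
            "score_on": matched["on"].to_numpy(),
            "delta": (matched["on"] - matched["pre"]).to_numpy(),
        }
    ).reset_index(drop=True)
    grp = deltas.groupby("response")["delta"]
    summary = pd.DataFrame(
        {
            "n": grp.size(),
            "mean_delta": grp.mean(),
            "se_delta": grp.sem(ddof=1),
        }
    )
    return PairedChange(deltas=deltas, summary=summary, unmatched=unmatched)


@dataclass(frozen=True)
class StratifiedSurvival:
    """Median-split survival stratification result."""

    endpoint: str
    median: float
    labels: pd.Series  # patient_id -> High/Low
    km_high: KMCurve
    km_low: KMCurve
    logrank: TestResult

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, curve in (("High", self.km_high), ("Low", self.km_low)):
            med = next(
                (float(t) for t, s in zip(curve.times, curve.survival) if s <= 0.5),
                np.nan,
            )
            rows.append(
                {
                    "stratum": name,
                    "n": int((self.labels == name).sum()),
                    "median_survival": med,
                }
            )
        df = pd.DataFrame(rows)
        df.attrs["logrank_p"] = self.logrank.p_two_sided
        return df


def stratified_survival(
    records: pd.DataFrame,
    scores: pd.Series,
    endpoint: str = "PFS",
    median: float | None = None,
    high_rule: str = "strict",
) -> StratifiedSurvival:
    """Median-split on-therapy scores, then KM + log-rank between strata.

    ``records`` holds one row per patient per timepoint with pfs_days /
    pfs_event / os_days / os_event; ``scores`` is indexed by patient_id and
    should be the on-therapy scores (stratification follows the on-therapy
    analysis).  A precomputed whole-cohort ``median`` may be reused for
    subgroup analyses.
    """
    endpoint = endpoint.upper()
    if endpoint not in ("PFS", "OS"):
        raise ValueError("endpoint must be 'PFS' or 'OS'")
    tcol, ecol = endpoint.lower() + "_days", endpoint.lower() + "_event"
    per_patient = (
        records.drop_duplicates("patient_id").set_index("patient_id")[[tcol, ecol]]
    )
    common = scores.index.intersection(per_patient.index)
    if len(common) == 0:
        raise ValueError("no patients shared between scores and survival records")
    sc = scores.loc[common]
    surv = per_patient.loc[common].dropna(subset=[tcol])
    sc = sc.loc[surv.index]
    labels, med = median_split(sc, median=median, high_rule=high_rule)
    hi = labels == "High"
    lo = labels == "Low"
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("median split produced an empty stratum")
    t = surv[tcol].to_numpy(dtype=float)
    e = surv[ecol].to_numpy(dtype=bool)
    return StratifiedSurvival(
        endpoint=endpoint,
        median=med,
        labels=labels,
        km_high=km_estimate(t[hi.to_numpy()], e[hi.to_numpy()]),
        km_low=km_estimate(t[lo.to_numpy()], e[lo.to_numpy()]),
        logrank=logrank_test(t[hi.to_numpy()], e[hi.to_numpy()], t[lo.to_numpy()], e[lo.to_numpy()]),
    )
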