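"""Stage orchestration and file I/O for the TCR signal-strength pipeline.

Each ``run_*`` function executes one stage against a configuration mapping
(typically one block of a YAML config), writes its tabular outputs under an
output directory, and drops a JSON manifest beside them recording the
package version, the master seed, and SHA-256 checksums of every input
file, so every command is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_synth, scoring, signature_sets, survival_stats, timer_dynamics

__all__ = [
    "load_config",
    "run_simulate_timer",
    "run_synth_cohort",
    "run_score",
    "run_derive",
    "run_stratify",
    "collect_report",
]

log = logging.getLogger("tcrstrong")

try:
    _VERSION = version("tcrstrong")
except PackageNotFoundError:  # pragma: no cover - editable-install edge
    _VERSION = "unknown"

SIGNATURES = {
    "TCR.strong": scoring.TCR_STRONG,
    "T.activation": scoring.T_ACTIVATION,
}

DEFAULT_DERIVE_THRESHOLDS = {
    "res": signature_sets.HUMAN_PRESET,
    "ot": signature_sets.HUMAN_PRESET,
    "strong4h": signature_sets.MOUSE_STRONG_PRESET,
    "pd1": signature_sets.MOUSE_PD1_PRESET,
}


def load_config(path) -> dict:
    """Load a YAML pipeline config."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, command: str, seed: int, inputs, outputs, **extra):
    manifest = {
        "command": command,
        "package": "tcrstrong",
        "version": _VERSION,
        "seed": int(seed),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": [str(p) for p in outputs],
        **extra,
    }
    path = outdir / f"{command}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("%s: wrote manifest %s", command, path)
    return manifest


def _outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _get_signature(cfg: dict) -> scoring.GeneSignature:
    sel = cfg.get("signature", "TCR.strong")
    if isinstance(sel, dict):
        return scoring.GeneSignature(
            name=sel.get("name", "custom"),
            genes=tuple(sel["genes"]),
            alias_map=dict(sel.get("alias_map", {})),
        )
    if sel not in SIGNATURES:
        raise ValueError(
            f"unknown signature {sel!r}; choose from {sorted(SIGNATURES)} "
            "or give a custom gene list"
        )
    return SIGNATURES[sel]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate_timer(cfg: dict, outdir, seed: int) -> dict:
    """Simulate Timer flow samples and summarise activity per time point.

    Config keys: ``protocol`` (doses as [time_h, dose_ug] pairs plus Hill /
    recalibration / blockade fields), ``kinetics`` (half-lives, rates,
    noise), ``n_cells`` and ``t_obs_h`` (scalar or list).  Writes one
    flow-event CSV per observation time plus a summary JSON with the
    fraction of cells signaling and the mean Timer angle.
    """
    out = _outdir(outdir)
    try:
        protocol = timer_dynamics.StimulationProtocol(
            doses=tuple(tuple(d) for d in cfg["protocol"]["doses"]),
            **{k: v for k, v in cfg["protocol"].items() if k != "doses"},
        )
        kinetics = timer_dynamics.TimerKinetics(**cfg.get("kinetics", {}))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed simulate-timer config: {exc}") from exc
    n_cells = int(cfg.get("n_cells", 5000))
    t_obs = cfg.get("t_obs_h", 24.0)
    t_obs = [float(t) for t in (t_obs if isinstance(t_obs, (list, tuple)) else [t_obs])]

    summary = []
    outputs = []
    for t in t_obs:
        events = timer_dynamics.simulate_flow_sample(
            n_cells, protocol, kinetics, t, seed=seed
        )
        path = out / f"events_t{t:g}h.csv"
        events.to_csv(path, index=False)
        outputs.append(path)
        frac = timer_dynamics.rechallenge_summary(events)
        tp = events["timer_positive"].astype(bool)
        summary.append(
            {
                "t_obs_h": t,
                "fraction_active": frac["active"],
                "fraction_timer_positive": float(tp.mean()),
                "responders": frac["responders"],
                "arrested_nonresponders": frac["arrested_nonresponders"],
                "mean_timer_angle_deg": (
                    timer_dynamics.mean_timer_angle(events) if tp.any() else None
                ),
            }
        )
    spath = out / "timer_summary.json"
    spath.write_text(json.dumps(summary, indent=2) + "\n")
    outputs.append(spath)
    _write_manifest(out, "simulate-timer", seed, [], outputs)
    return {"summary": summary, "outputs": outputs}


def run_synth_cohort(cfg: dict, outdir, seed: int) -> dict:
    """Generate a synthetic patient cohort and write the pipeline TSVs."""
    out = _outdir(outdir)
    config = cohort_synth.SynthCohortConfig(**{**cfg, "seed": int(seed)})
    cohort = cohort_synth.generate_cohort(config, seed)
    outputs = []
    for key in ("pre", "on"):
        path = out / f"expression_{key}.tsv"
        cohort[key].to_tsv(path)
        outputs.append(path)
    meta_path = out / "metadata.tsv"
    cohort["metadata"].to_csv(meta_path, sep="\t", index=False)
    outputs.append(meta_path)
    truth_path = out / "truth.json"
    truth_path.write_text(
        json.dumps(cohort["truth"].to_dict(orient="records"), indent=2, default=str)
        + "\n"
    )
    outputs.append(truth_path)
    _write_manifest(out, "synth-cohort", seed, [], outputs)
    return {"outputs": outputs, "cohort": cohort}


def run_score(cfg: dict, outdir, seed: int) -> dict:
    """Score an expression matrix: unit transform, then geometric mean.

    FPKM input is TPM-transformed first, counts input CPM-transformed
    first, TPM/CPM input scored directly.
    """
    out = _outdir(outdir)
    expr_path = Path(cfg["expression"])
    unit = cfg.get("unit", "FPKM")
    matrix = scoring.ExpressionMatrix.from_tsv(expr_path, unit)
    if unit == "FPKM":
        matrix = scoring.fpkm_to_tpm(matrix, offset=float(cfg.get("offset", 0.01)))
    elif unit == "counts":
        matrix = scoring.counts_to_cpm(matrix, offset=float(cfg.get("offset", 0.01)))
    signature = _get_signature(cfg)
    table = scoring.signature_score(
        matrix, signature, allow_missing=bool(cfg.get("allow_missing", False))
    )
    spath = out / "scores.tsv"
    table.to_csv(spath, sep="\t", index=False)
    _write_manifest(out, "score", seed, [expr_path], [spath], unit=unit,
                    signature=signature.name)
    return {"scores": table, "outputs": [spath]}


def run_derive(cfg: dict, outdir, seed: int) -> dict:
    """Threshold four DEG tables, map orthologs, classify groups, derive.

    Config keys: ``deg_tables`` mapping contrast name (res, ot, strong4h,
    pd1) to a TSV path; optional per-contrast ``thresholds`` overrides and
    a ``mouse_contrasts`` list (default strong4h and pd1) whose symbols go
    through ortholog mapping.
    """
    out = _outdir(outdir)
    paths = {}
    for contrast in cohort_synth.CONTRASTS:
        try:
            paths[contrast] = Path(cfg["deg_tables"][contrast])
        except KeyError as exc:
            raise ValueError(f"missing DEG table for contrast {contrast!r}") from exc
    thresholds = dict(DEFAULT_DERIVE_THRESHOLDS)
    for contrast, block in (cfg.get("thresholds") or {}).items():
        thresholds[contrast] = signature_sets.DEGThresholds(**block)
    mouse_contrasts = set(cfg.get("mouse_contrasts", ("strong4h", "pd1")))

    sets: dict[str, set[str]] = {}
    unmapped: dict[str, list[str]] = {}
    for contrast, path in paths.items():
        genes = signature_sets.threshold_deg(
            signature_sets.read_deg_tsv(path), thresholds[contrast]
        )
        if contrast in mouse_contrasts:
            result = signature_sets.map_orthologs(genes)
            genes = set(result.mapped)
            unmapped[contrast] = list(result.unmapped)
        sets[contrast] = genes

    assignment = signature_sets.classify_groups(
        sets["res"], sets["ot"], sets["strong4h"], sets["pd1"]
    )
    signature = signature_sets.derive_signature(assignment)

    gpath = out / "groups.tsv"
    assignment.rename("group").to_frame().to_csv(gpath, sep="\t")
    sig_path = out / "signature.txt"
    sig_path.write_text("\n".join(signature.genes) + "\n")
    _write_manifest(
        out, "derive-signature", seed, list(paths.values()), [gpath, sig_path],
        unmapped=unmapped, signature=list(signature.genes),
    )
    return {"assignment": assignment, "signature": signature,
            "outputs": [gpath, sig_path]}


def _split_sample_id(sample: str) -> tuple[str, str]:
    patient, _, timepoint = sample.rpartition("_")
    if timepoint not in ("pre", "on") or not patient:
        raise ValueError(
            f"cannot join sample id {sample!r}: expected '<patient>_<pre|on>'"
        )
    return patient, timepoint


def run_stratify(cfg: dict, outdir, seed: int) -> dict:
    """Median-split stratification with KM curves, tests and paired changes.

    Config keys: ``scores`` (TSV sample_id/signature/score with sample ids
    '<patient>_<pre|on>'), ``metadata`` (patient TSV), ``endpoint`` (PFS or
    OS, default PFS).  NE/missing-response patients are excluded from all
    analyses and listed in the manifest.
    """
    out = _outdir(outdir)
    scores_path = Path(cfg["scores"])
    meta_path = Path(cfg["metadata"])
    endpoint = str(cfg.get("endpoint", "PFS")).upper()
    scores = pd.read_csv(scores_path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t")

    parsed = [_split_sample_id(s) for s in scores["sample_id"]]
    scores["patient_id"] = [p for p, _ in parsed]
    scores["timepoint"] = [t for _, t in parsed]
    known = set(meta["patient_id"])
    missing = sorted(set(scores["patient_id"]) - known)
    if missing:
        raise ValueError(f"score sample ids with no metadata record: {missing}")

    response = {
        p: survival_stats.classify_response(b)
        for p, b in meta.drop_duplicates("patient_id")[["patient_id", "bor"]].values
    }
    excluded = sorted(p for p, r in response.items() if r == "excluded")
    meta = meta[~meta["patient_id"].isin(excluded)].copy()
    scores = scores[~scores["patient_id"].isin(excluded)]

    on_scores = (
        scores[scores["timepoint"] == "on"].set_index("patient_id")["score"]
    )
    result = survival_stats.stratified_survival(
        meta, on_scores, endpoint=endpoint,
        median=cfg.get("median"), high_rule=cfg.get("high_rule", "strict"),
    )

    resp = on_scores[[response[p] == "responder" for p in on_scores.index]]
    nonresp = on_scores[[response[p] == "nonresponder" for p in on_scores.index]]
    mwu = (
        survival_stats.mannwhitney_u(resp, nonresp)
        if len(resp) and len(nonresp)
        else None
    )

    rec = meta[["patient_id", "timepoint", "bor"]].merge(
        scores[["patient_id", "timepoint", "score"]],
        on=["patient_id", "timepoint"], how="inner",
    )
    paired = survival_stats.paired_change(rec) if len(rec) else None

    outputs = []
    for name, curve in (("high", result.km_high), ("low", result.km_low)):
        path = out / f"km_{name}.csv"
        curve.to_frame(group=name.capitalize()).to_csv(path, index=False)
        outputs.append(path)
    tests = {
        "endpoint": endpoint,
        "median_score": result.median,
        "logrank": vars(result.logrank).copy(),
    }
    if mwu is not None:
        tests["mannwhitney_on_therapy"] = vars(mwu).copy()
    tpath = out / "tests.json"
    tpath.write_text(json.dumps(tests, indent=2) + "\n")
    outputs.append(tpath)
    if paired is not None:
        ppath = out / "paired_change.tsv"
        paired.deltas.to_csv(ppath, sep="\t", index=False)
        outputs.append(ppath)
    _write_manifest(
        out, "stratify", seed, [scores_path, meta_path], outputs,
        excluded_patients=excluded,
        unmatched_paired=list(paired.unmatched) if paired is not None else [],
    )
    return {"result": result, "mannwhitney": mwu, "paired": paired,
            "excluded": excluded, "outputs": outputs}


def collect_report(outdirs, report_path) -> dict:
    """Collect every stage manifest under the given directories into one JSON."""
    manifests = []
    for d in outdirs:
        for path in sorted(Path(d).glob("*.manifest.json")):
            manifests.append(json.loads(path.read_text()))
    report = {"n_stages": len(manifests), "stages": manifests}
    Path(report_path).write_text(json.dumps(report, indent=2) + "\n")
    return report
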