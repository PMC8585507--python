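"""Fluorescent-Timer reporter kinetics and Tocky-style quantification.

A fluorescent Timer protein is translated in its blue form and matures
irreversibly into a red form, so the blue:red balance of a cell encodes time
since transcription.  With NFAT-driven transcription ``s(t)`` (active while a
T cell receives TCR signaling, zero otherwise) the two forms follow

    dB/dt = s(t) - lambda_B * B
    dR/dt = lambda_B * B - lambda_R * R

where every blue molecule lost matures into red (``lambda_B = ln 2 / 4 h``)
and red decays slowly (``lambda_R = ln 2 / 120 h``).  Cells are quantified in
blue-red space by quadrant gating into *signal loci* (new = Blue+Red-,
persistent = Blue+Red+, arrested = Blue-Red+) and by the *Timer angle*,
``theta = atan2(red_norm, blue_norm)`` in degrees: 0 deg means a brand-new
signal, 90 deg a signal that stopped long ago.

This module solves the kinetics in closed form, simulates per-cell flow
samples under dose / re-challenge protocols (including activation-threshold
recalibration by the priming dose and checkpoint-blockade multipliers), and
implements channel normalization, locus classification and angle summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimerKinetics",
    "SignalSchedule",
    "StimulationProtocol",
    "solve_timer",
    "activation_probability",
    "simulate_flow_sample",
    "normalize_channels",
    "timer_angle",
    "classify_locus",
    "mean_timer_angle",
    "rechallenge_summary",
    "EVENT_COLUMNS",
]

LN2 = math.log(2.0)

#: column layout of a CellEvent table
EVENT_COLUMNS = (
    "cell_id",
    "blue",
    "red",
    "blue_norm",
    "red_norm",
    "timer_positive",
    "locus",
    "angle_deg",
)

LOCI = ("negative", "new", "persistent", "arrested")


@dataclass(frozen=True)
class TimerKinetics:
    """Maturation/decay parameters of the Timer reporter.

    blue_half_life_h, red_half_life_h
        Protein half-lives in hours (blue 4 h, red 120 h).  The red
        half-life may be ``inf`` to switch red decay off entirely.
    transcription_rate
        Fluorescence production (a.u. per hour) while signaling is active.
    background_blue, background_red
        Mean autofluorescence added to each channel.
    noise_cv
        Coefficient of variation of the multiplicative log-normal
        measurement noise; also sets the background SD
        (``noise_cv * background mean``), so ``noise_cv = 0`` makes the
        measurement fully deterministic.
    """

    blue_half_life_h: float = 4.0
    red_half_life_h: float = 120.0
    transcription_rate: float = 100.0
    background_blue: float = 2.0
    background_red: float = 2.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if not self.blue_half_life_h > 0 or not self.red_half_life_h > 0:
            raise ValueError("half-lives must be positive")
        if not self.blue_half_life_h < self.red_half_life_h:
            raise ValueError("blue half-life must be shorter than red")
        if self.transcription_rate < 0:
            raise ValueError("transcription_rate must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.background_blue < 0 or self.background_red < 0:
            raise ValueError("backgrounds must be >= 0")

    @property
    def lambda_blue(self) -> float:
        return LN2 / self.blue_half_life_h

    @property
    def lambda_red(self) -> float:
        if math.isinf(self.red_half_life_h):
            return 0.0
        return LN2 / self.red_half_life_h


@dataclass(frozen=True)
class SignalSchedule:
    """Ordered, non-overlapping (t_start_h, t_end_h) transcription windows."""

    intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", iv)
        last_end = -math.inf
        for a, b in iv:
            if not a < b:
                raise ValueError(f"interval ({a}, {b}) must have t_start < t_end")
            if a < last_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            last_end = b

    def active(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.intervals)

    @staticmethod
    def merge(intervals: Iterable[tuple[float, float]]) -> "SignalSchedule":
        """Build a schedule from possibly-overlapping windows."""
        ivs = sorted((float(a), float(b)) for a, b in intervals)
        merged: list[list[float]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return SignalSchedule(tuple((a, b) for a, b in merged))


@dataclass(frozen=True)
class StimulationProtocol:
    """Immunization / re-challenge protocol for one flow sample.

    doses
        Ordered (time_h, dose_ug) pairs; the first dose is the priming
        dose, later doses are re-challenges.
    ec50_ug, hill_n
        Hill parameters of the per-cell activation probability.
    signal_duration_h
        How long transcription stays on once a cell activates.
    recalibration_kappa, recalibration_reset_h
        Re-challenge activation threshold recalibration: the effective EC50
        at a re-challenge is multiplied by
        ``1 + kappa * priming_dose / ec50`` when the cell activated at
        priming and the re-challenge comes within ``recalibration_reset_h``
        of priming (the threshold shift is reversible).
    blockade_ec50_mult, blockade_rate_mult
        Checkpoint-blockade knobs applied to re-challenge doses only:
        the EC50 multiplier (< 1 lowers the activation threshold, isotype
        control = 1) and the transcription-rate multiplier (> 1 makes the
        re-activation signal quantitatively stronger).
    """

    doses: tuple[tuple[float, float], ...]
    ec50_ug: float = 8.0
    hill_n: float = 1.0
    signal_duration_h: float = 6.0
    recalibration_kappa: float = 1.0
    recalibration_reset_h: float = 72.0
    blockade_ec50_mult: float = 1.0
    blockade_rate_mult: float = 1.0

    def __post_init__(self) -> None:
        dz = tuple((float(t), float(d)) for t, d in self.doses)
        object.__setattr__(self, "doses", dz)
        times = [t for t, _ in dz]
        if times != sorted(times):
            raise ValueError("doses must be sorted by time")
        if any(d < 0 for _, d in dz):
            raise ValueError("doses must be >= 0")
        if not self.ec50_ug > 0:
            raise ValueError("ec50_ug must be > 0")
        if not self.hill_n > 0:
            raise ValueError("hill_n must be > 0")
        if not self.signal_duration_h > 0:
            raise ValueError("signal_duration_h must be > 0")
        if self.recalibration_kappa < 0:
            raise ValueError("recalibration_kappa must be >= 0")
        if not 0 < self.blockade_ec50_mult <= 1:
            raise ValueError("blockade_ec50_mult must be in (0, 1]")
        if self.blockade_rate_mult < 1:
            raise ValueError("blockade_rate_mult must be >= 1")

    def recalibration_fold(self, priming_dose_ug: float, elapsed_h: float) -> float:
        """EC50 fold-shift at a re-challenge ``elapsed_h`` after priming."""
        if elapsed_h > self.recalibration_reset_h:
            return 1.0
        return 1.0 + self.recalibration_kappa * priming_dose_ug / self.ec50_ug


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _advance(B0: float, R0: float, s: float, lb: float, lr: float, dt: float):
    """Advance (B, R) across a segment of constant transcription rate s.

    Closed-form solution of the linear two-compartment system; handles
    lr == 0 (no red decay) and the lr == lb degenerate limit.
    """
    if dt == 0.0:
        return B0, R0
    bss = s / lb
    c = B0 - bss
    eb = math.exp(-lb * dt)
    B = bss + c * eb
    if lr == 0.0:
        # R' = lb * B : integrate directly
        R = R0 + s * dt + c * (1.0 - eb)
    elif abs(lr - lb) < 1e-12 * lb:
        er = math.exp(-lr * dt)
        R = R0 * er + s * (1.0 - er) / lr + lb * c * dt * er
    else:
        er = math.exp(-lr * dt)
        R = R0 * er + s * (1.0 - er) / lr + lb * c * (eb - er) / (lr - lb)
    return B, R


def _solve_segments(
    kinetics: TimerKinetics,
    segments: Sequence[tuple[float, float, float]],
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the Timer ODEs for piecewise-constant rate ``segments``.

    segments are (t_start, t_end, rate) with rate zero elsewhere; times must
    be ascending and nonnegative.  Returns (blue, red) arrays, B(0)=R(0)=0.
    """
    lb = kinetics.lambda_blue
    lr = kinetics.lambda_red
    edges = sorted({0.0, *(a for a, _, _ in segments), *(b for _, b, _ in segments),
                    *(float(t) for t in times)})

    def rate_at(t: float) -> float:
        for a, b, r in segments:
            if a <= t < b:
                return r
        return 0.0

    want = {float(t) for t in times}
    out_b: dict[float, float] = {}
    out_r: dict[float, float] = {}
    B = R = 0.0
    prev = 0.0
    if prev in want:
        out_b[prev], out_r[prev] = B, R
    for t in edges:
        if t <= prev:
            continue
        mid = 0.5 * (prev + t)
        B, R = _advance(B, R, rate_at(mid), lb, lr, t - prev)
        prev = t
        if t in want:
            out_b[t], out_r[t] = B, R
    blue = np.array([out_b[float(t)] for t in times])
    red = np.array([out_r[float(t)] for t in times])
    return blue, red


def solve_timer(
    kinetics: TimerKinetics,
    schedule: SignalSchedule,
    times: Sequence[float],
) -> pd.DataFrame:
    """Solve the blue/red Timer kinetics at the requested times.

    Returns a DataFrame with columns ``time_h``, ``blue``, ``red``; initial
    condition B(0) = R(0) = 0.  Uses the exact piecewise closed form.
    """
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("times must be nonempty")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    segs = [(a, b, kinetics.transcription_rate) for a, b in schedule.intervals]
    blue, red = _solve_segments(kinetics, segs, t)
    return pd.DataFrame({"time_h": t, "blue": blue, "red": red})


def activation_probability(
    dose_ug: float,
    ec50_ug: float,
    hill_n: float = 1.0,
    ec50_multiplier: float = 1.0,
) -> float:
    """Hill-type probability that a cell activates at a given dose.

    p = d^n / (d^n + (ec50 * mult)^n); p(0) = 0 and p is strictly
    increasing in dose.
    """
    if dose_ug < 0:
        raise ValueError("dose must be >= 0")
    half = ec50_ug * ec50_multiplier
    if not half > 0:
        raise ValueError("ec50 * multiplier must be > 0")
    if not hill_n > 0:
        raise ValueError("hill_n must be > 0")
    if dose_ug == 0:
        return 0.0
    dn = dose_ug ** hill_n
    return dn / (dn + half ** hill_n)


# ---------------------------------------------------------------------------
# flow-sample simulation
# ---------------------------------------------------------------------------

def _measure(
    rng: np.random.Generator, value: float, background: float, cv: float
) -> float:
    """Apply multiplicative log-normal noise plus truncated-Gaussian background."""
    if cv > 0:
        sigma = math.sqrt(math.log1p(cv * cv))
        value = value * rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)
        background = max(0.0, rng.normal(background, cv * background))
    return value + background


def simulate_flow_sample(
    n_cells: int,
    protocol: StimulationProtocol,
    kinetics: TimerKinetics,
    t_obs_h: float,
    seed: int,
    controls: pd.DataFrame | None = None,
    n_controls: int = 1000,
    k_sd: float = 3.0,
    blue_gate: float | None = None,
    red_gate: float | None = None,
) -> pd.DataFrame:
    """Simulate a flow sample of CellEvents under a stimulation protocol.

    Activation is digital: each cell independently crosses the activation
    threshold (Bernoulli with the Hill probability) per dose, and every
    activated cell then follows identical deterministic kinetics with
    ``signal_duration_h`` of transcription per activation.  Re-challenge
    doses see ``ec50 * recalibration_fold(priming dose) * blockade_ec50_mult``
    for cells that activated at priming, and a transcription rate scaled by
    ``blockade_rate_mult``.  Measurement noise and background are then
    applied, channels are normalized against ``controls`` (an unstimulated
    sample simulated internally when not given), and events are quadrant-
    gated into signal loci.

    Default gates sit at 10 % of the blue plateau (s / lambda_B) and 20 %
    of the total red yield (s * signal_duration_h) above background, so a
    cell observed 4 h into its signal reads Blue+Red- (new), one with
    transcription still on and matured red reads Blue+Red+ (persistent),
    and one whose blue has decayed away reads Blue-Red+ (arrested).

    Per-cell random streams are derived from (seed, cell index), so changing
    ``n_cells`` never reshuffles earlier cells.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seed = int(seed)

    doses = protocol.doses
    prime_time, prime_dose = (doses[0] if doses else (0.0, 0.0))

    # per-cell digital activations -> signaling pattern
    patterns: list[tuple[int, ...]] = []
    noise_draws: list[np.random.Generator] = []
    for i in range(n_cells):
        rng = np.random.default_rng([seed, 0, i])
        activated: list[int] = []
        prime_active = False
        for j, (t_dose, dose) in enumerate(doses):
            if t_dose > t_obs_h:
                break
            if j == 0:
                p = activation_probability(dose, protocol.ec50_ug, protocol.hill_n)
            else:
                fold = (
                    protocol.recalibration_fold(prime_dose, t_dose - prime_time)
                    if prime_active
                    else 1.0
                )
                p = activation_probability(
                    dose,
                    protocol.ec50_ug,
                    protocol.hill_n,
                    ec50_multiplier=fold * protocol.blockade_ec50_mult,
                )
            if rng.random() < p:
                activated.append(j)
                if j == 0:
                    prime_active = True
        patterns.append(tuple(activated))
        noise_draws.append(rng)

    # deterministic kinetics once per unique activation pattern
    cache: dict[tuple[int, ...], tuple[float, float]] = {}
    for pat in set(patterns):
        segs = []
        for j in pat:
            t_dose, _ = doses[j]
            rate = kinetics.transcription_rate
            if j > 0:
                rate *= protocol.blockade_rate_mult
            segs.append((t_dose, t_dose + protocol.signal_duration_h, rate))
        if segs:
            # later (blockade-boosted) segments win where windows overlap
            merged: list[tuple[float, float, float]] = []
            for a, b, r in sorted(segs):
                if merged and a < merged[-1][1]:
                    pa, pb, pr = merged.pop()
                    if pb > b:
                        merged.extend([(pa, a, pr), (a, b, max(pr, r)), (b, pb, pr)])
                    else:
                        merged.extend([(pa, a, pr), (a, b, r)])
                else:
                    merged.append((a, b, r))
            segs = [(a, b, r) for a, b, r in merged if b > a]
        blue, red = _solve_segments(kinetics, segs, np.array([t_obs_h], dtype=float))
        cache[pat] = (float(blue[0]), float(red[0]))

    rows = []
    for i in range(n_cells):
        b0, r0 = cache[patterns[i]]
        rng = noise_draws[i]
        b = _measure(rng, b0, kinetics.background_blue, kinetics.noise_cv)
        r = _measure(rng, r0, kinetics.background_red, kinetics.noise_cv)
        rows.append((f"cell{i:06d}", b, r))
    events = pd.DataFrame(rows, columns=["cell_id", "blue", "red"])

    if controls is None:
        ctrl_rows = []
        for i in range(n_controls):
            rng = np.random.default_rng([seed, 1, i])
            b = _measure(rng, 0.0, kinetics.background_blue, kinetics.noise_cv)
            r = _measure(rng, 0.0, kinetics.background_red, kinetics.noise_cv)
            ctrl_rows.append((f"ctrl{i:06d}", b, r))
        controls = pd.DataFrame(ctrl_rows, columns=["cell_id", "blue", "red"])

    s = kinetics.transcription_rate
    if blue_gate is None:
        blue_gate = kinetics.background_blue + 0.10 * s / kinetics.lambda_blue
    if red_gate is None:
        red_gate = kinetics.background_red + 0.20 * s * protocol.signal_duration_h
    gates = (max(blue_gate, 1e-9), max(red_gate, 1e-9))
    return normalize_channels(events, controls, k_sd=k_sd, strict=False, gates=gates)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def normalize_channels(
    events: pd.DataFrame,
    controls: pd.DataFrame,
    k_sd: float = 3.0,
    strict: bool = True,
    gates: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Normalize blue/red channels against an unstimulated control sample.

    Per channel: subtract the control mean, divide by the 99th percentile of
    the positive events' subtracted values, multiply by 100 and clip to
    [0, 100].  An event is ``timer_positive`` when its raw value exceeds
    control mean + ``k_sd`` * control SD on either channel, unless explicit
    raw ``gates`` (blue, red) are given.  Loci and Timer angles are filled
    from the same gates.

    ``strict=True`` (default) raises on empty or zero-variance controls;
    ``strict=False`` degrades to gating at the control mean when the control
    has no variance (fully deterministic simulations).
    """
    if len(controls) == 0:
        raise ValueError("controls must be nonempty")
    out = events.copy()
    gate_map = {}
    sub_map = {}
    pos_map = {}
    for i, ch in enumerate(("blue", "red")):
        mu = float(controls[ch].mean())
        if gates is not None:
            gate_map[ch] = float(gates[i])
        else:
            sd = float(controls[ch].std(ddof=1)) if len(controls) > 1 else 0.0
            if sd == 0.0 and strict:
                raise ValueError(f"zero-variance controls on channel {ch!r}")
            gate_map[ch] = mu + k_sd * sd
        sub_map[ch] = out[ch].to_numpy(dtype=float) - mu
        pos_map[ch] = out[ch].to_numpy(dtype=float) > gate_map[ch]
    timer_pos = pos_map["blue"] | pos_map["red"]
    for ch in ("blue", "red"):
        # scale each channel within the Timer-positive population so the
        # normalization does not hinge on a channel's own tail events
        sub = sub_map[ch]
        scale = np.percentile(sub[timer_pos], 99) if timer_pos.any() else np.nan
        if not np.isfinite(scale) or scale <= 0:
            norm = np.zeros(len(out))
        else:
            norm = np.clip(sub / scale * 100.0, 0.0, 100.0)
        out[f"{ch}_norm"] = norm
    out["timer_positive"] = timer_pos
    out["locus"] = classify_locus(
        out["blue"], out["red"], gate_map["blue"], gate_map["red"]
    )
    angle = np.full(len(out), np.nan)
    tp = out["timer_positive"].to_numpy()
    if tp.any():
        bn = out.loc[tp, "blue_norm"].to_numpy()
        rn = out.loc[tp, "red_norm"].to_numpy()
        angle[tp] = np.degrees(np.arctan2(rn, bn))
    out["angle_deg"] = angle
    out = out[[c for c in EVENT_COLUMNS if c in out.columns]]
    out.attrs["gates"] = gate_map
    return out


def timer_angle(blue_norm, red_norm):
    """Timer angle theta = atan2(red_norm, blue_norm) in degrees [0, 90].

    0 deg = pure blue (new signal), 90 deg = pure red (arrested signal).
    Raises when both inputs are zero (angle undefined).
    """
    b = np.asarray(blue_norm, dtype=float)
    r = np.asarray(red_norm, dtype=float)
    if np.any((b == 0) & (r == 0)):
        raise ValueError("timer angle undefined when both channels are zero")
    ang = np.degrees(np.arctan2(r, b))
    return float(ang) if ang.ndim == 0 else ang


def classify_locus(blue, red, blue_gate: float, red_gate: float):
    """Quadrant-gate raw fluorescence into signal loci.

    Blue+Red- -> new, Blue+Red+ -> persistent, Blue-Red+ -> arrested,
    Blue-Red- -> negative.
    """
    if not (blue_gate > 0 and red_gate > 0):
        raise ValueError("gates must be > 0")
    b = np.asarray(blue, dtype=float) > blue_gate
    r = np.asarray(red, dtype=float) > red_gate
    out = np.where(
        b & ~r, "new", np.where(b & r, "persistent", np.where(~b & r, "arrested", "negative"))
    )
    if out.ndim == 0:
        return str(out)
    return pd.Categorical(out, categories=list(LOCI))


def mean_timer_angle(events: pd.DataFrame) -> float:
    """Arithmetic mean Timer angle over timer-positive events only."""
    tp = events[events["timer_positive"].astype(bool)]
    if len(tp) == 0:
        raise ValueError("no timer-positive events")
    return float(tp["angle_deg"].mean())


def rechallenge_summary(events: pd.DataFrame) -> dict[str, float]:
    """Fractions summarising a re-challenge sample.

    responders
        Blue+Red+ (persistent locus) fraction of timer-positive events —
        cells that responded to both stimulations.
    arrested_nonresponders
        Blue-Red+ (arrested locus) fraction of timer-positive events —
        previously activated cells that failed to respond to re-challenge.
    active
        Blue+ fraction (new or persistent locus) of all events.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    locus = events["locus"].astype(str)
    tp = events["timer_positive"].astype(bool)
    n_tp = int(tp.sum())
    n_pers = int((locus == "persistent").sum())
    n_arr = int((locus == "arrested").sum())
    n_blue = int(locus.isin(["new", "persistent"]).sum())
    return {
        "responders": n_pers / n_tp if n_tp else 0.0,
        "arrested_nonresponders": n_arr / n_tp if n_tp else 0.0,
        "active": n_blue / len(events),
    }
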