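"""Timer reporter kinetics, flow simulation and Tocky quantification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from tcrstrong import (
    SignalSchedule,
    StimulationProtocol,
    TimerKinetics,
    activation_probability,
    classify_locus,
    mean_timer_angle,
    normalize_channels,
    rechallenge_summary,
    simulate_flow_sample,
    solve_timer,
    timer_angle,
)

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# solve_timer
# ---------------------------------------------------------------------------

def rk4_oracle(kinetics, schedule, t_end, dt=0.01):
    """Fourth-order Runge-Kutta integration of the Timer ODEs.

    Integrates each continuous piece (constant transcription rate) separately
    so the on/off discontinuities never fall inside a step.
    """
    lb, lr = kinetics.lambda_blue, kinetics.lambda_red
    edges = sorted(
        {0.0, t_end}
        | {a for a, _ in schedule.intervals if a < t_end}
        | {b for _, b in schedule.intervals if b < t_end}
    )
    y = np.zeros(2)
    for a, b in zip(edges[:-1], edges[1:]):
        s = kinetics.transcription_rate if schedule.active((a + b) / 2) else 0.0

        def f(y):
            blue, red = y
            return np.array([s - lb * blue, lb * blue - lr * red])

        n = max(1, int(round((b - a) / dt)))
        h = (b - a) / n
        for _ in range(n):
            k1 = f(y)
            k2 = f(y + h / 2 * k1)
            k3 = f(y + h / 2 * k2)
            k4 = f(y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def test_blue_plateau_is_rate_over_decay(unit_kinetics):
    """With transcription permanently on, blue plateaus at s / lambda_B."""
    sched = SignalSchedule(((0.0, 1e5),))
    out = solve_timer(unit_kinetics, sched, [5000.0])
    assert out["blue"].iloc[0] == pytest.approx(4.0 / LN2, rel=1e-9)


def test_blue_halves_every_half_life_after_arrest(unit_kinetics, single_pulse):
    """After transcription arrest, blue halves every 4 h."""
    out = solve_timer(unit_kinetics, single_pulse, [24.0, 28.0, 32.0])
    b = out["blue"].to_numpy()
    assert b[1] == pytest.approx(b[0] / 2, rel=1e-12)
    assert b[2] == pytest.approx(b[0] / 4, rel=1e-12)


def test_blue_half_life_recovered_by_root_finding(unit_kinetics, single_pulse):
    """The time for blue to halve after arrest equals the blue half-life."""
    b24 = solve_timer(unit_kinetics, single_pulse, [24.0])["blue"].iloc[0]

    def gap(dt):
        return solve_timer(unit_kinetics, single_pulse, [24.0 + dt])["blue"].iloc[0] - b24 / 2

    t_half = brentq(gap, 1.0, 10.0, xtol=1e-9)
    assert abs(t_half - 4.0) < 1e-3


def test_total_protein_conserved_without_red_decay(single_pulse):
    """With red decay off and transcription arrested, blue + red is constant."""
    kin = TimerKinetics(red_half_life_h=math.inf, transcription_rate=1.0)
    out = solve_timer(kin, single_pulse, [24.0, 48.0, 200.0])
    total = (out["blue"] + out["red"]).to_numpy()
    assert np.allclose(total, total[0], rtol=1e-12)


def test_terminal_red_slope_matches_red_half_life(unit_kinetics, single_pulse):
    """Once blue is negligible, red decays with its own 120 h half-life."""
    out = solve_timer(unit_kinetics, single_pulse, [300.0, 420.0])
    r = out["red"].to_numpy()
    slope = (np.log(r[1]) - np.log(r[0])) / 120.0
    assert -LN2 / slope == pytest.approx(120.0, rel=0.01)


def test_two_interval_schedule_matches_rk4_oracle():
    """An arbitrary on/off/on schedule agrees with independent RK4 integration."""
    kin = TimerKinetics(transcription_rate=7.3, noise_cv=0.0)
    sched = SignalSchedule(((1.5, 6.25), (20.0, 27.5)))
    t_end = 30.0
    expected = rk4_oracle(kin, sched, t_end)
    out = solve_timer(kin, sched, [t_end])
    assert out["blue"].iloc[0] == pytest.approx(expected[0], rel=1e-6)
    assert out["red"].iloc[0] == pytest.approx(expected[1], rel=1e-6)


def test_solve_timer_rejects_bad_times(unit_kinetics, single_pulse):
    with pytest.raises(ValueError):
        solve_timer(unit_kinetics, single_pulse, [])
    with pytest.raises(ValueError):
        solve_timer(unit_kinetics, single_pulse, [-1.0, 2.0])
    with pytest.raises(ValueError):
        solve_timer(unit_kinetics, single_pulse, [5.0, 2.0])


def test_angle_monotone_after_arrest(unit_kinetics, single_pulse):
    """Per-cell blue-red angle never decreases once transcription stops."""
    times = np.linspace(24.0, 200.0, 60)
    out = solve_timer(unit_kinetics, single_pulse, times)
    theta = np.degrees(np.arctan2(out["red"], out["blue"]))
    assert np.all(np.diff(theta) >= -1e-12)


# ---------------------------------------------------------------------------
# activation probability
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dose, ec50, n, mult, expected",
    [
        (0.0, 8.0, 1.0, 1.0, 0.0),
        (8.0, 8.0, 1.0, 1.0, 0.5),
        (16.0, 8.0, 1.0, 2.0, 0.5),  # multiplier shifts the midpoint
        (80.0, 8.0, 1.0, 1.0, 80.0 / 88.0),
    ],
)
def test_hill_activation_probability(dose, ec50, n, mult, expected):
    assert activation_probability(dose, ec50, n, mult) == pytest.approx(expected)


def test_activation_probability_strictly_increasing_in_dose():
    doses = np.linspace(0.1, 100, 50)
    p = [activation_probability(d, 8.0, 2.0) for d in doses]
    assert np.all(np.diff(p) > 0)


def test_activation_probability_rejects_nonpositive_ec50():
    with pytest.raises(ValueError):
        activation_probability(1.0, 0.0)


# ---------------------------------------------------------------------------
# flow-sample simulation
# ---------------------------------------------------------------------------

def test_zero_dose_gives_all_negative_sample(kinetics):
    prot = StimulationProtocol(doses=((0.0, 0.0),))
    ev = simulate_flow_sample(200, prot, kinetics, 4.0, seed=1)
    assert (ev["locus"].astype(str) == "negative").all()
    assert not ev["timer_positive"].any()


def test_digital_rule_no_noise_identical_values(priming_protocol):
    """Saturating dose and no noise: all activated cells identical."""
    kin = TimerKinetics(noise_cv=0.0)
    prot = StimulationProtocol(doses=((0.0, 8000.0),))
    ev = simulate_flow_sample(100, prot, kin, 4.0, seed=3)
    act = ev[ev["locus"].astype(str) != "negative"]
    assert len(act) > 90  # p = 8000/8008
    assert act["blue"].nunique() == 1
    assert act["red"].nunique() == 1


def test_activated_fraction_matches_binomial(kinetics):
    """Activated fraction within 3 binomial SEs of the Hill probability."""
    p = 0.3
    dose = p / (1 - p) * 8.0  # invert the Hill midpoint
    prot = StimulationProtocol(doses=((0.0, dose),))
    ev = simulate_flow_sample(10_000, prot, kinetics, 4.0, seed=5)
    frac = (ev["locus"].astype(str) != "negative").mean()
    se = math.sqrt(p * (1 - p) / 10_000)
    assert abs(frac - p) < 3 * se


def test_seed_streams_stable_under_n_cells_change(kinetics, priming_protocol):
    """Adding cells never reshuffles the per-cell streams simulated so far.

    Raw fluorescence, gating and loci of the first cells are unchanged;
    normalized channels are a sample-level statistic and may shift.
    """
    cols = ["cell_id", "blue", "red", "timer_positive", "locus"]
    small = simulate_flow_sample(50, priming_protocol, kinetics, 4.0, seed=9)
    big = simulate_flow_sample(200, priming_protocol, kinetics, 4.0, seed=9)
    pd.testing.assert_frame_equal(
        small[cols], big.iloc[:50].reset_index(drop=True)[cols]
    )


def test_locus_trajectory_new_to_persistent_to_arrested(kinetics):
    """Activated cells read new at 4 h, persistent mid-signal, arrested at 24 h."""
    prot = StimulationProtocol(doses=((0.0, 8000.0),))
    modal = {}
    for t in (4.0, 8.0, 24.0):
        ev = simulate_flow_sample(300, prot, kinetics, t, seed=2)
        act = ev[ev["locus"].astype(str) != "negative"]
        modal[t] = act["locus"].astype(str).mode()[0]
    assert modal == {4.0: "new", 8.0: "persistent", 24.0: "arrested"}


def test_recalibration_suppresses_rechallenge_response(kinetics):
    """Strong priming arrests more cells at re-challenge than weak priming."""
    strong = StimulationProtocol(doses=((0.0, 80.0), (24.0, 8.0)))
    weak = StimulationProtocol(doses=((0.0, 8.0), (24.0, 8.0)))
    s = rechallenge_summary(simulate_flow_sample(3000, strong, kinetics, 28.0, seed=4))
    w = rechallenge_summary(simulate_flow_sample(3000, weak, kinetics, 28.0, seed=4))
    assert s["arrested_nonresponders"] > w["arrested_nonresponders"]
    assert s["responders"] < w["responders"]


def test_recalibration_resets_after_interval(kinetics):
    """Waiting past the reset window restores re-challenge sensitivity."""
    early = StimulationProtocol(doses=((0.0, 80.0), (24.0, 8.0)))
    late = StimulationProtocol(doses=((0.0, 80.0), (96.0, 8.0)))
    assert early.recalibration_fold(80.0, 24.0) == pytest.approx(11.0)
    assert late.recalibration_fold(80.0, 96.0) == 1.0


def test_blockade_increases_responders_and_blue(kinetics):
    """Checkpoint blockade raises the responder fraction and responder blue."""
    base = StimulationProtocol(doses=((0.0, 80.0), (24.0, 8.0)))
    blocked = StimulationProtocol(
        doses=((0.0, 80.0), (24.0, 8.0)),
        blockade_ec50_mult=0.3,
        blockade_rate_mult=1.5,
    )
    ev_b = simulate_flow_sample(4000, base, kinetics, 28.0, seed=6)
    ev_x = simulate_flow_sample(4000, blocked, kinetics, 28.0, seed=6)
    rs_b, rs_x = rechallenge_summary(ev_b), rechallenge_summary(ev_x)
    assert rs_x["responders"] > rs_b["responders"]
    med_b = ev_b.loc[ev_b["locus"].astype(str) == "persistent", "blue"].median()
    med_x = ev_x.loc[ev_x["locus"].astype(str) == "persistent", "blue"].median()
    assert med_x > med_b


def test_dose_invariant_angle_trajectory(kinetics):
    """Mean Timer angle of ACTIVATED cells is dose-independent (digital rule)."""
    lo = StimulationProtocol(doses=((0.0, 8.0 / 9.0),))  # p = 0.1
    hi = StimulationProtocol(doses=((0.0, 72.0),))  # p = 0.9
    for t in (4.0, 12.0, 24.0):
        angles = []
        for prot in (lo, hi):
            ev = simulate_flow_sample(5000, prot, kinetics, t, seed=13)
            act = ev[ev["timer_positive"]]
            angles.append(act["angle_deg"].mean())
        assert abs(angles[0] - angles[1]) < 1.0


# ---------------------------------------------------------------------------
# normalization, angle, locus, summaries
# ---------------------------------------------------------------------------

def _controls(mu=10.0, sd=1.0, n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "blue": rng.normal(mu, sd, n),
            "red": rng.normal(mu, sd, n),
        }
    )


def test_normalize_event_at_control_mean_is_zero_and_negative():
    ctrl = _controls()
    events = pd.DataFrame(
        {"cell_id": ["e0", "e1"], "blue": [ctrl["blue"].mean(), 500.0],
         "red": [ctrl["red"].mean(), 500.0]}
    )
    out = normalize_channels(events, ctrl)
    assert out.loc[0, "blue_norm"] == 0.0
    assert not out.loc[0, "timer_positive"]
    assert out.loc[1, "timer_positive"]


def test_normalize_matches_hand_computed_quantiles():
    """Normalized values equal hand-computed (x - mean) / p99 * 100."""
    ctrl = _controls(seed=42)
    rng = np.random.default_rng(1)
    pos_vals = rng.uniform(100, 1000, 50)
    events = pd.DataFrame(
        {"cell_id": [f"e{i}" for i in range(50)], "blue": pos_vals, "red": pos_vals}
    )
    out = normalize_channels(events, ctrl)
    mu = ctrl["blue"].mean()
    p99 = np.percentile(pos_vals - mu, 99)
    expected = np.clip((pos_vals - mu) / p99 * 100.0, 0, 100)
    np.testing.assert_allclose(out["blue_norm"], expected, rtol=1e-12)


def test_normalize_rejects_degenerate_controls():
    events = _controls(n=5)
    with pytest.raises(ValueError):
        normalize_channels(events, events.iloc[:0])
    flat = _controls(n=5)
    flat["blue"] = 10.0
    flat["red"] = 10.0
    with pytest.raises(ValueError):
        normalize_channels(events, flat)


@pytest.mark.parametrize(
    "blue, red, expected",
    [(100.0, 0.0, 0.0), (0.0, 100.0, 90.0), (50.0, 50.0, 45.0)],
)
def test_timer_angle_corners(blue, red, expected):
    assert timer_angle(blue, red) == pytest.approx(expected)


def test_timer_angle_undefined_at_origin():
    with pytest.raises(ValueError):
        timer_angle(0.0, 0.0)


@pytest.mark.parametrize(
    "blue, red, expected",
    [
        (5.0, 0.5, "new"),
        (5.0, 5.0, "persistent"),
        (0.5, 5.0, "arrested"),
        (0.5, 0.5, "negative"),
    ],
)
def test_classify_locus_quadrants(blue, red, expected):
    assert classify_locus(blue, red, 1.0, 1.0) == expected


def test_mean_timer_angle_is_arithmetic_mean():
    ev = pd.DataFrame(
        {
            "timer_positive": [True, True, False],
            "angle_deg": [30.0, 60.0, np.nan],
        }
    )
    assert mean_timer_angle(ev) == pytest.approx(45.0)
    with pytest.raises(ValueError):
        mean_timer_angle(ev[ev["angle_deg"].isna()])


def test_rechallenge_summary_counts():
    ev = pd.DataFrame(
        {
            "locus": ["persistent"] * 60 + ["arrested"] * 40 + ["negative"] * 10,
            "timer_positive": [True] * 100 + [False] * 10,
        }
    )
    out = rechallenge_summary(ev)
    assert out["responders"] == pytest.approx(0.6)
    assert out["arrested_nonresponders"] == pytest.approx(0.4)
    assert out["active"] == pytest.approx(60 / 110)
    with pytest.raises(ValueError):
        rechallenge_summary(ev.iloc[:0])


def test_schedule_and_kinetics_validation():
    with pytest.raises(ValueError):
        SignalSchedule(((5.0, 1.0),))
    with pytest.raises(ValueError):
        SignalSchedule(((0.0, 5.0), (4.0, 8.0)))
    with pytest.raises(ValueError):
        TimerKinetics(blue_half_life_h=120.0, red_half_life_h=4.0)
    with pytest.raises(ValueError):
        TimerKinetics(noise_cv=-0.1)
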