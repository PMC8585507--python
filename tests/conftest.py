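import numpy as np
import pandas as pd
import pytest

from tcrstrong import SignalSchedule, StimulationProtocol, TimerKinetics


@pytest.fixture
def kinetics():
    return TimerKinetics()


@pytest.fixture
def unit_kinetics():
    """Noise-free kinetics with unit transcription rate for ODE checks."""
    return TimerKinetics(transcription_rate=1.0, noise_cv=0.0)


@pytest.fixture
def single_pulse():
    return SignalSchedule(((0.0, 24.0),))


@pytest.fixture
def priming_protocol():
    return StimulationProtocol(doses=((0.0, 80.0),))


@pytest.fixture
def paper_memberships():
    """Four-set memberships matching the published group I/II exemplars."""
    return {
        "ICOS": {"res", "ot", "strong4h", "pd1"},
        "TNIP3": {"res", "ot", "strong4h", "pd1"},
        "TNFRSF4": {"res", "strong4h", "pd1"},
        "IRF8": {"res", "strong4h", "pd1"},
        "STAT4": {"res", "strong4h", "pd1"},
        "IL2RA": {"res", "strong4h"},
        "CD5": {"res", "pd1"},
        "TNFRSF9": {"res", "ot", "pd1"},
        "IFNG": {"res", "ot", "strong4h"},
        "NOISE1": set(),
        "NOISE2": {"ot"},
    }


@pytest.fixture
def patient_records():
    """Small paired pre/on cohort with survival endpoints."""
    rows = []
    scores = {
        "A": (2.0, 6.0, "CR"),
        "B": (3.0, 3.5, "PR"),
        "C": (2.5, 2.4, "PD"),
        "D": (4.0, 4.1, "PD"),
        "E": (1.0, 5.0, "SD"),
        "F": (2.2, 2.0, "NE"),
    }
    surv = {
        "A": (300, True, 700, False),
        "B": (250, True, 600, True),
        "C": (80, True, 150, True),
        "D": (120, True, 200, True),
        "E": (400, False, 800, False),
        "F": (60, True, 90, True),
    }
    for pid, (pre, on, bor) in scores.items():
        pfs_d, pfs_e, os_d, os_e = surv[pid]
        for tp, sc in (("pre", pre), ("on", on)):
            rows.append(
                dict(
                    patient_id=pid, cohort="ipi_naive", timepoint=tp, bor=bor,
                    pfs_days=pfs_d, pfs_event=pfs_e, os_days=os_d, os_event=os_e,
                    score=sc,
                )
            )
    return pd.DataFrame(rows)
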