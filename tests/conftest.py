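import numpy as np
import pandas as pd
import pytest

from rollvection import BlockDesign, PsychometricObserver


def make_observer(mu_cw=0.0, mu_ccw=None, sigma=1.0, duration=8.0, bias=0.0, lapse=0.0):
    """Observer with given condition PSEs at one duration (both directions)."""
    if mu_ccw is None:
        mu_ccw = mu_cw
    return PsychometricObserver(
        baseline_bias=bias,
        vection_shift={(duration, "CW"): mu_cw - bias, (duration, "CCW"): mu_ccw - bias},
        sigma=sigma,
        lapse=lapse,
    )


def trials_frame(levels, responses, block_type="IN-8s", vfm_direction="CW"):
    """Minimal trial table around explicit levels/responses for fitting."""
    levels = np.asarray(levels, dtype=float)
    if len(responses) and not isinstance(responses[0], str):
        responses = ["CW" if r else "CCW" for r in responses]
    return pd.DataFrame(
        {
            "subject_id": "s0",
            "group": "control",
            "block_type": block_type,
            "vfm_direction": vfm_direction,
            "inertial_peak_vel": levels,
            "response": list(responses),
            "certainty": np.nan,
            "staircase_id": "t0",
            "trial_index": np.arange(levels.size),
            "rng_seed": 0,
        }
    )


@pytest.fixture
def design_8s():
    return BlockDesign(vfm_duration=8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
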