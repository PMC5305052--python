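"""Synthetic observers and cohort generation.

This module is the package's stand-in for human subjects.  Each simulated
subject carries

* a two-parameter cumulative-Gaussian decision model for the binary
  clockwise/counterclockwise direction judgment.  The mean mu of the
  Gaussian is the point of subjective equality (PSE); its width sigma is
  the direction-discrimination threshold.  Visual field motion (VFM)
  shifts the effective PSE by a duration- and direction-dependent amount
  (the vection effect), while the three visual-control conditions
  (darkness, static, zero coherence) leave only a small baseline bias;
* a certainty model producing 0-100 ratings that rise with stimulus
  duration along a saturating exponential.

Cohort-level calibration targets the study's group statistics: in the
"migraine" group the mean combined PSE shift grows from 0.045 deg/s at
1 s to 0.52 deg/s at 8 s (half of the printed 0.09 and 1.04 deg/s CW-CCW
differences) while the "control" group mean stays at zero; the
between-subject variance of the combined shift at 8 s is 2.32 deg^2/s^2
(migraine) vs 0.35 (control); the across-subject correlation between the
CW-VFM and CCW-VFM PSEs is ~0.44 and between CW and CCW certainty means
~0.97.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import SchemaError

__all__ = [
    "CONTROL_KINDS",
    "TRIAL_COLUMNS",
    "PsychometricObserver",
    "CertaintyObserver",
    "CohortSpec",
    "p_clockwise",
    "respond",
    "certainty_response",
    "simulate_cohort",
    "validate_trials",
    "default_shift_curves",
]

#: The three no-vection control conditions.
CONTROL_KINDS = ("darkness", "static", "zero-coherence")

#: Column order of the trial-log table (the single interchange format).
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "block_type",
    "vfm_direction",
    "inertial_peak_vel",
    "response",
    "certainty",
    "staircase_id",
    "trial_index",
    "rng_seed",
]

_DURATIONS = (1.0, 4.0, 8.0)


def default_shift_curves() -> dict:
    """Group mean combined-shift curves (deg/s) at the three durations.

    The 1 s and 8 s migraine values are half the printed CW-CCW PSE
    differences (0.09 and 1.04 deg/s); the 4 s value is interpolated
    linearly on log-duration (a stand-in, not a reproduction target).
    Controls sit at zero for all durations.
    """
    lo, hi = 0.045, 0.52
    frac = math.log(4.0) / math.log(8.0)
    return {
        "migraine": {1.0: lo, 4.0: lo + (hi - lo) * frac, 8.0: hi},
        "control": {1.0: 0.0, 4.0: 0.0, 8.0: 0.0},
    }


@dataclass
class PsychometricObserver:
    """Generative model of one subject's binary direction judgments.

    P(respond CW | v) = lapse/2 + (1 - lapse) * Phi((v - mu_cond)/sigma)

    where v is the signed inertial peak velocity (deg/s, + = CW) and
    mu_cond = baseline_bias for the control conditions or
    baseline_bias + vection_shift[(duration, vfm_direction)] for the
    inertial-nulling conditions.
    """

    subject_id: str = "s0"
    group: str = "control"
    baseline_bias: float = 0.0  # deg/s; |bias| < 1 in the screened cohort
    vection_shift: dict = field(default_factory=dict)  # (duration, dir) -> deg/s
    sigma: float = 1.0  # deg/s, > 0
    lapse: float = 0.0  # in [0, 0.1]

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")


@dataclass
class CertaintyObserver:
    """Generative model of one subject's 0-100 certainty ratings.

    The mean rating saturates with stimulus duration d:

        mean(d) = A_dir * max(0, 1 - exp(-(d - onset_latency)/rise_time))

    with A_dir = asymptote +/- direction_delta for CW/CCW.  Gaussian trial
    noise (sd = noise_sd) is added and the result truncated to [0, 100].
    direction_coupling records the cohort-level latent correlation between
    a subject's CW and CCW asymptotes (it is applied when the cohort is
    drawn, not per trial).
    """

    asymptote: float = 60.0  # rating units in [0, 100]
    rise_time: float = 4.0  # s
    onset_latency: float = 0.5  # s
    noise_sd: float = 6.0  # rating units
    direction_coupling: float = 0.97  # in [-1, 1]
    direction_delta: float = 0.0  # (A_cw - A_ccw)/2

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymptote <= 100.0:
            raise ValueError("asymptote must lie in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1.0 <= self.direction_coupling <= 1.0:
            raise ValueError("direction_coupling must lie in [-1, 1]")


@dataclass
class CohortSpec:
    """Study-condition parameters for a synthetic cohort.

    Defaults are the calibrated study conditions; see the module docstring
    for the targeted group statistics.
    """

    n_control: int = 9
    n_migraine: int = 10
    group_shift_curve: dict = field(default_factory=default_shift_curves)
    #: between-subject variance of the combined shift at 8 s, deg^2/s^2
    between_subject_var: dict = field(
        default_factory=lambda: {"migraine": 2.32, "control": 0.35}
    )
    #: across-subject correlation between CW-VFM and CCW-VFM PSE deviations
    in_direction_coupling: float = 0.44
    #: duration ramp applied to the per-subject shift deviations
    #: (log2(d)/log2(8): 0 at 1 s, 2/3 at 4 s, 1 at 8 s)
    sigma_range: tuple = (0.7, 1.3)  # deg/s, per-subject threshold draw
    lapse: float = 0.0
    baseline_bias_sd: float = 0.3  # deg/s
    group_baseline_mean: dict = field(
        default_factory=lambda: {"migraine": 0.03, "control": 0.0}
    )
    # certainty-model population parameters
    ce_asymptote_mean: float = 60.0
    ce_asymptote_sd: float = 20.0
    ce_rise_time: float = 4.0
    ce_onset_latency: float = 0.5
    ce_noise_sd: float = 6.0
    ce_direction_coupling: float = 0.97
    n_ce_per_block: int = 8  # 4 per VFM direction; the Methods value 4 is allowed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_migraine < 1:
            raise ValueError("cohort needs at least one subject per group")
        if any(v < 0 for v in self.between_subject_var.values()):
            raise ValueError("between-subject variances must be >= 0")
        if not -1.0 <= self.in_direction_coupling < 1.0:
            raise ValueError("in_direction_coupling must lie in [-1, 1)")
        if self.n_ce_per_block % 2:
            raise ValueError("n_ce_per_block must be even (balanced CW/CCW)")


def _shift_ramp(duration: float) -> float:
    """Duration ramp for between-subject shift deviations: 0 at 1 s, 1 at 8 s."""
    return math.log2(duration) / math.log2(8.0)


def _effective_mean(observer: PsychometricObserver, condition) -> float:
    if isinstance(condition, str):
        if condition in CONTROL_KINDS:
            return observer.baseline_bias
        raise ValueError(f"unknown condition {condition!r}")
    try:
        duration, direction = condition
    except (TypeError, ValueError):
        raise ValueError(f"unknown condition {condition!r}") from None
    key = (float(duration), str(direction))
    if key not in observer.vection_shift:
        raise ValueError(
            f"observer {observer.subject_id} has no vection shift for {key}"
        )
    return observer.baseline_bias + observer.vection_shift[key]


def p_clockwise(observer: PsychometricObserver, v: float, condition) -> float:
    """Probability of a clockwise report at signed inertial velocity v.

    ``condition`` is either a control kind ("darkness", "static",
    "zero-coherence") or a ``(duration_s, "CW"/"CCW")`` pair naming the
    VFM condition.
    """
    mu = _effective_mean(observer, condition)
    lam = observer.lapse
    return lam / 2.0 + (1.0 - lam) * float(ndtr((v - mu) / observer.sigma))


def respond(observer: PsychometricObserver, v: float, condition, rng) -> str:
    """Draw a single "CW"/"CCW" report (Bernoulli with p_clockwise)."""
    p = p_clockwise(observer, v, condition)
    return "CW" if rng.random() < p else "CCW"


def certainty_response(
    observer: CertaintyObserver, duration: float, direction: str, rng
) -> float:
    """Draw a 0-100 certainty rating for a VFM stimulus of given duration."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    sign = 1.0 if direction == "CW" else -1.0
    asym = float(np.clip(observer.asymptote + sign * observer.direction_delta, 0, 100))
    growth = max(0.0, 1.0 - math.exp(-(duration - observer.onset_latency) / observer.rise_time))
    mean = asym * growth
    rating = mean + (rng.normal(0.0, observer.noise_sd) if observer.noise_sd > 0 else 0.0)
    return float(np.clip(rating, 0.0, 100.0))


# ---------------------------------------------------------------------------
# cohort generation


def _draw_observers(spec: CohortSpec, rng) -> list:
    """Draw (PsychometricObserver, CertaintyObserver) pairs for the cohort."""
    out = []
    rho_in = spec.in_direction_coupling
    rho_ce = spec.ce_direction_coupling
    groups = [("control", spec.n_control, "C"), ("migraine", spec.n_migraine, "M")]
    for group, n, prefix in groups:
        var_combined = spec.between_subject_var[group]
        # per-direction deviation sd chosen so that
        # var((u - w)/2) = tau^2 (1 - rho)/2 equals the target combined var
        tau = math.sqrt(2.0 * var_combined / (1.0 - rho_in)) if var_combined > 0 else 0.0
        curve = spec.group_shift_curve[group]
        bias_mean = spec.group_baseline_mean.get(group, 0.0)
        for i in range(n):
            bias = float(np.clip(rng.normal(bias_mean, spec.baseline_bias_sd), -0.99, 0.99))
            sigma = float(rng.uniform(*spec.sigma_range))
            z1, z2 = rng.normal(size=2)
            u = tau * z1
            w = tau * (rho_in * z1 + math.sqrt(1.0 - rho_in**2) * z2)
            shifts = {}
            for d in sorted(curve):
                r = _shift_ramp(d)
                shifts[(float(d), "CW")] = curve[d] + r * u
                shifts[(float(d), "CCW")] = -curve[d] + r * w
            psy = PsychometricObserver(
                subject_id=f"{prefix}{i + 1:02d}",
                group=group,
                baseline_bias=bias,
                vection_shift=shifts,
                sigma=sigma,
                lapse=spec.lapse,
            )
            z1, z2 = rng.normal(size=2)
            a_cw = spec.ce_asymptote_mean + spec.ce_asymptote_sd * z1
            a_ccw = spec.ce_asymptote_mean + spec.ce_asymptote_sd * (
                rho_ce * z1 + math.sqrt(1.0 - rho_ce**2) * z2
            )
            a_cw, a_ccw = np.clip([a_cw, a_ccw], 0.0, 100.0)
            ce = CertaintyObserver(
                asymptote=float((a_cw + a_ccw) / 2.0),
                rise_time=spec.ce_rise_time,
                onset_latency=spec.ce_onset_latency,
                noise_sd=spec.ce_noise_sd,
                direction_coupling=rho_ce,
                direction_delta=float((a_cw - a_ccw) / 2.0),
            )
            out.append((psy, ce))
    return out


def simulate_cohort(spec: CohortSpec, design=None, seed: int | None = None) -> pd.DataFrame:
    """Simulate the full study for one cohort and return the trial table.

    Per subject: three visual-control blocks of 36 trials, three
    inertial-nulling (IN) blocks of 72 trials (4 interleaved staircases of
    18 trials at 1, 4 and 8 s VFM duration) and three certainty-estimation
    (CE) blocks.  Identical (spec, design, seed) yields a byte-identical
    table.

    Parameters
    ----------
    spec : CohortSpec
    design : staircase_engine.StudyDesign, optional
        Block layout; defaults to the study's layout.
    seed : int, optional
        Overrides ``spec.seed``.
    """
    from . import staircase_engine as se  # deferred to avoid an import cycle

    if design is None:
        design = se.StudyDesign()
    base_seed = spec.seed if seed is None else seed
    root = np.random.SeedSequence(base_seed)
    param_ss, block_ss = root.spawn(2)
    observers = _draw_observers(spec, np.random.default_rng(param_ss))

    n_blocks_per_subject = (
        len(design.control_kinds) + 2 * len(design.vfm_durations)
    )
    subject_seeds = block_ss.spawn(len(observers))
    frames = []
    for (psy, ce), sub_ss in zip(observers, subject_seeds):
        seeds = sub_ss.generate_state(n_blocks_per_subject) >> 1  # keep < 2**31
        k = 0
        for kind in design.control_kinds:
            frames.append(se.run_control_block(psy, kind, int(seeds[k]), design=design))
            k += 1
        for d in design.vfm_durations:
            bd = design.in_block(d)
            frames.append(se.run_block(psy, bd, int(seeds[k])))
            k += 1
        for d in design.vfm_durations:
            block_seed = int(seeds[k])
            k += 1
            rng = np.random.default_rng(block_seed)
            dirs = ["CW", "CCW"] * (spec.n_ce_per_block // 2)
            order = rng.permutation(len(dirs))
            rows = []
            for j, oi in enumerate(order):
                direction = dirs[oi]
                rating = certainty_response(ce, float(d), direction, rng)
                rows.append(
                    {
                        "subject_id": psy.subject_id,
                        "group": psy.group,
                        "block_type": f"CE-{d:g}s",
                        "vfm_direction": direction,
                        "inertial_peak_vel": 0.0,
                        "response": "none",
                        "certainty": rating,
                        "staircase_id": "ce",
                        "trial_index": j,
                        "rng_seed": block_seed,
                    }
                )
            frames.append(pd.DataFrame(rows, columns=TRIAL_COLUMNS))
    table = pd.concat(frames, ignore_index=True)
    validate_trials(table)
    return table


# ---------------------------------------------------------------------------
# trial-table schema


def validate_trials(table: pd.DataFrame) -> None:
    """Validate the trial-log schema; raise SchemaError naming offenders.

    Invariants: IN and control rows carry a binary CW/CCW response and no
    certainty rating; CE rows carry a certainty rating, no inertial motion
    and no direction response; trial_index is unique within
    (subject, block, staircase).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table is missing columns: {missing}")
    extra = [c for c in table.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise SchemaError(f"trial table has unknown columns: {extra}")

    is_ce = table["block_type"].str.startswith("CE")
    bad = table.index[is_ce & (table["inertial_peak_vel"] != 0.0)]
    if len(bad):
        raise SchemaError(
            f"CE rows must have zero inertial motion; offending rows: {list(bad[:10])}"
        )
    bad = table.index[is_ce & table["certainty"].isna()]
    if len(bad):
        raise SchemaError(f"CE rows must carry a certainty rating; rows: {list(bad[:10])}")
    bad = table.index[~is_ce & ~table["response"].isin(["CW", "CCW"])]
    if len(bad):
        raise SchemaError(
            f"IN/control rows must have a CW/CCW response; rows: {list(bad[:10])}"
        )
    bad = table.index[~is_ce & table["certainty"].notna()]
    if len(bad):
        raise SchemaError(f"IN/control rows must not carry certainty; rows: {list(bad[:10])}")
    dup = table.duplicated(
        subset=["subject_id", "block_type", "staircase_id", "trial_index"], keep=False
    )
    if dup.any():
        raise SchemaError(
            "trial_index must be unique within (subject, block, staircase); "
            f"duplicated rows: {list(table.index[dup][:10])}"
        )
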