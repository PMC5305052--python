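"""Roll-plane stimulus definitions.

The inertial stimulus used in the experiment is a single cycle of a sine
wave *in acceleration* delivered about the naso-occipital (roll) axis.
Integrating one full sine cycle gives a raised-cosine velocity profile that
starts and ends at exactly zero velocity and zero acceleration, so the
trajectory is free of discontinuities in acceleration, velocity and
position:

    accel(t) = A sin(2*pi*t/T)
    vel(t)   = (v_peak/2) * (1 - cos(2*pi*t/T))
    pos(t)   = (v_peak/2) * (t - (T/(2*pi)) * sin(2*pi*t/T))

with A = pi * v_peak / T so that max |vel| equals the configured peak
velocity (8 deg/s in the study).  The total displacement is
v_peak * T / 2 (4 deg for an 8 deg/s, 1 s stimulus).

The visual stimulus (a rotating star field) is never rendered here; its
parameters are carried as structured metadata only.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionProfile",
    "VisualStimulusSpec",
    "make_inertial_profile",
    "profile_summary",
]

#: Sign convention used throughout the package: positive angular quantities
#: are clockwise roll from the subject's point of view, for both the
#: inertial and the visual stimulus.
CLOCKWISE_POSITIVE = True

_VFM_SPEED = 55.0  # deg/s, constant star-field rotation speed
_VFM_DURATIONS = (1.0, 4.0, 8.0)  # s


@dataclass(frozen=True)
class MotionProfile:
    """Time-sampled roll trajectory for one inertial stimulus.

    Attributes
    ----------
    duration : float
        Stimulus duration T in seconds.
    peak_velocity : float
        Signed peak angular velocity in deg/s (+ = clockwise).
    sample_rate : float
        Sampling rate in Hz.
    t, accel, vel, pos : numpy.ndarray
        Time (s), angular acceleration (deg/s^2), velocity (deg/s) and
        position (deg) sampled on a uniform grid including both endpoints.
    """

    duration: float
    peak_velocity: float
    sample_rate: float
    t: np.ndarray = field(repr=False)
    accel: np.ndarray = field(repr=False)
    vel: np.ndarray = field(repr=False)
    pos: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self, path_or_buf) -> None:
        """Export as a 4-column CSV (t, accel, vel, pos) with one header line."""
        data = np.column_stack([self.t, self.accel, self.vel, self.pos])
        header = "t_s,accel_deg_s2,vel_deg_s,pos_deg"
        if isinstance(path_or_buf, (str, bytes)):
            np.savetxt(path_or_buf, data, delimiter=",", header=header, comments="")
        else:
            np.savetxt(path_or_buf, data, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path_or_buf) -> "MotionProfile":
        data = np.loadtxt(path_or_buf, delimiter=",", skiprows=1)
        t, accel, vel, pos = data.T
        duration = float(t[-1] - t[0])
        n = t.size - 1
        rate = n / duration if duration > 0 else float("nan")
        imax = int(np.argmax(np.abs(vel)))
        return cls(
            duration=duration,
            peak_velocity=float(vel[imax]),
            sample_rate=rate,
            t=t,
            accel=accel,
            vel=vel,
            pos=pos,
        )


@dataclass(frozen=True)
class VisualStimulusSpec:
    """Parameters of the rotating star-field stimulus (metadata only).

    The defaults mirror the study's display geometry: 0.05 cm stars at a
    density of 0.002 per cubic cm, filling 98 degrees of the horizontal
    field of view at a 25 cm viewing distance.  Coherent visual-field-motion
    (VFM) blocks rotate the field at a constant 55 deg/s for 1, 4 or 8 s;
    the zero-coherence control uses a 1 s stimulus with no net rotation.
    """

    angular_speed: float  # deg/s, signed (+ = CW)
    duration: float  # s
    direction: str  # "CW" or "CCW"
    coherence: float = 1.0
    star_diameter_cm: float = 0.05
    star_density_per_cm3: float = 0.002
    horizontal_fov_deg: float = 98.0
    viewing_distance_cm: float = 25.0

    def __post_init__(self) -> None:
        if self.direction not in ("CW", "CCW"):
            raise ValueError(f"direction must be 'CW' or 'CCW', got {self.direction!r}")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError(f"coherence must lie in [0, 1], got {self.coherence}")
        if self.coherence == 1.0:
            if abs(abs(self.angular_speed) - _VFM_SPEED) > 1e-9:
                raise ValueError(
                    "coherent VFM blocks use a 55 deg/s star field; got "
                    f"{self.angular_speed} deg/s"
                )
            if self.duration not in _VFM_DURATIONS:
                raise ValueError(
                    f"VFM duration must be one of {_VFM_DURATIONS}, got {self.duration}"
                )
        elif self.coherence == 0.0 and self.duration != 1.0:
            raise ValueError("zero-coherence control stimuli last 1 s")


def make_inertial_profile(
    peak_velocity: float, duration: float = 1.0, sample_rate: float = 1000.0
) -> MotionProfile:
    """Build the single-cycle sine-in-acceleration roll profile.

    Parameters
    ----------
    peak_velocity : float
        Signed peak angular velocity in deg/s (+ = clockwise).  The study
        used 8 deg/s as the largest stimulus.
    duration : float
        Stimulus duration in seconds (must be > 0).
    sample_rate : float
        Sampling rate in Hz (must be >= 100, typical motion-platform
        command rates; default 1 kHz).

    Returns
    -------
    MotionProfile
        Velocity and position are the exact analytic integrals of the
        acceleration evaluated at the sample times, not numerical ones.
    """
    if not np.isfinite(peak_velocity):
        raise ValueError("peak_velocity must be finite")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sample_rate < 100:
        raise ValueError(f"sample_rate must be >= 100 Hz, got {sample_rate}")

    n = int(round(duration * sample_rate))
    t = np.linspace(0.0, duration, n + 1)
    omega = 2.0 * np.pi / duration
    amp = np.pi * peak_velocity / duration
    accel = amp * np.sin(omega * t)
    vel = 0.5 * peak_velocity * (1.0 - np.cos(omega * t))
    pos = 0.5 * peak_velocity * (t - np.sin(omega * t) / omega)
    # force exact zeros at the endpoints (analytically true; avoids ~1e-16
    # residue from the trig evaluation at t = T)
    accel[0] = accel[-1] = 0.0
    vel[0] = vel[-1] = 0.0
    pos[0] = 0.0
    return MotionProfile(
        duration=float(duration),
        peak_velocity=float(peak_velocity),
        sample_rate=float(sample_rate),
        t=t,
        accel=accel,
        vel=vel,
        pos=pos,
    )


def profile_summary(profile: MotionProfile) -> dict:
    """Summarise a profile for invariant checking.

    Returns a dict with the signed peak velocity actually attained, the
    total displacement, and the endpoint velocity/acceleration values
    (which should be zero for a discontinuity-free stimulus).
    """
    if len(profile) == 0:
        raise ValueError("empty motion profile")
    imax = int(np.argmax(np.abs(profile.vel)))
    return {
        "peak_velocity": float(profile.vel[imax]),
        "total_displacement": float(profile.pos[-1] - profile.pos[0]),
        "start_velocity": float(profile.vel[0]),
        "end_velocity": float(profile.vel[-1]),
        "start_acceleration": float(profile.accel[0]),
        "end_acceleration": float(profile.accel[-1]),
        "duration": profile.duration,
        "n_samples": len(profile),
    }
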