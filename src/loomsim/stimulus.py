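"""Looming-stimulus kinematics and pre-synaptic lowpass filtering.

A circular object of half-size ``l`` approaching the eye at constant speed
``v`` from initial distance ``x0`` subtends the angular size

    Theta(t) = 2 * arctan(l / x(t)),     x(t) = x0 - v * t,

with rate of expansion (angular velocity)

    Theta_dot(t) = 2 * l * v / (x(t)**2 + l**2).

Both optical variables are discretized on a regular grid ``dt_stim`` and
passed through first-order discrete lowpass filters,

    lp(t + dt) = zeta * lp(t) + (1 - zeta) * raw(t),

which stand in for the delay and smoothing introduced by the pre-synaptic
layers (lamina and medulla).  ``zeta = 0`` means no filtering; larger
``zeta`` means a longer lag (effective time constant ~ dt / (1 - zeta)).

Angles are radians everywhere; degrees appear only in printed reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ApproachSpec",
    "StimulusTrace",
    "angular_size",
    "angular_velocity",
    "lowpass",
    "make_stimulus",
]

_PROTOCOLS = ("approach", "recession", "constant_angular_velocity")


def angular_size(l: float, x) -> np.ndarray | float:
    """Angular size Theta = 2*arctan(l/x) of a half-size-``l`` object at distance ``x``.

    Parameters
    ----------
    l : float
        Object half-size (m), > 0.
    x : float or array
        Distance eye-to-object (m), > 0.

    Returns
    -------
    Angle in radians, in (0, pi).

    Raises
    ------
    ValueError
        If ``l <= 0`` or any ``x <= 0`` (object at or behind the eye).
    """
    if l <= 0:
        raise ValueError(f"half-size l must be positive, got {l}")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("distance x must be positive (object at/behind eye)")
    out = 2.0 * np.arctan(l / x)
    return float(out) if out.ndim == 0 else out


def angular_velocity(l: float, v: float, x) -> np.ndarray | float:
    """Rate of expansion Theta_dot = 2*l*v / (x**2 + l**2).

    Finite for every distance, including ``x = 0`` where it attains its
    maximum ``2*v/l``.
    """
    if l <= 0:
        raise ValueError(f"half-size l must be positive, got {l}")
    if v < 0:
        raise ValueError(f"speed v must be non-negative, got {v}")
    x = np.asarray(x, dtype=float)
    out = 2.0 * l * v / (x**2 + l**2)
    return float(out) if out.ndim == 0 else out


def lowpass(signal: np.ndarray, zeta: float, y0: Optional[float] = None) -> np.ndarray:
    """First-order discrete lowpass ``y[k] = zeta*y[k-1] + (1-zeta)*x[k]``.

    The filter is initialised at ``y[0] = y0`` (default: ``x[0]``, i.e. no
    initial transient for a signal that starts at steady state).  With
    ``zeta = 0`` the output equals the input exactly (no filtering); the
    effective lag grows as ``-dt / ln(zeta)``, about ``dt/(1 - zeta)`` for
    zeta near 1.
    """
    if not 0.0 <= zeta < 1.0:
        raise ValueError(f"lowpass coefficient must lie in [0, 1), got {zeta}")
    x = np.asarray(signal, dtype=float)
    y = np.empty_like(x)
    y[0] = x[0] if y0 is None else y0
    for k in range(1, len(x)):
        y[k] = zeta * y[k - 1] + (1.0 - zeta) * x[k]
    return y


@dataclass(frozen=True)
class ApproachSpec:
    """Geometry and kinematics of one stimulation protocol.

    Defaults describe the standard object approach used throughout:
    half-size ``l`` = 0.06 m (diameter 0.12 m), speed ``v`` = 6 m/s and an
    initial distance placing the projected collision at ``t_c = x0 / v``.
    The default ``x0`` = 3 m puts collision at 0.5 s, the time base on
    which all timing results are expressed.

    ``theta0`` and ``theta_dot_const`` only apply to the
    ``constant_angular_velocity`` protocol, where the angular size grows
    linearly, ``Theta(t) = theta0 + theta_dot_const * t`` (defaults span
    roughly 1..80 degrees over a 0.5 s trace).
    """

    half_size_l: float = 0.06
    velocity_v: float = 6.0
    initial_distance_x0: float = 3.0
    protocol: str = "approach"
    dt_stim: float = 1e-3
    duration: Optional[float] = None
    theta0: float = 0.02
    theta_dot_const: float = 2.75

    def __post_init__(self):
        if self.half_size_l <= 0:
            raise ValueError("half_size_l must be > 0")
        if self.velocity_v <= 0:
            raise ValueError("velocity_v must be > 0")
        if self.initial_distance_x0 <= 0:
            raise ValueError("initial_distance_x0 must be > 0")
        if self.dt_stim <= 0:
            raise ValueError("dt_stim must be > 0")
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"protocol must be one of {_PROTOCOLS}")

    @property
    def t_collision(self) -> float:
        """Projected time of collision, x0 / v."""
        return self.initial_distance_x0 / self.velocity_v

    @property
    def l_over_v(self) -> float:
        """Halfsize-to-velocity ratio (s), the kinematic timing parameter."""
        return self.half_size_l / self.velocity_v

    @classmethod
    def from_l_over_v(cls, l_over_v: float, t_collision: float = 0.5,
                      velocity_v: float = 6.0, **kwargs) -> "ApproachSpec":
        """Build a spec realizing a given l/v ratio at fixed speed and t_c."""
        return cls(half_size_l=l_over_v * velocity_v, velocity_v=velocity_v,
                   initial_distance_x0=velocity_v * t_collision, **kwargs)

    def to_dict(self) -> dict:
        return {
            "half_size_l": self.half_size_l,
            "velocity_v": self.velocity_v,
            "initial_distance_x0": self.initial_distance_x0,
            "protocol": self.protocol,
            "dt_stim": self.dt_stim,
            "duration": self.duration,
            "theta0": self.theta0,
            "theta_dot_const": self.theta_dot_const,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ApproachSpec":
        return cls(**{k: v for k, v in d.items() if v is not None})


@dataclass
class StimulusTrace:
    """Discretized optical variables and their lowpass-filtered versions."""

    times: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    theta_lp: np.ndarray
    theta_dot_lp: np.ndarray
    zeta0: float
    zeta1: float
    spec: ApproachSpec
    truncated: bool = False

    @property
    def t_collision(self) -> Optional[float]:
        """Projected collision time; None for protocols without one."""
        if self.spec.protocol == "approach":
            return self.spec.t_collision
        return None

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "theta_rad": self.theta,
            "theta_dot_rad_s": self.theta_dot,
            "theta_lp_rad": self.theta_lp,
            "theta_dot_lp_rad_s": self.theta_dot_lp,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _approach_arrays(spec: ApproachSpec):
    """Raw (times, theta, theta_dot, truncated) for an approach on the dt grid.

    The grid is truncated at t_c (where x = 0 and Theta -> pi); the geometry
    is undefined for x < 0, so requesting a longer duration sets the
    ``truncated`` flag instead of extrapolating.
    """
    l, v, x0, dt = spec.half_size_l, spec.velocity_v, spec.initial_distance_x0, spec.dt_stim
    t_c = spec.t_collision
    duration = t_c if spec.duration is None else spec.duration
    truncated = False
    if duration > t_c + 1e-12:
        duration = t_c
        truncated = True
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    x = x0 - v * times
    x = np.clip(x, 0.0, None)  # guard rounding at the last sample
    # 2*arctan2(l, x) equals 2*arctan(l/x) for x > 0 and tends to pi as x -> 0
    theta = 2.0 * np.arctan2(l, x)
    theta_dot = 2.0 * l * v / (x**2 + l**2)
    return times, theta, theta_dot, truncated


def make_stimulus(spec: ApproachSpec, zeta0: float = 0.95, zeta1: float = 0.95) -> StimulusTrace:
    """Generate the optical variables for a protocol and lowpass-filter them.

    Protocols
    ---------
    approach
        x(t) = x0 - v*t on t in [0, duration], truncated at t_c.
    recession
        Exact time reversal of the corresponding approach.  The reversed
        angular-size signal shrinks over time; the magnitude of the reversed
        expansion rate (which is the approach Theta_dot mirrored in time)
        is fed to the excitatory pathway, since the drive must stay
        non-negative.
    constant_angular_velocity
        Theta grows linearly at ``theta_dot_const`` from ``theta0``;
        truncated if it would exceed pi.

    The lowpass recursions are initialised at the first raw sample,
    ``lp(0) = raw(0)``.
    """
    if spec.protocol == "approach":
        times, theta, theta_dot, truncated = _approach_arrays(spec)
    elif spec.protocol == "recession":
        app = replace(spec, protocol="approach")
        times, theta, theta_dot, truncated = _approach_arrays(app)
        theta = theta[::-1].copy()
        theta_dot = theta_dot[::-1].copy()  # mirrored magnitude of the expansion rate
    elif spec.protocol == "constant_angular_velocity":
        duration = 0.5 if spec.duration is None else spec.duration
        n = int(round(duration / spec.dt_stim))
        times = np.arange(n + 1) * spec.dt_stim
        theta = spec.theta0 + spec.theta_dot_const * times
        truncated = False
        if theta[-1] >= math.pi:
            keep = theta < math.pi
            times, theta = times[keep], theta[keep]
            truncated = True
        theta_dot = np.full_like(theta, spec.theta_dot_const)
    else:  # pragma: no cover - guarded by ApproachSpec validation
        raise ValueError(f"unknown protocol {spec.protocol!r}")

    theta_lp = lowpass(theta, zeta0)
    theta_dot_lp = lowpass(theta_dot, zeta1)
    return StimulusTrace(times=times, theta=theta, theta_dot=theta_dot,
                         theta_lp=theta_lp, theta_dot_lp=theta_dot_lp,
                         zeta0=zeta0, zeta1=zeta1, spec=spec, truncated=truncated)
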