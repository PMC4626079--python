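"""The eta-function baseline and the logarithmic-encoding / power-law analysis.

The phenomenological model of LGMD firing during an object approach is

    eta(t + delta) = Theta_dot(t) * exp(-alpha * Theta(t)),

an excitatory drive (rate of expansion) multiplied by an exponential
inhibition in angular size.  Its peak theory is exact: the peak precedes
the projected collision by ``alpha * (l/v)`` and always occurs at the
fixed angular size ``2*arctan(1/alpha)``, independent of the approach
kinematics.

One hypothesised biophysical reading is that the neuron encodes the two
terms logarithmically (``log Theta_dot - alpha*Theta = log eta``) and then
"undoes" the log with an approximate power law,

    g_p(t) = (log eta)**p,

optionally followed by a sigmoid readout S(x) = 1 / (1 + exp(-a*x)).  The
extrema of g_p fall at the same times as eta's peak, but the curves flatten
with growing p; the sigmoid restores a pronounced peak.  These operations
are implemented here as the comparison baseline for the membrane model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stimulus import StimulusTrace

__all__ = [
    "EtaParams",
    "DecodeParams",
    "eta_of_t",
    "eta_peak_theory",
    "g_p",
    "oriented_g_p",
    "sigmoid_decode",
    "exp_series_control",
    "rescale_to_range",
]

#: samples where the expansion rate falls below this are excluded from log-based ops
_THETA_DOT_FLOOR = 1e-12


@dataclass(frozen=True)
class EtaParams:
    """Parameters of the eta-function.

    alpha : inhibition scale per radian (> 0); typical fitted value 4.7.
    delta : neuronal latency (s); response at t reflects the stimulus at
            t + delta, so delta <= 0 shifts the curve later in time.
    amplitude_A, offset_o : affine scaling used when fitting rate data.
    """

    alpha: float = 4.7
    delta: float = 0.0
    amplitude_A: float = 1.0
    offset_o: float = 0.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass(frozen=True)
class DecodeParams:
    """Power-law order and sigmoid slope of the decoding stage."""

    exponent_p: int = 3
    sigmoid_a: float = 1.0
    offset_o: float = 0.0

    def __post_init__(self):
        if self.exponent_p < 1 or int(self.exponent_p) != self.exponent_p:
            raise ValueError("exponent_p must be a positive integer")
        if self.sigmoid_a <= 0:
            raise ValueError("sigmoid_a must be > 0")


def _raw_eta(trace: StimulusTrace, alpha: float) -> np.ndarray:
    # Stated in terms of the raw optical variables, not their lowpass versions.
    return trace.theta_dot * np.exp(-alpha * trace.theta)


def eta_of_t(trace: StimulusTrace, params: EtaParams = EtaParams()) -> np.ndarray:
    """Evaluate A * eta(t + delta) + o on the trace grid.

    The latency shift is applied by linear interpolation of the undelayed
    curve at ``t + delta`` (edge values held constant).  With the default
    A = 1, o = 0 the result is non-negative.
    """
    e = _raw_eta(trace, params.alpha)
    if params.delta != 0.0:
        e = np.interp(trace.times + params.delta, trace.times, e)
    return params.amplitude_A * e + params.offset_o


def eta_peak_theory(params: EtaParams, l_over_v: float) -> tuple[float, float]:
    """Analytic peak timing and peak angular size of the eta-function.

    Returns ``(T_rel, Theta_max)`` where ``T_rel = alpha * (l/v)`` is the
    time remaining to collision at the (undelayed) peak and
    ``Theta_max = 2*arctan(1/alpha)`` is the angular size at the peak,
    which does not depend on l/v.
    """
    if params.alpha <= 0:
        raise ValueError("peak theory requires alpha > 0")
    return params.alpha * l_over_v, 2.0 * math.atan(1.0 / params.alpha)


def g_p(trace: StimulusTrace, params: EtaParams, p: int) -> np.ndarray:
    """Power-law decoding g_p = (log Theta_dot - alpha*Theta)**p = (log eta)**p.

    Samples with an expansion rate below 1e-12 (log undefined or wildly
    negative) are returned as NaN rather than clipped; peak detection uses
    ``np.nanargmax`` downstream.
    """
    if p < 1 or int(p) != p:
        raise ValueError("p must be a positive integer")
    theta_dot = trace.theta_dot
    out = np.full(len(trace), np.nan)
    ok = theta_dot > _THETA_DOT_FLOOR
    out[ok] = (np.log(theta_dot[ok]) - params.alpha * trace.theta[ok]) ** p
    return out


def oriented_g_p(trace: StimulusTrace, params: EtaParams, p: int) -> np.ndarray:
    """g_p shifted/sign-flipped so its extremum is a non-negative maximum.

    Odd p: g_p has a maximum but is <= 0, so return ``g_p - min(g_p)``.
    Even p: g_p >= 0 has a *minimum* at eta's peak; return ``o - g_p`` with
    ``o = max(g_p)`` taken over the trace (up to t_c), converting the
    minimum into a maximum.
    """
    g = g_p(trace, params, p)
    if p % 2 == 1:
        return g - np.nanmin(g)
    return np.nanmax(g) - g


def sigmoid_decode(g: np.ndarray, a: float = 1.0) -> np.ndarray:
    """Sigmoid readout S(g) = 1 / (1 + exp(-a*g)), in (0, 1), monotone in g.

    NaNs (masked samples) propagate.
    """
    g = np.asarray(g, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-a * g))


def exp_series_control(trace: StimulusTrace, params: EtaParams, p_max: int = 35) -> np.ndarray:
    """Partial exponential series  sum_{p=1..p_max} (log eta)**p / p!.

    Converges to ``eta - 1`` as p_max grows; used as a sanity control that
    the family {g_p} carries enough information to rebuild eta itself.
    """
    log_eta = g_p(trace, params, 1)
    out = np.zeros_like(log_eta)
    term = np.ones_like(log_eta)
    for p in range(1, p_max + 1):
        term = term * log_eta / p
        out = out + term
    return out


def rescale_to_range(series: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Affine rescale of a series so its (nan-ignoring) range maps to [lo, hi]."""
    series = np.asarray(series, dtype=float)
    smin, smax = np.nanmin(series), np.nanmax(series)
    if smax == smin:
        return np.full_like(series, 0.5 * (lo + hi))
    return lo + (series - smin) * (hi - lo) / (smax - smin)
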