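"""Membrane-potential model of the LGMD with pooled noisy-threshold inhibition.

The neuron is a single RC compartment,

    C_m dV/dt = beta*(V_rest - V) + g_exc*(V_exc - V) + g_inh*(V_inh - V),

driven by the lowpass-filtered optical variables: excitation is the
filtered expansion rate, ``g_exc = theta_dot_lp``, and inhibition is the
pooled noisy-threshold input of :mod:`loomsim.pooling` evaluated on the
filtered angular size.  With ``V_inh ~ V_rest`` the inhibition is shunting
(silent): it raises the effective leak without hyperpolarizing, so it only
shows when excitation is present.  The half-wave-rectified potential
``[V]+`` stands in for the mean firing rate; no spiking mechanism is used.

Integration follows the reference procedure: classical RK4 with a 500 us
step, and ``n_relax`` extra RK steps with frozen conductances intercalated
at every stimulus sample (1 ms), driving V close to its instantaneous
equilibrium

    V_inf = (V_rest*beta + V_exc*g_exc + V_inh*g_inh) / (beta + g_exc + g_inh).

Because the ODE is linear in V for frozen conductances, an RK4 step is
exactly the affine map ``V -> V_inf + (V - V_inf) * r(z)`` with
``z = dt*(beta + g_exc + g_inh)/C_m`` and r the 4th-order Taylor polynomial
of exp(-z); the relaxation loop is applied through this closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .pooling import PoolParams, g_inh_expected
from .stimulus import ApproachSpec, StimulusTrace, make_stimulus

__all__ = [
    "NPsiParams",
    "ResponseTrace",
    "equilibrium_V",
    "rk4_step",
    "relax",
    "simulate",
    "simulate_spec",
    "log_compression_curve",
    "fit_log_compression",
]


@dataclass(frozen=True)
class NPsiParams:
    """Biophysical, noise and integration parameters of the membrane model.

    Defaults are the standard configuration: beta = 1 (leak conductance;
    with C_m = 1 the membrane time constant is 1/beta), V_rest = 1e-5,
    V_exc = 1, V_inh = -0.005 (shunting), inhibitory pool gamma = 500,
    sigma = 0.25, Delta0 = 0.9, N = 500, lowpass zeta0 = zeta1 = 0.95,
    RK4 step 500 us with 250 relaxation sub-steps per 1 ms stimulus sample.

    ``exc_noise`` optionally routes the excitatory pathway through its own
    noisy-threshold pool (same smoothing mechanism as inhibition); it is
    off by default, matching the standard model where only inhibition is
    noisy.
    """

    beta: float = 1.0
    C_m: float = 1.0
    V_rest: float = 1e-5
    V_exc: float = 1.0
    V_inh: float = -0.005
    pool: PoolParams = field(default_factory=PoolParams)
    zeta0: float = 0.95
    zeta1: float = 0.95
    dt_rk: float = 5e-4
    n_relax: int = 250
    exc_noise: Optional[PoolParams] = None
    noise_time: str = "frozen"

    def __post_init__(self):
        if not (self.V_inh <= self.V_rest <= self.V_exc):
            raise ValueError("require V_inh <= V_rest <= V_exc")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if self.dt_rk <= 0:
            raise ValueError("dt_rk must be > 0")
        if self.n_relax < 0:
            raise ValueError("n_relax must be >= 0")
        if self.noise_time not in ("frozen", "fresh"):
            raise ValueError("noise_time must be 'frozen' or 'fresh'")

    def with_sigma(self, sigma: float) -> "NPsiParams":
        """Copy with a different inhibitory noise level."""
        return replace(self, pool=replace(self.pool, noise_sigma=sigma))

    def with_pool(self, **kwargs) -> "NPsiParams":
        """Copy with modified inhibitory-pool fields."""
        return replace(self, pool=replace(self.pool, **kwargs))

    @classmethod
    def default_exc_noise(cls, sigma: float = 0.25) -> PoolParams:
        """Excitatory-pathway pool that reduces to g_exc ~ theta_dot_lp.

        Unit gain (channel average), zero threshold: the mean drive equals
        the filtered expansion rate plus pooled noise.
        """
        return PoolParams(n_channels_N=500, noise_sigma=sigma,
                          threshold_delta0=0.0, gain_gamma=1.0)


@dataclass
class ResponseTrace:
    """Simulated membrane potential, firing-rate proxy and peak timing."""

    times: np.ndarray
    V: np.ndarray
    rate: np.ndarray
    g_exc: np.ndarray
    g_inh: np.ndarray
    t_peak: float
    t_rel: Optional[float]
    t_collision: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times, "V": self.V, "rate": self.rate,
            "g_exc": self.g_exc, "g_inh": self.g_inh,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def equilibrium_V(g_exc, g_inh, params: NPsiParams):
    """Equilibrium potential, the conductance-weighted mean of reversals.

    Lies in [V_inh, V_exc] for any non-negative conductances and tends to
    V_exc (V_inh) as the excitatory (inhibitory) drive dominates.
    """
    g_exc = np.asarray(g_exc, dtype=float)
    g_inh = np.asarray(g_inh, dtype=float)
    num = params.V_rest * params.beta + params.V_exc * g_exc + params.V_inh * g_inh
    den = params.beta + g_exc + g_inh
    out = num / den
    return float(out) if out.ndim == 0 else out


def rk4_step(V: float, g_exc: float, g_inh: float, params: NPsiParams, dt: float) -> float:
    """One classical 4th-order Runge-Kutta update with frozen conductances."""
    def f(v):
        return (params.beta * (params.V_rest - v)
                + g_exc * (params.V_exc - v)
                + g_inh * (params.V_inh - v)) / params.C_m

    k1 = f(V)
    k2 = f(V + 0.5 * dt * k1)
    k3 = f(V + 0.5 * dt * k2)
    k4 = f(V + dt * k3)
    return V + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0


def _rk4_decay_factor(z):
    """Per-step contraction of RK4 on the linear membrane equation.

    4th-order Taylor polynomial of exp(-z), z = dt * g_total / C_m.
    """
    return 1.0 - z + z**2 / 2.0 - z**3 / 6.0 + z**4 / 24.0


def relax(V: float, g_exc: float, g_inh: float, params: NPsiParams,
          n_relax: Optional[int] = None) -> float:
    """Apply ``n_relax`` RK4 steps with frozen conductances.

    Uses the exact affine form of RK4 for the linear ODE, so the result is
    bit-identical to looping :func:`rk4_step`.  As n_relax grows the result
    converges geometrically to :func:`equilibrium_V`.
    """
    n = params.n_relax if n_relax is None else n_relax
    if n == 0:
        return V
    v_inf = equilibrium_V(g_exc, g_inh, params)
    z = params.dt_rk * (params.beta + g_exc + g_inh) / params.C_m
    return v_inf + (V - v_inf) * _rk4_decay_factor(z) ** n


def simulate(trace: StimulusTrace, params: NPsiParams = NPsiParams(),
             seed: int = 0) -> ResponseTrace:
    """Integrate the membrane model over a stimulus trace.

    Per stimulus sample: form the pooled inhibition from theta_lp and the
    excitation from theta_dot_lp (or the noisy excitatory pool if enabled),
    advance V by one RK4 step and then ``n_relax`` relaxation steps with the
    conductances frozen, and record.  V(0) = V_rest.

    Channel noise is drawn once per run by default (``noise_time="frozen"``):
    each of the N channels keeps its noise offset for the whole approach, so
    the pooled input is a random but temporally smooth function of the
    filtered angular size.  ``noise_time="fresh"`` redraws all N values at
    every stimulus sample instead (white noise in time); this adds
    sample-to-sample jitter to the response and noticeably biases the peak
    statistics.  Either way, noise is frozen during relaxation sub-steps.

    The peak time is the earliest global maximum of the rectified
    potential; for approach protocols ``t_rel = t_collision - t_peak``.
    """
    n = len(trace)
    if n == 0:
        raise ValueError("empty stimulus trace")
    rng = np.random.default_rng(seed)
    pool = params.pool

    def pooled(levels: np.ndarray, p: PoolParams) -> np.ndarray:
        if params.noise_time == "frozen":
            xi = rng.standard_normal(p.n_channels_N)[None, :]
        else:
            xi = rng.standard_normal((n, p.n_channels_N))
        drive = levels[:, None] + p.noise_sigma * xi - p.threshold_delta0
        return p.gain_gamma * np.maximum(drive, 0.0).mean(axis=1)

    g_inh = pooled(trace.theta_lp, pool)
    if params.exc_noise is None:
        g_exc = trace.theta_dot_lp.copy()
    else:
        g_exc = pooled(trace.theta_dot_lp, params.exc_noise)

    g_tot = params.beta + g_exc + g_inh
    v_inf = equilibrium_V(g_exc, g_inh, params)
    factor = _rk4_decay_factor(params.dt_rk * g_tot / params.C_m) ** (params.n_relax + 1)

    V = np.empty(n)
    v = params.V_rest
    for k in range(n):
        v = v_inf[k] + (v - v_inf[k]) * factor[k]
        V[k] = v

    rate = np.maximum(V, 0.0)
    i_peak = int(np.argmax(rate))  # earliest index on ties
    t_peak = float(trace.times[i_peak])
    t_c = trace.t_collision
    t_rel = (t_c - t_peak) if t_c is not None else None
    return ResponseTrace(times=trace.times, V=V, rate=rate, g_exc=g_exc,
                         g_inh=g_inh, t_peak=t_peak, t_rel=t_rel, t_collision=t_c)


def simulate_spec(spec: ApproachSpec, params: NPsiParams = NPsiParams(),
                  seed: int = 0) -> ResponseTrace:
    """Convenience: build the stimulus with the model's lowpass coefficients
    and simulate."""
    trace = make_stimulus(spec, zeta0=params.zeta0, zeta1=params.zeta1)
    return simulate(trace, params, seed=seed)


def log_compression_curve(params: NPsiParams, theta_const: float,
                          theta_dot_grid=None) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state V versus expansion rate at a fixed angular size.

    Excitation is swept over ``theta_dot_grid`` (default 0 to 50 in steps
    of 0.1) while the inhibitory drive is held at its expected pooled value
    for ``theta_const``.  The saturating approach toward V_exc makes the
    curve approximately logarithmic in the expansion rate — logarithmic
    compression emerges from the reversal potential, it is not built in.
    """
    if theta_dot_grid is None:
        theta_dot_grid = np.arange(0.0, 50.0 + 1e-9, 0.1)
    theta_dot_grid = np.asarray(theta_dot_grid, dtype=float)
    g_i = g_inh_expected(theta_const, params.pool)
    V = equilibrium_V(theta_dot_grid, np.full_like(theta_dot_grid, g_i), params)
    return theta_dot_grid, V


def fit_log_compression(theta_dot_grid: np.ndarray, V: np.ndarray,
                        exclude_below: float = 2.0) -> tuple[float, float, float]:
    """Fit V ~ a*log(theta_dot) + c, excluding the initial transient.

    Returns (a, c, r_squared).  Values with theta_dot <= ``exclude_below``
    are dropped before fitting.
    """
    keep = theta_dot_grid > exclude_below
    x = np.log(theta_dot_grid[keep])
    y = V[keep]
    a, c = np.polyfit(x, y, 1)
    pred = a * x + c
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot
    return float(a), float(c), float(r2)
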