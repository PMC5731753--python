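"""Firing-rate ring attractor with optional short-term synaptic plasticity.

The network is a fully connected ring of rate units tuned to a circular
feature (e.g. stimulus angle).  Excitatory signalling is carried by a single
slow NMDA-like gating variable per neuron,

    ds/dt = -s/tau_s + (1 - s) * gamma * f(I),

with the firing rate given by the smoothed threshold-linear transfer curve

    f(I) = (a*I - b) / (1 - exp(-d*(a*I - b))).

Recurrent coupling between neurons i and j has a Gaussian profile over the
difference of their preferred angles on top of uniform inhibition,

    g(dtheta) = J_minus + J_plus * exp(-dtheta^2 / (2 sigma^2)),

and each neuron receives an independent Ornstein-Uhlenbeck background
current.  A variant of the model endows every synapse with slow presynaptic
augmentation F (release-probability increment, time constant of seconds) and
faster vesicle depression D,

    dF/dt = alpha * (x - F) * f(I) - F / tau_F
    dD/dt = -p * f(I) * F * D + (1 - D) / tau_D,

which enter the gating dynamics multiplicatively,

    ds/dt = -s/tau_s + (1 - s) * gamma * (y + F) * D * f(I).

Because F and D depend only on the presynaptic rate, they are stored as one
scalar per presynaptic neuron (all efferent synapses of a neuron share them).

Units: currents in nA, rates in Hz, angles in degrees, time constants carried
in the units stated on each parameter field; all step functions take ``dt``
in milliseconds and convert internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .circular import wrap_deg

__all__ = [
    "NetworkParams",
    "PlasticityParams",
    "NetworkState",
    "ConnectivityMatrix",
    "transfer_rate",
    "build_connectivity",
    "recurrent_current",
    "step_gating",
    "step_plasticity",
    "step_noise",
    "ou_stationary_sd",
    "initial_state",
    "preferred_angles",
]


@dataclass(frozen=True)
class NetworkParams:
    """Biophysical constants of the rate network.

    Defaults are the fixed-synapse configuration (43.2° connectivity width,
    2.2 nA excitatory peak).  The plastic-synapse presets use broader or
    narrower tuning with the coupling peak balanced for persistent firing
    (see :mod:`serialbump.presets`).
    """

    n_neurons: int = 256
    gamma: float = 0.641          # gating gain, dimensionless
    tau_s: float = 60.0           # NMDA gating time constant, ms
    gain_a: float = 270.0         # transfer gain, Hz/nA
    thresh_b: float = 108.0       # transfer threshold, Hz
    curv_d: float = 0.154         # transfer curvature, s
    sigma_conn: float = 43.2      # connectivity Gaussian width, deg
    J_plus: float = 2.2           # excitatory coupling peak, nA
    J_minus: float = -0.5         # uniform inhibitory coupling, nA
    I0: float = 0.3297            # background-noise mean, nA
    tau_n: float = 2.0            # noise time constant, ms
    sigma_n: float = 0.009        # noise magnitude, nA
    dt: float = 0.5               # integration step, ms

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        for name in ("tau_s", "tau_n", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma_conn <= 0:
            raise ValueError("sigma_conn must be > 0")
        if self.J_plus <= 0:
            raise ValueError("J_plus must be > 0 (excitatory role)")
        if self.J_minus > 0:
            raise ValueError("J_minus must be <= 0 (inhibitory role)")

    def with_(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PlasticityParams:
    """Short-term augmentation/depression constants.

    Defaults are the plastic-synapse working-memory configuration; the
    sensory-adaptation variant overrides tau_F=3.8, p_release=0.006,
    x_ceiling=0.014, y_base=0.986.
    """

    enabled: bool = True
    alpha: float = 0.015          # augmentation rate, 1/(Hz*s)
    x_ceiling: float = 0.008      # augmentation target (upper bound on F)
    tau_F: float = 4.2            # augmentation decay, s
    p_release: float = 0.01       # depression rate, 1/(Hz*s)
    tau_D: float = 1.0            # depression recovery, s
    y_base: float = 0.992         # baseline release probability

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_ceiling < 1.0):
            raise ValueError("x_ceiling must be in [0, 1)")
        if not (0.0 < self.y_base <= 1.0):
            raise ValueError("y_base must be in (0, 1]")
        # total release probability y + F is bounded by y + x_ceiling
        if self.y_base + self.x_ceiling > 1.0 + 1e-12:
            raise ValueError("y_base + x_ceiling must not exceed 1")
        if self.tau_F <= 0 or self.tau_D <= 0:
            raise ValueError("plasticity time constants must be > 0")

    def with_(self, **kwargs) -> "PlasticityParams":
        return replace(self, **kwargs)


@dataclass
class NetworkState:
    """Dynamical variables of the network.

    Arrays have shape (n_neurons,) for a single simulation, or
    (batch, n_neurons) when many simulations are integrated side by side.
    F and D are per-presynaptic-neuron scalars.
    """

    preferred_angles: np.ndarray
    s: np.ndarray
    F: np.ndarray
    D: np.ndarray
    I_noise: np.ndarray
    t_ms: float = 0.0


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Effective coupling matrix (nA), already divided by n_neurons.

    ``weights[i, j]`` is the coupling from presynaptic neuron j onto
    postsynaptic neuron i.  Symmetric and circulant on the ring.
    """

    weights: np.ndarray


def preferred_angles(n_neurons: int) -> np.ndarray:
    """Preferred angles uniformly tiling [0°, 360°)."""
    return np.arange(n_neurons) * (360.0 / n_neurons)


def transfer_rate(I_total, params: NetworkParams):
    """Firing rate f(I) of the smoothed threshold-linear transfer curve.

    Continuous at a*I - b = 0 where the formula has a removable singularity
    with limit 1/d; strictly increasing and non-negative everywhere.
    """
    I_arr = np.asarray(I_total, dtype=float)
    if not np.all(np.isfinite(I_arr)):
        raise ValueError("transfer_rate requires finite input current")
    x = params.gain_a * I_arr - params.thresh_b
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        den = -np.expm1(-params.curv_d * x)
        out = np.where(x == 0.0, 1.0 / params.curv_d, x / den)
    # deep below threshold 1 - exp(-d*x) overflows to -inf; the limit is 0
    out = np.where(np.isfinite(out), out, 0.0)
    if np.isscalar(I_total) or np.ndim(I_total) == 0:
        return float(out)
    return out


def build_connectivity(params: NetworkParams) -> ConnectivityMatrix:
    """Gaussian-profile ring coupling, normalized by the network size.

    The raw profile J_minus + J_plus*exp(-dtheta^2/(2 sigma^2)) over the
    minimal circular angle difference is divided by n_neurons so that the
    recurrent current is the population mean of coupling-weighted gating
    variables; this keeps the current on the nA scale of the printed
    parameters at any network size.
    """
    theta = preferred_angles(params.n_neurons)
    dtheta = wrap_deg(theta[:, None] - theta[None, :])
    raw = params.J_minus + params.J_plus * np.exp(
        -(dtheta ** 2) / (2.0 * params.sigma_conn ** 2)
    )
    return ConnectivityMatrix(weights=raw / params.n_neurons)


def recurrent_current(s: np.ndarray, conn: ConnectivityMatrix) -> np.ndarray:
    """Recurrent current I_r,i = sum_j g_ij s_j (nA).

    ``s`` may be (n,) or (batch, n).  Short-term plasticity enters through
    the gating dynamics, not through this sum.
    """
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != conn.weights.shape[1]:
        raise ValueError(
            f"gating vector of length {s.shape[-1]} does not match "
            f"connectivity of size {conn.weights.shape[1]}"
        )
    return s @ conn.weights.T


def step_gating(
    s: np.ndarray,
    rates: np.ndarray,
    params: NetworkParams,
    dt_ms: float,
    plasticity: Optional[PlasticityParams] = None,
    F: Optional[np.ndarray] = None,
    D: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One explicit Euler step of the NMDA gating variable.

    With plasticity enabled the effective release probability (y + F) * D of
    the presynaptic neuron multiplies the rate-driven opening term.
    """
    dt = dt_ms * 1e-3
    tau_s = params.tau_s * 1e-3
    if plasticity is not None and plasticity.enabled:
        drive = params.gamma * (plasticity.y_base + F) * D * rates
    else:
        drive = params.gamma * rates
    return s + dt * (-s / tau_s + (1.0 - s) * drive)


def step_plasticity(
    F: np.ndarray,
    D: np.ndarray,
    rates: np.ndarray,
    plasticity: PlasticityParams,
    dt_ms: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit Euler step of augmentation F and depression D.

    Both depend only on the presynaptic rate of the same neuron.
    """
    if not plasticity.enabled:
        raise ValueError("step_plasticity called with plasticity disabled")
    dt = dt_ms * 1e-3
    F_new = F + dt * (
        plasticity.alpha * (plasticity.x_ceiling - F) * rates - F / plasticity.tau_F
    )
    D_new = D + dt * (
        -plasticity.p_release * rates * F * D + (1.0 - D) / plasticity.tau_D
    )
    return F_new, D_new


def ou_stationary_sd(params: NetworkParams) -> float:
    """Stationary standard deviation of the background current (nA).

    The noise equation tau_n * dI/dt = -(I - I0) + tau_n * sigma_n * eta(t)
    is integrated with the Euler-Maruyama increment
    sigma_n * sqrt(dt / tau_n) * z (the convention of standard reduced-model
    implementations), equivalent to the SDE
    dI = -(I - I0)/tau_n dt + sigma_n/sqrt(tau_n) dW, whose stationary
    distribution is Gaussian with mean I0 and sd sigma_n / sqrt(2).
    """
    return params.sigma_n / np.sqrt(2.0)


def step_noise(
    I_noise: np.ndarray,
    params: NetworkParams,
    dt_ms: float,
    z: np.ndarray,
) -> np.ndarray:
    """Exact-update Ornstein-Uhlenbeck step of the background current.

    ``z`` are standard-normal draws of the same shape as ``I_noise``.  The
    exact discretization is used so that steps comparable to tau_n remain
    stable; it matches the Euler-Maruyama convention documented in
    :func:`ou_stationary_sd` in mean, autocorrelation and stationary
    variance.
    """
    mu = np.exp(-dt_ms / params.tau_n)
    amp = ou_stationary_sd(params) * np.sqrt(1.0 - mu * mu)
    return params.I0 + (I_noise - params.I0) * mu + amp * z


def initial_state(
    params: NetworkParams,
    batch: Optional[int] = None,
) -> NetworkState:
    """State at t = 0: closed gates, unaugmented synapses, full vesicle pool.

    The noise current starts at its stationary mean I0.
    """
    n = params.n_neurons
    shape = (n,) if batch is None else (batch, n)
    return NetworkState(
        preferred_angles=preferred_angles(n),
        s=np.zeros(shape),
        F=np.zeros(shape),
        D=np.ones(shape),
        I_noise=np.full(shape, params.I0),
        t_ms=0.0,
    )
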