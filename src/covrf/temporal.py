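"""Time-causal temporal scale-space kernels and neuron dynamics.

The temporal half of the receptive-field model.  Truncated exponential
kernels h_exp(t; mu) = (1/mu) exp(-t/mu) for t > 0 are the canonical
time-causal temporal smoothing kernels; convolving an input current with
h_exp is exactly the leaky integrator mu * du/dt = -u + I.  A bank of K such
filters with time constants on a geometric series tau_k = c^(2(k-K)) tau_max
(tau = mu^2) covers logarithmically distributed temporal scales and is
covariant to temporal scaling of the input.

The leaky integrate-and-fire (LIF) neuron adds a Heaviside threshold and a
membrane reset; the Spike Response Model (SRM) closed form replaces the
instantaneous reset by a linearized reset kernel
eta(t - t_f; mu_r) = -theta_thr * exp(-(t - t_f)/mu_r), which recovers the
instantaneous reset in the limit mu_r -> 0.

All discrete-time updates use the exponential-Euler scheme

    u <- u * exp(-dt/mu) + (1 - exp(-dt/mu)) * I,

which is exact for piecewise-constant input and unconditionally stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TemporalScaleBank",
    "LIFParams",
    "LIFState",
    "geometric_time_constants",
    "log_time_constants",
    "h_exp",
    "li_evolve",
    "lif_step",
    "lif_run",
    "srm_response",
]


@dataclass(frozen=True)
class TemporalScaleBank:
    """K temporal scales tau_k = mu_k^2 on a geometric series."""

    K: int
    c: float
    tau_max: float
    taus: np.ndarray = field(repr=False)
    mus: np.ndarray = field(repr=False)

    @property
    def mu_min(self) -> float:
        return float(self.mus[0])

    @property
    def mu_max(self) -> float:
        return float(self.mus[-1])


def geometric_time_constants(K: int, c: float, tau_max: float) -> TemporalScaleBank:
    """Temporal scales tau_k = c^(2(k-K)) * tau_max for k = 1..K.

    ``c`` is the distribution parameter (default sqrt(2) elsewhere in the
    package); time constants are mu_k = sqrt(tau_k).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if c <= 1:
        raise ValueError("distribution parameter c must exceed 1")
    if tau_max <= 0:
        raise ValueError("tau_max must be positive")
    k = np.arange(1, K + 1)
    taus = c ** (2.0 * (k - K)) * tau_max
    return TemporalScaleBank(K=K, c=float(c), tau_max=float(tau_max),
                             taus=taus, mus=np.sqrt(taus))


def log_time_constants(K: int, mu_min: float = 1.0, mu_max: float = 4.0) -> TemporalScaleBank:
    """Endpoint-pinned variant: K time constants log-spaced on [mu_min, mu_max].

    The common ratio is (mu_max/mu_min)^(1/(K-1)), so for K = 4 on [1, 4] the
    constants are {1, 4^(1/3), 4^(2/3), 4}.  This is the initialization used
    for the temporal scale channels of the tracking network.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (0 < mu_min <= mu_max):
        raise ValueError("need 0 < mu_min <= mu_max")
    if K == 1:
        mus = np.array([mu_max])
        c = np.sqrt(2.0)
    else:
        mus = np.geomspace(mu_min, mu_max, K)
        c = (mu_max / mu_min) ** (1.0 / (K - 1))
    return TemporalScaleBank(K=K, c=float(c), tau_max=float(mu_max**2),
                             taus=mus**2, mus=mus)


def h_exp(t, mu: float):
    """Truncated exponential kernel (1/mu) exp(-t/mu) for t > 0, else 0."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, np.exp(-np.minimum(t, 700 * mu) / mu) / mu, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LIFParams:
    """Parameters of the leaky integrate-and-fire neuron.

    mu: membrane time constant (timesteps); theta_thr / theta_reset: firing
    threshold and reset potential; mu_r: reset time constant (0 means the
    instantaneous LIF reset); dt: integration step.
    """

    mu: float = 2.0
    theta_thr: float = 1.0
    theta_reset: float = 0.0
    mu_r: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.mu_r < 0:
            raise ValueError("mu_r must be non-negative")
        if not self.theta_thr > self.theta_reset:
            raise ValueError("theta_thr must exceed theta_reset")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class LIFState:
    """Per-unit membrane potential, last spike time and spike output."""

    u: np.ndarray
    t_f: np.ndarray  # last spike time; -inf when the unit never spiked
    z: np.ndarray  # binary spike output of the last step
    t: float = 0.0  # current simulation time

    @classmethod
    def zeros(cls, shape=()) -> "LIFState":
        return cls(
            u=np.zeros(shape),
            t_f=np.full(shape, -np.inf),
            z=np.zeros(shape),
            t=0.0,
        )


def li_evolve(signal, mu: float, dt: float = 1.0, u0=0.0) -> np.ndarray:
    """Leaky integrator mu * du/dt = -u + I by exponential Euler.

    Returns the potential after each input step: out[i] is u((i+1) * dt)
    starting from u(0) = u0 with I held at signal[i] during step i.  For an
    impulse response, set u0 to the impulse amplitude and feed zeros.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= mu:
        warnings.warn(
            "dt >= mu: the leaky integrator is heavily undersampled",
            stacklevel=2,
        )
    from scipy.signal import lfilter

    signal = np.asarray(signal, dtype=float)
    decay = np.exp(-dt / mu)
    # first-order IIR recurrence u_i = decay * u_{i-1} + (1 - decay) * x_i
    zi = np.array([decay * float(np.asarray(u0))])
    out, _ = lfilter([1.0 - decay], [1.0, -decay], signal, zi=zi)
    return out


def lif_step(state: LIFState, inp, params: LIFParams) -> LIFState:
    """Advance a LIF population by one integration step.

    Integrates the membrane by exponential Euler, emits z = 1 where the
    potential crosses theta_thr, and applies the instantaneous jump to
    theta_reset (recording the spike time t_f) at those units.
    """
    decay = np.exp(-params.dt / params.mu)
    u = state.u * decay + (1.0 - decay) * np.asarray(inp, dtype=float)
    t = state.t + params.dt
    z = (u >= params.theta_thr).astype(float)
    u = np.where(z > 0, params.theta_reset, u)
    t_f = np.where(z > 0, t, state.t_f)
    return LIFState(u=u, t_f=t_f, z=z, t=t)


def lif_run(signal, params: LIFParams, u0=0.0):
    """Run a LIF neuron over a 1-D input sequence.

    With mu_r == 0 the reset is the instantaneous jump of :func:`lif_step`.
    With mu_r > 0 the reset is the linearized SRM mechanism: each spike adds
    a reset trace -theta_thr * exp(-(t - t_f)/mu_r) and the threshold is
    applied to membrane-plus-trace, leaving the linear membrane integration
    untouched.  Threshold crossings are located inside the integration step
    by linear interpolation, and the reset trace of the SRM branch is
    started at the interpolated crossing time, which keeps the per-spike
    timing error at O(dt^2) instead of O(dt).

    Returns ``(potentials, spikes, spike_times)`` where potentials is the
    effective (reset-corrected) membrane trace.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    dt = params.dt
    decay = np.exp(-dt / params.mu)
    pot = np.empty(n)
    spikes = np.zeros(n)
    times = []
    if params.mu_r == 0.0:
        u = float(u0)
        prev = u
        for i in range(n):
            u = u * decay + (1.0 - decay) * signal[i]
            if u >= params.theta_thr:
                spikes[i] = 1.0
                den = u - prev
                frac = (params.theta_thr - prev) / den if den > 0 else 1.0
                times.append((i + min(max(frac, 0.0), 1.0)) * dt)
                u = params.theta_reset
            pot[i] = u
            prev = u
    else:
        decay_r = np.exp(-dt / params.mu_r)
        u = float(u0)
        r = 0.0
        prev_tot = u
        for i in range(n):
            u = u * decay + (1.0 - decay) * signal[i]
            r = r * decay_r
            tot = u + r
            if tot >= params.theta_thr:
                spikes[i] = 1.0
                den = tot - prev_tot
                frac = (params.theta_thr - prev_tot) / den if den > 0 else 1.0
                frac = min(max(frac, 0.0), 1.0)
                times.append((i + frac) * dt)
                # reset trace decays from the interpolated crossing time
                r -= params.theta_thr * np.exp(-(1.0 - frac) * dt / params.mu_r)
                tot = u + r
            pot[i] = tot
            prev_tot = tot
    return pot, spikes, np.asarray(times)


def srm_response(signal, t_f, params: LIFParams) -> np.ndarray:
    """Spike Response Model membrane trace with a single previous spike.

    z(t) = -theta_thr * exp(-(t - t_f)/mu_r) * [t >= t_f] + (kappa * I)(t)
    with membrane filter kappa = h_exp(.; mu), evaluated on the same
    discrete grid as :func:`li_evolve`.  ``t_f = None`` (or -inf) drops the
    reset term, reducing to the leaky integrator.
    """
    if params.mu_r <= 0:
        raise ValueError("srm_response requires mu_r > 0")
    signal = np.asarray(signal, dtype=float)
    conv = li_evolve(signal, params.mu, params.dt)
    t = (np.arange(1, signal.shape[0] + 1)) * params.dt
    if t_f is None or t_f == -np.inf:
        return conv
    reset = np.where(
        t >= t_f, -params.theta_thr * np.exp(-(t - t_f) / params.mu_r), 0.0
    )
    return conv + reset
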