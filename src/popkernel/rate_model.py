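"""Mean-field firing-rate model of a QIF population, and its brain signal.

The two-dimensional rate model

    τ² ṙ = Δ/π + 2 τ v r
    τ v̇ = v² + J τ r + η + I(t) − π² τ² r²

is the exact macroscopic limit of an all-to-all coupled population of
quadratic integrate-and-fire neurons whose quenched inputs follow a
Lorentzian distribution of half-width Δ centered at η; J is the recurrent
coupling and I(t) an external stimulus.  For suitable parameters the model
is bistable and a transient square-pulse stimulus switches it between a
low- and a high-activity branch.

Internally r carries units of ms⁻¹ (with τ in ms); traces report s⁻¹.
The population rate can be converted into an LFP/EEG prediction by scaling
it to expected spikes per kernel time step for a presynaptic population of
size N_pre and convolving with a population kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_engine import SignalSet, kernel_approx_signal

__all__ = [
    "RateModelParams",
    "RateTrace",
    "BISTABLE_SWITCH_PRESET",
    "BISTABLE_SWITCH_PRESET_AS_PRINTED",
    "integrate_rate_model",
    "steady_state_residual",
    "rate_to_brain_signal",
]


@dataclass
class SquarePulse:
    """Piecewise-constant stimulus I(t)."""

    amplitude: float = 0.0
    onset: float = 0.0      # ms
    duration: float = 0.0   # ms

    def __call__(self, t: float) -> float:
        if self.amplitude and self.onset <= t < self.onset + self.duration:
            return self.amplitude
        return 0.0


@dataclass
class RateModelParams:
    tau: float = 100.0       # ms
    delta: float = 2.0       # Lorentzian half-width
    eta: float = -10.0       # input center
    coupling: float = 15.0 * np.sqrt(2.0)  # J
    stimulus: SquarePulse = field(default_factory=SquarePulse)
    dt: float = 0.1          # ms (default tau/1000)
    t_total: float = 6000.0  # ms
    r0: float = 0.0          # ms^-1
    v0: float = 0.0
    pre_relax: float = 1000.0  # ms settled at I=0 before t = 0
    v_bound: float = 1e6     # divergence guard

    def __post_init__(self):
        if self.tau <= 0 or self.delta < 0 or self.r0 < 0:
            raise ValueError("need tau > 0, delta >= 0, r0 >= 0")
        if self.dt > self.tau / 100:
            raise ValueError("dt too coarse; need dt <= tau/100")


# Fig-style bistable switching protocol.  The coupling of the bistable
# regime scales with the heterogeneity as J = 15·sqrt(Δ); a variant with
# J = 15·Δ is kept as a preset for comparison.
BISTABLE_SWITCH_PRESET = RateModelParams(
    tau=100.0, delta=2.0, eta=-10.0, coupling=15.0 * np.sqrt(2.0),
    stimulus=SquarePulse(amplitude=4.0, onset=1000.0, duration=3000.0),
    t_total=6000.0)
BISTABLE_SWITCH_PRESET_AS_PRINTED = replace(
    BISTABLE_SWITCH_PRESET, coupling=15.0 * 2.0)


@dataclass
class RateTrace:
    t: np.ndarray       # ms
    r: np.ndarray       # s^-1
    v: np.ndarray       # model units

    def __post_init__(self):
        if np.any(self.r < -1e-12):
            raise ValueError("rate trace must be nonnegative")


def _derivs(r, v, p: RateModelParams, stim: float):
    tau = p.tau
    dr = (p.delta / (np.pi * tau) + 2.0 * r * v) / tau
    dv = (v * v + p.coupling * tau * r + p.eta + stim
          - (np.pi * tau * r) ** 2) / tau
    return dr, dv


def integrate_rate_model(p: RateModelParams) -> RateTrace:
    """Fixed-step 4th-order Runge–Kutta integration.

    The state is first relaxed for ``pre_relax`` ms with no stimulus so
    that t = 0 starts on an attractor branch; the stimulus clock runs from
    t = 0.  Divergence (|v| exceeding ``v_bound``) raises a RuntimeError
    naming the failing time step.
    """
    n_pre = int(round(p.pre_relax / p.dt))
    n_main = int(round(p.t_total / p.dt))
    r, v = p.r0, p.v0
    out_t = np.arange(n_main + 1) * p.dt
    out_r = np.empty(n_main + 1)
    out_v = np.empty(n_main + 1)

    def step(r, v, t_stim):
        h = p.dt
        s1 = p.stimulus(t_stim) if t_stim is not None else 0.0
        # piecewise-constant stimulus: evaluate once per step
        k1r, k1v = _derivs(r, v, p, s1)
        k2r, k2v = _derivs(r + h / 2 * k1r, v + h / 2 * k1v, p, s1)
        k3r, k3v = _derivs(r + h / 2 * k2r, v + h / 2 * k2v, p, s1)
        k4r, k4v = _derivs(r + h * k3r, v + h * k3v, p, s1)
        rn = r + h / 6 * (k1r + 2 * k2r + 2 * k3r + k4r)
        vn = v + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        return max(rn, 0.0), vn

    for i in range(n_pre):
        r, v = step(r, v, None)
        if not np.isfinite(v) or abs(v) > p.v_bound:
            raise RuntimeError(
                f"rate model diverged during pre-relaxation step {i}")
    out_r[0], out_v[0] = r, v
    for i in range(n_main):
        r, v = step(r, v, i * p.dt)
        if not np.isfinite(v) or abs(v) > p.v_bound:
            raise RuntimeError(
                f"rate model diverged at t = {i * p.dt:.3f} ms")
        out_r[i + 1], out_v[i + 1] = r, v
    return RateTrace(t=out_t, r=out_r * 1e3, v=out_v)


def steady_state_residual(trace: RateTrace, tau: float, delta: float,
                          at: int = -1) -> float:
    """|2 τ v r + Δ/π| at a converged state (internal ms⁻¹ rate units)."""
    r_ms = trace.r[at] * 1e-3
    return float(abs(2.0 * tau * trace.v[at] * r_ms + delta / np.pi))


def rate_to_brain_signal(trace: RateTrace, bank_or_kernel, n_presyn: int,
                         dt_kernel: float | None = None,
                         eeg: bool = False) -> SignalSet:
    """Convolve a rate trace with a population kernel.

    The rate (s⁻¹, per neuron) is converted to expected spikes per kernel
    time step for a presynaptic population of ``n_presyn`` neurons,
    R(t) = r(t)·10⁻³·dt·N_pre, resampled onto the kernel grid, and
    convolved with the population kernel.  This is the same computation as
    :func:`popkernel.signal_engine.kernel_approx_signal` applied to a
    binned spike ensemble.
    """
    from .kernel_builder import KernelBank

    if isinstance(bank_or_kernel, KernelBank):
        dt_kernel = bank_or_kernel.dt
    elif dt_kernel is None:
        raise ValueError("dt_kernel required with a bare kernel array")
    t_grid = np.arange(0.0, trace.t[-1], dt_kernel)
    r_interp = np.interp(t_grid, trace.t, trace.r)
    spikes_per_bin = r_interp * 1e-3 * dt_kernel * n_presyn
    return kernel_approx_signal(bank_or_kernel, spikes_per_bin,
                                dt=dt_kernel, eeg=eeg)
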