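"""Analytical prediction of the kernel-method approximation error.

For kernels drawn independently from a common distribution and spike trains
with population-averaged autocovariance A_s(τ) and cross-covariance C_s(τ),
the expected squared error of the population-kernel prediction is

    ⟨E²(r)⟩ = (N_pre − 1) ∫ dτ (A_k(r,τ) − C_k(r,τ)) (A_s(τ) − C_s(τ)),

with A_k / C_k the lag-integrated auto- and cross-correlations of the
single-cell kernels.  The expected squared *relative* error divides by the
expected ground-truth variance

    ⟨Var V(r)⟩ = N_pre ∫ dτ A_k A_s + N_pre (N_pre − 1) ∫ dτ C_k C_s.

The error vanishes when all kernels are equal (A_k = C_k) or all trains are
fully correlated (A_s = C_s).  For Multiple-Interaction-Process input the
spike covariances are delta functions, A_s = ν δ(τ), C_s = f² ν δ(τ), and
the lag integrals collapse exactly onto the zero-lag kernel correlations —
the module applies this analytically rather than approximating a delta on
the lag grid.

All lag integrals are discrete sums times the grid spacing; time is in ms
so rates enter in spikes/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel_builder import KernelBank, ToyKernelParams, toy_waveform
from .spike_models import (
    SpikeCovariances,
    SpikeTrainSet,
    estimate_spike_covariances,
)

__all__ = [
    "KernelCorrelations",
    "TheoryErrorReport",
    "DeltaCovariance",
    "mip_covariance",
    "poisson_covariance",
    "kernel_correlations",
    "toy_kernel_correlations",
    "expected_squared_error",
    "expected_relative_error",
    "expected_ground_truth_variance",
    "kout_decomposition",
    "estimate_impulse_response_statistics",
    "estimate_for_theory",
]


@dataclass
class KernelCorrelations:
    """Per-channel kernel auto-/cross-correlations on a symmetric lag grid.

    ``a_k`` and ``c_k`` have shape (n_channels, n_lags) in signal²·ms: the
    inner integral over τ' is a discrete sum times dt.
    """

    lags: np.ndarray
    a_k: np.ndarray
    c_k: np.ndarray
    dt: float
    n_kernels: int = 0

    @property
    def zero_index(self) -> int:
        return int(np.argmin(np.abs(self.lags)))

    def at_zero(self):
        """(A_k(r, 0), C_k(r, 0)) per channel."""
        z = self.zero_index
        return self.a_k[:, z], self.c_k[:, z]


@dataclass
class DeltaCovariance:
    """Analytic delta-shaped spike covariances A_s = a δ, C_s = c δ.

    ``a_mass`` and ``c_mass`` are the delta masses in spikes/ms.
    """

    a_mass: float
    c_mass: float


def mip_covariance(rate: float, f: float) -> DeltaCovariance:
    """Exact MIP spike covariances: A_s = ν δ(τ), C_s = f² ν δ(τ).

    ``rate`` in s^-1 (converted to spikes/ms internally).
    """
    nu = rate * 1e-3
    return DeltaCovariance(a_mass=nu, c_mass=f ** 2 * nu)


def poisson_covariance(rate: float) -> DeltaCovariance:
    return mip_covariance(rate, 0.0)


@dataclass
class TheoryErrorReport:
    """Expected errors per channel, with the predicted signal variance."""

    e2: np.ndarray
    e_rel2: np.ndarray
    var_v: np.ndarray
    mode: str = "max-over-channels"
    undefined: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def e(self) -> np.ndarray:
        return np.sqrt(self.e2)

    @property
    def e_rel(self) -> np.ndarray:
        return np.sqrt(self.e_rel2)


# ---------------------------------------------------------------------------
# kernel statistics
# ---------------------------------------------------------------------------

def _select(bank: KernelBank, eeg: bool) -> np.ndarray:
    if eeg:
        if bank.eeg_kernels is None:
            raise ValueError("bank has no EEG kernels")
        return bank.eeg_kernels[:, None, :]
    return bank.kernels


def kernel_correlations(bank: KernelBank, eeg: bool = False
                        ) -> KernelCorrelations:
    """Plug-in estimate of A_k and C_k from a finite kernel bank.

    A_k averages the lagged self-products over kernels; C_k averages over
    all ordered distinct pairs (computed from the correlation of the summed
    kernel minus the self terms).
    """
    k = _select(bank, eeg)
    n, n_ch, n_lag = k.shape
    if n < 2:
        raise ValueError("cross-correlation C_k needs at least two kernels")
    nfft = int(2 ** np.ceil(np.log2(2 * n_lag)))
    fk = np.fft.rfft(k, nfft, axis=2)
    auto = np.fft.irfft((fk * np.conj(fk)).sum(axis=0), nfft, axis=1)
    fs = fk.sum(axis=0)
    allsum = np.fft.irfft(fs * np.conj(fs), nfft, axis=1)
    cross = allsum - auto

    def arrange(x):
        return np.concatenate([x[:, nfft - (n_lag - 1):], x[:, :n_lag]],
                              axis=1)

    lags = np.arange(-(n_lag - 1), n_lag) * bank.dt
    a_k = arrange(auto) / n * bank.dt
    c_k = arrange(cross) / (n * (n - 1)) * bank.dt
    return KernelCorrelations(lags=lags, a_k=a_k, c_k=c_k, dt=bank.dt,
                              n_kernels=n)


def toy_kernel_correlations(params: ToyKernelParams) -> KernelCorrelations:
    """Exact A_k, C_k for the amplitude-only toy kernel distribution.

    With amplitudes A ~ Normal(μ, σ) multiplying a shared waveform w:
    A_k(τ) = (μ² + σ²) W(τ) and C_k(τ) = μ² W(τ), with W the lag
    autocorrelation of w.
    """
    w = toy_waveform(params)
    n_lag = w.size
    nfft = int(2 ** np.ceil(np.log2(2 * n_lag)))
    fw = np.fft.rfft(w, nfft)
    acf = np.fft.irfft(fw * np.conj(fw), nfft)
    acf = np.concatenate([acf[nfft - (n_lag - 1):], acf[:n_lag]])
    lags = np.arange(-(n_lag - 1), n_lag) * params.dt
    big_w = acf * params.dt
    mu, sd = params.amp_mean, params.amp_sd
    return KernelCorrelations(lags=lags, a_k=((mu ** 2 + sd ** 2)
                                              * big_w)[None, :],
                              c_k=(mu ** 2 * big_w)[None, :],
                              dt=params.dt, n_kernels=0)


# ---------------------------------------------------------------------------
# expected errors
# ---------------------------------------------------------------------------

def _lag_overlap(kc: KernelCorrelations, sc: SpikeCovariances):
    """Spike covariances resampled/trimmed onto the kernel lag grid.

    Covariances outside the estimated lag window are taken as zero (they
    decay; the window must cover the kernel correlation support).
    """
    a_s = np.interp(kc.lags, sc.lags, sc.a_s, left=0.0, right=0.0)
    c_s = np.interp(kc.lags, sc.lags, sc.c_s, left=0.0, right=0.0)
    return a_s, c_s


def expected_squared_error(kc: KernelCorrelations, sc, n_pre: int
                           ) -> TheoryErrorReport:
    """⟨E²(r)⟩ = (N−1) ∫ dτ (A_k − C_k)(A_s − C_s), per channel.

    ``sc`` is either an estimated :class:`SpikeCovariances` (numeric lag
    integral) or a :class:`DeltaCovariance` (delta masses applied exactly
    at zero lag).
    """
    if isinstance(sc, DeltaCovariance):
        a0, c0 = kc.at_zero()
        e2 = (n_pre - 1) * (sc.a_mass - sc.c_mass) * (a0 - c0)
    else:
        a_s, c_s = _lag_overlap(kc, sc)
        e2 = (n_pre - 1) * ((kc.a_k - kc.c_k) @ (a_s - c_s)) * kc.dt
    e2 = np.maximum(e2, 0.0)
    var_v = expected_ground_truth_variance(kc, sc, n_pre)
    return TheoryErrorReport(e2=e2, e_rel2=np.full_like(e2, np.nan),
                             var_v=var_v,
                             provenance={"n_pre": n_pre})


def expected_ground_truth_variance(kc: KernelCorrelations, sc, n_pre: int
                                   ) -> np.ndarray:
    """⟨Var V(r)⟩ = N ∫ A_k A_s + N(N−1) ∫ C_k C_s, per channel."""
    if isinstance(sc, DeltaCovariance):
        a0, c0 = kc.at_zero()
        return n_pre * sc.a_mass * a0 + n_pre * (n_pre - 1) * sc.c_mass * c0
    a_s, c_s = _lag_overlap(kc, sc)
    return (n_pre * (kc.a_k @ a_s)
            + n_pre * (n_pre - 1) * (kc.c_k @ c_s)) * kc.dt


def expected_relative_error(kc: KernelCorrelations, sc, n_pre: int,
                            mode: str = "max-over-channels"
                            ) -> TheoryErrorReport:
    """⟨E_rel²(r)⟩: expected squared error over expected signal variance.

    In ``max-over-channels`` mode the denominator is the variance of the
    channel where the predicted variance is largest (mirroring the
    empirical normalization for laminar recordings); ``per-signal``
    normalizes channel by channel.
    """
    rep = expected_squared_error(kc, sc, n_pre)
    var_v = rep.var_v
    if mode == "max-over-channels":
        denom = np.full_like(var_v, var_v.max())
    elif mode == "per-signal":
        denom = var_v
    else:
        raise ValueError(f"unknown mode {mode!r}")
    undefined = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        e_rel2 = np.where(undefined, np.nan, rep.e2 / np.where(
            undefined, 1.0, denom))
    return TheoryErrorReport(e2=rep.e2, e_rel2=e_rel2, var_v=var_v,
                             mode=mode, undefined=undefined,
                             provenance={"n_pre": n_pre})


# ---------------------------------------------------------------------------
# out-degree decomposition
# ---------------------------------------------------------------------------

def kout_decomposition(j_mean: float, j_var: float, a_chi: np.ndarray,
                       chibar2: np.ndarray, kout: int,
                       exact: bool = False):
    """Structural decomposition of A_k and C_k into single-synapse terms.

    With kernels k = Σ_m J_m χ_m over K_out independently drawn synapses,

        A_k = K_out ⟨J²⟩ A_χ + K_out (K_out − 1) ⟨J⟩² χ̄²   (exact)
        C_k = K_out² ⟨J⟩² χ̄²                                 (exact)

    The compact form (``exact=False``) additionally replaces
    K_out (K_out − 1) by K_out² in A_k, so that

        A_k − C_k ≈ K_out (Var J + Mean J²) A_χ,

    valid when the impulse responses are heterogeneous (A_χ ≫ χ̄², as near
    the synaptic input region).  Either way, A_k − C_k ∝ K_out (error
    ∝ √K_out) while C_k ∝ K_out² (signal ∝ K_out): the relative error
    shrinks as 1/√K_out.

    ``a_chi`` and ``chibar2`` are the unit-impulse-response statistics
    estimated by :func:`estimate_impulse_response_statistics`.
    """
    second_moment = j_var + j_mean ** 2
    c_k = kout ** 2 * j_mean ** 2 * chibar2
    if exact:
        a_k = (kout * second_moment * a_chi
               + kout * (kout - 1) * j_mean ** 2 * chibar2)
    else:
        a_k = kout * second_moment * a_chi + c_k
    return a_k, c_k


def estimate_impulse_response_statistics(cfg, n_samples: int = 200,
                                         factory=None, eeg: bool = False):
    """Estimate A_χ(r,τ) and χ̄²(r,τ) from unit-weight synapse responses.

    Draws ``n_samples`` postsynaptic cells (placement, synapse segment,
    time constant, delay) from the population configuration, computes each
    single-synapse response with unit weight, and returns

    * ``a_chi``: mean over draws of the lag autocorrelation of χ,
    * ``chibar2``: lag autocorrelation of the mean response ⟨χ⟩,

    both of shape (n_channels, 2·n_lags−1), units signal²·ms.
    """
    from dataclasses import replace as _replace

    from .kernel_builder import (KernelFactory,
                                 sample_population_realization)

    cfg_unit = _replace(cfg, k_out=n_samples)
    if factory is None:
        factory = KernelFactory(cfg_unit, with_eeg=eeg)
    cells = sample_population_realization(cfg_unit, 0, factory.morphology)
    chis = []
    for cell in cells:
        cell.event.weight = 1.0
        chis.append(factory.cell_lfp(cell))
    chis = np.array(chis)                      # (n, n_ch, n_lag)
    n, n_ch, n_lag = chis.shape
    nfft = int(2 ** np.ceil(np.log2(2 * n_lag)))
    fk = np.fft.rfft(chis, nfft, axis=2)
    auto = np.fft.irfft((fk * np.conj(fk)).mean(axis=0), nfft, axis=1)
    fmean = fk.mean(axis=0)
    meancorr = np.fft.irfft(fmean * np.conj(fmean), nfft, axis=1)

    def arrange(x):
        return np.concatenate([x[:, nfft - (n_lag - 1):], x[:, :n_lag]],
                              axis=1)

    a_chi = arrange(auto) * factory.cfg.dt
    chibar2 = arrange(meancorr) * factory.cfg.dt
    return a_chi, chibar2


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def estimate_for_theory(spikes: SpikeTrainSet, dt: float,
                        max_lag: float | None = None) -> SpikeCovariances:
    """Spike covariances on the kernel time grid for use in Eq-style sums."""
    if max_lag is None:
        max_lag = min(30.0, spikes.duration / 2 - dt)
    return estimate_spike_covariances(spikes, dt, max_lag)
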