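"""Spike-train ensembles with controlled rates and correlations.

Generators
----------
``generate_poisson``
    Independent homogeneous Poisson processes.
``generate_mip``
    Multiple Interaction Process (MIP): correlated trains built by thinning a
    common Poisson "mother" train with copy probability ``f``; the pairwise
    spike-count correlation coefficient is exactly ``c = f**2``.
``simulate_brunel``
    Sparsely connected balanced network of leaky integrate-and-fire neurons
    with delta synapses (Brunel-type), providing spike trains with a more
    natural correlation structure (asynchronous-irregular and slow
    synchronous-irregular regimes).

Statistics
----------
``bin_population_rate``
    Population rate by spike counting on a regular grid.
``estimate_spike_covariances``
    Population-averaged auto-/cross-covariance densities of binned trains.
``pairwise_count_correlation``
    Average pairwise Pearson correlation of windowed spike counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "SpikeCovariances",
    "BrunelParams",
    "BRUNEL_AI",
    "BRUNEL_SI_SLOW",
    "generate_poisson",
    "generate_mip",
    "simulate_brunel",
    "bin_population_rate",
    "estimate_spike_covariances",
    "pairwise_count_correlation",
]


@dataclass
class SpikeTrainSet:
    """An ensemble of spike-time sequences with a common observation window.

    Attributes
    ----------
    trains : list of ndarray
        Sorted spike times in ms, each in ``[0, duration)``.
    duration : float
        Observation time in ms.
    provenance : dict
        Generator name, parameters and seed.
    """

    trains: list
    duration: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for t in self.trains:
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(t) < 0):
                raise ValueError("spike trains must be sorted")

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def mean_rate(self) -> float:
        """Grand mean firing rate in s^-1."""
        return self.n_spikes / (self.n_trains * self.duration) * 1e3

    def subset(self, idx) -> "SpikeTrainSet":
        return replace(self, trains=[self.trains[i] for i in idx])


@dataclass
class SpikeCovariances:
    """Population-averaged spike-train covariance densities.

    ``a_s`` and ``c_s`` are densities on the lag grid such that discrete sums
    times ``binsize`` approximate continuous-time covariance integrals; for a
    homogeneous Poisson process the integral of ``a_s`` is the rate (per ms)
    and ``c_s`` vanishes.
    """

    lags: np.ndarray  # ms, symmetric about 0
    a_s: np.ndarray   # (ms^-2) autocovariance density
    c_s: np.ndarray   # (ms^-2) cross-covariance density
    binsize: float    # ms

    def integrated(self):
        """(∫a_s dτ, ∫c_s dτ), both in spikes/ms."""
        return (self.a_s.sum() * self.binsize, self.c_s.sum() * self.binsize)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _poisson_train(rate_per_ms: float, duration: float, rng) -> np.ndarray:
    n = rng.poisson(rate_per_ms * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_poisson(rate: float, duration: float, n_trains: int,
                     seed: int | np.random.Generator = 0) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains.

    Parameters
    ----------
    rate : float
        Firing rate in s^-1.
    duration : float
        Observation time in ms.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    r = rate * 1e-3  # spikes per ms
    trains = [_poisson_train(r, duration, rng) for _ in range(n_trains)]
    return SpikeTrainSet(trains, duration,
                         provenance={"generator": "poisson", "rate": rate,
                                     "duration": duration, "seed": seed})


def generate_mip(rate: float, f: float, duration: float, n_trains: int,
                 seed: int | np.random.Generator = 0) -> SpikeTrainSet:
    """Multiple Interaction Process.

    A Poisson mother train of rate ``rate`` is generated; each child train
    keeps every mother spike independently with probability ``f`` and adds an
    independent Poisson train of rate ``(1 - f) * rate``, so every child is a
    Poisson process of rate ``rate`` and the pairwise spike-count correlation
    coefficient is ``f**2`` for any counting window.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("f must lie in [0, 1]")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    r = rate * 1e-3
    mother = _poisson_train(r, duration, rng)
    trains = []
    for _ in range(n_trains):
        if f == 1.0:
            child = mother.copy()
        else:
            kept = mother[rng.random(mother.size) < f]
            own = _poisson_train((1.0 - f) * r, duration, rng)
            child = np.sort(np.concatenate([kept, own]))
        trains.append(child)
    return SpikeTrainSet(trains, duration,
                         provenance={"generator": "mip", "rate": rate, "f": f,
                                     "duration": duration, "seed": seed})


# ---------------------------------------------------------------------------
# Brunel network
# ---------------------------------------------------------------------------

@dataclass
class BrunelParams:
    """Parameters of the balanced random LIF network with delta synapses.

    ``g`` is the relative inhibitory strength, ``eta`` the external drive in
    units of the rate needed to reach threshold, ``J`` the excitatory synaptic
    jump in mV.  The full-scale network has 10,000 excitatory and 2,500
    inhibitory neurons with in-degrees C_E = 1,000 and C_I = 250; the
    ``scale`` factor shrinks both population sizes and in-degrees for fast
    runs while rescaling J by 1/sqrt(scale) to approximately preserve the
    fluctuation-driven regime.
    """

    g: float = 5.0
    eta: float = 2.0
    J: float = 0.1          # mV
    n_exc: int = 10000
    n_inh: int = 2500
    c_e: int = 1000
    c_i: int = 250
    delay: float = 1.5      # ms
    tau_m: float = 20.0     # ms
    theta: float = 20.0     # mV
    v_reset: float = 10.0   # mV
    t_ref: float = 2.0      # ms
    duration: float = 1000.0  # ms of recorded activity
    warmup: float = 500.0   # ms discarded
    dt: float = 0.1         # ms
    n_record: int = 100     # excitatory trains returned
    seed: int = 0

    def __post_init__(self):
        if min(self.g, self.eta, self.J) <= 0:
            raise ValueError("g, eta, J must be > 0")
        for name in ("n_exc", "n_inh", "c_e", "c_i"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def scaled(self, scale: float) -> "BrunelParams":
        """Scaled-down preset preserving the dynamical regime."""
        return replace(
            self,
            n_exc=int(self.n_exc * scale),
            n_inh=int(self.n_inh * scale),
            c_e=int(self.c_e * scale),
            c_i=int(self.c_i * scale),
            J=self.J / np.sqrt(scale),
        )


BRUNEL_AI = BrunelParams(g=5.0, eta=2.0, J=0.1)
BRUNEL_SI_SLOW = BrunelParams(g=4.5, eta=0.9, J=0.1)


def simulate_brunel(params: BrunelParams) -> SpikeTrainSet:
    """Simulate the balanced LIF network and return excitatory spike trains.

    Forward-Euler updates of the membrane potential at resolution ``dt``
    with instantaneous voltage jumps for recurrent and external (Poisson)
    input; the warm-up window is discarded.  A mean excitatory rate above
    400 s^-1 after warm-up raises a ``RuntimeError`` (runaway regime).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_exc + p.n_inh
    # fixed in-degree connectivity, stored as per-source target lists (CSR)
    src = np.concatenate([
        rng.integers(0, p.n_exc, size=n * p.c_e),
        rng.integers(p.n_exc, n, size=n * p.c_i),
    ])
    post = np.concatenate([
        np.repeat(np.arange(n), p.c_e),
        np.repeat(np.arange(n), p.c_i),
    ])
    order = np.argsort(src, kind="stable")
    tgt_flat = post[order]
    out_deg = np.bincount(src, minlength=n)
    tgt_ptr = np.zeros(n + 1, dtype=np.int64)
    tgt_ptr[1:] = np.cumsum(out_deg)
    del src, post, order

    nu_thr = p.theta / (p.J * p.c_e * p.tau_m)       # spikes/ms to threshold
    lam_ext = p.eta * nu_thr * p.c_e * p.dt          # external events/step

    n_steps = int(round((p.duration + p.warmup) / p.dt))
    delay_steps = max(1, int(round(p.delay / p.dt)))
    decay = np.exp(-p.dt / p.tau_m)
    v = rng.uniform(0.0, p.theta, size=n)
    ref_until = np.zeros(n, dtype=np.int64)
    buf = np.zeros((delay_steps, n))
    w_inh = -p.g * p.J
    spike_times = [[] for _ in range(p.n_record)]
    exc_count_post_warmup = 0

    for step in range(n_steps):
        t = step * p.dt
        inp = buf[step % delay_steps].copy()
        buf[step % delay_steps] = 0.0
        inp += p.J * rng.poisson(lam_ext, size=n)
        active = step >= ref_until
        v[active] = v[active] * decay + inp[active]
        spk = np.flatnonzero(active & (v >= p.theta))
        if spk.size:
            v[spk] = p.v_reset
            ref_until[spk] = step + int(round(p.t_ref / p.dt))
            slot = (step + delay_steps) % delay_steps
            spk_e = spk[spk < p.n_exc]
            spk_i = spk[spk >= p.n_exc]
            if spk_e.size:
                idx = np.concatenate(
                    [tgt_flat[tgt_ptr[s]:tgt_ptr[s + 1]] for s in spk_e])
                buf[slot] += p.J * np.bincount(idx, minlength=n)
            if spk_i.size:
                idx = np.concatenate(
                    [tgt_flat[tgt_ptr[s]:tgt_ptr[s + 1]] for s in spk_i])
                buf[slot] += w_inh * np.bincount(idx, minlength=n)
            if t >= p.warmup:
                exc_spk = spk[spk < p.n_exc]
                exc_count_post_warmup += exc_spk.size
                for s in exc_spk[exc_spk < p.n_record]:
                    spike_times[s].append(t - p.warmup)

    mean_rate = exc_count_post_warmup / p.n_exc / p.duration * 1e3
    if mean_rate > 400.0:
        raise RuntimeError(
            f"network rate diverged ({mean_rate:.0f} s^-1); unstable parameters")
    trains = [np.asarray(s) for s in spike_times]
    return SpikeTrainSet(trains, p.duration,
                         provenance={"generator": "brunel", "g": p.g,
                                     "eta": p.eta, "J": p.J, "seed": p.seed,
                                     "mean_exc_rate": mean_rate})


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def bin_counts(spikes: SpikeTrainSet, dt: float) -> np.ndarray:
    """Spike counts per train on a regular grid (n_trains, n_bins).

    The last partial bin is dropped.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_bins = int(np.floor(spikes.duration / dt + 1e-9))
    out = np.zeros((spikes.n_trains, n_bins))
    for i, t in enumerate(spikes.trains):
        b = np.floor(t / dt).astype(np.int64)
        b = b[b < n_bins]
        np.add.at(out[i], b, 1.0)
    return out


def summed_bin_counts(spikes: SpikeTrainSet, dt: float) -> np.ndarray:
    """Summed spike counts over all trains per bin (spikes/bin)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_bins = int(np.floor(spikes.duration / dt + 1e-9))
    allt = np.concatenate(spikes.trains) if spikes.trains else np.array([])
    b = np.floor(allt / dt).astype(np.int64)
    b = b[b < n_bins]
    return np.bincount(b, minlength=n_bins).astype(float)


def bin_population_rate(spikes: SpikeTrainSet, dt: float,
                        per_neuron: bool = False) -> np.ndarray:
    """Population rate R(t): summed spike count per bin divided by dt.

    Returns spikes per ms by default (so that ``sum(R) * dt`` equals the
    retained spike count); with ``per_neuron=True`` the rate is additionally
    divided by the number of trains and converted to s^-1 per neuron.
    """
    rate = summed_bin_counts(spikes, dt) / dt
    if per_neuron:
        rate = rate / spikes.n_trains * 1e3
    return rate


def pairwise_count_correlation(spikes: SpikeTrainSet, window: float = 100.0):
    """Average pairwise Pearson correlation of spike counts in windows.

    Returns ``(mean, sem)`` over all distinct (unordered) pairs.
    """
    x = bin_counts(spikes, window)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    ok = sd > 0
    x, sd = x[ok], sd[ok]
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least two trains with nonzero variance")
    c = (x @ x.T) / x.shape[1] / np.outer(sd, sd)
    iu = np.triu_indices(m, k=1)
    vals = c[iu]
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))


def _lagged_pair_counts(bins: np.ndarray, n_lag: int, n_bins: int):
    """Circular histogram of ordered bin-index differences within +-n_lag.

    ``bins`` must be sorted.  Counts every ordered pair (s, s') — including
    s == s' at difference 0 — whose circular bin difference lies in
    [-n_lag, n_lag].  Returns an array of length 2*n_lag + 1.
    """
    if bins.size == 0:
        return np.zeros(2 * n_lag + 1)
    ext = np.concatenate([bins - n_bins, bins, bins + n_bins])
    lo = np.searchsorted(ext, bins - n_lag, side="left")
    hi = np.searchsorted(ext, bins + n_lag, side="right")
    lengths = hi - lo
    # gather ext[lo_i:hi_i] - bins_i for all i via the repeat/cumsum trick
    total = int(lengths.sum())
    idx = np.repeat(hi - lengths.cumsum(), lengths) + np.arange(total)
    diffs = ext[idx] - np.repeat(bins, lengths)
    return np.bincount(diffs + n_lag, minlength=2 * n_lag + 1).astype(float)


def estimate_spike_covariances(spikes: SpikeTrainSet, binsize: float,
                               max_lag: float) -> SpikeCovariances:
    """Population-averaged auto- and cross-covariance densities.

    Trains are binned at ``binsize``; the lagged product of mean-subtracted
    counts is averaged over time (with a periodic boundary, so the mean
    correction is exact) and divided by ``binsize**2`` to form a covariance
    density in ms^-2.  ``a_s`` averages over trains, ``c_s`` over distinct
    ordered pairs.  Implemented by direct counting of spike pairs, which is
    algebraically identical to correlating the binned trains.
    """
    if binsize <= 0:
        raise ValueError("binsize must be > 0")
    if max_lag >= spikes.duration / 2:
        raise ValueError("max_lag must be < duration/2")
    m = spikes.n_trains
    if m < 2:
        raise ValueError("cross-covariance needs at least two trains")
    n_bins = int(np.floor(spikes.duration / binsize + 1e-9))
    n_lag = int(np.floor(max_lag / binsize))
    lags = np.arange(-n_lag, n_lag + 1) * binsize

    per_train_bins = []
    counts = np.zeros(m)
    for i, t in enumerate(spikes.trains):
        b = np.floor(t / binsize).astype(np.int64)
        b = b[b < n_bins]
        per_train_bins.append(b)
        counts[i] = b.size

    p_auto = np.zeros(2 * n_lag + 1)
    for b in per_train_bins:
        p_auto += _lagged_pair_counts(b, n_lag, n_bins)
    pooled = np.sort(np.concatenate(per_train_bins))
    p_all = _lagged_pair_counts(pooled, n_lag, n_bins)
    p_cross = p_all - p_auto

    mu = counts / n_bins
    norm = n_bins * binsize ** 2
    a_s = (p_auto - n_bins * np.sum(mu ** 2)) / m / norm
    sum_cross_mu = np.sum(mu) ** 2 - np.sum(mu ** 2)
    c_s = (p_cross - n_bins * sum_cross_mu) / (m * (m - 1)) / norm
    return SpikeCovariances(lags=lags, a_s=a_s, c_s=c_s, binsize=binsize)
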