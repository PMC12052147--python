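"""Construction of single-cell spike-to-signal kernels and kernel banks.

A single-cell kernel k_j(r, τ) is the compound extracellular response, at
every recording channel r, to one spike of presynaptic neuron j: the sum of
the postsynaptic responses h_ij of all K_out target cells of that neuron.
The population kernel k̄ is the arithmetic mean of the single-cell kernels
and is the object convolved with the population rate in the kernel method.

Two kernel families are provided:

* toy kernels — a fixed double-exponential waveform that varies only in
  amplitude (drawn from a normal distribution), used for analytically
  tractable experiments;
* biophysical kernels — built from a passive stylized layer-5 pyramidal
  population with randomly drawn cell positions, synapse locations, synaptic
  weights (lognormal), time constants and delays (normal), evaluated with
  the line-source LFP model and the four-sphere EEG model.

Because the cable model is linear and time invariant, the response to a
synapse at segment s is the discrete convolution of a cached unit impulse
response with the synaptic current; the per-cell response is that
convolution scaled by the synaptic weight.  The cached fast path and the
direct per-cell simulation agree to rounding error.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import truncnorm

from .forward_model import (
    ElectrodeArray,
    FourSphereParams,
    Morphology,
    PassiveCableSolver,
    PassiveParams,
    SynapticEvent,
    build_stylized_l5,
    default_electrode_array,
    four_sphere_transfer,
    line_source_matrix,
)

__all__ = [
    "ToyKernelParams",
    "PopulationConfig",
    "KernelBank",
    "toy_kernel",
    "toy_waveform",
    "sample_toy_bank",
    "CellRealization",
    "sample_population_realization",
    "KernelFactory",
    "build_single_cell_kernel",
    "build_kernel_bank",
    "build_kernel_banks",
    "table1_configs",
]


# ---------------------------------------------------------------------------
# toy kernels
# ---------------------------------------------------------------------------

@dataclass
class ToyKernelParams:
    """Double-exponential kernel waveform that varies only in amplitude."""

    amp_mean: float = 1.0   # μV
    amp_sd: float = 0.0     # μV
    tau_rise: float = 0.2   # ms
    tau_decay: float = 1.0  # ms
    dt: float = 0.1         # ms
    length: float = 10.0    # ms

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError(
                "need 0 < tau_rise < tau_decay (the equal-tau alpha-function "
                "limit is not supported)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def peak_time(self) -> float:
        """Analytic extremum of the double exponential (ms)."""
        t1, t2 = self.tau_rise, self.tau_decay
        return t1 * t2 / (t2 - t1) * np.log(t2 / t1)


def toy_waveform(params: ToyKernelParams) -> np.ndarray:
    """Unit-peak waveform w(t) on the lag grid t = 0, dt, 2dt, ...

    w(t) = (-exp(-t/τ1) + exp(-t/τ2)) / w_max with the analytic maximum, so
    the peak value is exactly 1 at the grid point nearest the extremum only
    if it falls on the grid; the *continuous* peak is exactly 1.
    """
    t = np.arange(int(round(params.length / params.dt))) * params.dt
    raw = -np.exp(-t / params.tau_rise) + np.exp(-t / params.tau_decay)
    tp = params.peak_time
    wmax = -np.exp(-tp / params.tau_rise) + np.exp(-tp / params.tau_decay)
    return raw / wmax


def toy_kernel(amplitude: float, params: ToyKernelParams) -> np.ndarray:
    """Single toy kernel with continuous-time peak value ``amplitude``."""
    return amplitude * toy_waveform(params)


# ---------------------------------------------------------------------------
# kernel bank container
# ---------------------------------------------------------------------------

@dataclass
class KernelBank:
    """Bank of single-cell kernels plus their population mean.

    ``kernels`` has shape (n_presyn, n_channels, n_lags) in μV per spike;
    ``eeg_kernels`` (optional) has shape (n_presyn, n_lags) in pV per spike.
    """

    kernels: np.ndarray
    dt: float
    channel_z: np.ndarray | None = None
    eeg_kernels: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    # optional exact factorization kernels = coeff_j × waveform (toy banks)
    amplitude_coefficients: np.ndarray | None = None
    shared_waveform: np.ndarray | None = None

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=float)
        if self.kernels.ndim == 2:  # single-channel toy banks
            self.kernels = self.kernels[:, None, :]

    @property
    def n_presyn(self) -> int:
        return self.kernels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.kernels.shape[1]

    @property
    def n_lags(self) -> int:
        return self.kernels.shape[2]

    @property
    def population_kernel(self) -> np.ndarray:
        """k̄(r, τ): arithmetic mean over the presynaptic axis."""
        return self.kernels.mean(axis=0)

    @property
    def population_eeg_kernel(self) -> np.ndarray | None:
        if self.eeg_kernels is None:
            return None
        return self.eeg_kernels.mean(axis=0)

    def heterogeneity(self) -> float:
        """Relative RMS kernel heterogeneity.

        Root-mean-square deviation of the single-cell kernels from the
        population kernel, normalized by the RMS of the population kernel;
        diverges when single-cell responses cancel in the mean (uniform
        input) and is small for stereotyped kernels.
        """
        kbar = self.population_kernel
        dev = self.kernels - kbar[None]
        return float(np.sqrt((dev ** 2).mean())
                     / np.sqrt((kbar ** 2).mean()))

    def flipped(self) -> "KernelBank":
        """Sign-reversed bank (inhibitory counterpart of excitatory input)."""
        return replace(
            self, kernels=-self.kernels,
            eeg_kernels=None if self.eeg_kernels is None
            else -self.eeg_kernels,
            amplitude_coefficients=None if self.amplitude_coefficients
            is None else -self.amplitude_coefficients)

    # -- persistence -------------------------------------------------------
    def to_h5(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("kernels", data=self.kernels)
            fh.create_dataset("population_kernel",
                              data=self.population_kernel)
            if self.eeg_kernels is not None:
                fh.create_dataset("eeg_kernels", data=self.eeg_kernels)
            fh.attrs["dt"] = self.dt
            if self.channel_z is not None:
                fh.attrs["channel_z"] = self.channel_z
            fh.attrs["config"] = json.dumps(self.config)

    @classmethod
    def from_h5(cls, path) -> "KernelBank":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                kernels=fh["kernels"][()],
                dt=float(fh.attrs["dt"]),
                channel_z=(np.asarray(fh.attrs["channel_z"])
                           if "channel_z" in fh.attrs else None),
                eeg_kernels=(fh["eeg_kernels"][()]
                             if "eeg_kernels" in fh else None),
                config=json.loads(fh.attrs.get("config", "{}")),
            )


def sample_toy_bank(params: ToyKernelParams, n: int,
                    seed: int | np.random.Generator = 0) -> KernelBank:
    """Bank of ``n`` toy kernels with Normal(amp_mean, amp_sd) amplitudes."""
    if n < 1:
        raise ValueError("need n >= 1 kernels")
    rng = np.random.default_rng(seed)
    amps = rng.normal(params.amp_mean, params.amp_sd, size=n)
    w = toy_waveform(params)
    return KernelBank(kernels=amps[:, None] * w[None, :], dt=params.dt,
                      config={"kind": "toy", **asdict(params), "n": n},
                      amplitude_coefficients=amps,
                      shared_waveform=w[None, :])


# ---------------------------------------------------------------------------
# population configuration (biophysical kernels)
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Geometry, connectivity and synapse distributions of one pathway.

    Defaults describe the basal-input reference case: 500 postsynaptic
    targets per presynaptic cell, somata in a 250 μm-radius disc with
    depths from a capped normal around -1270 μm, synapse depths weighted
    by a normal around the same depth, lognormal synaptic weights of mean
    0.1 nA, and normal synaptic time constants and delays.
    """

    r_pop: float = 250.0          # μm disc radius
    k_out: int = 500              # postsynaptic targets per presyn cell
    soma_z_mean: float = -1270.0  # μm
    soma_z_sd: float = 100.0      # μm (capped at ±cap_sd standard devs)
    cap_sd: float = 2.0
    syn_z_mean: float = -1270.0   # μm
    syn_z_sd: float = 100.0       # μm
    uniform_synapses: bool = False
    j_mean: float = 0.1           # nA, lognormal distribution mean
    j_s: float = 0.4              # lognormal shape parameter
    tau_syn_mean: float = 2.0     # ms
    tau_syn_sd: float = 0.2       # ms
    delay_mean: float = 1.0       # ms
    delay_sd: float = 0.2         # ms
    n_presyn_kernels: int = 100
    kernel_length: float = 30.0   # ms
    dt: float = 2.0 ** -4         # ms
    morphology_seed: int = 1234
    seed: int = 0
    name: str = "default"

    def __post_init__(self):
        if self.k_out < 1:
            raise ValueError("k_out must be >= 1")
        if self.r_pop <= 0:
            raise ValueError("r_pop must be > 0")
        for nm in ("soma_z_sd", "syn_z_sd", "tau_syn_sd", "delay_sd", "j_s"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


def table1_configs(kout_scale: float = 1.0, n_presyn_kernels: int = 100,
                   **common) -> dict:
    """The parameter variations explored around the default case.

    ``kout_scale`` uniformly scales all out-degrees (for reduced-size runs);
    extra keyword arguments are applied to every configuration.
    """
    def mk(name, **kw):
        kw.setdefault("k_out", 500)
        kw["k_out"] = max(1, int(round(kw["k_out"] * kout_scale)))
        return PopulationConfig(name=name,
                                n_presyn_kernels=n_presyn_kernels,
                                **kw, **common)

    return {
        "default": mk("default"),
        "apical": mk("apical", syn_z_mean=-200.0),
        "uniform": mk("uniform", uniform_synapses=True),
        "small radius": mk("small radius", r_pop=125.0),
        "large radius": mk("large radius", r_pop=500.0),
        "small Kout": mk("small Kout", k_out=250),
        "large Kout": mk("large Kout", k_out=1000),
        "similar synapses": mk("similar synapses", tau_syn_sd=0.1,
                               delay_sd=0.1, j_s=0.2),
        "variable synapses": mk("variable synapses", tau_syn_sd=0.4,
                                delay_sd=0.4, j_s=0.8),
        "narrow input region": mk("narrow input region", syn_z_sd=50.0),
        "broad input region": mk("broad input region", syn_z_sd=200.0),
    }


@dataclass
class CellRealization:
    """One postsynaptic cell of a single-cell-kernel realization."""

    soma_z: float
    x: float
    y: float
    rotation: float
    event: SynapticEvent


def _lognormal_weights(rng, mean: float, s: float, size: int) -> np.ndarray:
    """Lognormal draws with distribution mean ``mean`` and shape ``s``."""
    if s == 0:
        return np.full(size, mean)
    scale = mean * np.exp(-0.5 * s ** 2)
    return scale * np.exp(s * rng.standard_normal(size))


def sample_population_realization(cfg: PopulationConfig, presyn_index: int,
                                  morphology: Morphology | None = None,
                                  rng=None) -> list[CellRealization]:
    """Draw the K_out postsynaptic cells targeted by one presynaptic neuron.

    Soma depths come from a normal capped at ±cfg.cap_sd standard
    deviations, horizontal positions are uniform on a disc of radius r_pop,
    each cell carries a single synapse whose segment is chosen with
    probability proportional to a normal density evaluated at the segment
    depth (or uniformly over segments), and weight / time constant / delay
    are drawn per synapse.
    """
    if morphology is None:
        morphology = build_stylized_l5(seed=cfg.morphology_seed)
    if rng is None:
        rng = np.random.default_rng((cfg.seed, presyn_index))
    k = cfg.k_out
    if cfg.soma_z_sd > 0:
        z = truncnorm.rvs(-cfg.cap_sd, cfg.cap_sd, loc=cfg.soma_z_mean,
                          scale=cfg.soma_z_sd, size=k, random_state=rng)
    else:
        z = np.full(k, cfg.soma_z_mean)
    r = cfg.r_pop * np.sqrt(rng.random(k))
    phi = rng.uniform(0, 2 * np.pi, k)
    rot = rng.uniform(0, 2 * np.pi, k)
    mid_z_local = morphology.midpoint[:, 2]

    j = _lognormal_weights(rng, cfg.j_mean, cfg.j_s, k)
    tau = np.maximum(rng.normal(cfg.tau_syn_mean, cfg.tau_syn_sd, k), 0.1)
    delay = np.maximum(rng.normal(cfg.delay_mean, cfg.delay_sd, k), 0.0)

    cells = []
    for i in range(k):
        if cfg.uniform_synapses:
            seg = int(rng.integers(morphology.n_segments))
        elif cfg.syn_z_sd == 0:
            seg = int(np.argmin(np.abs(mid_z_local + z[i]
                                       - cfg.syn_z_mean)))
        else:
            depth = mid_z_local + z[i]
            logw = -0.5 * ((depth - cfg.syn_z_mean) / cfg.syn_z_sd) ** 2
            w = np.exp(logw)
            tot = w.sum()
            if not np.isfinite(tot) or tot <= 0:
                raise ValueError("synapse depth weighting assigns zero "
                                 "probability to every segment")
            seg = int(rng.choice(morphology.n_segments, p=w / tot))
        ev = SynapticEvent(segment=seg, weight=j[i], tau_syn=tau[i],
                           onset=delay[i])
        cells.append(CellRealization(soma_z=z[i], x=r[i] * np.cos(phi[i]),
                                     y=r[i] * np.sin(phi[i]),
                                     rotation=rot[i], event=ev))
    return cells


# ---------------------------------------------------------------------------
# kernel factory
# ---------------------------------------------------------------------------

class KernelFactory:
    """Shared forward-model state for building biophysical kernel banks.

    Holds the canonical (unplaced) morphology, the factorized cable solver,
    lazily cached per-segment unit impulse responses of the membrane
    currents and of the cell-local current dipole moment, the electrode
    layout, and the four-sphere transfer vector.
    """

    def __init__(self, cfg: PopulationConfig,
                 electrodes: ElectrodeArray | None = None,
                 passive: PassiveParams | None = None,
                 head: FourSphereParams | None = None,
                 with_eeg: bool = True,
                 template: "KernelFactory | None" = None):
        self.cfg = cfg
        shared = (template is not None
                  and template.cfg.morphology_seed == cfg.morphology_seed
                  and template.cfg.dt == cfg.dt
                  and template.cfg.kernel_length == cfg.kernel_length
                  and electrodes is None and passive is None)
        if shared:
            self.morphology = template.morphology
            self.passive = template.passive
            self.electrodes = template.electrodes
            self.solver = template.solver
        else:
            self.morphology = build_stylized_l5(seed=cfg.morphology_seed)
            self.passive = passive or PassiveParams()
            self.electrodes = electrodes or default_electrode_array()
            self.solver = PassiveCableSolver(self.morphology, self.passive,
                                             cfg.dt)
        self.n_lags = int(round(cfg.kernel_length / cfg.dt))
        self.with_eeg = with_eeg
        if with_eeg:
            self.head = head or FourSphereParams()
            # population current dipole placed at the mean soma depth,
            # vertex electrode directly above
            self._w_eeg = four_sphere_transfer(
                self.head, (0.0, 0.0, cfg.soma_z_mean),
                (0.0, 0.0, (self.head.radii[3] - self.head.radii[0]) * 1e3))
        if shared:
            self._chi = template._chi
            self._dip = template._dip
        else:
            # unit impulse responses for every possible synapse segment,
            # built once in a batched modal evaluation
            all_segs = np.arange(self.morphology.n_segments)
            resp = self.solver.impulse_current_responses(all_segs,
                                                         self.n_lags)
            mids = self.morphology.midpoint
            self._chi = {int(s): resp[k] for k, s in enumerate(all_segs)}
            self._dip = {int(s): mids.T @ resp[k]
                         for k, s in enumerate(all_segs)}

    def _ensure_responses(self, segments):
        pass  # responses precomputed eagerly in __init__

    def synapse_current(self, event: SynapticEvent) -> np.ndarray:
        """Unit-weight step-averaged current sequence of one synapse."""
        unit = replace(event, weight=1.0)
        return self.solver.event_current_sequence(unit, self.n_lags)

    def cell_lfp(self, cell: CellRealization) -> np.ndarray:
        """LFP contribution (n_channels, n_lags) of one postsynaptic cell."""
        self._ensure_responses([cell.event.segment])
        placed = self.morphology.transformed(dz=cell.soma_z,
                                             rotation=cell.rotation,
                                             dx=cell.x, dy=cell.y)
        mmat = line_source_matrix(placed, self.electrodes)
        chi_e = mmat @ self._chi[cell.event.segment]
        i_seq = self.synapse_current(cell.event)
        out = fftconvolve(chi_e, i_seq[None, :], axes=1)[:, :self.n_lags]
        # exact causality: no response before the synaptic delay bin
        out[:, :int(np.floor(cell.event.onset / self.cfg.dt))] = 0.0
        return cell.event.weight * out

    def cell_dipole(self, cell: CellRealization) -> np.ndarray:
        """Current dipole contribution (3, n_lags) in nA·μm."""
        self._ensure_responses([cell.event.segment])
        c, s = np.cos(cell.rotation), np.sin(cell.rotation)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        d_local = self._dip[cell.event.segment]
        i_seq = self.synapse_current(cell.event)
        d = fftconvolve(rot @ d_local, i_seq[None, :], axes=1)
        d = d[:, :self.n_lags]
        d[:, :int(np.floor(cell.event.onset / self.cfg.dt))] = 0.0
        return cell.event.weight * d

    def single_cell_kernel(self, presyn_index: int):
        """(LFP kernel (n_ch, n_lags) μV, EEG kernel (n_lags,) pV or None).

        The kernel is the sum over the presynaptic neuron's K_out
        postsynaptic targets of the per-cell responses to a unit spike at
        lag 0.
        """
        cells = sample_population_realization(self.cfg, presyn_index,
                                              self.morphology)
        lfp = np.zeros((self.electrodes.positions.shape[0], self.n_lags))
        dip = np.zeros((3, self.n_lags))
        for cell in cells:
            lfp += self.cell_lfp(cell)
            if self.with_eeg:
                dip += self.cell_dipole(cell)
        eeg = self._w_eeg @ dip if self.with_eeg else None
        return lfp, eeg

    def build_bank(self) -> KernelBank:
        n = self.cfg.n_presyn_kernels
        lfps = []
        eegs = []
        for jx in range(n):
            lfp, eeg = self.single_cell_kernel(jx)
            lfps.append(lfp)
            if eeg is not None:
                eegs.append(eeg)
        return KernelBank(
            kernels=np.array(lfps), dt=self.cfg.dt,
            channel_z=self.electrodes.positions[:, 2].copy(),
            eeg_kernels=np.array(eegs) if eegs else None,
            config={"kind": "biophysical", **asdict(self.cfg)})


def build_single_cell_kernel(cfg: PopulationConfig, presyn_index: int,
                             factory: KernelFactory | None = None):
    """Single-cell kernel for one presynaptic neuron (see KernelFactory)."""
    if factory is None:
        factory = KernelFactory(cfg)
    return factory.single_cell_kernel(presyn_index)


def build_kernel_bank(cfg: PopulationConfig, with_eeg: bool = True,
                      electrodes: ElectrodeArray | None = None) -> KernelBank:
    """Build the full bank of single-cell kernels for one pathway."""
    return KernelFactory(cfg, electrodes=electrodes,
                         with_eeg=with_eeg).build_bank()


def build_kernel_banks(configs: dict, with_eeg: bool = True) -> dict:
    """Build banks for several configurations, sharing cached impulse
    responses between configurations with a common morphology and grid."""
    banks = {}
    template = None
    for name, cfg in configs.items():
        factory = KernelFactory(cfg, with_eeg=with_eeg, template=template)
        if template is None:
            template = factory
        banks[name] = factory.build_bank()
    return banks
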