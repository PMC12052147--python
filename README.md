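# popkernel

Population rate-to-LFP/EEG kernels: construction, signal synthesis, and an
analytical theory of the approximation error.

## The problem

Local field potentials (LFP) and EEG signals are generated by the
transmembrane currents that synaptic inputs evoke in populations of
geometrically aligned pyramidal neurons.  Point-neuron networks and
firing-rate models — the workhorses of population-level simulation — carry
no spatial information, so these signals cannot be computed from them
directly.  The *kernel method* bridges the gap: for each synaptic pathway
one computes a population kernel k̄(r, τ) — the average extracellular
response at channel r to one presynaptic spike — and approximates the
signal by a single convolution with the population rate R(t):

    Ṽ(r, t) = (k̄(r) ∗ R)(t).

The exact ("ground truth") signal couples each presynaptic neuron's own
single-cell kernel k_j to its own spike train s_j:

    V(r, t) = Σ_j (k_j(r) ∗ s_j)(t),     k_j = Σ_i h_ij,

where h_ij is the response of postsynaptic cell i to a spike of neuron j.
`popkernel` implements both routes and, crucially, predicts when they
agree.  For kernels drawn from a common distribution and spike trains with
population-averaged auto-/cross-covariances A_s(τ), C_s(τ), the expected
squared error E²(r) = Var_t[V − Ṽ] is

    ⟨E²(r)⟩ = (N_pre − 1) ∫ dτ (A_k(r,τ) − C_k(r,τ)) (A_s(τ) − C_s(τ)),

with A_k, C_k the lag-integrated auto- and cross-correlations of the
single-cell kernels.  The error vanishes for identical kernels or fully
correlated spiking, grows with kernel heterogeneity, and — relative to the
signal amplitude — shrinks as 1/√K_out with the out-degree and as 1/√N_pre
for correlated inputs.  The package is aimed at computational
neuroscientists who want to attach biophysically grounded LFP/EEG
predictions to point-neuron or rate-model simulations and to know the
error bars on those predictions.

## What is inside

| module | contents |
| --- | --- |
| `popkernel.spike_models` | Poisson ensembles, Multiple Interaction Processes (pairwise count correlation c = f² exactly), a balanced LIF network with delta synapses (asynchronous-irregular and slow synchronous-irregular regimes), population-rate binning, auto-/cross-covariance estimation |
| `popkernel.forward_model` | stylized layer-5 pyramidal morphology, passive compartmental cable solver (Crank–Nicolson, exactly linear), line-source LFP in an infinite homogeneous medium, current dipole moment, four-sphere (brain/CSF/skull/scalp) EEG |
| `popkernel.kernel_builder` | toy double-exponential kernels varying only in amplitude; biophysical kernel banks sampling soma positions, synapse locations, lognormal weights, normal time constants and delays |
| `popkernel.signal_engine` | ground-truth and kernel-approximated signals, empirical error measures, multi-pathway superposition, parameter sweeps |
| `popkernel.error_theory` | kernel correlations A_k/C_k, expected absolute and relative errors, the out-degree decomposition into single-synapse statistics |
| `popkernel.rate_model` | two-dimensional QIF mean-field model (bistable switching) and rate-to-LFP/EEG conversion |

## Worked example

```python
import numpy as np
from popkernel import kernel_builder as kb, signal_engine as se
from popkernel import spike_models as sm, error_theory as et

params = kb.ToyKernelParams(amp_mean=1.0, amp_sd=0.5)   # μV
bank = kb.sample_toy_bank(params, n=1000, seed=1)
spikes = sm.generate_mip(rate=10.0, f=0.1, duration=20_000.0,
                         n_trains=1000, seed=2)
v, v_tilde, report = se.synthesize(bank, spikes)
theory = et.expected_relative_error(
    et.toy_kernel_correlations(params), et.mip_covariance(10.0, 0.1), 1000)
print(f"simulated E_rel = {report.e_rel[0]:.3f}, "
      f"theory = {theory.e_rel[0]:.3f}")
```

This prints

```
simulated E_rel = 0.153, theory = 0.148
```

i.e. with 1000 presynaptic cells whose kernel amplitudes scatter by 50%
around 1 μV and weakly correlated spiking (c = f² = 0.01), the population
kernel reproduces the compound signal up to a ~15% relative error — and
the closed-form prediction agrees with the simulation to within the
Monte-Carlo uncertainty.

Biophysical banks work the same way but take minutes rather than seconds:

```python
cfg = kb.PopulationConfig(k_out=100, n_presyn_kernels=50, seed=7)
bank = kb.build_kernel_bank(cfg)          # 16-channel LFP + EEG kernels
```

A thin CLI mirrors the library: `popkernel spikes mip --f 0.1 --out s.txt`,
`popkernel kernels build --preset default --out bank.h5`,
`popkernel signal synth --bank bank.h5 --spikes s.txt --out sig.h5`,
`popkernel ratemodel run --out rate.csv`.

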