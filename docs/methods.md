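# Methods

This note documents the models implemented in `popkernel`, their
assumptions, the default parameter choices, and the numerical decisions
behind them.

## Signal model and error theory

All cell and synapse models are fully linear: passive membranes,
current-based synapses, no plasticity.  Under linearity every presynaptic
spike evokes the same postsynaptic response, so the compound extracellular
signal can be written either postsynaptically (sum over target cells of
their input-driven responses) or presynaptically (sum over source neurons
of kernel-convolved spike trains); the two orderings are algebraically
identical and the test suite asserts their equality to 1e-12.

The kernel approximation replaces the per-neuron kernels k_j by their mean
k̄ and the per-neuron trains by the population rate.  Its squared error
E²(r) = Var_t[V − Ṽ] has the expectation (over kernel realizations)

    ⟨E²⟩ = (N−1) ∫ dτ (A_k − C_k)(A_s − C_s),

and the expected ground-truth variance is N ∫ A_k A_s + N(N−1) ∫ C_k C_s.
Discrete convention: all lag integrals are sums times the grid spacing on
the kernel time grid.  Delta-shaped spike covariances (Poisson, MIP) are
applied analytically — the delta mass multiplies the zero-lag kernel
correlation — never approximated as a 1/Δτ spike in a bin, which would
introduce binsize artifacts.

Kernel correlations are plug-in estimates from the finite bank (A_k from
self-products, C_k from all ordered distinct pairs); for the amplitude-only
toy model exact moments are available in closed form
(A_k = (μ²+σ²)W, C_k = μ²W with W the waveform autocorrelation).  The
distinction between the error of one kernel realization and its
expectation is real at small bank sizes; acceptance checks that compare
expectations therefore average over bank redraws.

Relative errors need a normalization.  For multi-channel (laminar)
recordings the denominator is the variance of the strongest channel —
near-silent channels would otherwise report huge but irrelevant relative
errors — and the theory mirrors this by normalizing with the channel of
maximum predicted variance.  Single-channel (toy) signals normalize by
their own variance.  Both conventions are exposed (`max-over-channels`,
`per-signal`).  Variances use the biased 1/N estimator in numerator and
denominator so ratios are convention-free.

## Spike-train models

*Poisson*: independent homogeneous processes, rate ν (default 10 s⁻¹,
observation 15.5 s, 100 trains — the standard conditions used throughout).

*MIP* (Multiple Interaction Process): a mother Poisson train at rate ν;
each child keeps each mother spike independently with probability f and
adds independent Poisson spikes at rate (1−f)ν.  Each child is exactly
Poisson(ν) and the pairwise count correlation is c = f² for any counting
window.  Thinning is per-spike (not exact-count subsampling) precisely so
that c = f² holds exactly.  Count-correlation checks use 100 ms windows;
because all pairs share one mother realization, the pair-averaged standard
error badly understates the uncertainty of the ensemble estimate, so
statistical tests average over independent ensembles.

*Balanced LIF network*: N = 12,500 (10,000 excitatory, 2,500 inhibitory)
leaky integrate-and-fire neurons with instantaneous voltage-jump synapses,
fixed in-degrees C_E = 1,000, C_I = 250, delay 1.5 ms, τ_m = 20 ms,
threshold 20 mV, reset 10 mV, refractory 2 ms, external Poisson drive
η × (threshold rate), time step 0.1 ms, forward-Euler with exact
exponential membrane decay per step.  Presets: asynchronous-irregular
(g = 5, η = 2, J = 0.1 mV) and slow synchronous-irregular (g = 4.5,
η = 0.9, J = 0.1 mV).  A warm-up of 300–500 ms is discarded (configurable;
the regime literature does not fix a value).  A scaled-down constructor
exists for quick exploration but shifts the dynamical regime, so regime
assertions run the full-size network.  Runaway rates (> 400 s⁻¹) raise
instead of returning garbage.

*Covariance estimation*: trains are binned (default 2⁻⁴ ms); the
population-averaged auto- and cross-covariance densities are computed by
direct counting of spike-pair bin differences with a periodic boundary,
which is algebraically identical to correlating the mean-subtracted binned
trains and makes the mean correction exact.  The estimator matches a
nested-loop pair-counting oracle to machine precision on small inputs.

## Forward model

*Morphology*: a programmatically generated, stylized layer-5 pyramidal
cell — one soma segment, a 1 mm apical trunk with small lateral jitter,
8 tuft branches, 8 basal branches (≈ 185 cylindrical segments, vertical
extent ≈ 1.4 mm).  It preserves the features the kernel statistics depend
on (basal/apical input-region asymmetry, elongated dipole geometry,
population spread) without reproducing any particular reconstructed cell;
kernel waveforms are validated by properties (polarity, causality,
scalings), not by matching published waveforms.

*Passive parameters*: R_m = 30 kΩ·cm², C_m = 1 μF/cm², R_a = 150 Ω·cm —
typical cortical pyramidal values.

*Cable solver*: compartmental conductance matrix (leak + axial Laplacian),
integrated with the trapezoidal (Crank–Nicolson) rule at dt = 2⁻⁴ ms.
Synaptic currents J·exp(−(t−d)/τ_syn) are integrated exactly over each
step, so the injected charge is exact and the scheme is globally
second-order (single-compartment RC response matches the closed form to
~1e-5).  Transmembrane source currents are computed as −L·V with L the
axial Laplacian, which conserves current to machine precision at every
step.  The scheme is exactly linear and time invariant, so per-segment
unit impulse responses can be cached and convolved with arbitrary synaptic
current sequences; these responses are evaluated in the eigenbasis of the
symmetrized cable operator, which is algebraically identical to marching
the scheme (verified to 1e-14) but fast enough to precompute the full
per-segment response bank at factory construction.

*LFP*: line-source approximation in an infinite homogeneous medium with
σ = 0.3 S/m, the soma as a point source, 16 laminar contacts at x = y = 0,
z = 0 … −1500 μm (100 μm spacing: the soma-depth distribution and the
apical tufts both lie inside the span; absolute electrode depths are a
package choice).  Source–contact distances are clamped at 5 μm.

*EEG*: current dipole moment p(t) = Σ_n I_n(t) r_n (origin-independent
because ΣI = 0), fed into a concentric four-sphere head model with radii
79/80/85/90 mm and conductivities 0.3/1.5/0.015/0.3 S/m (standard
published values).  The boundary-condition system is solved numerically
per expansion order in a per-shell scaled basis; the default truncation is
order 100 with a convergence check that raises on failure (order 20 is
*not* sufficient for sources 1 mm below the brain surface — measured 7%
truncation error).  The population dipole is evaluated at the mean soma
depth on the axis, with the scalp electrode at the vertex directly above;
summing per-cell dipoles before applying the head model is exact by
linearity since each cell's dipole is origin-independent.

## Kernel banks

*Toy kernels*: double exponential with rise 0.2 ms, decay 1 ms, unit
continuous-time peak, amplitudes Normal(1.0 μV, σ_A); grid dt = 0.1 ms,
length 10 ms.  The degenerate rise = decay (alpha-function) limit is
rejected rather than special-cased.

*Biophysical kernels*: for each presynaptic neuron, K_out (default 500)
postsynaptic cells are drawn — soma depth from Normal(−1270, 100) μm
capped at ±2 SD (so cells do not protrude above the cortical surface;
the cap bound is a package choice), horizontal position uniform on a disc
of radius 250 μm, random rotation about the vertical axis.  Each cell
receives one synapse; its segment is chosen from all segments with
probability proportional to a normal density in depth (mean −1270 μm,
SD 100 μm; "uniform" draws segments uniformly and treats any descriptive
depth statistics as outputs, not inputs).  Weights are lognormal with
distribution mean 0.1 nA and shape s = 0.4 (the "mean" is read as the
distribution mean, with the scale solved from it — the parameterization is
stated explicitly because mean-vs-scale readings differ by e^{s²/2}).
Time constants are Normal(2 ms, 0.2 ms) floored at 0.1 ms — the time
constant's mean is a package default (typical excitatory current decay),
configurable — and delays Normal(1 ms, 0.2 ms) floored at 0.  Kernels are
30 ms long at dt = 2⁻⁴ ms and exactly zero before each synapse's delay.
The `table1_configs` grid varies input region (apical −200 μm / basal
−1270 μm / uniform; SD 50/100/200 μm), out-degree (×½, ×2), population
radius (×½, ×2), and synaptic-parameter spreads (×½, ×2) around the
basal default, with a global `kout_scale` for reduced-size runs.

*Kernel heterogeneity* is summarized as the RMS deviation of single-cell
kernels from the population kernel, normalized by the population-kernel
RMS.  The *absolute* spread of kernel amplitudes is not a useful
heterogeneity measure here: amplitudes shrink as the input region widens
faster than their scatter grows, while the normalized measure — which is
what the relative-error theory responds to — is strictly ordered
uniform > broad > default > narrow.

## Signal synthesis

Spikes are binned to the kernel grid as unit impulses (no sub-bin
interpolation, consistent with the rate construction).  The ground truth
is computed by scattering each train's kernel at its spike bins — exact
discrete convolution — with spikes grouped into non-overlapping rounds so
the adds vectorize; for amplitude-factorized (toy) banks the sum over
cells is folded into a coefficient-weighted population rate before one
convolution, an exact rearrangement asserted against the general path.
The kernel approximation is a single FFT convolution per channel.

## Out-degree decomposition

Writing h_ij = ξ_ij J_ij χ_ij separates adjacency, weight, and unit
impulse response.  Exactly: A_k = K⟨J²⟩A_χ + K(K−1)⟨J⟩²χ̄²,
C_k = K²⟨J⟩²χ̄².  The compact form A_k − C_k ≈ K(VarJ + MeanJ²)A_χ
additionally requires A_χ ≫ χ̄², i.e. heterogeneous impulse responses,
which holds near the synaptic input region (measured A_χ/χ̄² ≈ 6–17
there) but fails at distant contacts where responses are stereotyped
(A_χ/χ̄² ≈ 1.1).  Both forms are implemented (`exact=` flag).  Validation
against directly estimated kernel correlations is done at laterally
displaced contacts: contacts on the population axis see a heavy-tailed
per-synapse response distribution (rare synapses within the 5 μm distance
clamp dominate A_χ), making finite-bank comparisons noisy.

Either way the structure implies: signal amplitude ∝ K_out, absolute
error ∝ √K_out, relative error ∝ 1/√K_out — verified empirically over
K_out ∈ {125, 250, 500} (log-log slopes within ±0.15 of +1 and −0.5).

## Rate model

The two-dimensional mean-field model τ²ṙ = Δ/π + 2τvr,
τv̇ = v² + Jτr + η + I(t) − π²τ²r² (the exact macroscopic limit of
all-to-all coupled QIF neurons with Lorentzian heterogeneity) is
integrated with fixed-step classical Runge–Kutta (default dt = τ/1000;
fourth-order convergence verified by step halving).  Internally r carries
ms⁻¹; traces report s⁻¹.  The state is pre-relaxed at I = 0 before the
stimulus clock starts, and a square pulse (amplitude 4, onset 1 s,
duration 3 s) switches the bistable regime Δ = 2, η = −10, τ = 100 ms
between its low- and high-activity branches.  For the coupling we ship
two presets: J = 15√Δ (the scaling under which the cited bistable regime
is defined; the default) and J = 15Δ (a printed variant that likely lost
a radical in typesetting); both are bistable under the pulse protocol,
and the acceptance check runs the default.  Rate-to-signal conversion
multiplies r(t) by 10⁻³·dt·N_pre (expected spikes per kernel bin for a
population of N_pre) and applies the same convolution code path as the
spike-based kernel approximation.

## Reduced problem sizes

The default experiment sizes in the test battery are chosen to finish in
minutes on one core while leaving the tested scalings resolvable:
biophysical banks use K_out = 100–125…500 with 50 kernels (instead of 500
with 100), sweeps use 10 s of spiking, and the theory-vs-simulation grid
uses 1000 toy kernels × 20 s × 20 redraws.  Where a contrast is an
expectation that single reduced-size realizations straddle (the
broad-vs-default input-region ordering), the test averages over bank
realizations rather than widening its assertion.

## Known limitations

* Everything is linear: no conductance-based synapses, no active or
  quasi-active membranes, no extracellular spike waveforms.  Real kernels
  inherit conductance and background-state dependence that this model
  deliberately excludes.
* The stylized morphology reproduces class-level geometry, not any
  measured cell; kernel waveforms should be read qualitatively.
* The synthetic spike ensembles (Poisson/MIP/balanced network) have
  controlled second-order statistics but none of the nonstationarity,
  rate adaptation, or higher-order structure of in-vivo spiking, so
  passing tests demonstrate correctness of the method and theory under
  the stated statistics, not predictive accuracy for any recorded LFP.
* The four-sphere head model is a concentric-sphere idealization with a
  single vertex electrode; no anatomical head geometry.
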