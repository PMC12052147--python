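"""Passive multicompartment neuron and volume-conductor forward models.

The morphology is a programmatically generated, stylized layer-5 pyramidal
cell (basal bush near the soma, a long apical trunk, an apical tuft), built
as a tree of cylindrical segments.  Membrane dynamics are fully passive with
current-based synapses, so the mapping from synaptic events to extracellular
signals is exactly linear — the property that underwrites the kernel method.

Extracellular potentials in an infinite homogeneous medium are computed with
the line-source approximation (the soma is treated as a point source); EEG
signals are computed from the current dipole moment placed in a concentric
four-sphere (brain / CSF / skull / scalp) head model evaluated by solving
the boundary-condition system order by order in the spherical-harmonic
expansion.

Units: positions in μm, time in ms, voltages in mV, currents in nA,
conductances in μS, capacitances in nF, LFPs in μV, EEGs in pV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "Morphology",
    "PassiveParams",
    "SynapticEvent",
    "MembraneCurrentField",
    "ElectrodeArray",
    "DipoleTrace",
    "FourSphereParams",
    "build_stylized_l5",
    "PassiveCableSolver",
    "solve_passive",
    "line_source_matrix",
    "lfp_line_source",
    "current_dipole",
    "four_sphere_transfer",
    "eeg_four_sphere",
    "default_electrode_array",
]


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@dataclass
class Morphology:
    """Tree of cylindrical segments.

    ``start``/``end`` are (n, 3) arrays in μm, ``diam`` (n,) in μm,
    ``parent`` (n,) holds the parent segment index (-1 for the root = soma).
    Children attach at their parent's end point.
    """

    start: np.ndarray
    end: np.ndarray
    diam: np.ndarray
    parent: np.ndarray
    labels: np.ndarray  # str section label per segment

    def __post_init__(self):
        self.start = np.atleast_2d(np.asarray(self.start, dtype=float))
        self.end = np.atleast_2d(np.asarray(self.end, dtype=float))
        self.diam = np.asarray(self.diam, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        if np.any(self.length <= 0):
            raise ValueError("all segment lengths must be > 0")
        if np.sum(self.parent < 0) != 1:
            raise ValueError("tree must have a single root")

    @property
    def n_segments(self) -> int:
        return self.start.shape[0]

    @property
    def length(self) -> np.ndarray:
        return np.linalg.norm(self.end - self.start, axis=1)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def soma_index(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def transformed(self, dz: float = 0.0, rotation: float = 0.0,
                    dx: float = 0.0, dy: float = 0.0) -> "Morphology":
        """Copy rotated about the z-axis then translated."""
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([dx, dy, dz])
        return Morphology(self.start @ rot.T + shift, self.end @ rot.T + shift,
                          self.diam.copy(), self.parent.copy(),
                          self.labels.copy())

    # -- SWC-like delimited text ------------------------------------------
    _SWC_TYPES = {"soma": 1, "basal": 3, "trunk": 4, "tuft": 4}

    def to_swc(self, path):
        """Write an SWC-like table (id, type, x, y, z, radius, parent).

        Coordinates are segment end points; the root row carries the soma
        start point as an extra leading sample with parent -1.
        """
        with open(path, "w") as fh:
            fh.write("# id type x y z radius parent (popkernel stylized)\n")
            root = self.soma_index
            x, y, z = self.start[root]
            fh.write(f"1 1 {x:.3f} {y:.3f} {z:.3f} "
                     f"{self.diam[root] / 2:.3f} -1\n")
            for i in range(self.n_segments):
                par = self.parent[i]
                pid = 1 if par < 0 else par + 2
                x, y, z = self.end[i]
                t = self._SWC_TYPES.get(str(self.labels[i]), 0)
                fh.write(f"{i + 2} {t} {x:.3f} {y:.3f} {z:.3f} "
                         f"{self.diam[i] / 2:.3f} {pid}\n")

    @classmethod
    def from_swc(cls, path) -> "Morphology":
        rows = np.loadtxt(path, comments="#")
        ids = rows[:, 0].astype(int)
        order = np.argsort(ids)
        rows = rows[order]
        idx = {int(r[0]): k for k, r in enumerate(rows)}
        start, end, diam, parent, labels = [], [], [], [], []
        typemap = {1: "soma", 3: "basal", 4: "trunk"}
        for r in rows[1:]:
            pid = int(r[6])
            prow = rows[idx[pid]]
            start.append(prow[2:5])
            end.append(r[2:5])
            diam.append(2 * r[5])
            parent.append(idx[pid] - 1 if pid != 1 else -1)
            labels.append(typemap.get(int(r[1]), "basal"))
        return cls(np.array(start), np.array(end), np.array(diam),
                   np.array(parent), np.array(labels))


def _grow_branch(segs, parent, origin, direction, length, n_seg, diam,
                 label, rng, wiggle=0.15):
    """Append a branch of n_seg segments; returns index of last segment."""
    pos = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    seg_len = length / n_seg
    last = parent
    for k in range(n_seg):
        step = d + wiggle * rng.standard_normal(3)
        step /= np.linalg.norm(step)
        new = pos + step * seg_len
        segs.append((pos.copy(), new.copy(), diam, last, label))
        pos = new
        last = len(segs) - 1
    return last


def build_stylized_l5(seed: int = 0, soma_z: float = 0.0,
                      rotation: float = 0.0, trunk_length: float = 1000.0,
                      n_basal: int = 8, n_tuft: int = 8) -> Morphology:
    """Stylized layer-5 pyramidal morphology.

    A basal bush of ``n_basal`` descending branches near the soma, an apical
    trunk ascending ``trunk_length`` μm, and ``n_tuft`` tuft branches at the
    top; total vertical extent ≈ 1.2–1.3 mm.  Deterministic given ``seed``;
    the soma is placed at ``(0, 0, soma_z)`` and the cell is rotated about
    the z-axis by ``rotation`` (rad).
    """
    rng = np.random.default_rng(seed)
    segs = []  # (start, end, diam, parent, label)
    segs.append((np.zeros(3), np.array([0.0, 0.0, 20.0]), 20.0, -1, "soma"))

    # apical trunk, straight up with small jitter, tapering diameter
    pos = np.array([0.0, 0.0, 20.0])
    last = 0
    n_trunk = 40
    seg_len = trunk_length / n_trunk
    for k in range(n_trunk):
        step = np.array([0.0, 0.0, 1.0]) + 0.03 * rng.standard_normal(3)
        step /= np.linalg.norm(step)
        new = pos + step * seg_len
        d = 5.0 - 2.5 * k / n_trunk
        segs.append((pos.copy(), new.copy(), d, last, "trunk"))
        pos = new
        last = len(segs) - 1
    trunk_top = last

    # apical tuft: branches fanning upward/outward from the trunk top
    for b in range(n_tuft):
        phi = 2 * np.pi * b / n_tuft + rng.uniform(0, 0.5)
        tilt = rng.uniform(0.5, 1.1)  # rad from vertical
        direction = np.array([np.sin(tilt) * np.cos(phi),
                              np.sin(tilt) * np.sin(phi), np.cos(tilt)])
        _grow_branch(segs, trunk_top, segs[trunk_top][1], direction,
                     length=rng.uniform(150, 220), n_seg=8, diam=1.2,
                     label="tuft", rng=rng)

    # basal bush: branches heading down and outward from the soma base
    for b in range(n_basal):
        phi = 2 * np.pi * b / n_basal + rng.uniform(0, 0.5)
        tilt = rng.uniform(1.8, 2.6)  # rad from vertical (downward)
        direction = np.array([np.sin(tilt) * np.cos(phi),
                              np.sin(tilt) * np.sin(phi), np.cos(tilt)])
        _grow_branch(segs, 0, np.zeros(3), direction,
                     length=rng.uniform(200, 280), n_seg=10, diam=1.5,
                     label="basal", rng=rng)

    start = np.array([s[0] for s in segs])
    end = np.array([s[1] for s in segs])
    diam = np.array([s[2] for s in segs])
    parent = np.array([s[3] for s in segs])
    labels = np.array([s[4] for s in segs])
    m = Morphology(start, end, diam, parent, labels)
    return m.transformed(dz=soma_z, rotation=rotation)


# ---------------------------------------------------------------------------
# passive cable dynamics
# ---------------------------------------------------------------------------

@dataclass
class PassiveParams:
    """Passive membrane and cytoplasm parameters (typical cortical values)."""

    rm: float = 30000.0  # Ω·cm² membrane resistivity
    cm: float = 1.0      # μF/cm² specific capacitance
    ra: float = 150.0    # Ω·cm axial resistivity

    def __post_init__(self):
        if min(self.rm, self.cm, self.ra) <= 0:
            raise ValueError("passive parameters must be strictly positive")


@dataclass
class SynapticEvent:
    """Current-based synapse with instantaneous rise and exponential decay.

    The injected current is ``J * exp(-(t - onset)/tau_syn)`` for
    ``t >= onset``; the sign of ``J`` (nA) encodes excitation/inhibition.
    """

    segment: int
    weight: float          # nA
    tau_syn: float = 2.0   # ms
    onset: float = 0.0     # ms

    def __post_init__(self):
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


@dataclass
class MembraneCurrentField:
    """Per-segment transmembrane current traces (nA) on a regular grid.

    The currents include the capacitive, leak and synaptic contributions;
    by construction they sum to zero over segments at every time step.
    """

    currents: np.ndarray  # (n_segments, n_t)
    dt: float

    @property
    def n_t(self) -> int:
        return self.currents.shape[1]

    def conservation_error(self) -> float:
        """max_t |Σ_n I_n| relative to the largest single current."""
        peak = np.abs(self.currents).max()
        if peak == 0:
            return 0.0
        return float(np.abs(self.currents.sum(axis=0)).max() / peak)


class PassiveCableSolver:
    """Compartmental cable solver on a morphology (Crank–Nicolson).

    The trapezoidal (Crank–Nicolson) update is unconditionally stable,
    second-order accurate, and exactly linear in the synaptic input, so
    superposition of event responses holds to rounding error and impulse
    responses can be cached and convolved with arbitrary input currents.
    """

    def __init__(self, morphology: Morphology, params: PassiveParams,
                 dt: float = 2.0 ** -4):
        self.m = morphology
        self.p = params
        self.dt = dt
        n = morphology.n_segments
        area_cm2 = np.pi * morphology.diam * morphology.length * 1e-8
        self.g_leak = area_cm2 / params.rm * 1e6            # μS
        self.c_m = params.cm * area_cm2 * 1e3               # nF
        # half-segment axial resistances (Ω); lengths/diams in μm -> cm
        r_half = (params.ra * (morphology.length * 1e-4 / 2)
                  / (np.pi * (morphology.diam * 1e-4 / 2) ** 2))
        rows, cols, vals = [], [], []
        for child in range(n):
            par = morphology.parent[child]
            if par < 0:
                continue
            g = 1e6 / (r_half[child] + r_half[par])          # μS
            rows += [child, par, child, par]
            cols += [par, child, child, par]
            vals += [-g, -g, g, g]
        self.lap = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        g_total = sp.diags(self.g_leak) + self.lap
        c_dt = sp.diags(self.c_m / dt)
        self._lu = splu((c_dt + 0.5 * g_total).tocsc())
        self._b_mat = (c_dt - 0.5 * g_total).tocsc()

    # -- time stepping -----------------------------------------------------
    def _march(self, i_syn: np.ndarray) -> np.ndarray:
        """Integrate V from rest given step-averaged input currents.

        ``i_syn[:, k]`` is the average injected current over the interval
        [k·dt, (k+1)·dt); the returned sample k is V at t = (k+1)·dt.
        Accepts (n_seg, n_t) or (n_seg, n_t, n_rhs).
        """
        single = i_syn.ndim == 2
        if single:
            i_syn = i_syn[:, :, None]
        n_seg, n_t, n_rhs = i_syn.shape
        v = np.zeros((n_seg, n_rhs))
        out = np.empty((n_seg, n_t, n_rhs))
        for k in range(n_t):
            rhs = self._b_mat @ v + i_syn[:, k, :]
            v = self._lu.solve(rhs)
            out[:, k, :] = v
        return out[:, :, 0] if single else out

    def event_current_sequence(self, event: SynapticEvent,
                               n_t: int) -> np.ndarray:
        """Step-averaged synaptic current of one event (length n_t).

        The exponential J·exp(-(t - onset)/τ) is integrated exactly over
        each time step, so the injected charge is exact regardless of where
        the onset falls within a step.
        """
        dt = self.dt
        k = np.arange(n_t)
        t0 = np.maximum(k * dt, event.onset)
        t1 = (k + 1) * dt
        seq = np.zeros(n_t)
        mask = t1 > event.onset
        tau = event.tau_syn
        seq[mask] = (event.weight * tau / dt
                     * (np.exp(-(t0[mask] - event.onset) / tau)
                        - np.exp(-(t1[mask] - event.onset) / tau)))
        return seq

    def input_currents(self, events, n_t: int) -> np.ndarray:
        """Step-averaged synaptic currents (n_seg, n_t) for a list of
        events."""
        n = self.m.n_segments
        i_syn = np.zeros((n, n_t))
        for ev in events:
            if not 0 <= ev.segment < n:
                raise IndexError(f"event targets segment {ev.segment}, "
                                 f"morphology has {n}")
            i_syn[ev.segment] += self.event_current_sequence(ev, n_t)
        return i_syn

    def membrane_currents(self, v: np.ndarray) -> np.ndarray:
        """Transmembrane (extracellular source) currents from voltages.

        I_n = -(L v)_n with L the axial Laplacian; identical to
        capacitive + leak - synaptic current and exactly conserved
        (columns of L sum to zero).
        """
        flat = v.reshape(v.shape[0], -1)
        out = -(self.lap @ flat)
        return out.reshape(v.shape)

    def solve(self, events, T: float) -> MembraneCurrentField:
        n_t = int(round(T / self.dt))
        i_syn = self.input_currents(events, n_t)
        v = self._march(i_syn)
        return MembraneCurrentField(self.membrane_currents(v), self.dt)

    def _eigen_basis(self):
        """Eigendecomposition of the symmetrized cable operator.

        With y = C^(1/2) V the trapezoidal update diagonalizes in the
        eigenbasis of S = C^(-1/2) G C^(-1/2) (symmetric positive
        definite), giving per-mode geometric recursions; used to evaluate
        impulse responses in closed form.
        """
        if not hasattr(self, "_eig"):
            cis = 1.0 / np.sqrt(self.c_m)
            g_total = (sp.diags(self.g_leak) + self.lap).toarray()
            s_mat = cis[:, None] * g_total * cis[None, :]
            lam, q = np.linalg.eigh(s_mat)
            self._eig = (lam, q, cis)
        return self._eig

    def impulse_current_responses(self, sources, n_t: int) -> np.ndarray:
        """Discrete unit-impulse current responses.

        For each source segment s, injects the discrete input sequence
        i[k] = δ_{k0} (1 nA average over the first step) at s and returns
        the membrane currents, shape (n_sources, n_segments, n_t).  The
        response to an arbitrary input sequence at s is the discrete
        convolution of this response with that sequence (exact, by
        linearity of the scheme).  Evaluated in the modal basis, which is
        algebraically identical to marching the trapezoidal scheme.
        """
        sources = np.asarray(sources, dtype=int)
        lam, q, cis = self._eigen_basis()
        inv_dt = 1.0 / self.dt
        a = (inv_dt - lam / 2) / (inv_dt + lam / 2)
        b = 1.0 / (inv_dt + lam / 2)
        # mode amplitudes over time: z_k = a^k * b * (W e_s)
        powers = a[:, None] ** np.arange(n_t)[None, :]      # (m, n_t)
        w_src = q.T[:, sources] * cis[sources][None, :]     # (m, ns)
        p_volt = cis[:, None] * q                           # (n, m)
        p_cur = -(self.lap @ p_volt)                        # (n, m)
        core = b[:, None] * powers                          # (m, n_t)
        out = np.empty((sources.size, self.m.n_segments, n_t))
        for j in range(sources.size):
            out[j] = p_cur @ (core * w_src[:, j:j + 1])
        return out


def solve_passive(morphology: Morphology, params: PassiveParams, events,
                  dt: float, T: float) -> MembraneCurrentField:
    """One-shot passive solve; see :class:`PassiveCableSolver`."""
    return PassiveCableSolver(morphology, params, dt).solve(events, T)


# ---------------------------------------------------------------------------
# extracellular forward models
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeArray:
    """Extracellular recording contacts in an infinite homogeneous medium."""

    positions: np.ndarray       # (n, 3) μm
    sigma: float = 0.3          # S/m
    min_distance: float = 5.0   # μm source-contact clamp

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def default_electrode_array(n_contacts: int = 16, spacing: float = 100.0,
                            top_z: float = 0.0) -> ElectrodeArray:
    """Laminar probe: contacts at x=y=0, z = top_z - i*spacing."""
    z = top_z - spacing * np.arange(n_contacts)
    pos = np.column_stack([np.zeros(n_contacts), np.zeros(n_contacts), z])
    return ElectrodeArray(pos)


def _stable_u(u: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """sqrt(u² + r²) - u, evaluated without cancellation for u > 0."""
    root = np.sqrt(u ** 2 + r2)
    out = root - u
    pos = u > 0
    out[pos] = r2[pos] / (root[pos] + u[pos])
    return out


def line_source_matrix(morphology: Morphology,
                       electrodes: ElectrodeArray) -> np.ndarray:
    """Mapping M (n_contacts, n_segments): LFP_μV = M @ I_nA.

    Each segment contributes as a uniform line source in an infinite
    homogeneous medium; the soma segment is treated as a point source at
    its midpoint.  Perpendicular (and point-source) distances are clamped
    at ``electrodes.min_distance``.
    """
    m, e = morphology, electrodes
    pos = e.positions[:, None, :]                      # (ne, 1, 3)
    a = m.start[None, :, :]
    b = m.end[None, :, :]
    ds = m.length[None, :]
    mu = (m.end - m.start) / m.length[:, None]
    x = np.einsum("enk,nk->en", pos - a, mu)           # longitudinal coord
    r2 = np.maximum(np.sum((pos - a) ** 2, axis=2) - x ** 2, 0.0)
    r2 = np.maximum(r2, e.min_distance ** 2)
    num = _stable_u(x - ds, r2)
    den = _stable_u(x, r2)
    mat = np.log(num / den) / ds / (4 * np.pi * e.sigma)

    soma = m.soma_index
    d_soma = np.linalg.norm(e.positions - m.midpoint[soma], axis=1)
    d_soma = np.maximum(d_soma, e.min_distance)
    mat[:, soma] = 1.0 / (4 * np.pi * e.sigma * d_soma)
    return mat * 1e3   # nA / (S/m) / μm -> μV


def lfp_line_source(currents: MembraneCurrentField, morphology: Morphology,
                    electrodes: ElectrodeArray) -> np.ndarray:
    """Extracellular potential traces (n_contacts, n_t) in μV."""
    return line_source_matrix(morphology, electrodes) @ currents.currents


@dataclass
class DipoleTrace:
    """Current dipole moment p(t) in nA·μm, shape (3, n_t)."""

    p: np.ndarray
    dt: float


def current_dipole(currents: MembraneCurrentField,
                   morphology: Morphology) -> DipoleTrace:
    """p(t) = Σ_n I_n(t) r_n over segment midpoints.

    Warns if the net membrane current is not conserved (the dipole would
    then depend on the coordinate origin).
    """
    if currents.conservation_error() > 1e-6:
        warnings.warn("net membrane current is nonzero; dipole moment is "
                      "origin-dependent", stacklevel=2)
    p = morphology.midpoint.T @ currents.currents
    return DipoleTrace(p, currents.dt)


# ---------------------------------------------------------------------------
# four-sphere head model
# ---------------------------------------------------------------------------

@dataclass
class FourSphereParams:
    """Concentric brain/CSF/skull/scalp head model (standard values)."""

    radii: tuple = (79.0, 80.0, 85.0, 90.0)            # mm, outer radii
    sigmas: tuple = (0.3, 1.5, 0.015, 0.3)             # S/m
    n_max: int = 100
    rtol: float = 1e-6  # convergence check on the truncated series

    def __post_init__(self):
        if not all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if min(self.sigmas) <= 0:
            raise ValueError("conductivities must be > 0")


def _four_sphere_radial_coeffs(head: FourSphereParams, rz_mm: float,
                               r_e_mm: float, n: int):
    """Shell-4 radial factor for expansion order n, unit source coefficient.

    Solves the 7x7 boundary-condition system (continuity of potential and
    radial current density at the three inner interfaces, zero radial
    current at the scalp surface) in a per-shell scaled basis.  The source
    term in shell 1 is (rz/r)^(n+1); returns the shell-4 radial factor
    A4*(r_e/r4)^n + B4*(r3/r_e)^(n+1) for a unit source coefficient.
    """
    r1, r2, r3, r4 = head.radii
    s1, s2, s3, s4 = head.sigmas
    rz = rz_mm

    # unknowns: A1, A2, B2, A3, B3, A4, B4
    # basis in shell j: A_j*(r/r_j)^n + B_j*(r_{j-1}/r)^(n+1)
    # source in shell 1: (rz/r)^(n+1)
    def f(r, rj):
        return (r / rj) ** n

    def fp(r, rj):  # d/dr
        return n / r * (r / rj) ** n

    def g(r, rin):
        return (rin / r) ** (n + 1)

    def gp(r, rin):
        return -(n + 1) / r * (rin / r) ** (n + 1)

    a = np.zeros((7, 7))
    rhs = np.zeros(7)
    # interface r1: phi1 = phi2 ; s1 phi1' = s2 phi2'
    a[0] = [f(r1, r1), -f(r1, r2), -g(r1, r1), 0, 0, 0, 0]
    rhs[0] = -g(r1, rz)
    a[1] = [s1 * fp(r1, r1), -s2 * fp(r1, r2), -s2 * gp(r1, r1), 0, 0, 0, 0]
    rhs[1] = -s1 * gp(r1, rz)
    # interface r2
    a[2] = [0, f(r2, r2), g(r2, r1), -f(r2, r3), -g(r2, r2), 0, 0]
    a[3] = [0, s2 * fp(r2, r2), s2 * gp(r2, r1),
            -s3 * fp(r2, r3), -s3 * gp(r2, r2), 0, 0]
    # interface r3
    a[4] = [0, 0, 0, f(r3, r3), g(r3, r2), -f(r3, r4), -g(r3, r3)]
    a[5] = [0, 0, 0, s3 * fp(r3, r3), s3 * gp(r3, r2),
            -s4 * fp(r3, r4), -s4 * gp(r3, r3)]
    # outer surface: zero radial current
    a[6] = [0, 0, 0, 0, 0, fp(r4, r4), gp(r4, r3)]
    coef = np.linalg.solve(a, rhs)
    a4, b4 = coef[5], coef[6]
    return a4 * f(r_e_mm, r4) + b4 * g(r_e_mm, r3)


def four_sphere_transfer(head: FourSphereParams, location,
                         electrode) -> np.ndarray:
    """Transfer vector w (pV per nA·μm): scalp potential = w · p.

    ``location`` is the dipole position (μm, with origin at the center of
    the head model spheres translated so that the cortical surface is at
    z = 0: a point at depth z has radius r1 + z).  ``electrode`` is the
    scalp contact position in the same frame.  The dipole must be strictly
    inside the brain sphere.
    """
    r1 = head.radii[0]
    loc_mm = np.asarray(location, float) / 1e3 + np.array([0.0, 0.0, r1])
    center = np.zeros(3)
    rz = np.linalg.norm(loc_mm - center)
    if rz >= r1:
        raise ValueError("dipole location must be strictly inside the brain "
                         "sphere")
    e_mm = np.asarray(electrode, float) / 1e3 + np.array([0.0, 0.0, r1])
    re = np.linalg.norm(e_mm)
    if not head.radii[2] < re <= head.radii[3] + 1e-9:
        raise ValueError("electrode must lie in the scalp shell")

    rhat = (loc_mm - center) / rz
    ehat = e_mm / re
    cos_t = float(np.clip(ehat @ rhat, -1.0, 1.0))
    tan_vec = ehat - cos_t * rhat
    tn = np.linalg.norm(tan_vec)
    that = tan_vec / tn if tn > 1e-12 else np.zeros(3)

    s1 = head.sigmas[0]
    # Legendre P_n and P_n^1 at cos_t via recurrences
    n_max = head.n_max
    pn = np.zeros(n_max + 1)
    pn1 = np.zeros(n_max + 1)
    pn[0] = 1.0
    if n_max >= 1:
        pn[1] = cos_t
        sin_t = np.sqrt(max(0.0, 1.0 - cos_t ** 2))
        pn1[1] = -sin_t  # P_1^1 (Condon–Shortley)
        if n_max >= 2:
            pn1[2] = -3.0 * sin_t * cos_t
    for n in range(2, n_max + 1):
        pn[n] = ((2 * n - 1) * cos_t * pn[n - 1] - (n - 1) * pn[n - 2]) / n
        if n >= 3:
            pn1[n] = ((2 * n - 1) * cos_t * pn1[n - 1]
                      - n * pn1[n - 2]) / (n - 1)

    w_rad = 0.0
    w_tan = 0.0
    tail_rad = tail_tan = 0.0
    for n in range(1, n_max + 1):
        radial_factor = _four_sphere_radial_coeffs(head, rz, re, n)
        # radial dipole: source coefficient n * p /(4 pi s1 rz^2)
        term_rad = radial_factor * n * pn[n] / (4 * np.pi * s1 * rz ** 2)
        # tangential dipole: source coefficient -p/(4 pi s1 rz^2), P_n^1
        term_tan = -radial_factor * pn1[n] / (4 * np.pi * s1 * rz ** 2)
        w_rad += term_rad
        w_tan += term_tan
        tail_rad, tail_tan = abs(term_rad), abs(term_tan)
    scale_ref = max(abs(w_rad), abs(w_tan), 1e-300)
    if max(tail_rad, tail_tan) > head.rtol * scale_ref:
        raise RuntimeError(
            "four-sphere series not converged at truncation order "
            f"{n_max}; last-term magnitude {max(tail_rad, tail_tan):.2e}")
    # units: p in nA·μm = 1e-15 A·m, rz in mm: 1/(S/m · mm²) = 1e6 /(S·m)
    # => volts per (nA·μm) = 1e-9; report pV => 1e3
    w = (w_rad * rhat + w_tan * that) * 1e3
    return w


def eeg_four_sphere(dipole: DipoleTrace, location,
                    head: FourSphereParams | None = None,
                    electrode=None) -> np.ndarray:
    """Scalp potential trace (pV) for a dipole at ``location``.

    By default the electrode sits at the vertex, directly above the
    population (x = y = 0 at the scalp surface).
    """
    if head is None:
        head = FourSphereParams()
    if electrode is None:
        electrode = np.array([0.0, 0.0, (head.radii[3] - head.radii[0])
                              * 1e3])
    w = four_sphere_transfer(head, location, electrode)
    return w @ dipole.p
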