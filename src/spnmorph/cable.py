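"""Passive branched-cable simulation with glutamatergic synapses.

The dendritic tree is discretised into cylindrical compartments (soma: one
isopotential sphere).  Membrane dynamics are passive; spine membrane is folded
in by multiplying C_m and dividing R_m by the correction F(x), which leaves
the membrane time constant R_m·C_m invariant.  Synapses are dual-exponential
AMPA/NMDA conductances with a voltage-dependent magnesium block on the NMDA
component.  The cable equation is integrated with a Crank–Nicolson scheme;
the time-varying synaptic conductances enter through a low-rank Woodbury
update of a pre-factorised system matrix, so each step costs one sparse
triangular solve.

Units: μm (geometry), ms (time), mV (voltage), nF (capacitance),
μS (conductance), nA (current); specific constants in μF/cm², Ω·cm², Ω·cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .core import DENDRITE, Reconstruction
from .morphometry import Segment, partition_segments, segment_profile


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane constants (F-correction applied separately)."""

    c_m: float = 1.0          # μF/cm²
    r_m: float = 10000.0      # Ω·cm²
    r_a: float = 150.0        # Ω·cm
    e_leak: float = -85.0     # mV
    temperature: float = 35.0  # °C

    def __post_init__(self):
        if min(self.c_m, self.r_m, self.r_a) <= 0:
            raise ValueError("c_m, r_m and r_a must be positive")
        if not -100.0 <= self.e_leak <= 0.0:
            raise ValueError("e_leak outside the physiological range")


# R_m presets are calibration constants: they set the measured terminal decay
# ordering (mouse < human) and keep the terminal electrotonic length similar
# across species; see docs/methods.md.
PASSIVE_PRESETS = {
    "mouse": PassiveParams(r_m=8000.0),
    "human": PassiveParams(r_m=15000.0),
}

# reversal potentials stored for the active-channel interface; unused in
# passive runs
E_NA_MV = 53.34
E_K_MV = -105.9

# NMDA:AMPA peak-conductance ratio is a calibration constant: with the base
# AMPA conductance of 0.5 nS it sets the clustered-input local depolarisation
# to ~50 mV on the mouse preset and makes the plateau NMDA-dependent; see
# docs/methods.md.
NMDA_AMPA_RATIO = 2.0


def space_constant(d_um: float, r_m: float, r_a: float) -> float:
    """Steady-state space constant λ = √(R_m·d/(4·R_a)), in μm."""
    if d_um <= 0 or r_m <= 0 or r_a <= 0:
        raise ValueError("diameter and resistivities must be positive")
    lam_cm = np.sqrt(r_m * (d_um * 1e-4) / (4.0 * r_a))
    return float(lam_cm * 1e4)


@dataclass
class ElectrotonicSummary:
    segment_index: int
    diameter: float      # μm
    length: float        # μm (physical, l)
    lam: float           # μm (space constant, λ)
    L: float             # l/λ, dimensionless


def electrotonic_lengths(recon: Reconstruction, passive: PassiveParams,
                         segments: list[Segment] | None = None
                         ) -> list[ElectrotonicSummary]:
    """Electrotonic length L = l/λ of every terminal segment."""
    if segments is None:
        segments = partition_segments(recon)
    out = []
    for s in segments:
        if not s.is_terminal:
            continue
        lam = space_constant(s.mean_diameter, passive.r_m, passive.r_a)
        out.append(ElectrotonicSummary(s.index, s.mean_diameter, s.length,
                                       lam, s.length / lam))
    return out


# ---------------------------------------------------------------------------
# model construction


class CableModel:
    """Compartmentalised reconstruction with corrected passive membrane."""

    def __init__(self, length_um, diam_um, x_mid_um, parent, is_soma,
                 passive: PassiveParams, f_correction=None,
                 channel_profiles=None, segments=None, seg_of_comp=None,
                 soma_radius_um: float | None = None):
        self.length_um = np.asarray(length_um, dtype=float)
        self.diam_um = np.asarray(diam_um, dtype=float)
        self.x_mid_um = np.asarray(x_mid_um, dtype=float)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.is_soma = np.asarray(is_soma, dtype=bool)
        self.passive = passive
        self.channel_profiles = dict(channel_profiles or {})
        self.segments = segments
        self.seg_of_comp = seg_of_comp
        n = len(self.length_um)

        # membrane areas (cm²); soma is a sphere, dendrites are cylinders
        area = np.where(
            self.is_soma,
            4.0 * np.pi * (soma_radius_um or 0.0) ** 2 * 1e-8,
            np.pi * self.diam_um * self.length_um * 1e-8)
        self.area_cm2 = area
        f = np.ones(n)
        if f_correction is not None:
            dend = ~self.is_soma
            f[dend] = np.asarray(f_correction(self.x_mid_um[dend]), dtype=float)
        self.f_x = f
        self.c_nF = passive.c_m * f * area * 1e3
        self.g_leak_uS = area * f / passive.r_m * 1e6

        # axial conductance to the parent; soma contributes no half-resistance
        g_ax = np.zeros(n)
        half = np.where(
            self.is_soma, 0.0,
            passive.r_a * (self.length_um / 2 * 1e-4)
            / (np.pi * (self.diam_um / 2 * 1e-4) ** 2))
        for k in range(n):
            p = self.parent[k]
            if p >= 0:
                g_ax[k] = 1e6 / (half[k] + half[p]) if (half[k] + half[p]) > 0 \
                    else 0.0
        self.g_axial_uS = g_ax

    @property
    def n_comp(self) -> int:
        return len(self.length_um)

    @property
    def soma_comp(self) -> int:
        return int(np.argmax(self.is_soma)) if self.is_soma.any() else 0

    def conductance_matrix(self) -> sparse.csr_matrix:
        """Leak + axial conductance matrix K (μS), so I_mem = K·V − g_leak·E."""
        n = self.n_comp
        rows, cols, vals = [], [], []
        diag = self.g_leak_uS.copy()
        for k in range(n):
            p = self.parent[k]
            if p >= 0 and self.g_axial_uS[k] > 0:
                g = self.g_axial_uS[k]
                diag[k] += g
                diag[p] += g
                rows += [k, p]
                cols += [p, k]
                vals += [-g, -g]
        K = sparse.coo_matrix(
            (np.concatenate([diag, vals]) if vals else diag,
             (np.concatenate([np.arange(n), rows]) if rows else np.arange(n),
              np.concatenate([np.arange(n), cols]) if cols else np.arange(n))),
            shape=(n, n))
        return K.tocsr()

    # -- locators -----------------------------------------------------------
    def comps_of_segment(self, seg_index: int) -> np.ndarray:
        return np.flatnonzero(self.seg_of_comp == seg_index)

    def comp_at(self, seg_index: int, fraction: float) -> int:
        """Compartment at an arc fraction (0 = base, 1 = tip) of a segment."""
        comps = self.comps_of_segment(seg_index)
        if len(comps) == 0:
            raise ValueError(f"segment {seg_index} has no compartments")
        i = int(round(fraction * (len(comps) - 1)))
        return int(comps[np.clip(i, 0, len(comps) - 1)])


def build_cable_model(recon: Reconstruction, passive: PassiveParams,
                      f_correction=None, channel_profiles=None,
                      d_lambda: float = 0.1, max_comp_um: float = 10.0
                      ) -> CableModel:
    """Discretise a standardised reconstruction into a cable model.

    Compartment length is at most min(d_lambda·λ_local, max_comp_um); the
    soma sphere is one isopotential compartment.  ``f_correction`` is a
    callable F(x) applied to dendritic compartments (C_m·F, R_m/F).
    """
    if not recon.is_standardized:
        raise ValueError("build_cable_model expects a standardised reconstruction")
    if not np.all(np.isfinite(recon.xyz)) or not np.all(np.isfinite(recon.radius)):
        raise ValueError("non-finite geometry")
    segments = partition_segments(recon)
    soma_r = recon.soma_radius

    length, diam, xmid, parent, seg_of = [0.0], [2 * soma_r], [0.0], [-1], [-1]
    is_soma = [True]
    last_comp_of_seg: dict[int, int] = {}
    for seg in segments:
        arc, dprof = segment_profile(recon, seg)
        total = float(arc[-1])
        mean_d = max(seg.mean_diameter, 1e-3)
        lam = space_constant(mean_d, passive.r_m, passive.r_a)
        target = min(d_lambda * lam, max_comp_um)
        n = max(1, int(np.ceil(total / target))) if total > 0 else 1
        dl = total / n if total > 0 else 1e-3
        pcomp = (0 if seg.parent < 0
                 else last_comp_of_seg[seg.parent])
        for i in range(n):
            mid = (i + 0.5) * dl
            d_here = float(np.interp(mid, arc, dprof)) if total > 0 \
                else seg.mean_diameter
            length.append(dl)
            diam.append(max(d_here, 1e-3))
            xmid.append(seg.base_path_distance + mid)
            parent.append(pcomp)
            seg_of.append(seg.index)
            is_soma.append(False)
            pcomp = len(length) - 1
        last_comp_of_seg[seg.index] = pcomp

    return CableModel(length, diam, xmid, parent, is_soma, passive,
                      f_correction=f_correction,
                      channel_profiles=channel_profiles,
                      segments=segments,
                      seg_of_comp=np.asarray(seg_of, dtype=np.int64),
                      soma_radius_um=soma_r)


def cylinder_model(length_um: float, diam_um: float, passive: PassiveParams,
                   n_comp: int = 100, f_correction=None) -> CableModel:
    """Uniform unbranched cylinder, sealed at both ends (analytic test rig)."""
    dl = length_um / n_comp
    length = [dl] * n_comp
    diam = [diam_um] * n_comp
    xmid = [(i + 0.5) * dl for i in range(n_comp)]
    parent = [-1] + list(range(n_comp - 1))
    return CableModel(length, diam, xmid, parent, [False] * n_comp, passive,
                      f_correction=f_correction)


def isopotential_model(radius_um: float, passive: PassiveParams) -> CableModel:
    """A single spherical compartment (τ = R_m·C_m oracle rig)."""
    return CableModel([0.0], [2 * radius_um], [0.0], [-1], [True], passive,
                      soma_radius_um=radius_um)


# ---------------------------------------------------------------------------
# stimuli


@dataclass(frozen=True)
class CurrentStep:
    comp: int
    t_on: float       # ms
    t_off: float      # ms
    amplitude: float  # nA


@dataclass
class Synapse:
    """Dual-exponential AMPA and/or NMDA conductance at one compartment.

    NMDA carries the Jahr–Stevens magnesium block
    1/(1 + [Mg]/K_mg · e^(−γV)); its conductance is evaluated at the previous
    step's local voltage (lagged linearisation).
    """

    comp: int
    onsets: np.ndarray                  # ms
    g_ampa: float = 0.5                 # nS peak
    g_nmda: float = 1.0                 # nS peak (NMDA:AMPA ratio 2.0)
    tau_ampa: tuple[float, float] = (0.2, 1.7)    # rise, decay ms
    tau_nmda: tuple[float, float] = (2.0, 100.0)  # rise, decay ms
    e_rev: float = 0.0                  # mV
    mg_mM: float = 1.0
    k_mg_mM: float = 3.57
    gamma_per_mV: float = 0.062

    def __post_init__(self):
        self.onsets = np.sort(np.asarray(self.onsets, dtype=float))
        if self.g_ampa < 0 or self.g_nmda < 0:
            raise ValueError("peak conductances must be non-negative")

    def mg_block(self, v_mV: float) -> float:
        return 1.0 / (1.0 + (self.mg_mM / self.k_mg_mM)
                      * np.exp(-self.gamma_per_mV * v_mV))


def glutamate_synapse(comp: int, onsets, g_ampa_nS: float = 0.5,
                      nmda_ratio: float = NMDA_AMPA_RATIO,
                      conductance_scale: float = 1.0,
                      nmda_on: bool = True) -> Synapse:
    """AMPA+NMDA synapse with a common conductance scale (human: ×1.37)."""
    g = g_ampa_nS * conductance_scale
    return Synapse(comp=comp, onsets=np.asarray(onsets, dtype=float),
                   g_ampa=g, g_nmda=g * nmda_ratio if nmda_on else 0.0)


def _dualexp_norm(tau_r: float, tau_d: float) -> float:
    tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    return 1.0 / (np.exp(-tp / tau_d) - np.exp(-tp / tau_r))


# ---------------------------------------------------------------------------
# simulation


class SolverError(RuntimeError):
    pass


@dataclass
class SimResult:
    t: np.ndarray                 # ms
    v: np.ndarray                 # (n_probes, n_t) mV
    probes: list[int]

    def probe(self, comp: int) -> np.ndarray:
        return self.v[self.probes.index(comp)]


def simulate(model: CableModel, synapses: list[Synapse] = (),
             currents: list[CurrentStep] = (), dt: float = 0.025,
             t_stop: float = 100.0, probes: list[int] | None = None,
             v_init: float | None = None) -> SimResult:
    """Integrate the passive cable equation (Crank–Nicolson).

    Synaptic conductances enter via a rank-m Woodbury correction of the
    pre-factorised Crank–Nicolson matrix, m = number of synaptic
    compartments.  With zero stimulus the resting state is a fixed point.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = model.n_comp
    e_leak = model.passive.e_leak
    if probes is None:
        probes = [model.soma_comp]
    probes = list(probes)
    K = model.conductance_matrix()
    C = model.c_nF
    A0 = (sparse.diags(C / dt) + 0.5 * K).tocsc()
    lu = splu(A0)

    syn_comps = sorted({s.comp for s in synapses})
    m = len(syn_comps)
    comp_slot = {c: i for i, c in enumerate(syn_comps)}
    if m:
        eye = np.zeros((n, m))
        for i, c in enumerate(syn_comps):
            eye[c, i] = 1.0
        Z = lu.solve(eye)                      # n×m
        S = Z[syn_comps, :]                    # m×m

    # synapse state: exponential trackers for rise/decay of AMPA and NMDA
    st = []
    for s in synapses:
        st.append({
            "syn": s, "slot": comp_slot[s.comp], "ptr": 0,
            "a_r": 0.0, "a_d": 0.0, "n_r": 0.0, "n_d": 0.0,
            "dec": (np.exp(-dt / s.tau_ampa[0]), np.exp(-dt / s.tau_ampa[1]),
                    np.exp(-dt / s.tau_nmda[0]), np.exp(-dt / s.tau_nmda[1])),
            "norm_a": _dualexp_norm(*s.tau_ampa),
            "norm_n": _dualexp_norm(*s.tau_nmda),
        })

    n_steps = int(round(t_stop / dt))
    t = np.arange(n_steps + 1) * dt
    V = np.full(n, e_leak if v_init is None else v_init, dtype=float)
    out = np.empty((len(probes), n_steps + 1))
    out[:, 0] = V[probes]
    gl_e = model.g_leak_uS * e_leak

    def inj(time: float) -> np.ndarray:
        I = np.zeros(n)
        for c in currents:
            if c.t_on <= time < c.t_off:
                I[c.comp] += c.amplitude
        return I

    def syn_conductance(advance: bool, v_prev: np.ndarray, time: float
                        ) -> np.ndarray:
        """Per-slot total synaptic conductance (μS) at the current state."""
        g = np.zeros(m)
        for s in st:
            syn: Synapse = s["syn"]
            if advance:
                dr, dd, nr, nd = s["dec"]
                s["a_r"] *= dr
                s["a_d"] *= dd
                s["n_r"] *= nr
                s["n_d"] *= nd
                while (s["ptr"] < len(syn.onsets)
                       and syn.onsets[s["ptr"]] <= time + 1e-12):
                    s["a_r"] += 1.0
                    s["a_d"] += 1.0
                    s["n_r"] += 1.0
                    s["n_d"] += 1.0
                    s["ptr"] += 1
            g_ampa = syn.g_ampa * s["norm_a"] * (s["a_d"] - s["a_r"])
            g_nmda = (syn.g_nmda * s["norm_n"] * (s["n_d"] - s["n_r"])
                      * syn.mg_block(float(v_prev[syn.comp])))
            g[s["slot"]] += (g_ampa + g_nmda) * 1e-3   # nS → μS
        return g

    g_now = syn_conductance(False, V, 0.0) if m else np.zeros(0)
    I_now = inj(0.0)
    for step in range(1, n_steps + 1):
        time = step * dt
        I_next = inj(time)
        if m:
            g_next = syn_conductance(True, V, time)
        rhs = C / dt * V - 0.5 * (K @ V) + gl_e + 0.5 * (I_now + I_next)
        if m:
            # explicit half of the synaptic term; e_rev = 0 for glutamate so
            # only the conductance part appears
            rhs[syn_comps] -= 0.5 * g_now * V[syn_comps]
        y = lu.solve(rhs)
        if m and np.any(g_next > 0):
            gh = 0.5 * g_next
            Mw = np.eye(m) + gh[:, None] * S
            w = np.linalg.solve(Mw, gh * y[syn_comps])
            V = y - Z @ w
        else:
            V = y
        if not np.all(np.isfinite(V)):
            raise SolverError(f"non-finite voltage at t = {time:.3f} ms")
        out[:, step] = V[probes]
        I_now = I_next
        if m:
            g_now = g_next
    return SimResult(t, out, probes)


# ---------------------------------------------------------------------------
# measurements and protocols


def measure_tau(model: CableModel, comp: int | None = None, dt: float = 0.05,
                pulse_ms: float = 0.5, amp_nA: float = 0.02,
                settle_ms: float = 2.0, window_ms: float = 40.0) -> float:
    """Decay time constant after a brief small current pulse at ``comp``.

    A log-linear fit to the late decay (after ``settle_ms``) extracts the
    slowest relaxation; for a passive membrane with uniform R_m·C_m this is
    the membrane time constant.
    """
    if comp is None:
        comp = model.soma_comp
    e = model.passive.e_leak
    t_stop = pulse_ms + settle_ms + window_ms
    res = simulate(model, currents=[CurrentStep(comp, 0.0, pulse_ms, amp_nA)],
                   dt=dt, t_stop=t_stop, probes=[comp])
    v = res.probe(comp) - e
    sel = res.t >= pulse_ms + settle_ms
    vv = v[sel]
    if np.any(vv <= 0):
        # keep the strictly positive decaying part only
        last = np.argmax(vv <= 0)
        vv = vv[:last]
        sel_t = res.t[sel][:last]
    else:
        sel_t = res.t[sel]
    if len(vv) < 4:
        raise SolverError("decay too fast to fit; increase window or amplitude")
    slope, _ = np.polyfit(sel_t, np.log(vv), 1)
    if slope >= 0:
        raise SolverError("non-monotone decay; model is not passive")
    return float(-1.0 / slope)


@dataclass
class AttenuationProfile:
    fractions: np.ndarray      # arc fraction along the terminal (1 = tip)
    amplitudes: np.ndarray     # peak depolarisation at each probe, mV
    latencies: np.ndarray      # time of peak, ms
    soma_amplitude: float
    soma_latency: float


def epsp_attenuation(model: CableModel, terminal_seg: int,
                     n_probes: int = 5, conductance_scale: float = 1.0,
                     dt: float = 0.05, t_stop: float = 150.0
                     ) -> AttenuationProfile:
    """EPSP peak profile for a single AMPA+NMDA synapse at a terminal tip."""
    fracs = np.linspace(1.0, 0.0, n_probes)
    probes = [model.comp_at(terminal_seg, f) for f in fracs]
    soma = model.soma_comp
    syn = glutamate_synapse(probes[0], [5.0],
                            conductance_scale=conductance_scale)
    res = simulate(model, synapses=[syn], dt=dt, t_stop=t_stop,
                   probes=probes + [soma])
    e = model.passive.e_leak
    amps, lats = [], []
    for i in range(len(probes)):
        tr = res.v[i] - e
        amps.append(float(tr.max()))
        lats.append(float(res.t[int(np.argmax(tr))]))
    tr = res.v[-1] - e
    return AttenuationProfile(fracs, np.array(amps), np.array(lats),
                              float(tr.max()), float(res.t[int(np.argmax(tr))]))


@dataclass
class DriveResult:
    rate_hz: float
    mean_dend_mV: float       # time-averaged depolarisation, mid-terminal
    mean_soma_mV: float


def distributed_drive(model: CableModel, terminal_seg: int,
                      n_synapses: int = 10, rate_hz: float = 10.0,
                      t_stop: float = 2000.0, seed=None, dt: float = 0.05,
                      conductance_scale: float = 1.0) -> DriveResult:
    """Asynchronous Poisson drive through synapses spread along a terminal.

    Synapses sit at uniform arc spacing; each fires an independent Poisson
    train at ``rate_hz``.  Depolarisation is time-averaged over the last 80%
    of the run at the mid-terminal compartment and the soma.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    fracs = np.linspace(0.0, 1.0, n_synapses + 2)[1:-1]
    syns = []
    for f in fracs:
        n_exp = rate_hz * t_stop / 1000.0
        n_ev = rng.poisson(n_exp)
        onsets = np.sort(rng.uniform(0.0, t_stop, size=n_ev))
        syns.append(glutamate_synapse(model.comp_at(terminal_seg, float(f)),
                                      onsets,
                                      conductance_scale=conductance_scale))
    mid = model.comp_at(terminal_seg, 0.5)
    res = simulate(model, synapses=syns, dt=dt, t_stop=t_stop,
                   probes=[mid, model.soma_comp])
    e = model.passive.e_leak
    sel = res.t >= 0.2 * t_stop
    return DriveResult(rate_hz,
                       float((res.v[0, sel] - e).mean()),
                       float((res.v[1, sel] - e).mean()))


@dataclass
class ClusterResult:
    t: np.ndarray
    v_local: np.ndarray
    v_soma: np.ndarray
    local_peak_mV: float
    soma_peak_mV: float
    plateau_duration_ms: float   # time above 50% of the local peak


def clustered_drive(model: CableModel, terminal_seg: int,
                    n_synapses: int = 10, isi_ms: float = 1.0,
                    nmda_on: bool = True, conductance_scale: float = 1.0,
                    g_ampa_nS: float = 0.5, t_stop: float = 500.0,
                    dt: float = 0.05, t_start: float = 10.0) -> ClusterResult:
    """Sequential clustered synaptic input at the middle of a terminal.

    ``n_synapses`` synapses at the mid-point fire in sequence with ``isi_ms``
    intervals; the NMDA component can be switched off to expose its role in
    sustaining the local plateau.
    """
    mid = model.comp_at(terminal_seg, 0.5)
    syns = [glutamate_synapse(mid, [t_start + i * isi_ms],
                              g_ampa_nS=g_ampa_nS,
                              conductance_scale=conductance_scale,
                              nmda_on=nmda_on)
            for i in range(n_synapses)]
    res = simulate(model, synapses=syns, dt=dt, t_stop=t_stop,
                   probes=[mid, model.soma_comp])
    e = model.passive.e_leak
    v_loc = res.v[0] - e
    v_som = res.v[1] - e
    peak = float(v_loc.max())
    above = v_loc >= 0.5 * peak
    duration = float(above.sum() * dt)
    return ClusterResult(res.t, v_loc, v_som, peak, float(v_som.max()),
                         duration)


# ---------------------------------------------------------------------------
# species rescaling


def rescale_species(recon: Reconstruction, diam_factor: float,
                    terminal_length_factor: float,
                    soma_radius: float | None = None) -> Reconstruction:
    """Swap a reconstruction between species scales.

    Dendritic diameters are multiplied by ``diam_factor``; every terminal
    segment is stretched along its own course about its base node by
    ``terminal_length_factor`` (branch points stay put); the soma sphere
    radius is replaced.  Mouse→human uses (1.7, 2.0); human→mouse (0.6, 0.5).
    """
    if diam_factor <= 0 or terminal_length_factor <= 0:
        raise ValueError("scale factors must be positive")
    out = recon.copy()
    dend = out.types == DENDRITE
    out.radius[dend] *= diam_factor
    segs = partition_segments(recon)
    for seg in segs:
        if not seg.is_terminal:
            continue
        base = recon.xyz[seg.node_path[0]]
        for r in seg.node_path[1:]:
            out.xyz[r] = base + terminal_length_factor * (recon.xyz[r] - base)
    if soma_radius is not None:
        out.radius[out.root_index] = soma_radius
    prov = dict(out.provenance)
    prov["rescaled"] = f"diam×{diam_factor}, terminal×{terminal_length_factor}"
    out.provenance = prov
    return out
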