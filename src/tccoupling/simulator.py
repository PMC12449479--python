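"""Trial execution: spatial discretization, implicit time stepping, probes.

The branched cable equation is integrated with backward Euler (gate states
updated by staggered analytic relaxation), which is unconditionally stable
for the stiff Ca²⁺ dynamics.  Compartments are split so that no segment
exceeds ``max_seg_length``; segments are kept in parent-before-child (Hines)
order so the linearized tree system is solved exactly in O(n) per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .errors import NumericalError, ParameterError, TreeLookupError
from .membrane import CellModel, FARADAY, GAS_R, double_exp_peak_time
from .morphology import Location

__all__ = [
    "SimConfig",
    "Injection",
    "SolverGrid",
    "SimState",
    "TrialRecording",
    "discretize",
    "init_state",
    "step",
    "run_trial",
    "detect_somatic_aps",
    "run_validation_protocols",
    "ValidationReport",
    "default_probes",
]


@dataclass(frozen=True)
class SimConfig:
    """Numerical configuration of a simulation trial.

    ``probe_sites`` maps labels to tree locations; trials used for the
    response analyses must include a ``soma`` probe and an apical Ca²⁺-zone
    probe (see :func:`default_probes`, which places the latter on the trunk
    100 µm below the primary branch point, where the thalamocortical synapse
    density peaks).
    """

    dt: float = 0.025                 # ms
    max_seg_length: float = 50.0      # µm
    v_init: float = -75.0             # mV
    probe_sites: tuple = ()           # ((label, Location), ...)
    record_stride: int = 1
    celsius: float = 34.0
    theta: float = 1.0      # 1 = backward Euler; 0.5 = Crank-Nicolson

    def __post_init__(self):
        if self.dt <= 0 or self.max_seg_length <= 0:
            raise ParameterError("dt and max_seg_length must be positive")
        if self.record_stride < 1:
            raise ParameterError("record_stride must be >= 1")
        if not (0.5 <= self.theta <= 1.0):
            raise ParameterError("theta must lie in [0.5, 1]")


def default_probes(morph, ca_zone_offset: float = 100.0) -> tuple:
    """Soma probe plus an apical probe at the TC-density peak below the BP."""
    target = morph.bp_distance - ca_zone_offset
    return (("soma", (morph.soma.id, 0.5)),
            ("apical", morph.location_at_distance(target, domains=("trunk",))))


@dataclass(frozen=True)
class Injection:
    """Injected current at a tree location.

    ``kind`` is ``"step"`` (constant ``amplitude_na`` for ``duration_ms``)
    or ``"epsp"`` (double-exponential waveform peaking at ``amplitude_na``).
    """

    location: Location
    onset_ms: float
    amplitude_na: float
    kind: str = "step"
    duration_ms: float = 0.0
    tau_rise: float = 0.5
    tau_decay: float = 5.0

    def waveform(self, t: np.ndarray) -> np.ndarray:
        rel = t - self.onset_ms
        if self.kind == "step":
            return np.where((rel >= 0) & (rel < self.duration_ms),
                            self.amplitude_na, 0.0)
        if self.kind == "epsp":
            tp = double_exp_peak_time(self.tau_rise, self.tau_decay)
            norm = 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))
            w = norm * (np.exp(-rel / self.tau_decay) - np.exp(-rel / self.tau_rise))
            return np.where(rel < 0, 0.0, self.amplitude_na * w)
        raise ParameterError(f"unknown injection kind {self.kind!r}")


@dataclass
class TrialRecording:
    """Membrane-potential traces at the probes plus somatic spike times."""

    time: np.ndarray                  # ms
    vm_traces: dict                   # label -> mV array
    somatic_spike_times: np.ndarray   # ms
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


class SolverGrid:
    """Flat-array representation of a discretized cell (see module docs)."""

    def __init__(self, cell: CellModel, config: SimConfig):
        self.cell = cell
        self.config = config
        morph = cell.morphology
        bio = cell.biophys

        parent, a_par, cm_nf, gl_us, el = [], [], [], [], []
        seg_comp, seg_dist, seg_area = [], [], []
        comp_segs: dict[int, tuple[int, int]] = {}
        comp_seg_index = {}  # comp_id -> index of its last segment
        for c in morph.compartments:
            nseg = max(1, int(math.ceil(c.length / config.max_seg_length)))
            dp, dd = cell.scaled_diameters(c.id)
            start = len(parent)
            for j in range(nseg):
                f0, f1 = j / nseg, (j + 1) / nseg
                d_lo = dp + (dd - dp) * f0
                d_hi = dp + (dd - dp) * f1
                l_um = c.length / nseg
                area_cm2 = math.pi * 0.5 * (d_lo + d_hi) * l_um * 1e-8
                if j == 0:
                    par = -1 if c.parent_id is None else comp_seg_index[c.parent_id]
                else:
                    par = len(parent) - 1
                parent.append(par)
                seg_comp.append(c.id)
                mid = c.proximal_distance + (f0 + f1) / 2 * c.length
                if c.domain == "soma":
                    mid = 0.0
                seg_dist.append(mid)
                seg_area.append(area_cm2)
                cm_nf.append(cell.cm[c.id] * area_cm2 * 1e3)
                gl_us.append(cell.g_leak[c.id] * area_cm2 * 1e6)
                el.append(bio.passive.e_leak)
                a_par.append(0.0)  # filled below
            comp_segs[c.id] = (start, nseg)
            comp_seg_index[c.id] = len(parent) - 1

        n = len(parent)
        self.n = n
        self.parent = np.asarray(parent, dtype=np.int64)
        self.seg_comp = np.asarray(seg_comp, dtype=np.int64)
        self.seg_dist = np.asarray(seg_dist)
        self.seg_area_cm2 = np.asarray(seg_area)
        self.cm_nf = np.asarray(cm_nf)
        self.gl_us = np.asarray(gl_us)
        self.el = np.asarray(el)
        self.comp_segs = comp_segs

        # axial conductances: half-segment resistances in series
        def half_res(i):  # ohm
            c = morph[self.seg_comp[i]]
            _, nseg = comp_segs[c.id]
            l_cm = (c.length / nseg) * 1e-4
            dp, dd = cell.scaled_diameters(c.id)
            # average radius of this segment
            start, _ = comp_segs[c.id]
            j = i - start
            f_mid = (j + 0.5) / nseg
            r_cm = 0.25 * (dp + (dd - dp) * f_mid) * 1e-4
            return bio.passive.ra * (l_cm / 2) / (math.pi * r_cm ** 2)

        a = np.zeros(n)
        for i in range(1, n):
            r = half_res(i) + half_res(self.parent[i])
            a[i] = 1e6 / r  # µS
        self.a_par = a

        # channels / gates
        chan_ptr, chan_seg, chan_gbar = [0], [], []
        chan_erev, chan_isca, chan_caflux, chan_gptr = [], [], [], [0]
        gp = {k: [] for k in ("vhalf", "k", "tmin", "tamp", "vtau", "sigma",
                              "q", "cadep", "cahalf", "cahill", "power", "off")}
        self.channels = list(bio.channels)
        total_states = 0
        for ch in bio.channels:
            for i in range(n):
                comp = int(self.seg_comp[i])
                dens = cell.density_at(ch.name, comp, float(self.seg_dist[i]))
                if dens > 0.0:
                    chan_seg.append(i)
                    chan_gbar.append(dens * self.seg_area_cm2[i] * 1e6)  # µS
            chan_ptr.append(len(chan_seg))
            nactive = chan_ptr[-1] - chan_ptr[-2]
            chan_erev.append(0.0 if ch.reversal == "ca_nernst" else float(ch.reversal))
            chan_isca.append(1 if ch.reversal == "ca_nernst" else 0)
            chan_caflux.append(1 if ch.ca_flux else 0)
            for g in ch.gates:
                gp["vhalf"].append(g.v_half)
                gp["k"].append(g.k)
                gp["tmin"].append(g.tau_min)
                gp["tamp"].append(g.tau_amp)
                gp["vtau"].append(g.v_tau)
                gp["sigma"].append(g.sigma)
                gp["q"].append(ch.q)
                gp["cadep"].append(1 if g.ca_dependent else 0)
                gp["cahalf"].append(g.ca_half)
                gp["cahill"].append(g.ca_hill)
                gp["power"].append(g.power)
                gp["off"].append(total_states)
                total_states += nactive
            chan_gptr.append(len(gp["power"]))

        self.chan_ptr = np.asarray(chan_ptr, dtype=np.int64)
        self.chan_seg = np.asarray(chan_seg, dtype=np.int64)
        self.chan_gbar = np.asarray(chan_gbar)
        self.chan_erev = np.asarray(chan_erev)
        self.chan_isca = np.asarray(chan_isca, dtype=np.uint8)
        self.chan_caflux = np.asarray(chan_caflux, dtype=np.uint8)
        self.chan_gptr = np.asarray(chan_gptr, dtype=np.int64)
        self.gate = {k: np.asarray(v, dtype=(np.int64 if k in ("power", "off")
                                             else (np.uint8 if k == "cadep" else float)))
                     for k, v in gp.items()}
        self.total_gate_states = total_states

        # calcium pool
        depth_cm = bio.ca.depth_um * 1e-4
        self.ca_factor = bio.ca.gamma * 1e-6 / (2 * FARADAY * self.seg_area_cm2 * depth_cm)
        self.ca_rest = bio.ca.ca_rest_mm
        self.ca_tau = bio.ca.decay_ms
        self.ca_out = bio.ca.ca_out_mm
        self.nernst_coef = 1e3 * GAS_R * (config.celsius + 273.15) / (2 * FARADAY)

        # synapses: double-exponential conductances superpose linearly, so
        # all synapses sharing (segment, receptor kinetics) are folded into
        # one compound state; an activation adds peak·norm to that state.
        s_seg, s_e, s_nmda, s_eta, s_gamma, s_tr, s_td = [], [], [], [], [], [], []
        compound: dict[tuple, int] = {}
        self.syn_of_id: dict[int, tuple] = {}
        for pl in cell.synapses:
            seg = self.loc_to_seg(pl.location)
            weight = cell.synapse_weight.get(pl.population, 1.0)
            idxs, ws = [], []
            for model in cell.synapse_models[pl.population]:
                is_nmda = model.kind == "NMDA"
                mg = model.mg_block
                eta = mg.eta_per_mm * mg.mg_mm if (is_nmda and mg) else 0.0
                gamma = mg.gamma_per_mv if (is_nmda and mg) else 1.0
                key = (seg, model.kind, model.tau_rise, model.tau_decay,
                       model.reversal, eta, gamma)
                if key not in compound:
                    compound[key] = len(s_seg)
                    s_seg.append(seg)
                    s_e.append(model.reversal)
                    s_nmda.append(1 if is_nmda else 0)
                    s_eta.append(eta)
                    s_gamma.append(gamma)
                    s_tr.append(model.tau_rise)
                    s_td.append(model.tau_decay)
                idxs.append(compound[key])
                # nS -> µS; event weight carries peak, normalization, plasticity
                ws.append(model.peak_conductance * 1e-3 * weight * model.norm)
            self.syn_of_id[pl.synapse_id] = (np.asarray(idxs, dtype=np.int64),
                                             np.asarray(ws))
        self.syn_seg = np.asarray(s_seg, dtype=np.int64)
        self.syn_g = np.ones(len(s_seg))
        self.syn_e = np.asarray(s_e)
        self.syn_nmda = np.asarray(s_nmda, dtype=np.uint8)
        self.syn_eta = np.asarray(s_eta)
        self.syn_gamma = np.asarray(s_gamma)
        self.syn_tau_r = np.asarray(s_tr)
        self.syn_tau_d = np.asarray(s_td)

        # probes
        labels, segs = [], []
        for label, loc in config.probe_sites:
            labels.append(label)
            segs.append(self.loc_to_seg(loc))
        self.probe_labels = labels
        self.probe_seg = np.asarray(segs, dtype=np.int64)

    # ------------------------------------------------------------------
    def loc_to_seg(self, location: Location) -> int:
        comp_id, frac = location
        if comp_id not in self.comp_segs:
            raise TreeLookupError(f"unknown compartment id {comp_id}")
        start, nseg = self.comp_segs[comp_id]
        j = min(nseg - 1, int(frac * nseg))
        return start + j

    def total_area(self) -> float:
        return float(np.sum(self.seg_area_cm2))

    def decay_factors(self, dt: float):
        return np.exp(-dt / self.syn_tau_r), np.exp(-dt / self.syn_tau_d)


def discretize(cell: CellModel, config: SimConfig) -> SolverGrid:
    """Split compartments to at most ``max_seg_length`` µm in Hines order."""
    return SolverGrid(cell, config)


@dataclass
class SimState:
    v: np.ndarray
    gx: np.ndarray
    ca: np.ndarray
    A: np.ndarray
    B: np.ndarray
    t_step: int = 0


def init_state(grid: SolverGrid, v_init: float | None = None) -> SimState:
    v0 = grid.config.v_init if v_init is None else v_init
    v = np.full(grid.n, float(v0))
    gx = np.empty(grid.total_gate_states)
    g = grid.gate
    for c, ch in enumerate(grid.channels):
        s0, s1 = grid.chan_ptr[c], grid.chan_ptr[c + 1]
        for gi in range(grid.chan_gptr[c], grid.chan_gptr[c + 1]):
            for j in range(s0, s1):
                if g["cadep"][gi]:
                    inf = 1.0 / (1.0 + (g["cahalf"][gi] / grid.ca_rest) ** g["cahill"][gi])
                else:
                    inf = 1.0 / (1.0 + math.exp(-(v0 - g["vhalf"][gi]) / g["k"][gi]))
                gx[g["off"][gi] + j - s0] = inf
    ca = np.full(grid.n, grid.ca_rest)
    A = np.zeros(len(grid.syn_seg))
    B = np.zeros(len(grid.syn_seg))
    return SimState(v, gx, ca, A, B, 0)


def _run_kernel(grid, state, ev_step, ev_syn, ev_w, inj_seg, inj, nsteps, out):
    fr, fd = grid.decay_factors(grid.config.dt)
    g = grid.gate
    status = _kernel.integrate(
        grid.parent, grid.a_par, grid.cm_nf / grid.config.dt, grid.gl_us, grid.el,
        grid.chan_ptr, grid.chan_seg, grid.chan_gbar, grid.chan_erev,
        grid.chan_isca, grid.chan_caflux, grid.chan_gptr,
        g["vhalf"], g["k"], g["tmin"], g["tamp"], g["vtau"], g["sigma"],
        g["q"], g["cadep"], g["cahalf"], g["cahill"], g["power"], g["off"],
        state.gx,
        state.ca, grid.ca_factor, grid.ca_rest, grid.ca_tau,
        grid.nernst_coef, grid.ca_out,
        grid.syn_seg, grid.syn_g, grid.syn_e, grid.syn_nmda, grid.syn_eta,
        grid.syn_gamma, fr, fd, state.A, state.B,
        ev_step, ev_syn, ev_w, inj_seg, inj,
        grid.probe_seg, grid.config.record_stride, out,
        state.v, grid.config.dt, state.t_step, nsteps, grid.config.theta,
    )
    if status >= 0:
        raise NumericalError(
            f"non-finite membrane potential at step {status} "
            f"(t = {status * grid.config.dt:.3f} ms)")
    state.t_step += nsteps


def step(grid: SolverGrid, state: SimState, events=(), injected_na=()) -> SimState:
    """Advance the state by one implicit time step.

    ``events`` is an iterable of synapse ids activated at this step;
    ``injected_na`` an iterable of (segment_index, current_nA).
    """
    idxs, ws = [], []
    for sid in events:
        ki, kw = grid.syn_of_id[sid]
        idxs.extend(ki.tolist())
        ws.extend(kw.tolist())
    ev_syn = np.asarray(idxs, dtype=np.int64)
    ev_step = np.full(len(idxs), state.t_step, dtype=np.int64)
    ev_w = np.asarray(ws)
    inj_list = list(injected_na)
    inj_seg = np.asarray([s for s, _ in inj_list], dtype=np.int64)
    inj = np.asarray([[c] for _, c in inj_list]) if inj_list else np.empty((0, 1))
    out = np.empty((len(grid.probe_seg), 2))
    _run_kernel(grid, state, ev_step, ev_syn, ev_w, inj_seg, inj, 1, out)
    return state


def _events_from_inputs(grid: SolverGrid, inputs, dt: float, nsteps: int):
    steps, syns, ws = [], [], []
    acts = inputs.activations  # merged once: the property concatenates epochs
    for sid in sorted(acts):
        times = acts[sid]
        if sid not in grid.syn_of_id:
            raise TreeLookupError(f"activation references unknown synapse id {sid}")
        ki, kw = grid.syn_of_id[sid]
        for t in times:
            if t < 0 or t > inputs.duration_ms:
                raise ParameterError(f"activation time {t} outside trial duration")
            s = min(int(round(t / dt)), nsteps - 1)
            for k, w in zip(ki, kw):
                steps.append(s)
                syns.append(k)
                ws.append(w)
    if not steps:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), np.empty(0))
    order = np.lexsort((np.asarray(syns), np.asarray(steps)))
    ev_step = np.asarray(steps, dtype=np.int64)[order]
    ev_syn = np.asarray(syns, dtype=np.int64)[order]
    ev_w = np.asarray(ws)[order]
    return ev_step, ev_syn, ev_w


def run_trial(cell: CellModel, inputs, config: SimConfig,
              injections=(), grid: SolverGrid | None = None,
              metadata: dict | None = None) -> TrialRecording:
    """Simulate one trial; deterministic given (cell, inputs, config).

    ``inputs`` provides ``activations`` (synapse id -> times in ms) and
    ``duration_ms``; epoch bookkeeping (discard windows, stimulus onset) is
    the caller's concern — the recording covers the full trial.
    """
    if grid is None:
        grid = discretize(cell, config)
    dt = config.dt
    nsteps = int(round(inputs.duration_ms / dt))
    ev_step, ev_syn, ev_w = _events_from_inputs(grid, inputs, dt, nsteps)

    inj_list = list(injections)
    t_full = np.arange(nsteps) * dt
    inj_seg = np.asarray([grid.loc_to_seg(j.location) for j in inj_list], dtype=np.int64)
    inj = (np.stack([j.waveform(t_full) for j in inj_list])
           if inj_list else np.empty((0, nsteps)))

    nrec = nsteps // config.record_stride + 1
    out = np.empty((len(grid.probe_seg), nrec))
    state = init_state(grid)
    _run_kernel(grid, state, ev_step, ev_syn, ev_w, inj_seg, inj, nsteps, out)

    time = np.arange(nrec) * dt * config.record_stride
    traces = {label: out[i].copy() for i, label in enumerate(grid.probe_labels)}
    meta = dict(metadata or {})
    meta.setdefault("dt", dt)
    meta.setdefault("t_onset", getattr(inputs, "t_onset", None))
    rec = TrialRecording(time, traces, np.empty(0), meta)
    if "soma" in traces:
        rec.somatic_spike_times = detect_somatic_aps(rec)
    return rec


def detect_somatic_aps(recording: TrialRecording, threshold: float = 0.0,
                       dead_time_ms: float = 1.0) -> np.ndarray:
    """Somatic spike times: strict upward crossings of the threshold with a
    minimum inter-event separation (linear interpolation between samples)."""
    v = recording.vm_traces["soma"]
    t = recording.time
    below = v[:-1] < threshold
    above = v[1:] > threshold
    idx = np.nonzero(below & above)[0]
    spikes = []
    last = -math.inf
    for i in idx:
        tc = t[i] + (threshold - v[i]) / (v[i + 1] - v[i]) * (t[i + 1] - t[i])
        if tc - last >= dead_time_ms:
            spikes.append(tc)
            last = tc
    return np.asarray(spikes)


# ---------------------------------------------------------------------------
# validation protocols
# ---------------------------------------------------------------------------

class _NoInputs:
    activations: dict = {}

    def __init__(self, duration_ms):
        self.duration_ms = duration_ms
        self.t_onset = None


@dataclass
class ValidationReport:
    """Electrophysiological characterization of a cell model.

    Checks the qualitative responses characteristic of layer-5 pyramidal
    tract neurons: a monotone f-I curve under prolonged somatic current
    steps, attenuated back-propagation of somatic APs into the apical
    dendrite, and BAC firing — a somatic AP paired with apical input within
    a few ms evokes a wide dendritic Ca²⁺ plateau that neither input alone
    produces.
    """

    fi_amps: list
    fi_counts: list
    bap_soma_amplitude: float
    bap_apical_amplitude: float
    coincidence_width: float
    apical_alone_width: float
    soma_alone_width: float

    @property
    def fi_monotone(self) -> bool:
        return all(b >= a for a, b in zip(self.fi_counts, self.fi_counts[1:]))

    @property
    def bap_attenuates(self) -> bool:
        return self.bap_apical_amplitude < self.bap_soma_amplitude

    @property
    def bac_firing(self) -> bool:
        return (self.coincidence_width >= 20.0
                and self.apical_alone_width < 20.0
                and self.soma_alone_width < 20.0)

    @property
    def passed(self) -> bool:
        return (self.fi_monotone and self.fi_counts[0] == 0
                and self.fi_counts[-1] >= 1 and self.bap_attenuates
                and self.bac_firing)


def _plateau_width(trace, time, threshold=-30.0):
    above = trace > threshold
    if not above.any():
        return 0.0
    # longest contiguous supra-threshold run
    best = cur = 0
    for a in above:
        cur = cur + 1 if a else 0
        best = max(best, cur)
    return best * float(time[1] - time[0])


def run_validation_protocols(cell: CellModel, config: SimConfig | None = None,
                             fi_amps=(0.0, 0.35, 0.55, 0.75),
                             bap_amp: float = 1.9,
                             bap_pulse_ms: float = 2.0,
                             bac_epsp_amp: float = 0.5,
                             bac_delay: float = 0.0) -> ValidationReport:
    """Run the f-I, bAP and coincidence (BAC) protocols on a cell."""
    from .morphology import Location  # noqa: F401  (documented type)

    morph = cell.morphology
    probes = default_probes(morph)
    base = config or SimConfig()
    cfg = SimConfig(dt=base.dt, max_seg_length=base.max_seg_length,
                    v_init=base.v_init, probe_sites=probes,
                    record_stride=base.record_stride, celsius=base.celsius)
    grid = discretize(cell, cfg)
    soma_loc = probes[0][1]
    apical_loc = probes[1][1]

    # f-I: 500 ms somatic steps after 150 ms settling
    counts = []
    for amp in fi_amps:
        rec = run_trial(cell, _NoInputs(700.0), cfg, grid=grid, injections=[
            Injection(soma_loc, 150.0, amp, "step", duration_ms=500.0)])
        counts.append(int(np.sum((rec.somatic_spike_times >= 150.0)
                                 & (rec.somatic_spike_times < 650.0))))

    # bAP: brief suprathreshold somatic pulse
    rec = run_trial(cell, _NoInputs(300.0), cfg, grid=grid, injections=[
        Injection(soma_loc, 150.0, bap_amp, "step", duration_ms=bap_pulse_ms)])
    sl = (rec.time >= 140.0) & (rec.time <= 220.0)
    base_s = rec.vm_traces["soma"][rec.time < 150.0][-10:].mean()
    base_a = rec.vm_traces["apical"][rec.time < 150.0][-10:].mean()
    bap_soma = float(rec.vm_traces["soma"][sl].max() - base_s)
    bap_apical = float(rec.vm_traces["apical"][sl].max() - base_a)

    def bac_run(somatic: bool, apical: bool) -> float:
        inj = []
        if somatic:
            inj.append(Injection(soma_loc, 150.0, bap_amp, "step",
                                 duration_ms=bap_pulse_ms))
        if apical:
            inj.append(Injection(apical_loc, 150.0 + bac_delay, bac_epsp_amp,
                                 "epsp", tau_rise=1.0, tau_decay=8.0))
        r = run_trial(cell, _NoInputs(350.0), cfg, grid=grid, injections=inj)
        win = (r.time >= 145.0) & (r.time <= 330.0)
        return _plateau_width(r.vm_traces["apical"][win], r.time[win])

    return ValidationReport(
        fi_amps=list(fi_amps), fi_counts=counts,
        bap_soma_amplitude=bap_soma, bap_apical_amplitude=bap_apical,
        coincidence_width=bac_run(True, True),
        apical_alone_width=bac_run(False, True),
        soma_alone_width=bac_run(True, False),
    )
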