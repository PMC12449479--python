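"""Per-synapse activation times from population rates and PSTHs.

Ongoing activity is homogeneous Poisson at each population's ongoing rate;
the sensory-evoked epoch adds spikes drawn from each population's PSTH bump.
Both are realized by per-sub-bin Bernoulli thinning (sub-bins refined until
rate·Δ < 0.1), drawn from counter-based streams keyed by
(seed, population, presynaptic cell) so that paired manipulations replay
identical spike trains for untouched populations.

Evoked and ongoing spikes are generated as separate processes and tagged at
generation: "sensory-evoked input" means activations from the PSTH bump, and
manipulations that deprive a pathway delete exactly those.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ParameterError
from .streams import stream

__all__ = [
    "PSTH",
    "TrialInputs",
    "TrialLayout",
    "InputGridPoint",
    "synthetic_psth",
    "default_psth_params",
    "poisson_spikes_from_psth",
    "build_trial_inputs",
    "DEFAULT_LATENCIES_MS",
]

# Evoked-bump onset latencies (ms after stimulus onset).  The thalamic volley
# reaches the deep layers ~1.8 ms before L4, and L6CC responses precede L4SP
# responses by 2.1 ms; the single VPM population is timed to its deep-layer
# (PT-targeting) arrival.
DEFAULT_LATENCIES_MS = {
    "VPM": 5.0,
    "L6CC": 5.6,
    "INH": 6.5,
    "L4SP": 7.7,   # = L6CC + 2.1
    "L5IT": 8.0,
    "L5PT": 8.0,
    "L2/3PN": 9.0,
}
VPM_L4_TIMED_LATENCY_MS = DEFAULT_LATENCIES_MS["VPM"] + 1.8

DEFAULT_BUMP_AREAS = {
    "VPM": 1.2, "L6CC": 1.0, "L4SP": 0.5, "L5PT": 0.4,
    "L5IT": 0.1, "L2/3PN": 0.05, "INH": 0.6,
}
DEFAULT_BUMP_WIDTHS_MS = {
    "VPM": 1.5, "L6CC": 1.5, "L4SP": 2.0, "L5PT": 2.0,
    "L5IT": 2.5, "L2/3PN": 2.5, "INH": 1.8,
}
STIMULUS_AREA_SCALE = {"principal": 1.0, "same_row_3": 1.3, "two_rows_3": 1.6}


@dataclass(frozen=True)
class PSTH:
    """Binned firing-rate profile; ``t_onset`` marks the evoked-bump onset."""

    bin_edges: np.ndarray      # ms
    rates: np.ndarray          # Hz per bin
    t_onset: float             # ms
    baseline_hz: float = 0.0

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "rates", rates)
        if len(edges) != len(rates) + 1:
            raise ParameterError("need len(bin_edges) == len(rates) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(rates < 0):
            raise ParameterError("rates must be >= 0")

    @property
    def bump_rates(self) -> np.ndarray:
        return np.clip(self.rates - self.baseline_hz, 0.0, None)

    def integral(self) -> float:
        """Expected spikes per cell over the binned support (rate in Hz)."""
        return float(np.sum(self.rates * np.diff(self.bin_edges)) / 1e3)

    def bump_integral(self) -> float:
        return float(np.sum(self.bump_rates * np.diff(self.bin_edges)) / 1e3)


@dataclass(frozen=True)
class PSTHParams:
    latency_ms: float
    width_ms: float
    area: float          # expected evoked spikes per cell at scale 1
    baseline_hz: float
    bin_ms: float = 0.25
    duration_ms: float = 60.0


def default_psth_params(cell_type: str, ongoing_rate_hz: float = 0.0) -> PSTHParams:
    if cell_type not in DEFAULT_LATENCIES_MS:
        raise ConfigError(f"unrecognized cell type {cell_type!r}")
    return PSTHParams(DEFAULT_LATENCIES_MS[cell_type],
                      DEFAULT_BUMP_WIDTHS_MS[cell_type],
                      DEFAULT_BUMP_AREAS[cell_type], ongoing_rate_hz)


def _alpha_cdf(t, width):
    t = np.clip(t, 0.0, None)
    return 1.0 - (1.0 + t / width) * np.exp(-t / width)


def synthetic_psth(cell_type: str, stimulus: str = "principal",
                   params: PSTHParams | None = None) -> PSTH:
    """Parametric evoked PSTH: an alpha-shaped bump on a flat baseline.

    The bump starts exactly at ``latency_ms`` and integrates (over the
    binned support) to ``area`` × the stimulus scale factor; bin rates are
    exact bin averages of the analytic bump, so numerical quadrature of
    (PSTH − baseline) recovers the requested area.
    """
    if params is None:
        params = default_psth_params(cell_type)
    if params.width_ms <= 0:
        raise ParameterError("bump width must be positive")
    if stimulus not in STIMULUS_AREA_SCALE:
        raise ConfigError(f"unknown stimulus {stimulus!r}")
    area = params.area * STIMULUS_AREA_SCALE[stimulus]
    edges = np.arange(0.0, params.duration_ms + params.bin_ms / 2, params.bin_ms)
    cdf = area * _alpha_cdf(edges - params.latency_ms, params.width_ms)
    # bin rate (Hz): expected spikes per bin / bin width (ms) * 1e3
    bump = np.diff(cdf) / np.diff(edges) * 1e3
    return PSTH(edges, bump + params.baseline_hz, t_onset=params.latency_ms,
                baseline_hz=params.baseline_hz)


# ---------------------------------------------------------------------------
# Poisson generation
# ---------------------------------------------------------------------------

def _thin_bins(edges: np.ndarray, rates_hz: np.ndarray, scale: float,
               rng: np.random.Generator) -> np.ndarray:
    """Bernoulli-thinned inhomogeneous Poisson draw over binned rates.

    Each bin is subdivided until rate·Δ < 0.1; one Bernoulli trial per
    sub-bin, with a uniform position within the sub-bin on success.
    """
    lam = np.asarray(rates_hz, dtype=float) * scale / 1e3  # spikes per ms
    widths = np.diff(edges)
    mask = lam > 0
    if not mask.any():
        return np.empty(0)
    lam, widths, t0s = lam[mask], widths[mask], edges[:-1][mask]
    nsub = np.maximum(1, np.ceil(widths * lam / 0.1)).astype(np.int64)
    delta = widths / nsub
    p = lam * delta
    if np.any(p >= 1.0):
        raise ConfigError("rate too high to thin after sub-bin refinement")
    total = int(nsub.sum())
    u = rng.random(total)
    bin_idx = np.repeat(np.arange(len(nsub)), nsub)
    starts = np.concatenate([[0], np.cumsum(nsub)[:-1]])
    pos = np.arange(total) - starts[bin_idx]
    hit = u < p[bin_idx]
    if not hit.any():
        return np.empty(0)
    jitter = rng.random(int(hit.sum()))
    hb = bin_idx[hit]
    return np.sort(t0s[hb] + (pos[hit] + jitter) * delta[hb])


def poisson_spikes_from_psth(psth: PSTH, scale: float, n_cells: int,
                             duration: float, seed: int) -> list[np.ndarray]:
    """Per-cell spike trains from a PSTH (rate zero outside its support).

    Expected count per cell is scale × ∫rate dt.  Each cell draws from its
    own counter-based stream, so trains are independent of n_cells ordering.
    """
    if scale < 0:
        raise ParameterError("scale must be >= 0")
    edges = np.clip(psth.bin_edges, 0.0, duration)
    out = []
    for cell in range(n_cells):
        rng = stream(seed, "psth", cell)
        out.append(_thin_bins(edges, psth.rates, scale, rng))
    return out


# ---------------------------------------------------------------------------
# trial assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputGridPoint:
    """One point of the input-configuration grid.

    Campaign grids enumerate ongoing inhibition 0.25–3.75 (step 0.25),
    evoked inhibition 0.1–1.0 (step 0.1), inhibitory timing shifts
    {0, −1, −2} ms and three whisker-stimulus conditions; the ongoing
    excitatory scale defaults to 1 and is varied 0.5–2 only by the
    ongoing-rate manipulation.
    """

    ongoing_inh_scale: float = 1.0
    evoked_inh_scale: float = 0.5
    inh_shift: float = 0.0
    stimulus: str = "principal"
    ongoing_exc_scale: float = 1.0
    evoked_exc_scale: float = 1.0

    def __post_init__(self):
        if self.stimulus not in STIMULUS_AREA_SCALE:
            raise ConfigError(f"unknown stimulus {self.stimulus!r}")
        for f in ("ongoing_inh_scale", "evoked_inh_scale", "ongoing_exc_scale",
                  "evoked_exc_scale"):
            if getattr(self, f) < 0:
                raise ParameterError(f"{f} must be >= 0")


@dataclass(frozen=True)
class TrialLayout:
    """Epoch structure of one simulated trial (times in ms)."""

    ongoing_ms: float = 445.0
    evoked_ms: float = 100.0
    discard_ms: float = 0.0

    @property
    def duration_ms(self) -> float:
        return self.ongoing_ms + self.evoked_ms

    @property
    def stimulus_onset_ms(self) -> float:
        return self.ongoing_ms


ONGOING_LAYOUT = TrialLayout(ongoing_ms=1245.0, evoked_ms=0.0, discard_ms=245.0)


@dataclass
class TrialInputs:
    """Replayable per-synapse activation times for one trial.

    ``ongoing`` and ``evoked`` keep the two generation processes separate
    (synapse_id -> sorted times); ``activations`` merges them.  ``t_onset``
    is the TC-onset marker: stimulus onset plus the earliest VPM evoked-bump
    latency.
    """

    ongoing: dict
    evoked: dict
    duration_ms: float
    stimulus_onset_ms: float | None = None
    t_onset: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def activations(self) -> dict:
        out = {}
        for sid in set(self.ongoing) | set(self.evoked):
            parts = [a for a in (self.ongoing.get(sid), self.evoked.get(sid))
                     if a is not None and len(a)]
            if parts:
                out[sid] = np.sort(np.concatenate(parts))
        return out

    def copy(self) -> "TrialInputs":
        return TrialInputs({k: v.copy() for k, v in self.ongoing.items()},
                           {k: v.copy() for k, v in self.evoked.items()},
                           self.duration_ms, self.stimulus_onset_ms,
                           self.t_onset, dict(self.meta))

    def counts(self) -> tuple[int, int]:
        n_on = sum(len(v) for v in self.ongoing.values())
        n_ev = sum(len(v) for v in self.evoked.values())
        return n_on, n_ev


def build_trial_inputs(placements, populations: dict,
                       grid_point: InputGridPoint, layout: TrialLayout,
                       seed: int, trial: int = 0) -> TrialInputs:
    """Realize one trial's synaptic activation times.

    Ongoing activity runs at each population's ongoing rate for the whole
    trial (inhibition scaled by ``ongoing_inh_scale``, excitation by
    ``ongoing_exc_scale``); the evoked epoch adds PSTH-bump spikes
    (inhibitory bump scaled by ``evoked_inh_scale`` and shifted by
    ``inh_shift``).  All synapses of one connection share their presynaptic
    cell's spike train.  Deterministic given (seed, trial).
    """
    # synapses grouped by presynaptic cell
    cells: dict[tuple, list] = {}
    for pl in placements:
        cells.setdefault((pl.population, pl.presyn_cell_id), []).append(pl.synapse_id)

    if layout.evoked_ms > 0:
        missing = [ct for ct in {p for p, _ in cells}
                   if populations[ct].evoked_psth is None]
        if missing:
            raise ConfigError(f"evoked epoch requested but no PSTH for {missing}")

    ongoing: dict[int, np.ndarray] = {}
    evoked: dict[int, np.ndarray] = {}
    onset = layout.stimulus_onset_ms
    dur = layout.duration_ms
    flat = np.array([0.0, dur])

    for (ct, cell_id), sids in sorted(cells.items()):
        pop = populations[ct]
        is_inh = ct == "INH"
        on_scale = (grid_point.ongoing_inh_scale if is_inh
                    else grid_point.ongoing_exc_scale)
        rng = stream(seed, "trial", trial, ct, cell_id)
        on_times = _thin_bins(flat, np.array([pop.ongoing_rate]), on_scale, rng)
        ev_times = np.empty(0)
        if layout.evoked_ms > 0 and pop.evoked_psth is not None:
            psth = pop.evoked_psth
            if is_inh:
                bump_scale = grid_point.evoked_inh_scale
            else:
                bump_scale = (STIMULUS_AREA_SCALE[grid_point.stimulus]
                              * grid_point.evoked_exc_scale)
            ev_times = _thin_bins(psth.bin_edges, psth.bump_rates, bump_scale, rng)
            if is_inh and grid_point.inh_shift:
                ev_times = ev_times + grid_point.inh_shift
            ev_times = ev_times + onset
            ev_times = ev_times[(ev_times >= 0) & (ev_times <= dur)]
        for sid in sids:
            if len(on_times):
                ongoing[sid] = on_times.copy()
            if len(ev_times):
                evoked[sid] = ev_times.copy()

    vpm_latency = (populations["VPM"].evoked_psth.t_onset
                   if "VPM" in populations and populations["VPM"].evoked_psth is not None
                   else min(DEFAULT_LATENCIES_MS.values()))
    t_onset = None if layout.evoked_ms == 0 else onset + vpm_latency
    meta = {"seed": seed, "trial": trial, "grid_point": grid_point,
            "layout": layout}
    return TrialInputs(ongoing, evoked, dur, onset, t_onset, meta)
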