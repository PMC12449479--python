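"""Response classification, dendritic Ca²⁺-event detection and waveform,
density and depolarization metrics.

Somatic responses inside the 50-ms post-stimulus window are labelled by the
burst rules used for the in vivo recordings: a burst of 3 APs is any 3 APs
within 30 ms, a burst of 2 APs any 2 consecutive APs within 10 ms; trials
satisfying both count as 3-AP bursts.  Dendritic Ca²⁺ APs are maximal
contiguous excursions of the apical probe above −30 mV, characterized by
onset (up-crossing), width (up-to-down crossing) and peak voltage, with
sub-sample precision from linear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (ConfigError, DegenerateTraceError, ParameterError)
from .morphology import Morphology, normalized_x_from_distance

__all__ = [
    "ResponseClass",
    "CaEvent",
    "DensityProfile",
    "classify_response",
    "detect_ca_events",
    "classify_ca_origin",
    "dendritic_waveform_metrics",
    "density_profile",
    "mad_threshold_events",
    "prestim_depolarization",
    "RESPONSE_WINDOW_MS",
    "BURST3_SPAN_MS",
    "BURST2_ISI_MS",
]

RESPONSE_WINDOW_MS = 50.0
BURST3_SPAN_MS = 30.0
BURST2_ISI_MS = 10.0
CA_THRESHOLD_MV = -30.0


@dataclass(frozen=True)
class ResponseClass:
    label: str                     # none | single | burst2 | burst3
    n_aps: int
    first_ap_latency: float | None  # ms relative to window start


@dataclass(frozen=True)
class CaEvent:
    onset: float      # ms (up-crossing of -30 mV)
    width: float      # ms (up-to-down crossing)
    peak: float       # mV
    origin: str = "unattributed"   # sensory | nonsensory | unattributed


def classify_response(spike_times, window=None) -> ResponseClass:
    """Label the somatic response inside the analysis window.

    ``window`` is (t_start, t_end); spikes are restricted to it.  Burst of 3:
    any 3 spikes spanning ≤ 30 ms (more spikes within the span still
    qualify); else burst of 2: any 2 consecutive spikes ≤ 10 ms apart; else
    single if ≥ 1 spike; else none.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if window is not None:
        t = t[(t >= window[0]) & (t <= window[1])]
    n = len(t)
    latency = None if n == 0 else float(t[0] - (window[0] if window else 0.0))
    if n >= 3 and np.any(t[2:] - t[:-2] <= BURST3_SPAN_MS):
        return ResponseClass("burst3", n, latency)
    if n >= 2 and np.any(np.diff(t) <= BURST2_ISI_MS):
        return ResponseClass("burst2", n, latency)
    if n >= 1:
        return ResponseClass("single", n, latency)
    return ResponseClass("none", 0, None)


def _interp_crossing(t0, v0, t1, v1, thr):
    return t0 + (thr - v0) / (v1 - v0) * (t1 - t0)


def detect_ca_events(time, trace, threshold: float = CA_THRESHOLD_MV,
                     window=None, stimulus_onset: float | None = None) -> list[CaEvent]:
    """Dendritic Ca²⁺ APs as supra-threshold excursions of the apical trace.

    Each maximal contiguous segment above the threshold becomes one event
    (events separated by sub-threshold dips are not merged).  When
    ``stimulus_onset`` is given, events whose onset precedes it are still
    returned; callers exclude those trials from sensory analyses.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(trace, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, v = t[m], v[m]
    if len(v) == 0:
        return []
    if np.all(v > threshold):
        raise DegenerateTraceError("trace never below threshold")
    if not np.any(v > threshold):
        return []

    above = v > threshold
    events = []
    i = 0
    n = len(v)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        onset = (t[i] if i == 0
                 else _interp_crossing(t[i - 1], v[i - 1], t[i], v[i], threshold))
        end = (t[j - 1] if j == n
               else _interp_crossing(t[j - 1], v[j - 1], t[j], v[j], threshold))
        events.append(CaEvent(float(onset), float(end - onset),
                              float(v[i:j].max())))
        i = j
    return events


def classify_ca_origin(paired) -> list[CaEvent]:
    """Attribute each control-trial Ca²⁺ event as sensory or nonsensory.

    ``paired`` is a PairedTrial whose manipulation removed indirect sensory
    input.  A control event is sensory-evoked if the manipulated apical trace
    has no supra-threshold segment overlapping the event's span (the event
    no longer crosses −30 mV without indirect input); otherwise nonsensory.
    """
    from .manipulations import PairedTrial  # local import to avoid cycle

    if not isinstance(paired, PairedTrial):
        raise ConfigError("classify_ca_origin expects a PairedTrial")
    if paired.spec.kind != "deprive_indirect":
        raise ConfigError("origin attribution requires a deprive_indirect pair")
    ctl, man = paired.control, paired.manipulated
    ctl_events = detect_ca_events(ctl.time, ctl.vm_traces["apical"])
    try:
        man_events = detect_ca_events(man.time, man.vm_traces["apical"])
    except DegenerateTraceError:
        man_events = []
    out = []
    for ev in ctl_events:
        span = (ev.onset, ev.onset + ev.width)
        overlaps = any(m.onset < span[1] and m.onset + m.width > span[0]
                       for m in man_events)
        origin = "nonsensory" if overlaps else "sensory"
        out.append(CaEvent(ev.onset, ev.width, ev.peak, origin))
    return out


@dataclass(frozen=True)
class WaveformMetrics:
    amplitude: float           # mV above pre-window baseline
    fwhm: float | None         # ms; None when undefined
    peak_time: float
    edge_flagged: bool


def dendritic_waveform_metrics(time, trace, window,
                               baseline_ms: float = 20.0) -> WaveformMetrics:
    """Amplitude and full-width-half-maximum of the dendritic response.

    Amplitude is peak minus the mean of the ``baseline_ms`` preceding the
    window; FWHM uses linearly interpolated half-amplitude crossings around
    the peak.  A peak on the window edge or missing half-crossing flags the
    result instead of failing.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(trace, dtype=float)
    pre = (t >= window[0] - baseline_ms) & (t < window[0])
    if not pre.any():
        raise ParameterError("no samples available for the pre-window baseline")
    baseline = float(v[pre].mean())
    m = (t >= window[0]) & (t <= window[1])
    tw, vw = t[m], v[m]
    k = int(np.argmax(vw))
    amp = float(vw[k] - baseline)
    edge = k == 0 or k == len(vw) - 1
    if amp <= 0:
        return WaveformMetrics(max(amp, 0.0), None, float(tw[k]), True)
    half = baseline + amp / 2.0
    left = None
    for i in range(k, 0, -1):
        if vw[i - 1] <= half <= vw[i]:
            left = _interp_crossing(tw[i - 1], vw[i - 1], tw[i], vw[i], half)
            break
    right = None
    for i in range(k, len(vw) - 1):
        if vw[i + 1] <= half <= vw[i]:
            right = _interp_crossing(tw[i], vw[i], tw[i + 1], vw[i + 1], half)
            break
    if left is None or right is None:
        return WaveformMetrics(amp, None, float(tw[k]), True)
    return WaveformMetrics(amp, float(right - left), float(tw[k]), edge)


@dataclass(frozen=True)
class DensityProfile:
    """Synapse density vs normalized apical coordinate for one domain group."""

    bin_edges_x: np.ndarray       # normalized coordinate
    density: np.ndarray           # synapses / µm per bin
    counts: np.ndarray
    group: str                    # "basal+oblique" | "trunk+tuft"


_GROUPS = {"basal+oblique": ("basal", "oblique"), "trunk+tuft": ("trunk", "tuft")}


def density_profile(placements, morph: Morphology, group: str,
                    bin_um: float = 100.0) -> DensityProfile:
    """Bin synapses per 100 µm of path distance, divide by dendritic length
    per bin, and map bin edges into the normalized soma-BP-tuft coordinate."""
    if group not in _GROUPS:
        raise ConfigError(f"group must be one of {sorted(_GROUPS)}")
    domains = _GROUPS[group]
    comps = morph.in_domains(domains)
    if not comps:
        raise ConfigError(f"morphology has no {group} dendrites")
    on_tuft = group == "trunk+tuft"

    max_d = max(c.path_distance_to_soma for c in comps)
    edges = np.arange(0.0, max_d + bin_um, bin_um)
    nb = len(edges) - 1

    # dendritic length per distance bin
    length = np.zeros(nb)
    for c in comps:
        lo, hi = c.proximal_distance, c.path_distance_to_soma
        for b in range(nb):
            ov = min(hi, edges[b + 1]) - max(lo, edges[b])
            if ov > 0:
                length[b] += ov

    counts = np.zeros(nb, dtype=int)
    kept = 0
    dom_set = set(domains)
    for pl in placements:
        if morph[pl.location[0]].domain not in dom_set:
            continue
        b = min(int(pl.path_distance // bin_um), nb - 1)
        counts[b] += 1
        kept += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(length > 0, counts / np.maximum(length, 1e-12), 0.0)
    if np.any((counts > 0) & (length <= 0)):
        raise ConfigError("synapses fall in a bin with zero dendritic length")

    x_edges = np.array([normalized_x_from_distance(morph, d, on_tuft=on_tuft and d > 0)
                        for d in edges])
    return DensityProfile(x_edges, dens, counts, group)


def mad_threshold_events(trace, stimulus_onset_index: int,
                         window_samples: int | None = None,
                         n_mad: float = 3.0):
    """Detect a post-stimulus event in an imaging (ΔF/F) trace.

    The threshold is median + ``n_mad`` × MAD of the pre-stimulus baseline;
    an event requires a supra-threshold sample inside the post-stimulus
    window, and traces whose first supra-threshold sample precedes stimulus
    onset are excluded (event=False, excluded=True).
    """
    v = np.asarray(trace, dtype=float)
    base = v[:stimulus_onset_index]
    if len(base) < 2:
        raise ParameterError("need pre-stimulus baseline samples")
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    if mad == 0:
        raise DegenerateTraceError("constant baseline: MAD threshold undefined")
    thr = med + n_mad * mad
    above = np.nonzero(v > thr)[0]
    end = (len(v) if window_samples is None
           else min(len(v), stimulus_onset_index + window_samples))
    if len(above) == 0:
        return {"event": False, "onset_index": None, "excluded": False}
    first = int(above[0])
    if first < stimulus_onset_index:
        return {"event": False, "onset_index": first, "excluded": True}
    if first >= end:
        return {"event": False, "onset_index": None, "excluded": False}
    return {"event": True, "onset_index": first, "excluded": False}


def prestim_depolarization(recording, probe: str = "apical",
                           t_onset: float | None = None,
                           window_ms: float = 20.0) -> float:
    """Time-averaged probe potential over the ``window_ms`` before TC onset."""
    if t_onset is None:
        t_onset = recording.metadata.get("t_onset")
    if t_onset is None:
        raise ParameterError("recording carries no TC-onset marker")
    t = recording.time
    v = recording.vm_traces[probe]
    m = (t >= t_onset - window_ms) & (t < t_onset)
    if m.sum() < 2:
        raise ParameterError("window lies outside the recording")
    tw, vw = t[m], v[m]
    return float(np.trapezoid(vw, tw) / (tw[-1] - tw[0]))


def peak_bin_recovery(morph, profile, n: int = 1000, seeds=range(20),
                      bin_um: float = 100.0) -> int:
    """Sampling-consistency check for the TC density profile.

    For each seed, draw ``n`` TC placements, bin the trunk synapses per
    ``bin_um`` of path distance (bins aligned so the profile's peak is
    bin-centred), divide by trunk length per bin, and ask whether the
    empirical mode coincides with the analytic mode of the same binned
    density.  Returns the number of seeds for which it does.
    """
    from .connectome import sample_tc_synapses

    trunks = morph.in_domains("trunk")
    peak_d = morph.bp_distance - profile.peak_offset_um
    start = (peak_d - bin_um / 2.0) % bin_um
    max_d = max(c.path_distance_to_soma for c in trunks)
    edges = np.arange(start - bin_um, max_d + bin_um, bin_um)
    nb = len(edges) - 1

    length = np.zeros(nb)
    expected = np.zeros(nb)
    for c in trunks:
        sub = np.linspace(c.proximal_distance, c.path_distance_to_soma, 51)
        mid = 0.5 * (sub[:-1] + sub[1:])
        dl = np.diff(sub)
        for d, w in zip(mid, dl):
            b = int((d - edges[0]) // bin_um)
            if 0 <= b < nb:
                length[b] += w
                expected[b] += profile.apical_density(d, morph.bp_distance) * w
    valid = length > bin_um / 2.0  # ignore sliver bins at the ends
    analytic_mode = int(np.argmax(np.where(valid, expected / np.maximum(length, 1e-9), -1.0)))

    wins = 0
    for seed in seeds:
        counts = np.zeros(nb)
        for pl in sample_tc_synapses(morph, profile, n, seed=seed):
            if morph[pl.location[0]].domain != "trunk":
                continue
            b = int((pl.path_distance - edges[0]) // bin_um)
            if 0 <= b < nb:
                counts[b] += 1
        empirical = np.where(valid, counts / np.maximum(length, 1e-9), -1.0)
        if int(np.argmax(empirical)) == analytic_mode:
            wins += 1
    return wins
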