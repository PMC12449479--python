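"""Paired-replay manipulation engine.

A manipulation transforms a stored trial's inputs (and, for the
passive-apical and TC-plasticity kinds, the cell) while leaving every
untouched activation bit-identical, so control and manipulated trials are
directly comparable.  The numbered deprivation kinds delete the
sensory-evoked (PSTH-bump-tagged) activations of the targeted presynaptic
populations while retaining their ongoing activity:

1  deprive_indirect      all cortical excitatory types in vS1
2  deprive_direct_tc     TC synapses from VPM thalamus
3-7 deprive_type         one cortical type (L2/3PN, L4SP, L5IT, L5PT, L6CC)
8  deprive_tc_and_l6cc   VPM and L6CC together
9  passive_apical        zero active conductances on trunk/tuft/obliques
10 tc_distance_bin       remove ≤50 TC evoked activations in a 200 µm band
11 prestim_window_removal remove ≤50 cortical-EXC activations in the 20 ms
                          before TC onset on one dendritic domain

plus ``ongoing_scale`` (rescale ongoing excitatory rates 0.5–2 and
regenerate under the paired stream) and ``tc_plasticity`` (×2.5 TC synaptic
weight, emulating thalamocortical facilitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .activity import TrialInputs, build_trial_inputs
from .connectome import CORTICAL_EXC_TYPES
from .errors import ConfigError, ParameterError
from .streams import stream

__all__ = ["ManipulationSpec", "PairedTrial", "apply_manipulation",
           "paired_replay", "cell_transform", "DEPRIVATION_TARGETS"]

DEPRIVATION_TARGETS = {
    "deprive_indirect": set(CORTICAL_EXC_TYPES),
    "deprive_direct_tc": {"VPM"},
    "deprive_tc_and_l6cc": {"VPM", "L6CC"},
}

KINDS = (tuple(DEPRIVATION_TARGETS) + ("deprive_type", "passive_apical",
         "tc_distance_bin", "prestim_window_removal", "ongoing_scale",
         "tc_plasticity"))


@dataclass(frozen=True)
class ManipulationSpec:
    kind: str
    target_population: str | None = None       # deprive_type
    distance_interval: tuple | None = None     # tc_distance_bin, µm
    target_domain: str | None = None           # prestim_window_removal
    window_ms: float = 20.0                    # prestim_window_removal
    n_remove: int = 50                         # kinds 10 and 11, per trial
    scale_factor: float = 1.0                  # ongoing_scale
    weight_factor: float = 2.5                 # tc_plasticity

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"unknown manipulation kind {self.kind!r}")
        if self.kind == "deprive_type" and self.target_population not in CORTICAL_EXC_TYPES:
            raise ConfigError("deprive_type needs a cortical excitatory target")
        if self.kind == "tc_distance_bin" and self.distance_interval is None:
            raise ConfigError("tc_distance_bin needs a distance interval")
        if self.kind == "prestim_window_removal" and self.target_domain is None:
            raise ConfigError("prestim_window_removal needs a target domain")

    def tag(self) -> str:
        parts = [self.kind]
        if self.target_population:
            parts.append(self.target_population)
        if self.distance_interval:
            parts.append(f"{self.distance_interval[0]:g}-{self.distance_interval[1]:g}um")
        if self.target_domain:
            parts.append(self.target_domain)
        if self.kind == "ongoing_scale":
            parts.append(f"x{self.scale_factor:g}")
        return ":".join(parts)


@dataclass
class PairedTrial:
    control: object          # TrialRecording
    manipulated: object
    spec: ManipulationSpec
    control_inputs: TrialInputs | None = None
    manipulated_inputs: TrialInputs | None = None


def _delete_population_evoked(inputs: TrialInputs, placements, targets) -> TrialInputs:
    pop_of = {pl.synapse_id: pl.population for pl in placements}
    out = inputs.copy()
    out.evoked = {sid: t for sid, t in out.evoked.items()
                  if pop_of.get(sid) not in targets}
    return out


def _remove_sampled(inputs: TrialInputs, eligible, rng, n_remove) -> TrialInputs:
    """Delete up to n_remove (synapse_id, time) activations chosen uniformly
    without replacement; clamped to availability."""
    out = inputs.copy()
    if not eligible:
        return out
    k = min(n_remove, len(eligible))
    idx = rng.choice(len(eligible), size=k, replace=False)
    chosen: dict[int, set] = {}
    for i in idx:
        sid, which, j = eligible[i]
        chosen.setdefault((sid, which), set()).add(j)
    for (sid, which), js in chosen.items():
        table = out.evoked if which == "evoked" else out.ongoing
        keep = np.array([j not in js for j in range(len(table[sid]))])
        t = table[sid][keep]
        if len(t):
            table[sid] = t
        else:
            del table[sid]
    return out


def apply_manipulation(inputs: TrialInputs, placements, spec: ManipulationSpec,
                       seed: int, populations=None) -> TrialInputs:
    """Transform trial inputs according to the manipulation spec.

    Deletion kinds return inputs whose activation sets are subsets of the
    control's; sampling-based kinds (10, 11) draw from a stream keyed by
    (seed, spec, trial) so repeated application is reproducible.  Kinds 9
    and ``tc_plasticity`` leave the inputs untouched (see
    :func:`cell_transform`).
    """
    trial = inputs.meta.get("trial", 0)
    if spec.kind in DEPRIVATION_TARGETS:
        return _delete_population_evoked(inputs, placements, DEPRIVATION_TARGETS[spec.kind])
    if spec.kind == "deprive_type":
        return _delete_population_evoked(inputs, placements, {spec.target_population})
    if spec.kind in ("passive_apical", "tc_plasticity"):
        return inputs.copy()

    if spec.kind == "tc_distance_bin":
        lo, hi = spec.distance_interval
        by_id = {pl.synapse_id: pl for pl in placements}
        eligible = [(sid, "evoked", j)
                    for sid, times in sorted(inputs.evoked.items())
                    for j in range(len(times))
                    if by_id[sid].population == "VPM"
                    and lo <= by_id[sid].path_distance < hi]
        rng = stream(seed, "manipulation", spec.tag(), trial)
        return _remove_sampled(inputs, eligible, rng, spec.n_remove)

    if spec.kind == "prestim_window_removal":
        if inputs.t_onset is None:
            raise ConfigError("inputs carry no TC-onset marker")
        t0, t1 = inputs.t_onset - spec.window_ms, inputs.t_onset
        by_id = {pl.synapse_id: pl for pl in placements}
        eligible = []
        for which, table in (("ongoing", inputs.ongoing), ("evoked", inputs.evoked)):
            for sid, times in sorted(table.items()):
                pl = by_id[sid]
                if pl.population not in CORTICAL_EXC_TYPES:
                    continue
                for j, t in enumerate(times):
                    if t0 <= t < t1:
                        eligible.append((sid, which, j))
        rng = stream(seed, "manipulation", spec.tag(), trial)
        out = _remove_sampled(inputs, eligible, rng, spec.n_remove)
        return out

    if spec.kind == "ongoing_scale":
        if spec.scale_factor == 1.0:
            return inputs.copy()
        if populations is None:
            raise ConfigError("ongoing_scale needs the populations table")
        meta = inputs.meta
        gp = replace(meta["grid_point"],
                     ongoing_exc_scale=meta["grid_point"].ongoing_exc_scale
                     * spec.scale_factor)
        return build_trial_inputs(placements, populations, gp, meta["layout"],
                                  meta["seed"], trial=meta["trial"])

    raise ConfigError(f"unknown manipulation kind {spec.kind!r}")  # pragma: no cover


def cell_transform(cell, spec: ManipulationSpec):
    """Cell-side effect of a manipulation (identity for input-only kinds)."""
    if spec.kind == "passive_apical":
        return cell.with_passive_apical()
    if spec.kind == "tc_plasticity":
        return cell.with_synapse_weight("VPM", spec.weight_factor)
    return cell


def paired_replay(cell, inputs: TrialInputs, spec: ManipulationSpec,
                  sim_config, seed: int = 0, populations=None,
                  grid=None) -> PairedTrial:
    """Replay a stored trial under control and manipulated conditions.

    The control recording uses the inputs as stored; the manipulated one
    shares every non-manipulated activation exactly.  Recordings carry the
    manipulation tag in their metadata.
    """
    from .simulator import discretize, run_trial

    placements = cell.synapses
    man_inputs = apply_manipulation(inputs, placements, spec, seed, populations)
    man_cell = cell_transform(cell, spec)
    if grid is None:
        grid = discretize(cell, sim_config)
    control = run_trial(cell, inputs, sim_config, grid=grid,
                        metadata={"manipulation": "control"})
    man_grid = grid if man_cell is cell else discretize(man_cell, sim_config)
    manipulated = run_trial(man_cell, man_inputs, sim_config, grid=man_grid,
                            metadata={"manipulation": spec.tag()})
    return PairedTrial(control, manipulated, spec, inputs, man_inputs)
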