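"""Synthetic network embedding: synapse placement, source assignment, and
unitary-PSP conductance calibration.

The generator stands in for a dense anatomical network model: synapses are
placed on the morphology by explicit density rules — the thalamocortical
(TC) profile rises along the apical trunk to a peak ~100 µm below the
primary branch point and decays exponentially toward the tuft, with ~60% of
TC synapses on basal/oblique dendrites; cortical excitatory types follow
per-domain preference weights (L6CC basal-weighted, L4SP apical-weighted);
5000 inhibitory synapses are spread uniformly by dendritic length, each with
its own virtual presynaptic neuron.  TC synapses are randomly assigned to a
pool of 350 thalamic neurons; cortical synapses are grouped into
multi-synapse connections that fire together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CalibrationError, ConfigError, ParameterError
from .membrane import CellModel, MgBlockParams, SynapseModel
from .morphology import Location, Morphology
from .streams import stream

__all__ = [
    "PresynPopulation",
    "SynapsePlacement",
    "TCDensityProfile",
    "sample_tc_synapses",
    "sample_cortical_synapses",
    "sample_inhibitory_synapses",
    "assign_presynaptic_sources",
    "calibrate_upsp",
    "CalibrationResult",
    "excitatory_synapse_models",
    "inhibitory_synapse_models",
    "placements_to_frame",
    "EXC_TYPES",
    "CORTICAL_EXC_TYPES",
]

EXC_TYPES = ("VPM", "L2/3PN", "L4SP", "L5IT", "L5PT", "L6CC")
CORTICAL_EXC_TYPES = ("L2/3PN", "L4SP", "L5IT", "L5PT", "L6CC")
DENDRITE_DOMAINS = ("basal", "oblique", "trunk", "tuft")


@dataclass(frozen=True)
class PresynPopulation:
    """A presynaptic cell type: pool size, rates, placement preference."""

    cell_type: str
    n_cells: int
    ongoing_rate: float                      # Hz
    evoked_psth: object = None               # activity.PSTH, evoked bump
    domain_preference: dict = field(default_factory=dict)
    upsp_targets: tuple | None = None        # (mean, median, max) mV
    synapses_per_connection: int = 3
    excitatory: bool = True

    def __post_init__(self):
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.ongoing_rate < 0:
            raise ParameterError("ongoing_rate must be >= 0")
        if self.domain_preference:
            w = np.array(list(self.domain_preference.values()), dtype=float)
            if (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
                raise ParameterError("domain preference weights must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SynapsePlacement:
    synapse_id: int
    location: Location
    population: str
    presyn_cell_id: int | None
    path_distance: float


@dataclass(frozen=True)
class TCDensityProfile:
    """TC synapse density along the dendrites.

    Basal and oblique dendrites carry a flat density; along the trunk the
    density rises from ``trunk_base_density`` to ``peak_density`` at
    ``peak_offset_um`` below the BP (convex rise, surging near the peak the
    way the measured profiles do), then decays exponentially with length
    constant ``decay_length_um`` toward the tuft tips.
    ``proximal_share`` is the expected fraction of synapses on
    basal+oblique dendrites.
    """

    proximal_share: float = 0.6
    trunk_base_density: float = 0.2   # relative synapses/µm at the soma end
    peak_density: float = 1.0         # relative synapses/µm at the peak
    peak_offset_um: float = 100.0     # peak this far below the BP
    decay_length_um: float = 150.0
    rise_power: float = 3.0           # convexity of the rise toward the peak

    def __post_init__(self):
        if not (0.0 <= self.proximal_share <= 1.0):
            raise ParameterError("proximal_share must lie in [0, 1]")
        if min(self.trunk_base_density, self.peak_density,
               self.decay_length_um) <= 0 or self.peak_offset_um < 0:
            raise ParameterError("profile densities and lengths must be positive")

    def apical_density(self, d: float, bp_distance: float) -> float:
        """Relative density at path distance d on the trunk/tuft axis.

        The density stays low proximally and surges toward the peak
        (convex rise of order ``rise_power``), then decays exponentially.
        """
        d_peak = bp_distance - self.peak_offset_um
        if d <= d_peak:
            return (self.trunk_base_density
                    + (self.peak_density - self.trunk_base_density)
                    * (d / d_peak) ** self.rise_power)
        return self.peak_density * math.exp(-(d - d_peak) / self.decay_length_um)


# ---------------------------------------------------------------------------
# placement sampling
# ---------------------------------------------------------------------------

def _length_weighted_location(morph, domains, rng) -> tuple[Location, float]:
    comps = morph.in_domains(domains)
    if not comps:
        raise ConfigError(f"no compartments in domains {domains}")
    lengths = np.array([c.length for c in comps])
    i = rng.choice(len(comps), p=lengths / lengths.sum())
    frac = rng.uniform()
    c = comps[i]
    return (c.id, float(frac)), c.proximal_distance + frac * c.length


def _profile_bins(morph: Morphology, profile: TCDensityProfile, nsub: int = 10):
    """Sub-compartment bins on trunk+tuft weighted by density × length."""
    bins = []  # (comp_id, f0, f1, weight, d_mid)
    bp = morph.bp_distance
    for c in morph.in_domains(("trunk", "tuft")):
        for j in range(nsub):
            f0, f1 = j / nsub, (j + 1) / nsub
            d_mid = c.proximal_distance + (f0 + f1) / 2 * c.length
            w = profile.apical_density(d_mid, bp) * c.length / nsub
            bins.append((c.id, f0, f1, w, d_mid))
    return bins


def sample_tc_synapses(morph: Morphology, profile: TCDensityProfile,
                       n_total: int, seed: int) -> list[SynapsePlacement]:
    """Place TC synapses ∝ density × local dendritic length.

    Each synapse falls on basal+oblique with probability ``proximal_share``
    (uniform by length there) and otherwise on the trunk/tuft axis following
    the density profile.  Deterministic given the seed.
    """
    if n_total < 0:
        raise ParameterError("n_total must be >= 0")
    if profile.peak_offset_um >= morph.bp_distance:
        raise ConfigError("profile peak lies proximal to the soma (offset too large)")
    rng = stream(seed, "tc_placement")
    bins = _profile_bins(morph, profile)
    weights = np.array([b[3] for b in bins])
    weights = weights / weights.sum()
    out = []
    for i in range(n_total):
        if rng.uniform() < profile.proximal_share:
            loc, d = _length_weighted_location(morph, ("basal", "oblique"), rng)
        else:
            b = bins[rng.choice(len(bins), p=weights)]
            frac = rng.uniform(b[1], b[2])
            loc = (b[0], float(frac))
            c = morph[b[0]]
            d = c.proximal_distance + frac * c.length
        out.append(SynapsePlacement(i, loc, "VPM", None, d))
    return out


def sample_cortical_synapses(morph: Morphology, populations: dict,
                             counts: dict, seed: int,
                             start_id: int = 0) -> list[SynapsePlacement]:
    """Place cortical excitatory synapses by per-type domain preference."""
    out = []
    sid = start_id
    for ct in sorted(counts):
        n = counts[ct]
        if n < 0:
            raise ParameterError("counts must be >= 0")
        if n == 0:
            continue
        pop = populations[ct]
        prefs = pop.domain_preference or {d: 0.25 for d in DENDRITE_DOMAINS}
        doms = sorted(prefs)
        w = np.array([prefs[d] for d in doms])
        for d in doms:
            if prefs[d] > 0 and not morph.in_domains((d,)):
                raise ConfigError(f"{ct}: nonzero weight on empty domain {d!r}")
        rng = stream(seed, "cortical_placement", ct)
        for _ in range(n):
            dom = doms[rng.choice(len(doms), p=w / w.sum())]
            loc, dist = _length_weighted_location(morph, (dom,), rng)
            out.append(SynapsePlacement(sid, loc, ct, None, dist))
            sid += 1
    return out


def sample_inhibitory_synapses(morph: Morphology, seed: int, n: int = 5000,
                               start_id: int = 0) -> list[SynapsePlacement]:
    """Uniform-by-length inhibitory placements, one virtual neuron each."""
    rng = stream(seed, "inhibitory_placement")
    out = []
    for i in range(n):
        loc, d = _length_weighted_location(morph, DENDRITE_DOMAINS, rng)
        out.append(SynapsePlacement(start_id + i, loc, "INH", i, d))
    return out


def assign_presynaptic_sources(placements: list[SynapsePlacement],
                               populations: dict, seed: int) -> list[SynapsePlacement]:
    """Assign presynaptic cell ids.

    TC synapses draw uniformly from the thalamic pool (350 neurons by
    default); cortical synapses are grouped into connections of
    ``synapses_per_connection`` synapses sharing one presynaptic neuron;
    inhibitory synapses keep their one-virtual-neuron-per-synapse ids.
    """
    out = []
    by_pop: dict[str, list[int]] = {}
    for idx, pl in enumerate(placements):
        by_pop.setdefault(pl.population, []).append(idx)
    assigned: dict[int, int] = {}
    for ct, idxs in by_pop.items():
        if ct == "INH":
            continue
        pop = populations[ct]
        rng = stream(seed, "source_assignment", ct)
        if ct == "VPM":
            ids = rng.integers(0, pop.n_cells, size=len(idxs))
            for i, pid in zip(idxs, ids):
                assigned[i] = int(pid)
        else:
            order = rng.permutation(len(idxs))
            gsize = max(1, pop.synapses_per_connection)
            for gstart in range(0, len(order), gsize):
                pid = int(rng.integers(0, pop.n_cells))
                for k in order[gstart:gstart + gsize]:
                    assigned[idxs[k]] = pid
    for idx, pl in enumerate(placements):
        if pl.population == "INH":
            out.append(pl)
        else:
            out.append(replace(pl, presyn_cell_id=assigned[idx]))
    return out


def placements_to_frame(placements, morph: Morphology | None = None) -> pd.DataFrame:
    rows = []
    for pl in placements:
        x = None
        if morph is not None:
            from .morphology import normalized_x_from_distance
            dom = morph[pl.location[0]].domain
            x = normalized_x_from_distance(morph, pl.path_distance,
                                           on_tuft=(dom == "tuft"))
        rows.append({"synapse_id": pl.synapse_id, "population": pl.population,
                     "presyn_cell_id": pl.presyn_cell_id,
                     "comp_id": pl.location[0], "fraction": pl.location[1],
                     "path_distance_um": pl.path_distance, "normalized_x": x})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synapse model factories
# ---------------------------------------------------------------------------

def excitatory_synapse_models(peak_ns: float, nmda_ratio: float = 1.0,
                              ampa_tau=(0.2, 2.0), nmda_tau=(2.0, 50.0),
                              mg: MgBlockParams | None = None):
    """AMPA+NMDA receptor pair sharing an activation; peaks in nS."""
    mg = mg or MgBlockParams()
    return (SynapseModel("AMPA", ampa_tau[0], ampa_tau[1], 0.0, peak_ns),
            SynapseModel("NMDA", nmda_tau[0], nmda_tau[1], 0.0,
                         peak_ns * nmda_ratio, mg_block=mg))


def inhibitory_synapse_models(peak_ns: float = 1.0, tau=(0.5, 8.0),
                              reversal: float = -80.0):
    """GABA_A synapse; the peak conductance is fixed at 1 nS by default."""
    return (SynapseModel("GABA_A", tau[0], tau[1], reversal, peak_ns),)


# ---------------------------------------------------------------------------
# uPSP calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    population: str
    peak_conductance: float          # nS
    achieved: tuple                  # (mean, median, max) mV
    targets: tuple
    objective: float
    n_evaluations: int
    skipped: bool = False


def upsp_objective(achieved, targets) -> float:
    """Weighted squared error; mean and median weighted twice vs maximum."""
    dm, dmed, dmax = (a - t for a, t in zip(achieved, targets))
    return 2 * dm ** 2 + 2 * dmed ** 2 + dmax ** 2


def measure_upsp_stats(cell: CellModel, placements, peak_ns: float,
                       nmda_ratio: float = 1.0, sim_config=None,
                       activation_ms: float = 40.0,
                       window_ms: float = 50.0) -> tuple:
    """Somatic uPSP (mean, median, max) over connections activated one at a
    time from rest; amplitude = peak depolarization from the pre-activation
    baseline within ``window_ms`` of activation."""
    from .simulator import SimConfig, default_probes, discretize, run_trial

    models = {pl.population: excitatory_synapse_models(peak_ns, nmda_ratio)
              for pl in placements}
    test_cell = cell.with_synapses(placements, models)
    cfg = sim_config or SimConfig(probe_sites=default_probes(cell.morphology))
    grid = discretize(test_cell, cfg)

    connections: dict[int, list[int]] = {}
    for pl in placements:
        connections.setdefault(pl.presyn_cell_id, []).append(pl.synapse_id)
    if not connections:
        raise ParameterError("need at least one connection")

    class _Inputs:
        def __init__(self, acts, dur):
            self.activations = acts
            self.duration_ms = dur
            self.t_onset = activation_ms

    amps = []
    dur = activation_ms + window_ms + 5.0
    for pid in sorted(connections):
        acts = {sid: [activation_ms] for sid in connections[pid]}
        rec = run_trial(test_cell, _Inputs(acts, dur), cfg, grid=grid)
        t, v = rec.time, rec.vm_traces["soma"]
        base = v[(t >= activation_ms - 5.0) & (t < activation_ms)].mean()
        amps.append(float(v[(t >= activation_ms)
                            & (t <= activation_ms + window_ms)].max() - base))
    amps = np.asarray(amps)
    return (float(amps.mean()), float(np.median(amps)), float(amps.max()))


def calibrate_upsp(cell: CellModel, placements, targets, bounds=(0.05, 20.0),
                   nmda_ratio: float = 1.0, rel_tol: float = 0.01,
                   sim_config=None) -> CalibrationResult:
    """Find the peak conductance whose simulated uPSP statistics best match
    the targets (mean and median weighted twice relative to the maximum).

    Inhibitory populations are not calibrated: their peak conductance is
    fixed at 1 nS.
    """
    pops = {pl.population for pl in placements}
    if len(pops) != 1:
        raise ParameterError("calibrate one population at a time")
    pop = pops.pop()
    if pop == "INH":
        return CalibrationResult(pop, 1.0, (), tuple(targets), 0.0, 0, skipped=True)

    evals = [0]

    def j_of_log(lg):
        evals[0] += 1
        stats = measure_upsp_stats(cell, placements, math.exp(lg), nmda_ratio,
                                   sim_config=sim_config)
        return upsp_objective(stats, targets)

    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    # log-spaced bracketing scan, then bounded scalar minimization
    grid_lg = np.linspace(lo, hi, 9)
    vals = [j_of_log(lg) for lg in grid_lg]
    k = int(np.argmin(vals))
    if k == 0 or k == len(grid_lg) - 1:
        raise CalibrationError(
            f"{pop}: no interior bracket within bounds {bounds}; "
            f"objective minimized at the boundary ({math.exp(grid_lg[k]):.3g} nS)")
    res = optimize.minimize_scalar(
        j_of_log, bounds=(grid_lg[k - 1], grid_lg[k + 1]), method="bounded",
        options={"xatol": rel_tol})
    g = float(math.exp(res.x))
    achieved = measure_upsp_stats(cell, placements, g, nmda_ratio,
                                  sim_config=sim_config)
    return CalibrationResult(pop, g, achieved, tuple(targets),
                             upsp_objective(achieved, targets), evals[0] + 1)
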