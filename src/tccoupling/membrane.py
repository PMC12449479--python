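"""Channel kinetics, synaptic conductances and per-compartment cell assembly.

Gating follows the standard Hodgkin-Huxley formalism.  Each gate is described
by a Boltzmann steady state

    x_inf(v) = 1 / (1 + exp(-(v - v_half) / k))

(with k < 0 for inactivation gates) and a bell-shaped voltage-dependent time
constant

    tau(v) = tau_min + tau_amp / (2 cosh((v - v_tau) / sigma)) / q

where q is the channel's temperature factor.  The calcium-activated SK gate
instead uses a Hill function of the submembrane Ca²⁺ concentration.  The
specific parameter values are a packaged reference set tuned to support
back-propagating APs, dendritic Ca²⁺ plateaus and BAC firing; no claim is
made of matching any published channel database numerically.

Maximal conductance rules are per-domain with an optional linear decay over
path distance clamped at a minimum (the rule used for the fast
delayed-rectifier "Kv3.1" density) and an optional path-distance window
(used to restrict Ca²⁺ channels to the apical hot zone around the BP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ParameterError
from .morphology import APICAL_DOMAINS, AXONAL_DOMAINS, Morphology

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "ConductanceRule",
    "BiophysModel",
    "SynapseModel",
    "CellModel",
    "double_exp_conductance",
    "double_exp_peak_time",
    "nmda_block_factor",
    "kv31_density",
    "gating_rates",
    "build_cell",
    "FARADAY",
    "ca_nernst_mv",
]

FARADAY = 96485.332  # C/mol
GAS_R = 8.3144626    # J/(mol K)


def ca_nernst_mv(ca_i: float, ca_o: float = 2.0, celsius: float = 34.0) -> float:
    """Nernst reversal for Ca²⁺ (mV) at intracellular concentration ca_i mM."""
    return 1e3 * GAS_R * (celsius + 273.15) / (2 * FARADAY) * math.log(ca_o / ca_i)


# ---------------------------------------------------------------------------
# gates and channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation variable raised to ``power``."""

    power: int
    v_half: float = 0.0       # mV
    k: float = 1.0            # mV; negative => inactivation
    tau_min: float = 0.1      # ms
    tau_amp: float = 0.0      # ms
    v_tau: float = 0.0        # mV
    sigma: float = 15.0       # mV
    ca_dependent: bool = False
    ca_half: float = 4.3e-4   # mM (used when ca_dependent)
    ca_hill: float = 4.0

    def __post_init__(self):
        if self.power < 0:
            raise ParameterError("gate power must be >= 0")
        if self.tau_min <= 0 or self.tau_amp < 0:
            raise ParameterError("gate time constants must be positive")

    def steady_state(self, v: float, ca: float | None = None) -> float:
        if self.ca_dependent:
            c = max(ca if ca is not None else 0.0, 1e-12)
            return 1.0 / (1.0 + (self.ca_half / c) ** self.ca_hill)
        return 1.0 / (1.0 + math.exp(-(v - self.v_half) / self.k))

    def time_constant(self, v: float, q: float = 1.0) -> float:
        if self.ca_dependent:
            return self.tau_min / q
        u = (v - self.v_tau) / self.sigma
        return (self.tau_min + self.tau_amp / (2.0 * math.cosh(u))) / q


@dataclass(frozen=True)
class ConductanceRule:
    """Maximal conductance over a set of domains.

    ``gbar`` S/cm² at distance 0, optionally decaying linearly with path
    distance (``slope`` S/cm² per µm) down to ``minimum``, and optionally
    restricted to a path-distance window (hot zone).
    """

    gbar: float
    domains: frozenset[str]
    slope: float = 0.0
    minimum: float = 0.0
    window: tuple[float, float] | None = None

    def __post_init__(self):
        if self.gbar < 0 or self.minimum < 0 or self.slope < 0:
            raise ParameterError("conductances and slope must be >= 0")
        if self.minimum > self.gbar:
            raise ParameterError("minimum density exceeds base density")

    def density(self, domain: str, distance: float) -> float:
        if domain not in self.domains:
            return 0.0
        if self.window is not None and not (self.window[0] <= distance <= self.window[1]):
            return 0.0
        return kv31_density(self.gbar, self.slope, self.minimum, distance)


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    gates: tuple[GateSpec, ...]
    reversal: float | str          # mV, or "ca_nernst"
    rules: tuple[ConductanceRule, ...]
    q: float = 1.0                 # temperature factor applied to all gate taus
    ca_flux: bool = False          # current contributes to the Ca²⁺ pool

    def density(self, domain: str, distance: float) -> float:
        return sum(r.density(domain, distance) for r in self.rules)


@dataclass(frozen=True)
class CaDynamics:
    decay_ms: float = 80.0
    depth_um: float = 0.1
    ca_rest_mm: float = 1e-4
    ca_out_mm: float = 2.0
    gamma: float = 0.05  # fraction of Ca current reaching the pool


@dataclass(frozen=True)
class Passive:
    g_leak: float = 3e-5      # S/cm²
    e_leak: float = -80.0     # mV
    ra: float = 100.0         # Ω·cm
    cm: float = 1.0           # µF/cm²

    def __post_init__(self):
        if min(self.g_leak, self.ra, self.cm) <= 0:
            raise ParameterError("passive parameters must be positive")


@dataclass(frozen=True)
class BiophysModel:
    channels: tuple[ChannelSpec, ...]
    passive: Passive = Passive()
    ca: CaDynamics = CaDynamics()
    apical_diameter_scale: float = 1.0
    myelin_factor: float = 50.0  # capacitance and leak divided by this on myelin

    def __post_init__(self):
        if not (0.3 <= self.apical_diameter_scale <= 3.0):
            raise ParameterError("apical_diameter_scale must lie in [0.3, 3]")


# ---------------------------------------------------------------------------
# synapses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgBlockParams:
    mg_mm: float = 1.0
    gamma_per_mv: float = 0.062  # voltage sensitivity of the unblock sigmoid
    eta_per_mm: float = 0.28     # scale of the Mg²⁺ term


@dataclass(frozen=True)
class SynapseModel:
    """Double-exponential conductance synapse (AMPA, NMDA or GABA_A)."""

    kind: str                    # "AMPA" | "NMDA" | "GABA_A"
    tau_rise: float              # ms
    tau_decay: float             # ms
    reversal: float              # mV
    peak_conductance: float      # nS
    mg_block: MgBlockParams | None = None

    def __post_init__(self):
        if self.kind not in ("AMPA", "NMDA", "GABA_A"):
            raise ParameterError(f"unknown synapse kind {self.kind!r}")
        if not (0.0 < self.tau_rise < self.tau_decay):
            raise ParameterError("require 0 < tau_rise < tau_decay")
        if self.peak_conductance < 0:
            raise ParameterError("peak conductance must be >= 0")

    @property
    def norm(self) -> float:
        """Normalization so the double-exponential peaks at peak_conductance."""
        tr, td = self.tau_rise, self.tau_decay
        tp = double_exp_peak_time(tr, td)
        return 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))


def double_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Argmax of exp(-t/tau_decay) - exp(-t/tau_rise)."""
    if not tau_rise < tau_decay:
        raise ParameterError("require tau_rise < tau_decay")
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def double_exp_conductance(t, model: SynapseModel):
    """Conductance (nS) at time t (ms) after activation; 0 at t=0, peak at g_max."""
    t = np.asarray(t, dtype=float)
    g = model.peak_conductance * model.norm * (
        np.exp(-t / model.tau_decay) - np.exp(-t / model.tau_rise))
    return np.where(t < 0, 0.0, g) if g.ndim else (0.0 if t < 0 else float(g))


def nmda_block_factor(v, params: MgBlockParams = MgBlockParams()):
    """Voltage-dependent Mg²⁺ unblock of the NMDA receptor, in (0, 1).

    Sigmoidal form 1 / (1 + eta * [Mg] * exp(-gamma * v)); monotone
    increasing in v, approaching 0 at strong hyperpolarization and 1 at
    strong depolarization.
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + params.eta_per_mm * params.mg_mm * np.exp(-params.gamma_per_mv * v))
    return float(out) if out.ndim == 0 else out


def kv31_density(base: float, slope: float, minimum: float, soma_distance: float) -> float:
    """Linear decrease of channel density with soma distance, clamped at minimum."""
    if minimum > base:
        raise ParameterError("minimum density exceeds base density")
    if slope < 0 or minimum < 0:
        raise ParameterError("slope and minimum must be >= 0")
    return max(base - slope * soma_distance, minimum)


def gating_rates(channel: ChannelSpec, v: float, ca: float | None = None):
    """Per-gate (steady state, time constant ms) at membrane potential v."""
    return [(g.steady_state(v, ca), g.time_constant(v, channel.q))
            for g in channel.gates]


# ---------------------------------------------------------------------------
# cell assembly
# ---------------------------------------------------------------------------

@dataclass
class CellModel:
    """Morphology with resolved per-compartment biophysics.

    Channel densities are defined by the biophysical rules evaluated at any
    path distance, modulated by a per-compartment ``mask`` (1 everywhere
    after :func:`build_cell`; manipulations may zero it).  ``densities``
    tabulates S/cm² at compartment midpoints.  Apical diameters carry the
    diameter scale.  Synapses are attached separately (see
    :func:`tccoupling.connectome.embed_synapses`).
    """

    morphology: Morphology
    biophys: BiophysModel
    mask: dict[str, dict[int, float]]
    cm: dict[int, float]
    g_leak: dict[int, float]
    diameter_scale: dict[int, float]
    synapses: list = field(default_factory=list)       # SynapsePlacement, resolved
    synapse_models: dict = field(default_factory=dict)  # population -> models
    synapse_weight: dict = field(default_factory=dict)  # population -> scale

    def _channel(self, name: str) -> ChannelSpec:
        for ch in self.biophys.channels:
            if ch.name == name:
                return ch
        raise ConfigError(f"unknown channel {name!r}")

    def density_at(self, name: str, comp_id: int, distance: float) -> float:
        """Channel density (S/cm²) at an exact path distance on a compartment."""
        c = self.morphology[comp_id]
        if c.domain == "myelin":
            return 0.0
        ch = self._channel(name)
        return ch.density(c.domain, distance) * self.mask[name][comp_id]

    @property
    def densities(self) -> dict[str, dict[int, float]]:
        out: dict[str, dict[int, float]] = {}
        for ch in self.biophys.channels:
            out[ch.name] = {}
            for c in self.morphology.compartments:
                mid = 0.5 * (c.proximal_distance + c.path_distance_to_soma)
                out[ch.name][c.id] = self.density_at(ch.name, c.id, mid)
        return out

    def scaled_diameters(self, comp_id: int) -> tuple[float, float]:
        c = self.morphology[comp_id]
        s = self.diameter_scale[comp_id]
        return c.diameter_proximal * s, c.diameter_distal * s

    def with_passive_apical(self) -> "CellModel":
        """Copy with voltage/Ca-gated conductances zeroed on trunk, tuft and
        obliques (leak retained) — the passive-apical manipulation."""
        mask = {name: dict(table) for name, table in self.mask.items()}
        for c in self.morphology.compartments:
            if c.domain in APICAL_DOMAINS:
                for table in mask.values():
                    table[c.id] = 0.0
        return replace(self, mask=mask)

    def with_synapses(self, placements, models) -> "CellModel":
        return replace(self, synapses=list(placements), synapse_models=dict(models))

    def with_synapse_weight(self, population: str, factor: float) -> "CellModel":
        w = dict(self.synapse_weight)
        w[population] = w.get(population, 1.0) * factor
        return replace(self, synapse_weight=w)


def build_cell(morph: Morphology, biophys: BiophysModel) -> CellModel:
    """Assemble the per-compartment conductance table.

    Every compartment receives the passive parameters; channel densities are
    evaluated through the channel's domain/distance rules; apical (trunk,
    tuft, oblique) diameters are multiplied by the diameter scale; the
    myelinated axon gets capacitance and leak divided by ``myelin_factor``
    and no active channels.
    """
    if not morph.has_axon:
        raise ParameterError("attach the axon before building the cell")
    known = {d for ch in biophys.channels for r in ch.rules for d in r.domains}
    from .morphology import ALL_DOMAINS
    unknown = known - ALL_DOMAINS
    if unknown:
        raise ConfigError(f"conductance rule references unknown domains {sorted(unknown)}")

    mask: dict[str, dict[int, float]] = {
        ch.name: {c.id: 1.0 for c in morph.compartments} for ch in biophys.channels}
    cm: dict[int, float] = {}
    g_leak: dict[int, float] = {}
    scale: dict[int, float] = {}
    for c in morph.compartments:
        myelin = c.domain == "myelin"
        cm[c.id] = biophys.passive.cm / (biophys.myelin_factor if myelin else 1.0)
        g_leak[c.id] = biophys.passive.g_leak / (biophys.myelin_factor if myelin else 1.0)
        scale[c.id] = (biophys.apical_diameter_scale
                       if c.domain in APICAL_DOMAINS else 1.0)
    return CellModel(morph, biophys, mask, cm, g_leak, scale)
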