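"""Reference fixtures: a packaged PT-like cell, its network embedding and
PSTH set, built from the versioned parameter file ``data/reference_cell.yaml``.

The parameter set was tuned so the reference cell reproduces the qualitative
electrophysiology of layer-5 pyramidal tract neurons (monotone f-I curve,
attenuating back-propagating APs, BAC firing with a ≥20 ms dendritic Ca²⁺
plateau under coincident somatic + apical input) — see
:func:`tccoupling.simulator.run_validation_protocols`.
"""

from __future__ import annotations

import hashlib
import importlib.resources as resources
from dataclasses import dataclass

import yaml

from .activity import PSTHParams, default_psth_params, synthetic_psth
from .connectome import (PresynPopulation, TCDensityProfile,
                         assign_presynaptic_sources, excitatory_synapse_models,
                         inhibitory_synapse_models, sample_cortical_synapses,
                         sample_inhibitory_synapses, sample_tc_synapses)
from .errors import ConfigError
from .membrane import (BiophysModel, CaDynamics, CellModel, ChannelSpec,
                       ConductanceRule, GateSpec, MgBlockParams, Passive,
                       build_cell)
from .morphology import MorphologyParams, attach_axon, generate_pt_morphology

__all__ = [
    "load_reference_config",
    "reference_config_hash",
    "reference_morphology",
    "reference_biophys",
    "reference_populations",
    "reference_placements",
    "make_reference_cell",
    "generate_fixtures",
    "FixtureBundle",
]


def _read_text() -> str:
    return (resources.files("tccoupling.data") / "reference_cell.yaml").read_text()


def load_reference_config() -> dict:
    return yaml.safe_load(_read_text())


def reference_config_hash() -> str:
    return hashlib.sha256(_read_text().encode()).hexdigest()[:16]


def reference_morphology(seed: int = 0):
    morph = generate_pt_morphology(MorphologyParams(seed=seed))
    return attach_axon(morph)


def _gate(d: dict) -> GateSpec:
    return GateSpec(power=int(d["power"]), v_half=d.get("v_half", 0.0),
                    k=d.get("k", 1.0), tau_min=d.get("tau_min", 0.1),
                    tau_amp=d.get("tau_amp", 0.0), v_tau=d.get("v_tau", 0.0),
                    sigma=d.get("sigma", 15.0),
                    ca_dependent=d.get("ca_dependent", False),
                    ca_half=d.get("ca_half", 4.3e-4),
                    ca_hill=d.get("ca_hill", 4.0))


def _rule(d: dict, bp_distance: float) -> ConductanceRule:
    window = None
    if "window_rel_bp" in d:
        lo, hi = d["window_rel_bp"]
        window = (bp_distance + lo, bp_distance + hi)
    elif "window" in d:
        window = tuple(d["window"])
    return ConductanceRule(gbar=float(d["gbar"]),
                           domains=frozenset(d["domains"]),
                           slope=float(d.get("slope", 0.0)),
                           minimum=float(d.get("minimum", 0.0)),
                           window=window)


def reference_biophys(bp_distance: float, config: dict | None = None) -> BiophysModel:
    """Build the biophysical model; hot-zone windows anchor to the BP."""
    cfg = config or load_reference_config()
    channels = []
    for name, ch in cfg["channels"].items():
        channels.append(ChannelSpec(
            name=name,
            gates=tuple(_gate(g) for g in ch["gates"]),
            reversal=("ca_nernst" if ch["reversal"] == "ca_nernst"
                      else float(ch["reversal"])),
            rules=tuple(_rule(r, bp_distance) for r in ch["rules"]),
            q=float(ch.get("q", 1.0)),
            ca_flux=bool(ch.get("ca_flux", False))))
    p = cfg["passive"]
    c = cfg["ca_dynamics"]
    return BiophysModel(
        channels=tuple(channels),
        passive=Passive(g_leak=p["g_leak"], e_leak=p["e_leak"],
                        ra=p["ra"], cm=p["cm"]),
        ca=CaDynamics(decay_ms=c["decay_ms"], depth_um=c["depth_um"],
                      ca_rest_mm=c["ca_rest_mm"], ca_out_mm=c["ca_out_mm"],
                      gamma=c["gamma"]),
        apical_diameter_scale=cfg.get("apical_diameter_scale", 1.0))


def reference_populations(stimulus: str = "principal",
                          config: dict | None = None) -> dict:
    """Presynaptic population table with synthetic evoked PSTHs attached."""
    cfg = config or load_reference_config()
    targets = cfg.get("upsp_targets") or {}
    pops = {}
    for ct, p in cfg["populations"].items():
        base = default_psth_params(ct, ongoing_rate_hz=p["ongoing_rate"])
        psth = synthetic_psth(ct, stimulus="principal", params=base)
        pops[ct] = PresynPopulation(
            cell_type=ct,
            n_cells=int(p.get("n_cells", p["n_synapses"])),
            ongoing_rate=float(p["ongoing_rate"]),
            evoked_psth=psth,
            domain_preference=dict(p.get("domain_preference", {})),
            upsp_targets=(tuple(targets[ct]) if ct in targets else None),
            excitatory=(ct != "INH"))
    return pops


def reference_placements(morph, seed: int = 0, config: dict | None = None):
    """TC + cortical + inhibitory placements with assigned sources."""
    cfg = config or load_reference_config()
    pops = reference_populations(config=cfg)
    prof = TCDensityProfile(**cfg["tc_profile"])
    n_tc = cfg["populations"]["VPM"]["n_synapses"]
    tc = sample_tc_synapses(morph, prof, n_tc, seed)
    counts = {ct: cfg["populations"][ct]["n_synapses"]
              for ct in cfg["populations"] if ct not in ("VPM", "INH")}
    cortical = sample_cortical_synapses(morph, pops, counts, seed,
                                        start_id=len(tc))
    inh = sample_inhibitory_synapses(morph, seed,
                                     n=cfg["populations"]["INH"]["n_synapses"],
                                     start_id=len(tc) + len(cortical))
    return assign_presynaptic_sources(tc + cortical + inh, pops, seed)


def reference_synapse_models(config: dict | None = None) -> dict:
    cfg = (config or load_reference_config())["synapses"]
    mg = MgBlockParams(**cfg["mg_block"])
    per_type = cfg.get("nmda_ratio_per_type", {})
    models = {}
    for ct, peak in cfg["peak_ns"].items():
        models[ct] = excitatory_synapse_models(
            float(peak), nmda_ratio=per_type.get(ct, cfg["nmda_ratio"]),
            ampa_tau=tuple(cfg["ampa_tau"]), nmda_tau=tuple(cfg["nmda_tau"]),
            mg=mg)
    models["INH"] = inhibitory_synapse_models(
        peak_ns=cfg["gaba_peak_ns"], tau=tuple(cfg["gaba_tau"]),
        reversal=cfg["gaba_reversal"])
    return models


def make_reference_cell(seed: int = 0, with_synapses: bool = True,
                        config: dict | None = None) -> tuple[CellModel, dict]:
    """The packaged reference cell (embedded by default) and its populations."""
    cfg = config or load_reference_config()
    morph = reference_morphology(seed=seed)
    bio = reference_biophys(morph.bp_distance, cfg)
    cell = build_cell(morph, bio)
    pops = reference_populations(config=cfg)
    if with_synapses:
        placements = reference_placements(morph, seed=seed, config=cfg)
        cell = cell.with_synapses(placements, reference_synapse_models(cfg))
    return cell, pops


@dataclass
class FixtureBundle:
    cell: CellModel
    populations: dict
    config_hash: str
    seed: int
    validation: object = None


def generate_fixtures(seed: int = 0, validate: bool = True) -> FixtureBundle:
    """Reference cell + placements + PSTHs, hash-stable given the seed."""
    from .simulator import run_validation_protocols

    cell, pops = make_reference_cell(seed=seed)
    bundle = FixtureBundle(cell, pops, reference_config_hash(), seed)
    if validate:
        report = run_validation_protocols(cell)
        bundle.validation = report
        if not report.passed:
            raise ConfigError("reference cell failed the validation protocols")
    return bundle
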