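"""Model-selection campaign: enumerate input configurations, run staged
simulations, and keep those whose activity matches the in vivo bands.

The campaign is organised like a statsmodels model:
:class:`ModelSelectionCampaign` is built from a network-embedded cell and a
:class:`CampaignConfig`; ``fit(seed)`` runs the three stages and returns a
:class:`CampaignResults` carrying the per-configuration statistics,
accept/reject flags and a consensus summary across accepted configurations.

Stages and selection bands (fractions over trials):

* ongoing — trials of ongoing activity; keep configurations whose mean
  somatic AP rate is > 0 and ≤ 11 Hz;
* coarse evoked — few trials per configuration; keep those with ≥1-AP
  response probability > 0, 2-AP burst probability > 0 and ≤ 0.40, 3-AP
  burst probability ≤ 0.25;
* fine evoked — many trials for the survivors; keep 3-AP burst
  probabilities ≤ 0.13, the maximum observed in vivo.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activity import (InputGridPoint, ONGOING_LAYOUT, TrialLayout,
                       build_trial_inputs)
from .analysis import classify_response
from .errors import ConfigError, ParameterError
from .simulator import SimConfig, default_probes, discretize, run_trial

__all__ = [
    "SelectionBands",
    "CampaignConfig",
    "ConfigurationResult",
    "ModelSelectionCampaign",
    "CampaignResults",
    "run_ongoing_stage",
    "run_evoked_stage",
    "select_configurations",
    "full_grid",
    "desk_grid",
]


@dataclass(frozen=True)
class SelectionBands:
    """Acceptance bands for the staged selection (probabilities in [0, 1])."""

    ongoing_rate_min_hz: float = 0.0     # exclusive
    ongoing_rate_max_hz: float = 11.0    # inclusive
    response_prob_min: float = 0.0       # exclusive
    burst2_prob_min: float = 0.0         # exclusive
    burst2_prob_max: float = 0.40        # inclusive
    burst3_prob_max_coarse: float = 0.25
    burst3_prob_max_fine: float = 0.13

    def ongoing_pass(self, rate: float) -> bool:
        return self.ongoing_rate_min_hz < rate <= self.ongoing_rate_max_hz

    def coarse_pass(self, resp: float, b2: float, b3: float) -> bool:
        return (resp > self.response_prob_min
                and self.burst2_prob_min < b2 <= self.burst2_prob_max
                and b3 <= self.burst3_prob_max_coarse)

    def fine_pass(self, resp: float, b2: float, b3: float) -> bool:
        return (resp > self.response_prob_min
                and self.burst2_prob_min < b2 <= self.burst2_prob_max
                and b3 <= self.burst3_prob_max_fine)


def full_grid() -> dict:
    """The full published input grid (not desk-scale)."""
    return {
        "ongoing_inh_scale": tuple(np.arange(0.25, 3.76, 0.25)),
        "evoked_inh_scale": tuple(np.arange(0.1, 1.01, 0.1)),
        "inh_shift": (0.0, -1.0, -2.0),
        "stimulus": ("principal", "same_row_3", "two_rows_3"),
    }


def desk_grid() -> dict:
    """Shrunk grid for desk-scale runs."""
    return {
        "ongoing_inh_scale": (0.5, 1.5),
        "evoked_inh_scale": (0.2, 0.5, 0.8),
        "inh_shift": (0.0, -1.0),
        "stimulus": ("principal",),
    }


@dataclass(frozen=True)
class CampaignConfig:
    grid: dict = field(default_factory=desk_grid)
    bands: SelectionBands = SelectionBands()
    ongoing_trials: int = 48
    coarse_trials: int = 20
    fine_trials: int = 200
    ongoing_layout: TrialLayout = ONGOING_LAYOUT
    evoked_layout: TrialLayout = TrialLayout(ongoing_ms=445.0, evoked_ms=100.0)
    analysis_window_ms: float = 50.0

    def __post_init__(self):
        for f in ("ongoing_trials", "coarse_trials", "fine_trials"):
            if getattr(self, f) < 1:
                raise ParameterError(f"{f} must be >= 1")
        if self.ongoing_layout.discard_ms >= self.ongoing_layout.duration_ms:
            raise ParameterError("discard window exceeds trial length")

    @classmethod
    def desk(cls, ongoing_trials=8, coarse_trials=20, fine_trials=100):
        return cls(grid=desk_grid(), ongoing_trials=ongoing_trials,
                   coarse_trials=coarse_trials, fine_trials=fine_trials)

    @classmethod
    def full(cls):
        return cls(grid=full_grid())


@dataclass
class ConfigurationResult:
    config_id: str
    grid_point: InputGridPoint
    ongoing_rate: float = np.nan
    ongoing_pass: bool = False
    response_prob: float = np.nan
    burst2_prob: float = np.nan
    burst3_prob: float = np.nan
    coarse_pass: bool = False
    fine_pass: bool = False
    stage_reached: str = "ongoing"

    @property
    def accepted(self) -> bool:
        return self.ongoing_pass and self.coarse_pass and self.fine_pass


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _ongoing_rate(cell, populations, grid_point, campaign, sim, seed, grid):
    layout = campaign.ongoing_layout
    window = layout.duration_ms - layout.discard_ms
    rates = []
    for k in range(campaign.ongoing_trials):
        inputs = build_trial_inputs(cell.synapses, populations, grid_point,
                                    layout, seed, trial=k)
        rec = run_trial(cell, inputs, sim, grid=grid)
        n = int(np.sum(rec.somatic_spike_times >= layout.discard_ms))
        rates.append(n / (window / 1e3))
    return float(np.mean(rates))


def run_ongoing_stage(cell, populations, grid_point: InputGridPoint,
                      campaign: CampaignConfig, sim: SimConfig, seed: int,
                      grid=None) -> tuple[float, bool]:
    """Mean somatic AP rate over post-discard epochs and its pass flag."""
    if grid is None:
        grid = discretize(cell, sim)
    rate = _ongoing_rate(cell, populations, grid_point, campaign, sim, seed, grid)
    return rate, campaign.bands.ongoing_pass(rate)


def run_evoked_stage(cell, populations, grid_point: InputGridPoint,
                     campaign: CampaignConfig, sim: SimConfig, seed: int,
                     stage: str = "coarse", grid=None) -> dict:
    """Run evoked trials, classify the 50-ms response window, apply bands."""
    if stage not in ("coarse", "fine"):
        raise ConfigError("stage must be 'coarse' or 'fine'")
    if grid is None:
        grid = discretize(cell, sim)
    layout = campaign.evoked_layout
    n_trials = campaign.coarse_trials if stage == "coarse" else campaign.fine_trials
    counts = {"none": 0, "single": 0, "burst2": 0, "burst3": 0}
    for k in range(n_trials):
        inputs = build_trial_inputs(cell.synapses, populations, grid_point,
                                    layout, seed, trial=k)
        rec = run_trial(cell, inputs, sim, grid=grid)
        win = (inputs.t_onset, inputs.t_onset + campaign.analysis_window_ms)
        counts[classify_response(rec.somatic_spike_times, win).label] += 1
    resp = (counts["single"] + counts["burst2"] + counts["burst3"]) / n_trials
    b2 = counts["burst2"] / n_trials
    b3 = counts["burst3"] / n_trials
    check = campaign.bands.coarse_pass if stage == "coarse" else campaign.bands.fine_pass
    return {"response_prob": resp, "burst2_prob": b2, "burst3_prob": b3,
            "n_trials": n_trials, "passed": check(resp, b2, b3)}


def select_configurations(results) -> dict:
    """Accepted set plus per-metric consensus (median and quartiles).

    ``results`` is an iterable of :class:`ConfigurationResult`.  An empty
    accepted set yields a warning entry rather than an exception.
    """
    results = list(results)
    accepted = [r for r in results if r.accepted]
    summary: dict = {"n_total": len(results), "n_accepted": len(accepted),
                     "accepted_ids": [r.config_id for r in accepted],
                     "warning": None, "consensus": {}}
    if not accepted:
        summary["warning"] = "no configuration passed all stages"
        return summary
    for metric in ("ongoing_rate", "response_prob", "burst2_prob", "burst3_prob"):
        vals = np.array([getattr(r, metric) for r in accepted], dtype=float)
        summary["consensus"][metric] = {
            "median": float(np.median(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
        }
    return summary


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ModelSelectionCampaign:
    """Staged grid search over input configurations for one embedded cell.

    Parameters
    ----------
    cell : CellModel
        Network-embedded cell (synapses and synapse models attached).
    populations : dict
        Presynaptic population table (cell type -> PresynPopulation).
    config : CampaignConfig
        Grids, trial counts and selection bands.
    sim_config : SimConfig, optional
        Numerical settings; defaults to standard probes on the cell.
    """

    def __init__(self, cell, populations, config: CampaignConfig | None = None,
                 sim_config: SimConfig | None = None):
        self.cell = cell
        self.populations = populations
        self.config = config or CampaignConfig.desk()
        self.sim_config = sim_config or SimConfig(
            probe_sites=default_probes(cell.morphology))
        if not cell.synapses:
            raise ConfigError("cell has no synapses attached")

    def grid_points(self):
        g = self.config.grid
        axes = [g["ongoing_inh_scale"], g["evoked_inh_scale"],
                g["inh_shift"], g["stimulus"]]
        for on, ev, sh, st in itertools.product(*axes):
            yield InputGridPoint(ongoing_inh_scale=on, evoked_inh_scale=ev,
                                 inh_shift=sh, stimulus=st)

    def fit(self, seed: int = 0, progress=None) -> "CampaignResults":
        """Run the three-stage campaign; deterministic given the seed."""
        grid = discretize(self.cell, self.sim_config)
        cfg = self.config

        # the ongoing stage depends only on the ongoing axes
        ongoing_cache: dict[tuple, tuple[float, bool]] = {}
        results: list[ConfigurationResult] = []
        for gp in self.grid_points():
            okey = (gp.ongoing_inh_scale, gp.ongoing_exc_scale)
            if okey not in ongoing_cache:
                ongoing_cache[okey] = run_ongoing_stage(
                    self.cell, self.populations,
                    replace(gp, evoked_inh_scale=0.0), cfg, self.sim_config,
                    seed, grid=grid)
                if progress:
                    progress(f"ongoing inh={okey[0]:g}: "
                             f"{ongoing_cache[okey][0]:.2f} Hz")
            rate, opass = ongoing_cache[okey]
            cid = (f"inh{gp.ongoing_inh_scale:g}_ev{gp.evoked_inh_scale:g}_"
                   f"sh{gp.inh_shift:g}_{gp.stimulus}")
            res = ConfigurationResult(cid, gp, rate, opass)
            if opass:
                res.stage_reached = "coarse"
                coarse = run_evoked_stage(self.cell, self.populations, gp, cfg,
                                          self.sim_config, seed, "coarse", grid)
                res.response_prob = coarse["response_prob"]
                res.burst2_prob = coarse["burst2_prob"]
                res.burst3_prob = coarse["burst3_prob"]
                res.coarse_pass = coarse["passed"]
                if progress:
                    progress(f"coarse {cid}: resp={res.response_prob:.2f} "
                             f"b2={res.burst2_prob:.2f} b3={res.burst3_prob:.2f}")
                if coarse["passed"]:
                    res.stage_reached = "fine"
                    fine = run_evoked_stage(self.cell, self.populations, gp,
                                            cfg, self.sim_config, seed, "fine",
                                            grid)
                    res.response_prob = fine["response_prob"]
                    res.burst2_prob = fine["burst2_prob"]
                    res.burst3_prob = fine["burst3_prob"]
                    res.fine_pass = fine["passed"]
            results.append(res)
        return CampaignResults(self, results, seed)


class CampaignResults:
    """Outcome of a fitted campaign; see :meth:`summary`."""

    def __init__(self, model: ModelSelectionCampaign,
                 results: list[ConfigurationResult], seed: int):
        self.model = model
        self.results = results
        self.seed = seed
        self.selection = select_configurations(results)

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "config_id": r.config_id,
                "ongoing_inh_scale": r.grid_point.ongoing_inh_scale,
                "evoked_inh_scale": r.grid_point.evoked_inh_scale,
                "inh_shift": r.grid_point.inh_shift,
                "stimulus": r.grid_point.stimulus,
                "ongoing_rate_hz": r.ongoing_rate,
                "ongoing_pass": r.ongoing_pass,
                "response_prob": r.response_prob,
                "burst2_prob": r.burst2_prob,
                "burst3_prob": r.burst3_prob,
                "coarse_pass": r.coarse_pass,
                "fine_pass": r.fine_pass,
                "accepted": r.accepted,
                "stage_reached": r.stage_reached,
            })
        return pd.DataFrame(rows)

    @property
    def accepted(self) -> list[ConfigurationResult]:
        return [r for r in self.results if r.accepted]

    def consensus(self) -> dict:
        return self.selection["consensus"]

    def summary(self) -> str:
        df = self.frame
        lines = [
            "Model-selection campaign".center(70),
            "=" * 70,
            f"configurations: {len(df)}   seed: {self.seed}",
            f"ongoing pass:   {int(df.ongoing_pass.sum())}"
            f"   coarse pass: {int(df.coarse_pass.sum())}"
            f"   accepted: {int(df.accepted.sum())}",
            "-" * 70,
            df.drop(columns=["config_id", "stage_reached"]).to_string(index=False),
        ]
        if self.selection["consensus"]:
            lines.append("-" * 70)
            lines.append("model consensus (median [q25, q75] across accepted):")
            for metric, s in self.selection["consensus"].items():
                lines.append(f"  {metric:>14}: {s['median']:.3f} "
                             f"[{s['q25']:.3f}, {s['q75']:.3f}]")
        if self.selection["warning"]:
            lines.append(f"warning: {self.selection['warning']}")
        return "\n".join(lines)
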