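# tccoupling

Conductance-based simulation of **thalamocortical coupling** — the mechanism
by which direct thalamic (VPM) input to the apical Ca²⁺ domain of layer-5
pyramidal tract (PT) neurons enables bursts of 3 action potentials in
sensory-evoked cortical output.

The package is aimed at computational neuroscientists who want a compact,
fully self-contained re-implementation of this in-silico experiment:
a branched-cable Hodgkin–Huxley neuron driven by a synthetic connectome and
PSTH-derived Poisson inputs, a staged model-selection campaign against
in-vivo activity bands, a paired-replay manipulation engine for pathway
deprivations, and the spike/dendritic-event analysis rules.

## The model in brief

The membrane potential $V$ on the branched cable obeys

$$C_m \frac{\partial V}{\partial t} = \frac{1}{r_a}\nabla^2 V
  - \sum_c \bar g_c\, m_c^{p_c} h_c\,(V - E_c)
  - \sum_s g_s(t)\,(V - E_s) + I_{inj},$$

with Hodgkin–Huxley gates relaxing as
$\dot x = (x_\infty(V) - x)/\tau_x(V)$, double-exponential synaptic
conductances $g_s(t) \propto e^{-t/\tau_d} - e^{-t/\tau_r}$ (AMPA+NMDA with
sigmoidal Mg²⁺ unblock, GABA_A fixed at 1 nS), and an apical "hot zone" of
low- and high-voltage-activated Ca²⁺ channels around the primary branch
point (BP). The system is integrated implicitly (backward Euler or
Crank–Nicolson) with an exact O(n) tree solve per step.

Somatic responses in the 50-ms post-stimulus window are classified by the
in-vivo burst rules — 3 APs within 30 ms → burst of 3; else 2 APs within
10 ms → burst of 2 — and dendritic Ca²⁺ APs are detected as apical-probe
excursions above −30 mV. A model configuration is *accepted* when its
ongoing rate lies in (0, 11] Hz and its evoked response probabilities lie
within the observed bands (burst-2 ≤ 40%, burst-3 ≤ 13%).

## Worked example

Run paired control/manipulated trials on the packaged reference cell,
depriving it of direct thalamocortical input:

```bash
$ tccoupling manipulate --kind deprive_direct_tc --trials 10 --seed 1
{"kind": "deprive_direct_tc", "trials": 10,
 "control": {"burst2": 9, "burst3": 1},
 "manipulated": {"single": 8, "none": 2}}
```

Every control trial responds, mostly with 2-AP bursts and occasionally a
3-AP burst; removing the sensory-evoked TC activations (while replaying all
other inputs bit-identically) abolishes the bursts while most trials keep a
single-AP response — the burst component of the output is TC-dependent.

A desk-scale selection campaign over input configurations:

```bash
$ tccoupling campaign run --preset desk --seed 1
                       Model-selection campaign
======================================================================
configurations: 12   seed: 1
ongoing pass:   0   coarse pass: 0   accepted: 0
----------------------------------------------------------------------
 ongoing_inh_scale  evoked_inh_scale  ...  ongoing_rate_hz  accepted
               0.5               0.2  ...              0.0     False
               ...
warning: no configuration passed all stages
```

On the packaged reference fixture every configuration is rejected at the
ongoing stage: the fixture's sparse Poisson background never fires the cell
spontaneously, so its ongoing rate (0 Hz) falls outside the in-vivo band
(> 0 and ≤ 11 Hz) at every inhibition scale. This is a faithful outcome of
the selection rules on a cell whose background is too weak — see
`docs/methods.md` ("Known limitations") for why, and for what the
evoked-response stages report when run directly.

The library mirrors statsmodels conventions: build a
`ModelSelectionCampaign(cell, populations, config)` and call
`.fit(seed)` to obtain a `CampaignResults` with a per-configuration
`frame`, accept/reject flags, a consensus summary and `.summary()`.

```python
from tccoupling.fixtures import make_reference_cell
from tccoupling.campaign import CampaignConfig, ModelSelectionCampaign

cell, populations = make_reference_cell(seed=0)
results = ModelSelectionCampaign(cell, populations, CampaignConfig.desk()).fit(seed=1)
print(results.summary())
```

## Layout

| module | contents |
| --- | --- |
| `morphology` | PT-like compartment trees, SWC I/O, normalized apical coordinate |
| `membrane` | channel kinetics, synapse models, per-compartment cell assembly |
| `simulator` | discretization, implicit tree solver, trials, validation protocols |
| `connectome` | synapse placement, source assignment, uPSP calibration |
| `activity` | synthetic PSTHs, Poisson inputs, counter-based paired streams |
| `campaign` | staged model selection (Model/Results interface) |
| `manipulations` | the eleven deprivations, plasticity, ongoing scaling |
| `analysis` | burst classification, Ca²⁺ events, waveforms, density profiles |
| `fixtures` | the versioned reference cell and its network embedding |
| `io`, `cli` | persistence, manifests, `tccoupling` command-line entry points |

See `docs/methods.md` for the scientific assumptions, parameter defaults
and known limitations.
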