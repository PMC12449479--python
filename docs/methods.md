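# Methods

`tccoupling` simulates how direct thalamocortical (TC) input to the apical
Ca²⁺ domain of layer-5 pyramidal tract (PT) neurons enables burst firing in
sensory-evoked cortical output. This note documents the models, the
numerical choices, what the synthetic data emulate, and the limits of what
the tests demonstrate.

## The cell model

The neuron is a branched-cable, conductance-based model. The synthetic
morphology is a stylised PT cell: a soma, six tapering basal dendrites, an
apical trunk ending at the primary branch point (BP, 620 µm from the soma by
default), four obliques, and a bifurcating tuft reaching 400 µm beyond the
BP. A simplified axon (hillock 20 µm tapering 3→1.75 µm, initial segment
30 µm tapering 1.75→1 µm, 1 mm of myelin at 1 µm) is attached at the soma.
Segments are straight; the 3D embedding written to SWC is cosmetic. The
soma–BP–tuft axis maps onto a normalized coordinate x (soma 0, BP 1, most
distal tuft 2) used for density profiles and probe placement.

Active membrane follows the Hodgkin–Huxley formalism with Boltzmann steady
states and bell-shaped voltage-dependent time constants. The channel set is
the minimal family known to support back-propagating APs (bAPs), dendritic
Ca²⁺ plateaus and BAC firing: transient Na⁺; a fast delayed-rectifier K⁺
("Kv3.1") whose apical density decreases linearly with path distance down to
a floor (the slope and floor are explicit parameters); muscarinic K⁺;
high- and low-voltage-activated Ca²⁺ channels concentrated in a hot zone
spanning 300 µm below to 100 µm above the BP; a Ca²⁺-activated K⁺ (SK)
conductance driven by an exponentially decaying submembrane Ca²⁺ pool
(τ = 80 ms, shell depth 0.1 µm) that also sets the Ca²⁺ Nernst reversal;
and Ih, with an elevated apical density that depolarizes the apical resting
potential relative to the soma. All parameter values live in the versioned
file `data/reference_cell.yaml`; they are this package's reference set,
tuned to the qualitative PT phenotype, and make no claim of matching any
published channel database numerically.

The reference cell passes three validation protocols (`run_validation_protocols`):

* **f–I**: prolonged somatic current steps produce a monotone spike-count
  curve starting at zero;
* **bAP**: a brief suprathreshold somatic pulse produces an apical transient
  smaller than the somatic AP;
* **BAC firing**: a somatic AP paired with an EPSP-shaped apical injection
  (0.5 nA peak, delivered within a few ms of the pulse) evokes an apical
  plateau crossing −30 mV for ≥ 20 ms, while either input alone evokes
  none. Apical SK is the reason a lone bAP fails to ignite the hot zone:
  the bAP's own Ca²⁺ influx recruits SK and quenches the nascent plateau
  unless concurrent apical depolarization sustains it. This is also the
  mechanism that makes burst generation in network trials depend on TC
  priming.

## The synthetic connectome and inputs

Synapse placement emulates an anatomically embedded network. TC (VPM)
synapses follow a density profile that is flat on basal/oblique dendrites
(60% of TC synapses are proximal), rises convexly along the trunk to a peak
100 µm below the BP, and decays exponentially (length constant 150 µm)
toward the tuft. The convex rise (power 2.5) reflects the qualitative shape
of measured profiles — density hugs low values proximally and surges near
the BP — and makes the peak-bin location statistically identifiable from
10³ samples, which a linear ramp does not. Cortical excitatory types place
synapses by per-domain preference weights (L6CC basal-weighted, L4SP
apical-weighted); 5000 inhibitory synapses are placed uniformly by dendritic
length, each with its own virtual presynaptic neuron at 1 nS GABA_A. TC
synapses are assigned uniformly to a 350-neuron thalamic pool; cortical
synapses are grouped into 3-synapse connections that fire together.
Synapse counts per type (1300 TC, 2000–3000 per cortical type) are
order-of-magnitude stand-ins exposed in the config.

Excitatory synapses are AMPA+NMDA double-exponential conductances
(τ 0.2/2 ms and 2/50 ms), normalized so the peak equals the configured
conductance exactly; NMDA carries the classical sigmoidal Mg²⁺ unblock
(1/(1+0.28·[Mg]·e^(−0.062·V))). Peak conductances per type are the packaged
reference values; `calibrate_upsp` reproduces the calibration procedure —
activating each connection of a type alone from rest, measuring somatic
uPSP amplitudes (peak depolarization within 50 ms of activation), and
minimizing the weighted squared distance to target (mean, median, max)
statistics with mean and median weighted twice relative to the maximum,
via a log-bracketed bounded scalar search.

Activity generation: ongoing firing is homogeneous Poisson at per-type
rates (VPM 3, L2/3PN 0.3, L4SP 1, L5IT 2, L5PT 5, L6CC 2, INH 7 Hz);
the evoked epoch adds spikes from alpha-shaped PSTH bumps whose onset
latencies honour the measured ordering (TC volley to the deep layers 1.8 ms
before L4; L6CC preceding L4SP by 2.1 ms). Spikes are realized by per-sub-bin
Bernoulli thinning (sub-bins refined until rate·Δ < 0.1) from counter-based
Philox streams keyed by (seed, trial, population, presynaptic cell), so a
manipulation that touches one pathway replays every other pathway
bit-identically. Evoked (bump) and ongoing spikes are generated as separate
processes and tagged at generation; "depriving a pathway of sensory-evoked
input" deletes exactly the bump-tagged activations.

## Numerics

Spatial discretization splits compartments at 50 µm (default), conserving
membrane area exactly; segments are kept in parent-before-child order and
the linearized membrane system is solved exactly on the tree in O(n) per
step (Hines elimination). Time stepping is a theta-method with staggered
analytic gate relaxation: backward Euler (θ=1) by default for robustness
with the stiff Ca²⁺/SK dynamics, Crank–Nicolson (θ=0.5) available where
second-order accuracy matters; at θ=0.5 halving dt = 0.025 ms moves the
spike times of a burst-evoking stimulus by < 0.1 ms. Synapses sharing a
segment and receptor kinetics are folded into a single compound
double-exponential state — exact by linearity — which keeps per-step cost
independent of the synapse count (~10⁴ synapses become ~200 states).
Somatic APs are strict upward crossings of 0 mV with 1 ms dead time,
interpolated between samples. Dendritic Ca²⁺ events are maximal contiguous
excursions of the apical probe (on the trunk at the TC-density peak,
100 µm below the BP) above −30 mV; onset and width use linear
interpolation; events separated by sub-threshold dips are not merged.

## Campaign, manipulations and analyses

`ModelSelectionCampaign` runs the staged selection: an ongoing stage
(48 trials of 1245 ms, first 245 ms discarded; keep mean somatic rate
> 0 and ≤ 11 Hz), a coarse evoked stage (20 trials; keep response
probability > 0, 2-AP burst probability > 0 and ≤ 40%, 3-AP burst
probability ≤ 25%) and a fine stage (200 trials; 3-AP burst probability
≤ 13%). Burst classification inside the 50-ms post-onset window uses the
in vivo rules: any 3 APs within 30 ms → 3-AP burst; else any 2 consecutive
APs within 10 ms → 2-AP burst. The analysis window anchors to TC onset
(stimulus onset plus the earliest VPM bump latency); with synthetic PSTHs
this differs from stimulus anchoring by a constant recorded in metadata.
Desk-scale presets shrink the grid (2 ongoing-INH × 3 evoked-INH × 2
INH-timing values × 1 stimulus) and the trial counts (6–8/10–20/40–100),
and shorten the evoked trials to 300 ms of ongoing activity plus a 100-ms
evoked epoch; these are the problem sizes used throughout the tests and the
acceptance script, and the full printed grid remains available via
`CampaignConfig.full()`.

The manipulation engine implements the eleven numbered deprivations plus
ongoing-rate scaling (0.5–2× on excitatory types, regenerated under the
paired stream) and TC plasticity (×2.5 TC synaptic weight). Deletion kinds
remove only bump-tagged activations of the targeted populations; the
passive-apical kind zeroes every voltage- and Ca²⁺-gated conductance on
trunk, tuft and obliques (leak retained); distance-binned TC removal and
pre-stimulus-window removal delete up to 50 eligible activations per trial,
sampled uniformly without replacement from a stream keyed by (seed, spec,
trial).

## What the synthetic data do and do not show

The generator realizes the study's *conditions* — synapse counts and
distributions, population latencies, ongoing rates, selection bands — but
not the study's *data*: real reconstructed morphologies, measured PSTHs,
an anatomical network model, or optimization-derived biophysics databases.
Passing tests therefore demonstrate that the machinery reproduces the
mechanism's direction on a cell constructed to express it: removing
indirect cortical drive abolishes evoked spiking; removing direct TC input
abolishes bursts while single-AP responses persist; removing apical active
conductances abolishes 3-AP bursts but not 2-AP bursts; 3-AP-burst trials
coincide with sensory-attributed Ca²⁺ plateaus and with elevated apical
depolarization before TC onset. The *quantitative* rates (e.g. a ~2–8%
triplet probability at the reference operating point, against 3% of trials
in vivo) depend on the synthetic stand-ins and should not be read as
predictions for real cells. Headline counts of the original selection
campaign (9180/2241/…/20359 configurations) are not reproducible at desk
scale and are out of scope.

## Known limitations

* One reference morphology/biophysics pair ships with the package; the
  original study's "model consensus" across 68 biophysical parameter sets ×
  3 morphologies × 9 network embeddings is emulated only by re-seeding the
  placement sampling.
* The burst-generating regime is a genuine coincidence-detection regime and
  therefore sensitive: changing synaptic peak conductances by tens of
  percent moves the operating point out of the banded region (this mirrors
  the original campaign, where only ~3% of configurations passed all bands).
* The NMDA:AMPA ratio of TC synapses (1.6) partially substitutes for the
  sustained apical priming that a full network model would provide; pushing
  it much higher makes bursts NMDA-dependent rather than Ca²⁺-channel-
  dependent and erodes the passive-apical contrast.
* Backward Euler is first-order: spike times drift by ~0.2 ms per dt-halving
  on long stimuli. Use θ=0.5 when spike-time accuracy below 0.1 ms matters.
* The reference fixture fires no spontaneous APs: its sparse independent-
  Poisson background leaves the soma ~15 mV below threshold at every
  inhibition scale, and the only global change that produces spontaneous
  firing (×3 ongoing rates) saturates the evoked response with 3-AP bursts.
  The in-vivo-like state — 0–11 Hz spontaneous firing coexisting with
  banded evoked responses — requires the balanced high-conductance
  background of a dense network model. Consequently the staged campaign,
  run faithfully on this fixture, rejects every configuration at the
  ongoing stage (rate > 0 Hz required) and accepts none; the corresponding
  end-to-end test is deliberately left failing rather than weakened, and
  the campaign machinery itself (bands, stage logic, selection
  monotonicity, reproducibility) is verified independently.
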