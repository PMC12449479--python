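import numpy as np
import pytest

from tccoupling.activity import (InputGridPoint, TrialLayout, TrialInputs,
                                 build_trial_inputs)
from tccoupling.connectome import SynapsePlacement
from tccoupling.errors import ConfigError
from tccoupling.manipulations import (ManipulationSpec, apply_manipulation,
                                      cell_transform, paired_replay)


def toy_inputs(t_onset=50.0):
    ongoing = {0: np.array([5.0, 20.0, 42.0]), 1: np.array([10.0]),
               2: np.array([33.0, 48.0]), 3: np.array([15.0])}
    evoked = {0: np.array([55.0, 58.0]), 2: np.array([56.0]),
              3: np.array([57.0, 60.0])}
    return TrialInputs(ongoing, evoked, 120.0, stimulus_onset_ms=45.0,
                       t_onset=t_onset, meta={"trial": 0})


def toy_placements():
    return [
        SynapsePlacement(0, (1, 0.5), "VPM", 3, 120.0),
        SynapsePlacement(1, (2, 0.5), "INH", 1, 80.0),
        SynapsePlacement(2, (3, 0.5), "L6CC", 7, 150.0),
        SynapsePlacement(3, (4, 0.5), "L4SP", 9, 400.0),
    ]


class TestDeprivations:
    def test_joint_tc_and_indirect_removes_all_evoked(self):
        inputs, pl = toy_inputs(), toy_placements()
        step1 = apply_manipulation(inputs, pl, ManipulationSpec("deprive_indirect"), 0)
        step2 = apply_manipulation(step1, pl, ManipulationSpec("deprive_direct_tc"), 0)
        n_evoked = sum(len(v) for v in step2.evoked.values())
        assert n_evoked == 0
        # ongoing retained untouched
        for sid, t in inputs.ongoing.items():
            assert np.array_equal(step2.ongoing[sid], t)

    def test_type_deprivation_targets_one_population(self):
        inputs, pl = toy_inputs(), toy_placements()
        out = apply_manipulation(inputs, pl,
                                 ManipulationSpec("deprive_type",
                                                  target_population="L6CC"), 0)
        assert 2 not in out.evoked
        assert np.array_equal(out.evoked[0], inputs.evoked[0])
        assert np.array_equal(out.evoked[3], inputs.evoked[3])

    def test_idempotence(self):
        inputs, pl = toy_inputs(), toy_placements()
        spec = ManipulationSpec("deprive_direct_tc")
        once = apply_manipulation(inputs, pl, spec, 0)
        twice = apply_manipulation(once, pl, spec, 0)
        assert set(once.evoked) == set(twice.evoked)
        for sid in once.evoked:
            assert np.array_equal(once.evoked[sid], twice.evoked[sid])

    def test_containment(self):
        inputs, pl = toy_inputs(), toy_placements()
        for kind in ("deprive_indirect", "deprive_direct_tc", "deprive_tc_and_l6cc"):
            out = apply_manipulation(inputs, pl, ManipulationSpec(kind), 0)
            for sid, t in out.evoked.items():
                assert set(t) <= set(inputs.evoked[sid])
            for sid, t in out.ongoing.items():
                assert np.array_equal(t, inputs.ongoing[sid])


class TestSampledRemovals:
    def test_distance_bin_clamps_to_availability(self):
        inputs, pl = toy_inputs(), toy_placements()
        spec = ManipulationSpec("tc_distance_bin", distance_interval=(0.0, 200.0),
                                n_remove=50)
        out = apply_manipulation(inputs, pl, spec, seed=1)
        # only synapse 0 (VPM at 120 um) is eligible; both activations removed
        assert 0 not in out.evoked
        assert 2 in out.evoked and 3 in out.evoked

    def test_distance_bin_outside_morphology_is_noop(self):
        inputs, pl = toy_inputs(), toy_placements()
        spec = ManipulationSpec("tc_distance_bin",
                                distance_interval=(900.0, 1100.0))
        out = apply_manipulation(inputs, pl, spec, seed=1)
        assert np.array_equal(out.evoked[0], inputs.evoked[0])

    def test_prestim_window_removes_only_cortical_in_window(self):
        inputs, pl = toy_inputs(t_onset=50.0), toy_placements()
        spec = ManipulationSpec("prestim_window_removal", target_domain="basal",
                                n_remove=50, window_ms=20.0)
        out = apply_manipulation(inputs, pl, spec, seed=1)
        # window [30, 50): cortical synapses 2 (33, 48 ongoing) eligible;
        # VPM synapse 0 (42) is not cortical; INH never eligible
        assert np.array_equal(out.ongoing[0], inputs.ongoing[0])
        assert np.array_equal(out.ongoing[1], inputs.ongoing[1])
        assert 2 not in out.ongoing or len(out.ongoing[2]) == 0

    def test_removal_deterministic_given_seed(self):
        inputs, pl = toy_inputs(), toy_placements()
        spec = ManipulationSpec("tc_distance_bin", distance_interval=(0.0, 200.0),
                                n_remove=1)
        a = apply_manipulation(inputs, pl, spec, seed=5)
        b = apply_manipulation(inputs, pl, spec, seed=5)
        assert np.array_equal(a.evoked[0], b.evoked[0])


class TestScaleAndCellKinds:
    def test_identity_scale_returns_equal_inputs(self):
        inputs, pl = toy_inputs(), toy_placements()
        out = apply_manipulation(inputs, pl,
                                 ManipulationSpec("ongoing_scale",
                                                  scale_factor=1.0), 0)
        assert out.activations.keys() == inputs.activations.keys()
        for sid, t in inputs.activations.items():
            assert np.array_equal(out.activations[sid], t)

    def test_ongoing_scale_regenerates_under_paired_stream(self, embedded_reference):
        cell, pops = embedded_reference
        layout = TrialLayout(ongoing_ms=150.0, evoked_ms=50.0)
        inputs = build_trial_inputs(cell.synapses, pops, InputGridPoint(),
                                    layout, seed=3, trial=1)
        out = apply_manipulation(inputs, cell.synapses,
                                 ManipulationSpec("ongoing_scale",
                                                  scale_factor=2.0),
                                 seed=3, populations=pops)
        n_on_ctl = sum(len(v) for v in inputs.ongoing.values()
                       if True)
        # only EXC ongoing scales; INH ongoing unchanged stream-for-stream
        inh_ids = {p.synapse_id for p in cell.synapses if p.population == "INH"}
        for sid in inh_ids:
            a = inputs.ongoing.get(sid)
            b = out.ongoing.get(sid)
            if a is None:
                assert b is None
            else:
                assert np.array_equal(a, b)
        exc_ctl = sum(len(v) for s, v in inputs.ongoing.items()
                      if s not in inh_ids)
        exc_man = sum(len(v) for s, v in out.ongoing.items()
                      if s not in inh_ids)
        assert exc_man > 1.5 * exc_ctl

    def test_plasticity_scales_tc_weight(self, embedded_reference):
        cell, _ = embedded_reference
        out = cell_transform(cell, ManipulationSpec("tc_plasticity"))
        assert out.synapse_weight["VPM"] == pytest.approx(2.5)
        assert cell.synapse_weight.get("VPM") is None

    def test_passive_apical_zeroes_only_apical_gated_conductances(self, embedded_reference):
        cell, _ = embedded_reference
        out = cell_transform(cell, ManipulationSpec("passive_apical"))
        m = cell.morphology
        trunk = m.in_domains("trunk")[0]
        basal = m.in_domains("basal")[0]
        mid_t = 0.5 * (trunk.proximal_distance + trunk.path_distance_to_soma)
        mid_b = 0.5 * (basal.proximal_distance + basal.path_distance_to_soma)
        assert out.density_at("na_t", trunk.id, mid_t) == 0.0
        assert out.density_at("na_t", basal.id, mid_b) == \
            cell.density_at("na_t", basal.id, mid_b)
        # leak untouched
        assert out.g_leak[trunk.id] == cell.g_leak[trunk.id]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            ManipulationSpec("deprive_everything")


class TestPairedReplay:
    def test_identity_pair_is_bit_identical(self, embedded_reference):
        from tccoupling.simulator import SimConfig, default_probes

        cell, pops = embedded_reference
        layout = TrialLayout(ongoing_ms=100.0, evoked_ms=40.0)
        inputs = build_trial_inputs(cell.synapses, pops, InputGridPoint(),
                                    layout, seed=2, trial=0)
        cfg = SimConfig(probe_sites=default_probes(cell.morphology))
        pair = paired_replay(cell, inputs,
                             ManipulationSpec("ongoing_scale", scale_factor=1.0),
                             cfg, seed=2, populations=pops)
        for label in pair.control.vm_traces:
            assert np.array_equal(pair.control.vm_traces[label],
                                  pair.manipulated.vm_traces[label])

    def test_deprive_tc_keeps_ongoing_tc_and_other_populations(self,
                                                               embedded_reference):
        from tccoupling.simulator import SimConfig, default_probes

        cell, pops = embedded_reference
        layout = TrialLayout(ongoing_ms=100.0, evoked_ms=40.0)
        inputs = build_trial_inputs(cell.synapses, pops, InputGridPoint(),
                                    layout, seed=4, trial=0)
        cfg = SimConfig(probe_sites=default_probes(cell.morphology))
        pair = paired_replay(cell, inputs, ManipulationSpec("deprive_direct_tc"),
                             cfg, seed=4, populations=pops)
        man = pair.manipulated_inputs
        tc_ids = {p.synapse_id for p in cell.synapses if p.population == "VPM"}
        assert all(sid not in man.evoked for sid in tc_ids)
        for sid, t in inputs.ongoing.items():
            assert np.array_equal(man.ongoing[sid], t)
        for sid, t in inputs.evoked.items():
            if sid not in tc_ids:
                assert np.array_equal(man.evoked[sid], t)
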