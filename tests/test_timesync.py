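import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndi import fixtures, timesync
from ndi.errors import NoTimeMappingError
from ndi.timesync import (
    ClockType, SyncGraph, TimeMapping, TimeReference,
    build_syncgraph, convert_time, estimate_mapping_shared_triggers,
    readtimeseries,
)

from conftest import make_paired_session

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)
scales = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestTimeMapping:
    @settings(derandomize=True, max_examples=200)
    @given(scales, finite, finite)
    def test_inverse_roundtrip(self, scale, shift, t):
        m = TimeMapping(scale, shift)
        assert m.inverse().apply(m.apply(t)) == pytest.approx(t, abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(scales, finite, scales, finite, finite)
    def test_composition_associates_with_application(self, s1, b1, s2, b2, t):
        m1, m2 = TimeMapping(s1, b1), TimeMapping(s2, b2)
        assert m1.then(m2).apply(t) == pytest.approx(
            m2.apply(m1.apply(t)), rel=1e-9, abs=1e-6
        )

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            TimeMapping(0.0, 1.0)


class TestTriggerRegression:
    def test_exact_affine_data(self):
        est = estimate_mapping_shared_triggers([1, 2, 3], [1.5, 2.5, 3.5], 1e-6)
        m, rms = est
        assert m.scale == pytest.approx(1.0)
        assert m.shift == pytest.approx(0.5)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_drift_and_offset(self):
        rng = np.random.default_rng(4)
        ta = fixtures.make_trigger_train(rng, 50, 60.0)
        tb = 1.0001 * ta + 0.5 + rng.normal(0, 1e-4, 50)
        m, _ = estimate_mapping_shared_triggers(ta, tb, 1e-3)
        assert abs(m.scale - 1.0001) < 1e-5
        assert abs(m.shift - 0.5) < 1e-3

    def test_abstains_on_unrelated_trains(self):
        rng = np.random.default_rng(5)
        a = np.sort(rng.uniform(0, 60, 50))
        b = np.sort(rng.uniform(0, 60, 50))
        assert estimate_mapping_shared_triggers(a, b, 1e-3) is None

    def test_abstains_below_two_triggers(self):
        assert estimate_mapping_shared_triggers([1.0], [1.5, 2.5], 1e-3) is None

    def test_aligns_unequal_counts_by_intervals(self):
        rng = np.random.default_rng(6)
        ta = fixtures.make_trigger_train(rng, 40, 60.0)
        tb = 1.0002 * ta + 0.3
        m, rms = estimate_mapping_shared_triggers(ta[5:], tb, 1e-3)
        assert m.scale == pytest.approx(1.0002, abs=1e-6)
        assert m.shift == pytest.approx(0.3, abs=1e-6)


class TestGraphPaths:
    def _triangle(self):
        g = SyncGraph()
        for node in ("A", "B", "C"):
            g.add_node(f"daq:{node}", "e1", ClockType.DEV_LOCAL_TIME)
        ab = TimeMapping(1.0, 5.0)
        bc = TimeMapping(2.0, 0.0)
        g.add_edge(("daq:A", "e1", "dev_local_time"),
                   ("daq:B", "e1", "dev_local_time"), ab, "syncrule")
        g.add_edge(("daq:B", "e1", "dev_local_time"),
                   ("daq:C", "e1", "dev_local_time"), bc, "syncrule")
        return g

    def test_identity_when_source_is_target(self):
        g = self._triangle()
        ref = TimeReference("daq:A", ClockType.DEV_LOCAL_TIME, "e1")
        t, _ = convert_time(g, 10.0, ref, "daq:A", ClockType.DEV_LOCAL_TIME)
        assert t == 10.0

    def test_two_edge_composition(self):
        g = self._triangle()
        ref = TimeReference("daq:A", ClockType.DEV_LOCAL_TIME, "e1")
        t, _ = convert_time(g, 10.0, ref, "daq:C", ClockType.DEV_LOCAL_TIME)
        assert t == pytest.approx(2 * (10 + 5))

    def test_offset_is_subtracted_before_mapping(self):
        g = self._triangle()
        ref = TimeReference("daq:A", ClockType.DEV_LOCAL_TIME, "e1", offset=2.0)
        t, _ = convert_time(g, 12.0, ref, "daq:B", ClockType.DEV_LOCAL_TIME)
        assert t == pytest.approx(15.0)

    def test_roundtrip_error_below_nanosecond(self):
        g = self._triangle()
        rng = np.random.default_rng(0)
        times = rng.uniform(-1e3, 1e3, 1000)
        ref_a = TimeReference("daq:A", ClockType.DEV_LOCAL_TIME, "e1")
        out, ref_c = convert_time(g, times, ref_a, "daq:C",
                                  ClockType.DEV_LOCAL_TIME)
        back, _ = convert_time(g, out, ref_c, "daq:A",
                               ClockType.DEV_LOCAL_TIME)
        assert np.max(np.abs(back - times)) < 1e-9

    def test_no_path_raises_with_endpoints(self):
        g = self._triangle()
        g.add_node("daq:D", "e1", ClockType.DEV_LOCAL_TIME)
        ref = TimeReference("daq:A", ClockType.DEV_LOCAL_TIME, "e1")
        with pytest.raises(NoTimeMappingError, match="daq:D"):
            convert_time(g, 0.0, ref, "daq:D", ClockType.DEV_LOCAL_TIME)

    def test_no_time_nodes_are_excluded(self):
        g = SyncGraph()
        g.add_node("daq:X", "e1", ClockType.NO_TIME)
        assert g.nodes() == []


class TestSessionGraph:
    def test_local_clocks_link_only_simultaneous_epochs(self, tmp_path):
        """Two local-clock DAQs with a shared-trigger rule: conversion works
        within each simultaneous epoch pair and fails across pairs."""
        s, gt = make_paired_session(tmp_path / "s", n_epochs=3, seed=3)
        graph = build_syncgraph(s)
        ea = s.epochs("elec_mfdaq")
        eb = s.epochs("vis_stim_daq")
        for i in range(3):
            ref = TimeReference("daq:elec_mfdaq", ClockType.DEV_LOCAL_TIME,
                                ea[i].epoch_id)
            t, ref_out = convert_time(graph, 10.0, ref, "daq:vis_stim_daq",
                                      ClockType.DEV_LOCAL_TIME)
            m = gt["epochs"][i]["mapping"]
            assert ref_out.epoch_id == eb[i].epoch_id
            assert t == pytest.approx(m["scale"] * 10 + m["shift"], abs=2e-3)
        # non-simultaneous pair: the only reachable stim epoch is the paired one
        reach = {
            n[1]
            for n in graph._bfs(("daq:elec_mfdaq", ea[0].epoch_id,
                                 "dev_local_time"))[0]
            if n[0] == "daq:vis_stim_daq"
        }
        assert reach == {eb[0].epoch_id}
        # and same-device epochs are mutually unreachable (local clocks only)
        reach_self = {
            n[1]
            for n in graph._bfs(("daq:elec_mfdaq", ea[0].epoch_id,
                                 "dev_local_time"))[0]
            if n[0] == "daq:elec_mfdaq"
        }
        assert reach_self == {ea[0].epoch_id}

    def test_utc_keeper_connects_everything(self, tmp_path):
        """When the stimulus DAQ also keeps UTC, every epoch pair converts."""
        stim = fixtures.ToyStimEpochSpec(utc_anchor=1.6e9)
        s, _ = make_paired_session(tmp_path / "s", n_epochs=3, seed=4,
                                   stim=stim)
        graph = build_syncgraph(s)
        ea = s.epochs("elec_mfdaq")
        eb = s.epochs("vis_stim_daq")
        for i in range(3):
            src = ("daq:elec_mfdaq", ea[i].epoch_id, "dev_local_time")
            reach = {n[1] for n in graph._bfs(src)[0]
                     if n[0] == "daq:vis_stim_daq" and n[2] == "dev_local_time"}
            assert reach == {e.epoch_id for e in eb}

    def test_single_daq_no_rules_only_self_edges(self, flat_session):
        s, _ = flat_session
        graph = build_syncgraph(s)
        assert graph.g.number_of_edges() == 0
        assert len(graph.nodes()) == 3

    def test_path_independence_two_consistent_routes(self, tmp_path):
        """A->C direct and A->B->C composed agree within 10x fit residual."""
        rng = np.random.default_rng(8)
        ta = fixtures.make_trigger_train(rng, 50, 60.0)
        mab = TimeMapping(1.0001, 0.5)
        mbc = TimeMapping(0.9999, -2.0)
        tb = mab.apply(ta) + rng.normal(0, 1e-4, 50)
        tc = mbc.apply(mab.apply(ta)) + rng.normal(0, 1e-4, 50)
        eab, rab = estimate_mapping_shared_triggers(ta, tb, 1e-3)
        ebc, rbc = estimate_mapping_shared_triggers(tb, tc, 1e-3)
        eac, rac = estimate_mapping_shared_triggers(ta, tc, 1e-3)
        resid = max(rab, rbc, rac)
        t = np.linspace(0, 60, 101)
        direct = eac.apply(t)
        composed = eab.then(ebc).apply(t)
        assert np.max(np.abs(direct - composed)) < 10 * resid


class TestReadTimeseries:
    def test_cross_device_events_shift_by_clock_offset(self, tmp_path):
        """Stimulus events read in the electrode's reference are shifted by
        the (inverse) ground-truth clock mapping."""
        from ndi.elements import discover_probes

        s, gt = make_paired_session(tmp_path / "s", n_epochs=1, seed=5)
        probes = discover_probes(s)
        stim_probe = next(p for p in probes if p.name == "vis_stim")
        cortex = next(p for p in probes if p.name == "cortex")
        graph = build_syncgraph(s, elements=probes)
        ea = s.epochs("elec_mfdaq")[0]
        ref = TimeReference("element:" + cortex.key,
                            ClockType.DEV_LOCAL_TIME, ea.epoch_id)
        values, times, ref_out = readtimeseries(graph, stim_probe, ref,
                                                0.0, 30.0)
        m = gt["epochs"][0]["mapping"]
        trig_stim = np.sort(gt["epochs"][0]["trigger_times_stim"])
        expected = (trig_stim - m["shift"]) / m["scale"]
        got = np.sort(times)
        assert len(got) == len(expected)
        assert np.max(np.abs(got - expected)) < 2e-3
        assert ref_out == ref

    def test_own_reference_starts_at_epoch_t0(self, flat_session):
        from ndi.elements import discover_probes

        s, _ = flat_session
        cortex = next(p for p in discover_probes(s) if p.name == "cortex")
        graph = build_syncgraph(s, elements=[cortex])
        ep = cortex.epochs[0]
        ref = TimeReference(cortex.item_key, ClockType.DEV_LOCAL_TIME,
                            ep.epoch_id)
        data, times, _ = readtimeseries(graph, cortex, ref, ep.t0, ep.t1)
        assert times[0] == pytest.approx(ep.t0)
        assert data.shape[0] == len(times)
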