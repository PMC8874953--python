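import numpy as np
import pytest

from ndi import apps, fixtures
from ndi.apps import (
    compute_tuning_curve, detect_spikes, filter_isi, fit_double_gaussian,
    orientation_direction_indices,
)

from conftest import detection_errors


class TestDetector:
    def test_planted_spikes_recovered(self):
        spec = fixtures.ToyBinEpochSpec()
        rng = np.random.default_rng(np.random.SeedSequence([21, 0]))
        analog, _, gt = fixtures._render_bin_epoch(rng, spec)
        params = apps.default_extraction_parameters()
        peaks = detect_spikes(analog[:, 0].astype(float), spec.sample_rate,
                              params)
        hits, false = detection_errors(peaks / spec.sample_rate,
                                       gt["spike_times"])
        assert hits == 20 and false == 0

    def test_refractory_keeps_earliest_crossing(self):
        """Two crossings 1 ms apart with a 2 ms refractory yield one spike."""
        rate = 20000.0
        x = np.zeros(2000)
        template = fixtures.spike_template(rate, 10.0)
        for t in (0.020, 0.021):
            i = int(t * rate)
            x[i : i + len(template)] += template
        params = apps.default_extraction_parameters()
        params["filter"] = {"kind": "none"}
        params["threshold"] = {"method": "absolute", "value": 4.0, "sign": 1}
        params["refractory_ms"] = 2.0
        assert len(detect_spikes(x, rate, params)) == 1
        params["refractory_ms"] = 0.5
        assert len(detect_spikes(x, rate, params)) == 2

    def test_negative_sign_detection(self):
        rate = 20000.0
        x = np.zeros(2000)
        template = -fixtures.spike_template(rate, 10.0)
        i = int(0.02 * rate)
        x[i : i + len(template)] += template
        params = apps.default_extraction_parameters()
        params["filter"] = {"kind": "none"}
        params["threshold"] = {"method": "absolute", "value": 4.0, "sign": -1}
        peaks = detect_spikes(x, rate, params)
        assert len(peaks) == 1
        # aligned to the (negative) extremum
        assert x[peaks[0]] == x.min()

    def test_empty_trace_no_spikes(self):
        params = apps.default_extraction_parameters()
        params["filter"] = {"kind": "none"}
        params["threshold"] = {"method": "absolute", "value": 4.0, "sign": 1}
        assert len(detect_spikes(np.zeros(1000), 20000.0, params)) == 0


class TestIsiFilter:
    def test_rule_application(self):
        out = filter_isi([0, 0.05, 0.2, 0.25, 0.4], 0.1)
        assert np.array_equal(out, [0, 0.2, 0.4])

    def test_zero_min_isi_keeps_all(self):
        times = [0.0, 0.001, 0.002]
        assert np.array_equal(filter_isi(times, 0.0), times)

    def test_retained_intervals_all_exceed_threshold(self, tuned_pipeline):
        sw = apps.load_spikewaves(tuned_pipeline["session"],
                                  tuned_pipeline["spikewave_ids"][0])
        kept = filter_isi(sw["times"], 0.1)
        assert len(kept) > 0
        assert np.all(np.diff(kept) >= 0.1)


class TestExtractionPipeline:
    def test_extraction_detects_ground_truth(self, tuned_pipeline):
        sw = apps.load_spikewaves(tuned_pipeline["session"],
                                  tuned_pipeline["spikewave_ids"][0])
        truth = tuned_pipeline["groundtruth"]["epochs"][0]["spike_times"]
        hits, false = detection_errors(sw["times"], truth)
        assert hits / len(truth) > 0.95
        assert false <= 0.02 * len(truth)

    def test_rerun_is_deterministic_except_identity(self, tuned_pipeline):
        s = tuned_pipeline["session"]
        sw_ids2 = apps.extract_spikes(s, tuned_pipeline["cortex"],
                                      tuned_pipeline["params_id"])
        a = apps.load_spikewaves(s, tuned_pipeline["spikewave_ids"][0])
        b = apps.load_spikewaves(s, sw_ids2[0])
        assert sw_ids2[0] != tuned_pipeline["spikewave_ids"][0]
        assert np.array_equal(a["times"], b["times"])
        assert np.array_equal(a["waveforms"], b["waveforms"])

    def test_spikewaves_respect_refractory(self, tuned_pipeline):
        sw = apps.load_spikewaves(tuned_pipeline["session"],
                                  tuned_pipeline["spikewave_ids"][0])
        assert np.all(np.diff(sw["times"]) >= 0.001 - 1e-9)

    def test_waveform_window_size(self, tuned_pipeline):
        sw = apps.load_spikewaves(tuned_pipeline["session"],
                                  tuned_pipeline["spikewave_ids"][0])
        rate = sw["sample_rate"]
        assert sw["waveforms"].shape[1] == round(0.0015 * rate)

    def test_params_doc_precedes_extraction(self, tuned_pipeline):
        s = tuned_pipeline["session"]
        params_doc = s.database.get(tuned_pipeline["params_id"])
        sw_doc = s.database.get(tuned_pipeline["spikewave_ids"][0])
        assert params_doc["timestamp"] <= sw_doc["timestamp"]
        dep_names = {d["name"] for d in sw_doc["depends_on"]}
        assert dep_names == {"element_id", "extraction_parameters_id"}


class TestStimulusResponses:
    def test_untuned_element_has_zero_mean_response(self, tmp_path):
        """With flat tuning equal to the baseline rate, baseline-subtracted
        responses average to zero within 3 standard errors."""
        from ndi import elements, timesync

        from conftest import TRIGGER_RULE, bin_daq, stim_daq
        from ndi.session import create_session

        flat = fixtures.TuningParams(C=8.0, Rp=0.0, Rn=0.0, baseline_rate=8.0)
        dirs = [0.0, 90.0, 180.0, 270.0]
        fixtures.make_tuned_responses(tmp_path / "s", dirs, reps=25,
                                      tuning=flat, seed=17)
        s = create_session("flat-tuning", tmp_path / "s")
        s.add_daq_system(bin_daq(syncrules=[TRIGGER_RULE]))
        s.add_daq_system(stim_daq())
        probes = elements.discover_probes(s)
        cortex = next(p for p in probes if p.name == "cortex")
        stim_probe = next(p for p in probes if p.name == "vis_stim")
        params_id = apps.add_extraction_parameters(s)
        sw_ids = apps.extract_spikes(s, cortex, params_id)
        neuron = apps.make_spike_times_element(s, cortex, sw_ids)
        graph = timesync.build_syncgraph(s, elements=probes + [neuron])
        stim_ids = apps.ingest_stimulus_presentations(s, stim_probe)
        resp_id = apps.stimulus_responses(s, neuron, stim_ids[0], graph)
        responses = [r["response"] for r in
                     s.database.get(resp_id)["body"]["responses"]]
        n = len(responses)
        se = np.sqrt(2 * 8.0 / 1.0) / np.sqrt(n)  # var of rate difference
        assert abs(np.mean(responses)) <= 3 * se

    def test_sync_mapping_changes_responses(self, tuned_pipeline):
        """Responses computed with the sync mapping peak at the generative
        preferred direction; ignoring the clock offset misaligns windows."""
        s = tuned_pipeline["session"]
        gt = tuned_pipeline["groundtruth"]
        doc = s.database.get(tuned_pipeline["response_id"])
        responses = doc["body"]["responses"]
        dirs, mean, _, _ = compute_tuning_curve(
            [r["params"]["angle"] for r in responses],
            [r["response"] for r in responses],
        )
        best = dirs[int(np.argmax(mean))]
        assert abs(fixtures.angdiff(best - gt["tuning"]["theta_pref"])) <= 30
        # recompute rates ignoring the mapping: windows land partly in gaps
        ep = gt["epochs"][0]
        spikes = np.array(ep["spike_times"])
        m = ep["mapping"]
        naive = []
        for pres in s.database.get(
                tuned_pipeline["stim_ids"][0])["body"]["presentations"]:
            onset, offset = pres["onset"], pres["offset"]  # stim clock, unmapped
            naive.append(np.sum((spikes >= onset) & (spikes < offset))
                         / (offset - onset))
        mapped = [r["rate"] for r in responses]
        assert not np.allclose(naive, mapped)

    def test_zero_duration_presentation_rejected(self, tuned_pipeline):
        from ndi.docdb import new_document

        s = tuned_pipeline["session"]
        stim_doc = s.database.get(tuned_pipeline["stim_ids"][0])
        body = dict(stim_doc["body"])
        body["presentations"] = [{"onset": 1.0, "offset": 1.0, "stim_id": 1,
                                  "params": {"angle": 0.0}}]
        bad = new_document("stimulus_presentation", s.id, body,
                           stim_doc["depends_on"])
        bad_id = s.database.add(bad)
        with pytest.raises(ValueError, match="duration"):
            apps.stimulus_responses(s, tuned_pipeline["neuron"], bad_id,
                                    tuned_pipeline["graph"])


class TestTuningMath:
    def test_noiseless_fit_recovers_parameters(self):
        d = np.arange(0, 360, 30.0)
        y = apps.double_gaussian(d, 1.0, 10.0, 5.0, 60.0, 25.0)
        fit = fit_double_gaussian(d, y)
        assert abs(fixtures.angdiff(fit["theta_pref"] - 60.0)) < 1.0
        assert abs(fit["sigma"] - 25.0) / 25.0 < 0.05
        assert fit["Rp"] == pytest.approx(10.0, rel=0.02)

    def test_flat_curve_gives_zero_indices(self):
        d = np.arange(0, 360, 30.0)
        oi, di = orientation_direction_indices(d, np.full(12, 2.5))
        assert (oi, di) == (0.0, 0.0)

    def test_textbook_index_values(self):
        d = np.array([60.0, 150.0, 240.0, 330.0])
        r = np.array([10.0, 0.0, 5.0, 0.0])
        oi, di = orientation_direction_indices(d, r)
        assert di == pytest.approx(0.5)
        assert oi == pytest.approx(1.0)

    def test_all_zero_curve_degenerates_to_constant_model(self):
        d = np.arange(0, 360, 45.0)
        fit = fit_double_gaussian(d, np.zeros(8))
        assert fit["Rp"] == 0.0 and fit["Rn"] == 0.0 and fit["C"] == 0.0
        assert orientation_direction_indices(d, np.zeros(8)) == (0.0, 0.0)

    def test_needs_four_directions(self, tuned_pipeline):
        from ndi.docdb import new_document
        from ndi.errors import NDIError

        s = tuned_pipeline["session"]
        doc = new_document(
            "stimulus_response", s.id,
            {"responses": [
                {"stim_id": 1, "params": {"angle": a}, "onset": 0.0,
                 "offset": 1.0, "rate": 1.0, "baseline": 0.0, "response": 1.0}
                for a in (0.0, 90.0, 180.0)
            ]},
            depends_on=[],
        )
        rid = s.database.add(doc)
        with pytest.raises(NDIError, match="directions"):
            apps.oridir_analysis(s, rid)


class TestEndToEndTuning:
    def test_fit_recovers_generative_preference(self, tuned_pipeline):
        gt = tuned_pipeline["groundtruth"]["tuning"]
        fit = tuned_pipeline["result"]["fit"]
        assert abs(fixtures.angdiff(fit["theta_pref"] - gt["theta_pref"])) <= 10
        oi = tuned_pipeline["result"]["indices"]["oi"]
        di = tuned_pipeline["result"]["indices"]["di"]
        assert oi > 0.5 and 0.2 < di < 0.8

    def test_curve_directions_are_the_stimulus_angles(self, tuned_pipeline):
        dirs, mean, sem, n = tuned_pipeline["result"]["curve"]
        assert list(dirs) == list(range(0, 360, 30))
        assert all(n == 5 for n in n.tolist())
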