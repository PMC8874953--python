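import numpy as np
import pytest

from ndi import apps, elements, fixtures, timesync
from ndi.daq import DaqSystem, FileNavigator
from ndi.session import create_session

TRIGGER_RULE = {
    "kind": "shared_triggers",
    "daq_a": "elec_mfdaq", "channel_a": "di1",
    "daq_b": "vis_stim_daq", "channel_b": "e1",
    "tolerance": 1e-3,
}


def bin_daq(name="elec_mfdaq", kind="epochdir", syncrules=()):
    return DaqSystem(
        name, FileNavigator(kind, [r".*\.toybin$"]), "mfdaq_toybin",
        syncrules=list(syncrules),
    )


def stim_daq(name="vis_stim_daq"):
    return DaqSystem(
        name, FileNavigator("epochdir", [r".*\.toystim$"]), "stim_toystim"
    )


def make_paired_session(path, n_epochs=3, seed=3, stim=None, **kw):
    """Epochdir fixture session + registered electrode and stimulus DAQs."""
    gt = fixtures.make_session_epochdir(path, n_epochs, seed=seed, stim=stim,
                                        **kw)
    s = create_session("paired", path)
    s.add_daq_system(bin_daq(syncrules=[TRIGGER_RULE]))
    s.add_daq_system(stim_daq())
    return s, gt


@pytest.fixture(scope="session")
def flat_session(tmp_path_factory):
    root = tmp_path_factory.mktemp("flat") / "data"
    gt = fixtures.make_session_flat(root, 3, seed=1)
    s = create_session("flat", root)
    s.add_daq_system(bin_daq("toydaq", kind="flat"))
    return s, gt


@pytest.fixture(scope="session")
def paired_session(tmp_path_factory):
    root = tmp_path_factory.mktemp("paired") / "data"
    return make_paired_session(root, n_epochs=3, seed=3)


@pytest.fixture(scope="session")
def tuned_pipeline(tmp_path_factory):
    """Full pipeline run on a direction-tuned session: fixture -> probes ->
    spike extraction -> responses -> tuning documents."""
    root = tmp_path_factory.mktemp("tuned") / "data"
    directions = list(range(0, 360, 30))
    gt = fixtures.make_tuned_responses(root, directions, reps=5, seed=11)
    s = create_session("tuned", root)
    s.add_daq_system(bin_daq(syncrules=[TRIGGER_RULE]))
    s.add_daq_system(stim_daq())
    probes = elements.discover_probes(s)
    cortex = next(p for p in probes if p.name == "cortex")
    stim_probe = next(p for p in probes if p.name == "vis_stim")
    params_id = apps.add_extraction_parameters(s)
    sw_ids = apps.extract_spikes(s, cortex, params_id)
    neuron = apps.make_spike_times_element(s, cortex, sw_ids)
    graph = timesync.build_syncgraph(s, elements=[cortex, stim_probe, neuron])
    stim_ids = apps.ingest_stimulus_presentations(s, stim_probe)
    resp_id = apps.stimulus_responses(s, neuron, stim_ids[0], graph)
    result = apps.oridir_analysis(s, resp_id)
    return {
        "session": s, "groundtruth": gt, "cortex": cortex,
        "stim_probe": stim_probe, "neuron": neuron, "graph": graph,
        "params_id": params_id, "spikewave_ids": sw_ids,
        "stim_ids": stim_ids, "response_id": resp_id, "result": result,
    }


def detection_errors(detected, truth, tol=5e-4):
    """(n_hits, n_false) matching detections to ground-truth times."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if len(detected) == 0:
        return 0, 0
    hits = sum(np.abs(detected - t).min() <= tol for t in truth)
    false = sum(np.abs(truth - t).min() > tol for t in detected)
    return int(hits), int(false)
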