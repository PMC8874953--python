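"""Demonstration analysis apps: spike extraction and direction tuning.

These exercise the full pipeline pattern: parameters are stored as a
document *before* any computation, every result is a document depending on
the documents it was computed from, and any element — raw probe, filtered
copy, or artificial data — goes through the same calls.

Spike extraction: bandpass filter, threshold-crossing detection, refractory
enforcement, waveform window extraction.  Spike times are reported at the
waveform peak (the local extremum within the crossing), the standard
alignment choice.

Tuning analysis: per-direction mean responses (baseline-subtracted firing
rates), orientation/direction selectivity indices, and a double-Gaussian
circular tuning fit

    R(theta) = C + Rp * exp(-angdiff(theta - theta_pref)^2 / (2 sigma^2))
             + Rn * exp(-angdiff(theta - theta_pref - 180)^2 / (2 sigma^2))

fit by nonlinear least squares with a multi-start over preferred-direction
initializations to avoid circular local minima.
"""

from __future__ import annotations

import io

import numpy as np
from scipy import optimize, signal

from .docdb import new_document
from .errors import NDIError
from .fixtures import angdiff
from .query import q_and, q_isa  # noqa: F401  (re-exported convenience)
from .timesync import ClockType, TimeReference, convert_time

SPIKE_APP = {"name": "spike_extractor", "version": "0.1"}
TUNING_APP = {"name": "oridir_tuning", "version": "0.1"}


# ---------------------------------------------------------------------------
# spike extraction


def default_extraction_parameters() -> dict:
    """Spike-band defaults: 300-3000 Hz bandpass, 4 x robust-sd threshold,
    0.5/1.0 ms extraction window, 1 ms refractory, 0.2 ms minimum crossing
    width (suppresses single-sample noise excursions)."""
    return {
        "filter": {"kind": "bandpass", "low": 300.0, "high": 3000.0, "order": 3},
        "threshold": {"method": "std_multiple", "value": 4.0, "sign": 1},
        "window": {"pre_ms": 0.5, "post_ms": 1.0},
        "refractory_ms": 1.0,
        "min_width_ms": 0.2,
    }


def add_extraction_parameters(session, params: dict | None = None,
                              app: dict | None = None) -> str:
    """Store extraction parameters as a document (pipeline step before any
    extraction) and return its id."""
    params = params or default_extraction_parameters()
    window = params["window"]
    if window["pre_ms"] + window["post_ms"] <= 0:
        raise ValueError("extraction window must have positive length")
    if params["refractory_ms"] < 0:
        raise ValueError("refractory period must be >= 0")
    doc = new_document(
        "spike_extraction_parameters", session.id,
        {"app": dict(app or SPIKE_APP), **params},
    )
    return session.database.add(doc)


def bandpass_filter(x: np.ndarray, rate: float, spec: dict) -> np.ndarray:
    """Zero-phase Butterworth bandpass (or passthrough for kind 'none')."""
    if spec.get("kind", "none") == "none":
        return np.asarray(x, dtype=float)
    nyq = rate / 2.0
    low = max(spec["low"] / nyq, 1e-6)
    high = min(spec["high"] / nyq, 0.999)
    sos = signal.butter(spec.get("order", 3), [low, high], btype="bandpass",
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def robust_sd(x: np.ndarray) -> float:
    """Median-absolute-deviation noise estimate (insensitive to spikes)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.6744897501960817)


def detect_spikes(x: np.ndarray, rate: float, params: dict) -> np.ndarray:
    """Peak sample indices of threshold crossings on the filtered trace.

    A crossing is a contiguous suprathreshold run at least ``min_width_ms``
    long; its spike time is the sample of the local extremum.  Crossings
    within the refractory period of the previously kept spike are skipped
    (earliest kept).
    """
    filt = bandpass_filter(x, rate, params["filter"])
    thr_spec = params["threshold"]
    sign = 1 if thr_spec.get("sign", 1) >= 0 else -1
    y = sign * filt
    if thr_spec["method"] == "absolute":
        thr = float(thr_spec["value"])
    elif thr_spec["method"] == "std_multiple":
        thr = float(thr_spec["value"]) * robust_sd(filt)
    else:
        raise ValueError(f"unknown threshold method {thr_spec['method']!r}")
    above = y >= thr
    if not above.any():
        return np.zeros(0, dtype=int)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(y)]])
    min_width = max(1, int(round(params.get("min_width_ms", 0.0) * rate / 1000.0)))
    refractory = params["refractory_ms"] / 1000.0 * rate
    peaks = []
    last = -np.inf
    for s, e in zip(starts, ends):
        if e - s < min_width:
            continue
        peak = s + int(np.argmax(y[s:e]))
        if peak - last < refractory:
            continue
        peaks.append(peak)
        last = peak
    return np.asarray(peaks, dtype=int)


def extract_spikes(session, element, params_doc_id: str) -> list[str]:
    """Run extraction on every epoch of a sampled element.

    Writes one spikewaves document per epoch (times + waveform matrix in the
    blob), each depending on the element document and the parameters
    document.  Returns the document ids in epoch order.
    """
    if element.element_kind != "timeseries":
        raise NDIError("spike extraction needs a sampled timeseries element")
    params_doc = session.database.get(params_doc_id)
    params = {k: v for k, v in params_doc["body"].items() if k != "app"}
    doc_ids = []
    for ep in element.epochs:
        data, times = element.read_local(ep.epoch_id, ep.t0, ep.t1)
        x = np.asarray(data)[:, 0] if np.ndim(data) == 2 else np.asarray(data)
        if len(times) > 1:
            rate = 1.0 / float(times[1] - times[0])
        else:
            rate = 1.0
        peaks = detect_spikes(x, rate, params)
        pre = int(round(params["window"]["pre_ms"] * rate / 1000.0))
        post = int(round(params["window"]["post_ms"] * rate / 1000.0))
        keep = peaks[(peaks - pre >= 0) & (peaks + post <= len(x))]
        waveforms = np.stack(
            [x[p - pre : p + post] for p in keep]
        ) if len(keep) else np.zeros((0, pre + post))
        spike_times = np.asarray(times)[keep] if len(keep) else np.zeros(0)
        buf = io.BytesIO()
        np.savez(buf, times=spike_times, waveforms=waveforms)
        doc = new_document(
            "spikewaves", session.id,
            {
                "app": dict(SPIKE_APP),
                "epoch_id": ep.epoch_id,
                "sample_rate": rate,
                "n_spikes": int(len(keep)),
                "window": dict(params["window"]),
            },
            depends_on=[
                {"name": "element_id", "value": element.document_id},
                {"name": "extraction_parameters_id", "value": params_doc_id},
            ],
        )
        doc_ids.append(session.database.add(doc, blob=buf.getvalue()))
    return doc_ids


def load_spikewaves(session, doc_id: str) -> dict:
    doc = session.database.get(doc_id)
    arrays = np.load(io.BytesIO(session.database.get_blob(doc_id)))
    return {
        "epoch_id": doc["body"]["epoch_id"],
        "times": arrays["times"],
        "waveforms": arrays["waveforms"],
        "sample_rate": doc["body"]["sample_rate"],
    }


def filter_isi(times, min_isi: float) -> np.ndarray:
    """Keep spikes whose interval to the previous *retained* spike is at
    least ``min_isi`` (first spike always retained)."""
    if min_isi < 0:
        raise ValueError("min_isi must be >= 0")
    kept = []
    for t in np.asarray(times, dtype=float):
        if not kept or t - kept[-1] >= min_isi:
            kept.append(t)
    return np.asarray(kept)


def make_spike_times_element(session, probe, spikewave_doc_ids,
                             name: str | None = None, reference: int = 1):
    """Materialize extracted spike times as an event element (the 'neuron'),
    inheriting the probe's epochs and clocks."""
    from .elements import create_derived_element

    epochs_data = {}
    for doc_id in spikewave_doc_ids:
        sw = load_spikewaves(session, doc_id)
        epochs_data[sw["epoch_id"]] = {"times": sw["times"]}
    return create_derived_element(
        session, name or f"{probe.name}-spikes", reference, "spikes",
        underlying=probe, epochs_data=epochs_data, element_kind="events",
    )


# ---------------------------------------------------------------------------
# stimulus responses


def ingest_stimulus_presentations(session, stim_probe) -> list[str]:
    """Store each stimulus epoch's presentations/triggers as a document.

    The document keeps times in the stimulus device's own clock and records
    which DAQ acquired them, so later consumers can convert through the sync
    graph.  Returns one document id per epoch.
    """
    system = session.get_daq(stim_probe.daq_name)
    doc_ids = []
    for ep in stim_probe.epochs:
        entry = system.epoch(session.root, ep.epoch_id)
        from .daq import read_presentations

        data = read_presentations(system, entry)
        doc = new_document(
            "stimulus_presentation", session.id,
            {
                "epoch_id": ep.epoch_id,
                "presentations": data["presentations"],
                "triggers": data["triggers"],
                "daq_name": stim_probe.daq_name,
            },
            depends_on=[
                {"name": "stimulus_element_id", "value": stim_probe.document_id}
            ],
        )
        doc_ids.append(session.database.add(doc))
    return doc_ids


def stimulus_responses(session, element, stim_doc_id: str, graph) -> str:
    """Baseline-subtracted response of an event element to each presentation.

    Presentation intervals (stimulus clock) are converted into the element's
    device-local clock through the sync graph; the response to one
    presentation is the firing rate during [onset, offset) minus the rate
    during the preceding interstimulus interval (blank screen), so ongoing
    activity is normalized to zero.
    """
    stim_doc = session.database.get(stim_doc_id)
    body = stim_doc["body"]
    stim_ref = TimeReference(
        referent=f"daq:{body['daq_name']}",
        clocktype=ClockType.DEV_LOCAL_TIME,
        epoch_id=body["epoch_id"],
    )
    responses = []
    prev_offset_local = None
    for pres in body["presentations"]:
        if pres["offset"] <= pres["onset"]:
            raise ValueError("zero- or negative-duration presentation")
        onset, ref_el = convert_time(
            graph, pres["onset"], stim_ref, element.item_key,
            ClockType.DEV_LOCAL_TIME,
        )
        offset, _ = convert_time(
            graph, pres["offset"], stim_ref, element.item_key,
            ClockType.DEV_LOCAL_TIME,
        )
        ep = element.epoch(ref_el.epoch_id)
        _, spike_times = element.read_local(ref_el.epoch_id, onset, offset)
        rate = len(spike_times) / (offset - onset)
        if prev_offset_local is None:
            base_lo, base_hi = ep.t0, onset
        else:
            base_lo, base_hi = prev_offset_local, onset
        if base_hi - base_lo > 1e-9:
            _, base_spikes = element.read_local(ref_el.epoch_id, base_lo, base_hi)
            baseline = len(base_spikes) / (base_hi - base_lo)
        else:
            baseline = 0.0
        responses.append({
            "stim_id": pres["stim_id"],
            "params": pres["params"],
            "onset": onset,
            "offset": offset,
            "rate": rate,
            "baseline": baseline,
            "response": rate - baseline,
        })
        prev_offset_local = offset
    doc = new_document(
        "stimulus_response", session.id,
        {"responses": responses},
        depends_on=[
            {"name": "element_id", "value": element.document_id},
            {"name": "stimulus_presentation_id", "value": stim_doc_id},
        ],
    )
    return session.database.add(doc)


# ---------------------------------------------------------------------------
# tuning


def compute_tuning_curve(angles, responses):
    """Group responses by direction -> (directions, mean, sem, n)."""
    angles = np.asarray(angles, dtype=float)
    responses = np.asarray(responses, dtype=float)
    directions = np.unique(angles)
    mean, sem, n = [], [], []
    for d in directions:
        vals = responses[angles == d]
        mean.append(float(vals.mean()))
        sem.append(float(vals.std(ddof=1) / np.sqrt(len(vals)))
                   if len(vals) > 1 else 0.0)
        n.append(int(len(vals)))
    return directions, np.array(mean), np.array(sem), np.array(n)


def _nearest_direction(directions, target):
    d = np.asarray(directions, dtype=float)
    return int(np.argmin(np.abs(angdiff(d - target))))


def orientation_direction_indices(directions, means):
    """DI = (R(tp) - R(tp+180)) / R(tp); OI = (R(tp) - mean R(tp+-90)) / R(tp),
    with tp the direction of maximal response and responses rectified at 0.
    An all-zero curve has both indices defined as 0."""
    r = np.maximum(np.asarray(means, dtype=float), 0.0)
    if not np.any(r > 0):
        return 0.0, 0.0
    ip = int(np.argmax(r))
    tp = float(np.asarray(directions, dtype=float)[ip])
    rp = r[ip]
    r_opp = r[_nearest_direction(directions, tp + 180.0)]
    r_orth = 0.5 * (
        r[_nearest_direction(directions, tp + 90.0)]
        + r[_nearest_direction(directions, tp - 90.0)]
    )
    di = float((rp - r_opp) / rp)
    oi = float((rp - r_orth) / rp)
    return oi, di


def double_gaussian(theta, c, rp, rn, theta_pref, sigma):
    d1 = angdiff(np.asarray(theta, dtype=float) - theta_pref)
    d2 = angdiff(np.asarray(theta, dtype=float) - theta_pref - 180.0)
    return (c + rp * np.exp(-(d1**2) / (2 * sigma**2))
            + rn * np.exp(-(d2**2) / (2 * sigma**2)))


def fit_double_gaussian(directions, means) -> dict:
    """Least-squares double-Gaussian fit with a 22.5-degree multi-start grid
    over the preferred direction; sigma bounded to [1, 90] degrees and both
    lobe amplitudes non-negative.  The dominant lobe is reported as Rp (the
    fit is relabeled when needed) and theta_pref normalized to [0, 360)."""
    d = np.asarray(directions, dtype=float)
    y = np.asarray(means, dtype=float)
    if np.allclose(y, 0.0):
        return {"C": 0.0, "Rp": 0.0, "Rn": 0.0, "theta_pref": 0.0,
                "sigma": 45.0, "residual": 0.0}
    span = float(y.max() - y.min())
    best = None
    for theta0 in np.arange(0.0, 360.0, 22.5):
        x0 = [float(y.min()), max(span, 1e-6), max(span / 2, 1e-6),
              theta0, 30.0]
        try:
            res = optimize.least_squares(
                lambda p: double_gaussian(d, *p) - y,
                x0,
                bounds=([-np.inf, 0.0, 0.0, -360.0, 1.0],
                        [np.inf, np.inf, np.inf, 720.0, 90.0]),
            )
        except Exception:  # pragma: no cover - ill-conditioned start
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    c, rp, rn, tp, sigma = best.x
    if rn > rp:
        rp, rn = rn, rp
        tp += 180.0
    tp %= 360.0
    residual = float(np.sqrt(2 * best.cost / len(y)))
    return {"C": float(c), "Rp": float(rp), "Rn": float(rn),
            "theta_pref": float(tp), "sigma": float(sigma),
            "residual": residual}


def oridir_analysis(session, response_doc_id: str) -> dict:
    """Collate a response document into a tuning curve, compute OI/DI and
    the double-Gaussian fit, and store both as dependent documents.

    Returns {"tuning_curve_id", "oridir_id", "curve", "indices", "fit"}.
    """
    doc = session.database.get(response_doc_id)
    responses = doc["body"]["responses"]
    angles = [r["params"]["angle"] for r in responses]
    values = [r["response"] for r in responses]
    if len(set(angles)) < 4:
        raise NDIError("tuning analysis needs at least 4 distinct directions")
    directions, mean, sem, n = compute_tuning_curve(angles, values)
    curve_doc = new_document(
        "tuning_curve", session.id,
        {
            "directions": directions.tolist(),
            "mean": mean.tolist(),
            "sem": sem.tolist(),
            "n": n.tolist(),
        },
        depends_on=[{"name": "stimulus_response_id", "value": response_doc_id}],
    )
    curve_id = session.database.add(curve_doc)
    oi, di = orientation_direction_indices(directions, mean)
    fit = fit_double_gaussian(directions, mean)
    oridir_doc = new_document(
        "oridir_tuning", session.id,
        {
            "app": dict(TUNING_APP),
            "oi": oi,
            "di": di,
            "fit": {k: v for k, v in fit.items() if k != "residual"},
            "fit_residual": fit["residual"],
        },
        depends_on=[{"name": "tuning_curve_id", "value": curve_id}],
    )
    oridir_id = session.database.add(oridir_doc)
    return {
        "tuning_curve_id": curve_id,
        "oridir_id": oridir_id,
        "curve": (directions, mean, sem, n),
        "indices": {"oi": oi, "di": di},
        "fit": fit,
    }
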