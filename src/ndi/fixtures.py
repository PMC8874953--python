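"""Synthetic on-disk sessions with known ground truth.

Generates sessions in the two toy acquisition formats so that navigation,
reading, synchronization, spike extraction, and tuning analysis are all
testable without any external data:

* ``make_session_flat`` — one ``.toybin`` file per epoch in a flat directory
  (an electrode channel with embedded spikes, a sine test channel, and a
  digital trigger channel);
* ``make_session_epochdir`` — one subdirectory per epoch holding a
  ``.toybin`` file and a ``.toystim`` file whose clocks disagree by a known
  offset and drift, tied together by a shared digital trigger train;
* ``make_tuned_responses`` — an epochdir session whose stimulus file cycles
  grating directions and whose electrode channel carries an
  inhomogeneous-Poisson spike train rated by a double-Gaussian direction
  tuning law.

Every generator is seedable (identical seeds give identical bytes) and
writes a ``groundtruth.json`` sidecar recording embedded spike times,
trigger trains, the true clock mapping per epoch, and tuning parameters.
The sidecar is for tests only — the library under test never reads it.

All times are seconds and all angles degrees.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import toyformats
from .daq import write_probemap

GROUNDTRUTH_FILE = "groundtruth.json"


@dataclass
class ToyBinEpochSpec:
    """Recipe for one sampled-data epoch.

    Channel ai1 carries Gaussian noise (sd ``noise_sd``) with ``n_spikes``
    embedded biphasic spike templates of peak amplitude
    ``spike_amplitude * noise_sd``; ai2 (when present) carries a clean sine;
    di1 carries the trigger pulse train.
    """

    duration: float = 0.5
    sample_rate: float = 20000.0
    n_analog: int = 2
    n_digital: int = 1
    t0: float = 0.0
    noise_sd: float = 1.0
    n_spikes: int = 20
    spike_amplitude: float = 5.0
    min_spike_gap: float = 0.0075
    sine_freq: float = 7.0
    sine_amp: float = 0.5
    n_triggers: int = 10
    trigger_width: int = 5


@dataclass
class ToyStimEpochSpec:
    """Recipe for the stimulus device paired with a toybin epoch.

    The stimulus clock relates to the electrode clock by
    ``t_stim = (1 + clock_drift) * t_bin + clock_offset`` and the shared
    triggers it reports are jittered by ``jitter_sd`` seconds.
    ``utc_anchor``, when set, marks the device as also keeping UTC (UTC of
    stimulus-clock zero).
    """

    clock_offset: float = 0.5
    clock_drift: float = 1e-4
    jitter_sd: float = 1e-4
    utc_anchor: float | None = None
    n_presentations: int = 6
    stim_duration: float = 1.0
    interstimulus: float = 1.0


@dataclass
class TuningParams:
    """Double-Gaussian direction tuning law (rates in Hz, angles degrees)."""

    C: float = 5.0
    Rp: float = 30.0
    Rn: float = 15.0
    theta_pref: float = 60.0
    sigma: float = 30.0
    baseline_rate: float = 5.0


# ---------------------------------------------------------------------------
# primitives


def angdiff(delta):
    """Circular difference wrapped to [-180, 180) degrees."""
    return (np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0


def double_gaussian_rate(theta, p: TuningParams):
    """Firing rate (Hz) at direction ``theta`` under the tuning law:
    two Gaussian lobes 180 degrees apart over a constant offset."""
    d1 = angdiff(np.asarray(theta, dtype=float) - p.theta_pref)
    d2 = angdiff(np.asarray(theta, dtype=float) - p.theta_pref - 180.0)
    return (
        p.C
        + p.Rp * np.exp(-(d1**2) / (2 * p.sigma**2))
        + p.Rn * np.exp(-(d2**2) / (2 * p.sigma**2))
    )


def spike_template(sample_rate: float, amplitude: float) -> np.ndarray:
    """Biphasic extracellular spike template, 1.5 ms long.

    A 0.6 ms positive lobe (peak = ``amplitude``) followed by a 0.9 ms
    negative lobe at 40% of the peak; threshold-detectable by construction.
    """
    n_pos = max(3, int(round(0.0006 * sample_rate)))
    n_neg = max(3, int(round(0.0009 * sample_rate)))
    pos = np.sin(np.linspace(0.0, np.pi, n_pos, endpoint=False))
    neg = -0.4 * np.sin(np.linspace(0.0, np.pi, n_neg, endpoint=False))
    return amplitude * np.concatenate([pos, neg])


def make_trigger_train(rng, n: int, duration: float, margin: float = 1.0):
    """Roughly regular trigger times with +-20% spacing jitter, sorted."""
    if n <= 0:
        return np.zeros(0)
    base = np.linspace(margin, max(margin, duration - margin), n)
    spacing = (duration - 2 * margin) / max(1, n - 1)
    times = base + rng.uniform(-0.2, 0.2, size=n) * spacing
    return np.sort(np.clip(times, 0.0, max(0.0, duration - 1e-3)))


def place_spike_times(rng, duration: float, n: int, min_gap: float,
                      margin: float = 0.01) -> np.ndarray:
    """Draw ``n`` spike times uniformly with a minimum separation."""
    lo, hi = margin, duration - margin
    times: list[float] = []
    attempts = 0
    while len(times) < n and attempts < 100000:
        t = rng.uniform(lo, hi)
        if all(abs(t - u) >= min_gap for u in times):
            times.append(t)
        attempts += 1
    if len(times) < n:
        raise ValueError("could not place spikes with requested separation")
    return np.sort(np.array(times))


def _thin_to_min_gap(times: np.ndarray, min_gap: float) -> np.ndarray:
    kept: list[float] = []
    for t in np.sort(times):
        if not kept or t - kept[-1] >= min_gap:
            kept.append(t)
    return np.array(kept)


def embed_spikes(trace: np.ndarray, spike_times, template: np.ndarray,
                 sample_rate: float, t0: float = 0.0):
    """Add the template at each spike start time; returns the (snapped)
    ground-truth peak times."""
    peak_off = int(np.argmax(template))
    peaks = []
    for t in spike_times:
        i = int(round((t - t0) * sample_rate))
        if i < 0 or i + len(template) > len(trace):
            continue
        trace[i : i + len(template)] += template
        peaks.append(t0 + (i + peak_off) / sample_rate)
    return np.array(peaks)


def embed_triggers(bits: np.ndarray, trigger_times, sample_rate: float,
                   t0: float = 0.0, width: int = 5):
    """Set pulse windows in a digital channel; returns snapped edge times."""
    snapped = []
    for t in trigger_times:
        i = int(round((t - t0) * sample_rate))
        if i <= 0 or i + width >= len(bits):
            continue
        bits[i : i + width] = 1
        snapped.append(t0 + i / sample_rate)
    return np.array(snapped)


# ---------------------------------------------------------------------------
# epoch rendering


def _render_bin_epoch(rng, spec: ToyBinEpochSpec, spike_times=None,
                      trigger_times=None):
    n = int(round(spec.duration * spec.sample_rate))
    analog = np.zeros((n, spec.n_analog), dtype=np.float32)
    digital = np.zeros((n, spec.n_digital), dtype=np.uint8)
    gt: dict = {}
    if spec.n_analog >= 1:
        trace = rng.normal(0.0, spec.noise_sd, size=n)
        if spike_times is None:
            spike_times = place_spike_times(
                rng, spec.duration, spec.n_spikes, spec.min_spike_gap
            )
        template = spike_template(
            spec.sample_rate, spec.spike_amplitude * spec.noise_sd
        )
        gt["spike_times"] = embed_spikes(
            trace, spike_times, template, spec.sample_rate, spec.t0
        ).tolist()
        analog[:, 0] = trace.astype(np.float32)
    for ch in range(1, spec.n_analog):
        t = spec.t0 + np.arange(n) / spec.sample_rate
        analog[:, ch] = (
            spec.sine_amp * np.sin(2 * np.pi * spec.sine_freq * t)
        ).astype(np.float32)
    if spec.n_digital >= 1:
        if trigger_times is None:
            trigger_times = make_trigger_train(
                rng, spec.n_triggers, spec.duration,
                margin=min(0.05, spec.duration / 10),
            )
        gt["trigger_times"] = embed_triggers(
            digital[:, 0], trigger_times, spec.sample_rate, spec.t0,
            spec.trigger_width,
        ).tolist()
    return analog, digital, gt


def _prepare_target(path) -> Path:
    target = Path(path)
    target.mkdir(parents=True, exist_ok=True)
    if any(target.iterdir()):
        raise FileExistsError(f"target directory {target} is not empty")
    return target


def _write_groundtruth(target: Path, gt: dict) -> None:
    (target / GROUNDTRUTH_FILE).write_text(json.dumps(gt, indent=1, sort_keys=True))


def load_groundtruth(path) -> dict:
    return json.loads((Path(path) / GROUNDTRUTH_FILE).read_text())


def _probemap_rows(daq_name: str, subject: str, n_analog: int):
    rows = [
        {"name": "cortex", "reference": 1, "type": "n-trode",
         "devicestring": f"{daq_name}:ai1", "subject": subject}
    ]
    if n_analog >= 2:
        rows.append(
            {"name": "testsignal", "reference": 1, "type": "sharp-Vm",
             "devicestring": f"{daq_name}:ai2", "subject": subject}
        )
    return rows


# ---------------------------------------------------------------------------
# session generators


def make_session_flat(path, n_epochs: int, spec: ToyBinEpochSpec | None = None,
                      seed: int = 0, daq_name: str = "toydaq",
                      subject: str = "ferret01") -> dict:
    """Flat layout: ``e####.toybin`` files in one directory, one per epoch.

    Filenames sort in epoch order.  Returns (and writes) the ground truth.
    """
    spec = spec or ToyBinEpochSpec()
    target = _prepare_target(path)
    seeds = np.random.SeedSequence(seed).spawn(max(n_epochs, 1))
    gt = {"seed": seed, "layout": "flat", "daq": daq_name, "epochs": []}
    for e in range(n_epochs):
        rng = np.random.default_rng(seeds[e])
        analog, digital, egt = _render_bin_epoch(rng, spec)
        fname = f"e{e + 1:04d}.toybin"
        toyformats.write_toybin(
            target / fname, analog, digital, spec.sample_rate, spec.t0
        )
        write_probemap(
            target / (fname + ".epochprobemap.tsv"),
            _probemap_rows(daq_name, subject, spec.n_analog),
        )
        egt["files"] = [fname]
        gt["epochs"].append(egt)
    _write_groundtruth(target, gt)
    return gt


def make_session_epochdir(path, n_epochs: int,
                          spec: ToyBinEpochSpec | None = None,
                          stim: ToyStimEpochSpec | None = None,
                          seed: int = 0,
                          daq_bin: str = "elec_mfdaq",
                          daq_stim: str = "vis_stim_daq",
                          subject: str = "ferret01",
                          drop_stim_in=()) -> dict:
    """Epoch-per-subdirectory layout with paired ``.toybin``/``.toystim``.

    The shared trigger train appears in the toybin digital channel
    (electrode clock) and in the toystim trigger list (stimulus clock),
    related by ``(scale, shift) = (1 + drift, offset)``.  Epochs listed in
    ``drop_stim_in`` (1-based) are written without their ``.toystim`` file to
    exercise the epoch-validity rule.
    """
    spec = spec or ToyBinEpochSpec(
        duration=30.0, sample_rate=5000.0, n_analog=1, n_spikes=40,
        n_triggers=30,
    )
    stim = stim or ToyStimEpochSpec()
    target = _prepare_target(path)
    seeds = np.random.SeedSequence(seed).spawn(max(n_epochs, 1))
    scale = 1.0 + stim.clock_drift
    gt = {
        "seed": seed, "layout": "epochdir",
        "daq_bin": daq_bin, "daq_stim": daq_stim, "epochs": [],
    }
    directions = [0.0, 45.0, 90.0, 135.0, 180.0, 225.0]
    for e in range(n_epochs):
        rng = np.random.default_rng(seeds[e])
        sub = target / f"t{e + 1:04d}"
        sub.mkdir()
        analog, digital, egt = _render_bin_epoch(rng, spec)
        toyformats.write_toybin(
            sub / "record.toybin", analog, digital, spec.sample_rate, spec.t0
        )
        write_probemap(
            sub / "record.toybin.epochprobemap.tsv",
            _probemap_rows(daq_bin, subject, spec.n_analog),
        )
        shift = stim.clock_offset + e * 1.0  # distinct offsets per epoch
        trig_bin = np.array(egt["trigger_times"])
        trig_stim = scale * trig_bin + shift + rng.normal(
            0.0, stim.jitter_sd, size=len(trig_bin)
        )
        presentations = []
        span = spec.duration - 2.0
        for k in range(stim.n_presentations):
            onset_bin = 1.0 + k * span / max(1, stim.n_presentations)
            onset = scale * onset_bin + shift
            presentations.append({
                "onset": onset,
                "offset": onset + stim.stim_duration,
                "stim_id": k % len(directions) + 1,
                "params": {"angle": directions[k % len(directions)]},
            })
        egt["mapping"] = {"scale": scale, "shift": shift}
        egt["trigger_times_stim"] = trig_stim.tolist()
        egt["files"] = [f"{sub.name}/record.toybin"]
        if (e + 1) not in drop_stim_in:
            clock = {"type": "dev_local_time"}
            if stim.utc_anchor is not None:
                clock = {"type": "utc", "utc_anchor": stim.utc_anchor + e * 3600.0}
            toyformats.write_toystim(
                sub / "record.toystim", trig_stim, presentations, clock
            )
            write_probemap(
                sub / "record.toystim.epochprobemap.tsv",
                [{"name": "vis_stim", "reference": 1, "type": "stimulator",
                  "devicestring": f"{daq_stim}:e1", "subject": subject}],
            )
            egt["files"].append(f"{sub.name}/record.toystim")
            egt["presentations_stim"] = presentations
        gt["epochs"].append(egt)
    _write_groundtruth(target, gt)
    return gt


def make_tuned_responses(path, directions, reps: int,
                         tuning: TuningParams | None = None,
                         stim: ToyStimEpochSpec | None = None,
                         sample_rate: float = 10000.0,
                         spike_amplitude: float = 8.0,
                         noise_sd: float = 1.0,
                         seed: int = 0,
                         daq_bin: str = "elec_mfdaq",
                         daq_stim: str = "vis_stim_daq",
                         subject: str = "ferret01") -> dict:
    """Single-epoch epochdir session with direction-tuned spiking.

    The stimulus file presents each direction ``reps`` times (cycling the
    direction list) with interstimulus gaps; the electrode channel carries
    an inhomogeneous-Poisson spike train whose rate follows the
    double-Gaussian tuning law during presentations and ``baseline_rate``
    during gaps.  Presentation times in the stimulus file are expressed in
    the stimulus clock, which is offset/drifted from the electrode clock.
    """
    directions = [float(d) for d in directions]
    if not directions:
        raise ValueError("directions must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tuning = tuning or TuningParams()
    stim = stim or ToyStimEpochSpec()
    target = _prepare_target(path)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = 1.0 + stim.clock_drift
    shift = stim.clock_offset

    period = stim.stim_duration + stim.interstimulus
    pre_gap = 1.0
    n_pres = len(directions) * reps
    duration = pre_gap + n_pres * period + 1.0
    n = int(round(duration * sample_rate))

    # piecewise-constant rate: baseline in gaps, tuning law during stimuli
    onsets_bin = pre_gap + np.arange(n_pres) * period
    angles = np.array([directions[k % len(directions)] for k in range(n_pres)])
    spike_times: list[float] = []
    segments = []
    cursor = 0.0
    for onset, angle in zip(onsets_bin, angles):
        segments.append((cursor, onset, tuning.baseline_rate))
        segments.append((onset, onset + stim.stim_duration,
                         float(double_gaussian_rate(angle, tuning))))
        cursor = onset + stim.stim_duration
    segments.append((cursor, duration, tuning.baseline_rate))
    for a, b, rate in segments:
        count = rng.poisson(rate * (b - a))
        spike_times.extend(rng.uniform(a, b, size=count))
    min_gap = 0.0025
    spike_arr = _thin_to_min_gap(np.array(spike_times), min_gap)

    trace = rng.normal(0.0, noise_sd, size=n)
    template = spike_template(sample_rate, spike_amplitude * noise_sd)
    peaks = embed_spikes(trace, spike_arr, template, sample_rate)

    digital = np.zeros((n, 1), dtype=np.uint8)
    trig_bin = make_trigger_train(rng, 30, duration)
    trig_snapped = embed_triggers(digital[:, 0], trig_bin, sample_rate)
    trig_stim = scale * trig_snapped + shift + rng.normal(
        0.0, stim.jitter_sd, size=len(trig_snapped)
    )

    sub = target / "t0001"
    sub.mkdir()
    toyformats.write_toybin(
        sub / "record.toybin", trace.astype(np.float32)[:, None], digital,
        sample_rate, 0.0,
    )
    write_probemap(
        sub / "record.toybin.epochprobemap.tsv",
        _probemap_rows(daq_bin, subject, 1),
    )
    presentations = [
        {
            "onset": scale * onset + shift,
            "offset": scale * (onset + stim.stim_duration) + shift,
            "stim_id": int(k % len(directions)) + 1,
            "params": {"angle": float(angle)},
        }
        for k, (onset, angle) in enumerate(zip(onsets_bin, angles))
    ]
    clock = {"type": "dev_local_time"}
    if stim.utc_anchor is not None:
        clock = {"type": "utc", "utc_anchor": stim.utc_anchor}
    toyformats.write_toystim(sub / "record.toystim", trig_stim,
                             presentations, clock)
    write_probemap(
        sub / "record.toystim.epochprobemap.tsv",
        [{"name": "vis_stim", "reference": 1, "type": "stimulator",
          "devicestring": f"{daq_stim}:e1", "subject": subject}],
    )
    gt = {
        "seed": seed, "layout": "epochdir", "daq_bin": daq_bin,
        "daq_stim": daq_stim,
        "tuning": asdict(tuning),
        "epochs": [{
            "files": ["t0001/record.toybin", "t0001/record.toystim"],
            "spike_times": peaks.tolist(),
            "trigger_times": trig_snapped.tolist(),
            "trigger_times_stim": trig_stim.tolist(),
            "mapping": {"scale": scale, "shift": shift},
            "onsets_bin": onsets_bin.tolist(),
            "angles": angles.tolist(),
            "stim_duration": stim.stim_duration,
        }],
    }
    _write_groundtruth(target, gt)
    return gt


def sample_direction_responses(rng, tuning: TuningParams, directions,
                               reps: int, duration: float = 1.0):
    """Lightweight Poisson draw of baseline-subtracted responses (Hz).

    Emulates what the response pipeline measures — spike count over each
    presentation minus the preceding-gap baseline rate — without rendering
    a full session to disk.  Returns (angles, responses).
    """
    angles = np.tile(np.asarray(directions, dtype=float), reps)
    rates = double_gaussian_rate(angles, tuning)
    counts = rng.poisson(rates * duration)
    base = rng.poisson(tuning.baseline_rate * duration, size=len(angles))
    return angles, counts / duration - base / duration
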