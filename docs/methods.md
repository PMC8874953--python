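# Methods

This note documents the models, conventions, parameter defaults, and
numerical choices behind the package, and what the synthetic fixtures do and
do not emulate.

## Conventions

All times are seconds; all angles are degrees. An epoch covers the half-open
device-local interval `[t0, t1)` and sample `k` lies at `t0 + k/rate`, so
reads never resample and repeated interval reads tile a recording exactly.
Channels are 1-based with prefixes `ai` (analog in), `di` (digital in), `e`
(event/marker). Identifiers are a fixed-width hex millisecond timestamp plus
16 random hex characters: lexicographic order is creation order for events
≥ 1 ms apart, and 64 random bits make collisions negligible without any
central registry.

## Epoch discovery and identity

A navigator is a small rule, not a file list. `flat`: every file under the
session root matching *all* filename regexes is its own epoch (multi-file
epochs therefore require the `epochdir` layout). `epochdir`: every immediate
subdirectory containing at least one match per regex is an epoch; a
subdirectory missing any required file type is silently invalid. Ordering is
lexicographic on the matched file/subdirectory name, so scans are
deterministic. Epoch identity is persisted in a hidden per-DAQ id-map keyed
by the SHA-256 of the epoch's sorted relative file names: re-scans, added
epochs, and deleted epochs never change an existing epoch's id; renaming an
epoch's files deliberately gives it a new identity.

## Time model

A timestamp travels with a time reference `(referent, clocktype, epoch_id,
offset)`; `t` under the reference means `t − offset` on the referent's epoch
clock. Mappings between clocks are affine, `t' = scale·t + shift` with
`scale > 0` — the minimal form that captures both clock offset and linear
drift and composes/inverts exactly. Piecewise or higher-order drift models
are an extension point, not implemented.

The sync graph has one node per (item, epoch, clock type) and three edge
classes: **sync-rule** edges between simultaneously recorded epochs of two
DAQ systems, **inheritance** identity edges (a probe or derived element
shares the epochs of the item underneath it; a device that also keeps UTC
gets a local→UTC edge with shift equal to its UTC anchor), and **same-units**
identity edges between any two nodes on the same global clock. Every edge is
stored with its inverse. Nodes with clock type `no_time` join no edges.

Conversion takes the path with fewest edges (lexicographic node-key
tie-break): with no cost model available, fewer hops means fewer composed
fit errors, and the tie-break makes results reproducible. If two rules
propose edges between the same node pair, the smaller-residual edge wins.
A missing path raises an error naming both endpoints; this is a legitimate
outcome, not a failure mode.

**Shared-trigger regression.** Given trigger trains from both devices, the
mapping is the least-squares line `t_B = scale·t_A + shift`. With unequal
counts the shorter inter-trigger-interval sequence is slid along the longer
and the offset with the uniquely minimal summed |Δinterval| is used; a tied
minimum means the alignment is ambiguous and the rule abstains. The rule
also abstains with fewer than two triggers per side or when the RMS residual
exceeds its tolerance (default 1 ms) — it never fabricates low-confidence
edges. With 50 triggers spread over 60 s and 0.1 ms timing jitter the
closed-form error propagation gives sd(scale) ≈ 1e-6 and sd(shift) ≈ 0.03 ms,
which is why the recovery checks use thresholds of 1e-5 and 1 ms.

## Documents, schemas, queries

A document has five core fields (id, session id, schema name+version, UTC
ISO-8601 millisecond timestamp, named dependency list), schema-specific body
fields, and an optional binary blob in a sidecar file. The store is one JSON
file per document under `documents/` with blobs under `blobs/`; an in-memory
index is rebuilt on open. Schema validation uses a deliberately restricted
dialect — field kinds string/integer/number/list/object with a required
flag, plus superclass composition (effective fields are the recursive union;
same-named fields must agree in kind; a field required anywhere is required)
— because composition is the semantics under test, and a full JSON-Schema
engine would add a dependency without adding behavior. A schema version
integer is stored; migration is unimplemented.

Dependencies must exist at insert time, which makes the dependency graph
acyclic by construction. Removal either refuses when dependents exist or
cascades over the dependent closure in topological (dependents-first) order.

Queries are predicate trees. Dot paths address core and body fields
uniformly; traversing a list fans out to its members (a leaf matches if any
member matches). "Partial" string match is interpreted as substring.
`exact_number` uses exact binary equality — tolerance searches are expressed
with two inequality leaves. `isa` matches a document whose schema equals the
parameter or inherits from it transitively. The test suite checks the
evaluator against an independently written linear-scan oracle on randomized
stores.

## Spike extraction

Per epoch: zero-phase Butterworth bandpass (default 300–3000 Hz, order 3),
threshold detection on the filtered trace, refractory enforcement (keep the
earliest crossing, skip crossings within the refractory period, default
1 ms), extraction of a `[−0.5, +1.0]` ms window around each spike, and
clipping of events whose window exceeds the epoch. The spike time is the
local extremum within the suprathreshold run — peak alignment, the standard
choice. Two robustness choices matter at low thresholds:

* the `std_multiple` threshold uses a median-absolute-deviation noise
  estimate of the filtered trace, so the spikes themselves do not inflate
  the estimate;
* a minimum crossing width (default 0.2 ms) rejects single-sample noise
  excursions. At a 4σ threshold Gaussian noise crosses at ≈3e-5 per sample,
  so some width criterion is required for a detector expected to report
  *only* true events; 0.2 ms is well below the template's ≈0.45 ms
  suprathreshold width and well above the filtered noise correlation time.

An inter-spike-interval filter (`filter_isi`) retains spikes whose interval
to the previous *retained* spike meets a minimum (first spike always kept).

## Stimulus responses and tuning

Presentation windows live on the stimulus device's clock and are converted
into the spike element's clock through the sync graph — never assumed equal.
The response to one presentation is the firing rate during `[onset, offset)`
minus the rate during the preceding interstimulus interval (for the first
presentation, the interval from epoch start), normalizing ongoing activity
to zero. Interstimulus intervals cannot overlap stimuli in this design; a
zero-length gap yields a zero baseline.

The tuning curve is the per-direction mean ± SEM. With `θp` the direction of
maximal (rectified-at-zero) response, the selectivity indices are

    DI = (R(θp) − R(θp+180°)) / R(θp)
    OI = (R(θp) − ½[R(θp+90°) + R(θp−90°)]) / R(θp)

with opposite/orthogonal values read at the nearest sampled direction and
both indices defined as 0 for an all-zero curve. The double-Gaussian fit
(two lobes 180° apart over a constant offset, circular angle difference in
[−180°, 180°)) uses `scipy.optimize.least_squares` with `θp` free, bounds
σ ∈ [1°, 90°] and `Rp, Rn ≥ 0`, and a multi-start over a 22.5° grid of `θp`
initializations — the circular parameter otherwise traps local minima. If
the fit converges with the larger lobe labeled `Rn`, lobes are swapped and
`θp` rotated by 180°, so `Rp` always names the dominant lobe; an all-zero
curve returns the constant-only model.

## Synthetic fixtures: what they emulate

The `.toybin`/`.toystim` formats exercise a real binary reader (fixed
header, interleaved float32 frames, bit-packed digital channels) and an
event/parameter reader without mimicking any vendor layout. Generator
defaults are the study conditions the tests measure under:

* **flat sessions** (spike recovery): 20 kHz, 0.5 s epochs, white Gaussian
  noise of sd 1, 20 embedded biphasic spikes (1.5 ms, 0.6 ms positive lobe,
  negative lobe at 40%) at 5× noise sd, ≥7.5 ms apart; a 7 Hz sine test
  channel; 10 digital triggers.
* **epochdir sessions** (synchronization): 5 kHz, 30 s epochs, 30 shared
  triggers; stimulus clock offset 0.5 s (+1 s per epoch so epochs are
  distinguishable) and drift 1e-4; trigger report jitter 0.1 ms; optional
  UTC anchor marks the stimulus device as a global-clock keeper.
* **tuned sessions**: 10 kHz, directions cycled `reps` times, 1 s stimulus /
  1 s gap, inhomogeneous-Poisson spikes with rate `C = 5`, `Rp = 30`,
  `Rn = 15`, `θp = 60°`, `σ = 30°` Hz during stimuli and 5 Hz baseline in
  gaps, thinned to a 2.5 ms minimum separation so templates stay separable;
  spike amplitude 8× noise sd so tuning recovery measures the pipeline, not
  detector luck.

All generators derive per-epoch RNG streams from a root seed, so identical
seeds give byte-identical sessions, and the same recipe written flat or as
epoch subdirectories carries identical sample payloads — the basis of the
organization-independence check. Ground truth (spike peak times snapped to
the sample grid, trigger trains on both clocks, the true affine mapping,
tuning parameters) goes to a `groundtruth.json` sidecar that the library
itself never reads.

What the fixtures do **not** emulate: spike waveform variability and
overlap, non-Gaussian or nonstationary noise, electrode drift, nonlinear or
piecewise clock drift, missed/extra triggers beyond count mismatch, and
imaging modalities. Passing tests therefore demonstrate the interface
machinery — navigation, reading, synchronization, provenance, querying, and
the estimator/fitter math — on clean, well-specified signals, not detector
performance on real recordings.

## Problem sizes

The statistical checks run at desk scale, chosen to finish in minutes on one
CPU while keeping the estimators in their asymptotic regime: 100 seeded
trigger fixtures for mapping recovery, 100 seeded Poisson tuning draws
(10 reps/direction) fitted for preferred-direction recovery (the Poisson
draws use the generator's response sampler directly; the file-backed path is
covered end-to-end by the pipeline tests), 500 documents × 200 random
queries for oracle equivalence, and 10 epochs for raw round-trips.

## Known limitations

Single-writer local store only (no locking, no client/server backends);
readers exist for the two toy formats only, though the reader interface is
the extension point for real formats; timeseries and event elements only (no
imaging); affine clock models only; no spike sorting — extraction stops at
waveforms and times.
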