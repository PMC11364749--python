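# Methods

## The problem

Conventional flow cytometry reduces each detector pulse to three
scalars (area, height, width) and sorts on fluorescent stains.  A
pulse-shape cytometer instead digitizes the *whole* transit waveform of
every cell on several scattered-light channels (different forward-
scatter angles plus side scatter) and makes real-time sort decisions
from the shape itself, enabling label-free sorting — for example by
cell-cycle phase, where diameter, internal structure, and extinction
change systematically from G1 through S to G2/M.

`mapsort` implements that computational pipeline end to end on
synthetic data: pulse simulation, wavelet feature extraction,
per-channel clustering, conjunction sort-cluster ranking, and a
discrete-event model of the mechanical sorter.

## Pulse model and simulator

A particle of diameter *d* crossing a focused beam of 1/e² full width
*w*₀ = 3 µm at flow speed *v* = 5.2 m/s produces a pulse of effective
length (*d* + *w*₀)/*v*, the sum-of-widths approximation of the
beam–particle convolution (an exact Gaussian⊗chord convolution adds
nothing at the 100 ns sampling grid).  At the 10 MHz digitizer rate and
8 µs trigger window every event is an 80-sample waveform per channel.

Each channel's waveform is

    baseline + amplitude · bell(t; width, asymmetry) − depth · dip(t) + ε,

where `bell` is a skew-normal profile peak-normalised to 1 with FWHM
equal to the transit length, `dip` is a narrower (0.6×) bell subtracted
at the pulse centre to emulate extinction-dominated angles, and ε is
i.i.d. Gaussian noise (default sd 0.02 a.u. against unit-order
amplitudes, i.e. SNR ≈ 50 — a clean detector).  The pulse centre is
quantized to the sample grid; trigger jitter is uniform over ±2
samples.  Peak shifts are rounded to whole samples, so noise-free
symmetric pulses are exactly symmetric about an integer peak sample.

The default three-population mixture mimics a proliferating culture:
abundances 0.55/0.25/0.20 (G1/S/G2M), diameters 10/12/14 µm (sd
0.6–0.7 µm), and channel morphologies that reproduce the qualitative
axes real cell-cycle pulse data show — pulse length growing with phase
everywhere, channel-specific height changes on two channels, a
progressive peak shift on the third, and extinction depth *decreasing*
with phase on the fourth.  Optional per-population stain intensities
(a DNA-content-like dye doubling from G1 to G2M and an S-phase
incorporation marker) are drawn as well-separated Gaussians so the
reference-gating path can be exercised.

What the simulator does **not** emulate: Mie scattering physics,
correlated detector noise, doublet/debris events in the stream (the
gating module is tested on constructed fixtures instead), optical
drift, or day-to-day instrument variation.  Passing tests therefore
demonstrate the correctness of the decision pipeline, not classifier
performance on real cells.

Determinism: every stream descends from one integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical streams.

## Features

The sort feature space is the deepest-level Haar detail of the trigger
window.  With the orthonormal per-level 1/√2 normalisation the 4-level
cascade collapses to one coefficient per 16-sample block,

    c_b = (Σ first 8 samples − Σ last 8 samples) / 4,

hence exactly 5 coefficients per channel for 80 samples.  "Scale" here
follows the convention that a Haar atom of scale *s* spans 2*s*
samples, so scale 8 ⇒ 16-sample blocks.  The deepest-level
*approximation* branch (block sums / 4, also 5 values) is available via
`HaarFeatures(branch="approximation")` since an instrument could store
either; the detail branch is the default because detail coefficients
are what "wavelet coefficients" conventionally denotes.  The
implementation is verified against PyWavelets' `wavedec` level-4
output in the tests.

A streaming variant emits one coefficient per 16 consecutive samples
from an arbitrary sample offset in [0, 16), matching the batch result
exactly on aligned windows — the form a real-time FPGA implementation
computes on the continuous data stream.

A/H/W pulse parameters use: baseline = median of the first and last 4
window samples (the paper-trail formats are silent on the estimator;
window edges are pulse-free by construction), area = sum of
baseline-subtracted samples clipped at 0, height = max, width = count
of samples strictly above 50% of height (vendor conventions differ;
50% is the common choice).

## Clustering and the sort decision

Each channel is clustered independently by k-means on its raw 5-D
coefficient vectors (no scaling by default — the coefficients share
units within a channel; standardisation is available as an option).
Defaults: k = 6 per channel (hardware bound 8), k-means++
initialisation, 10 restarts keeping the best inertia, tolerance 1e-6,
≤300 iterations, all events included.  `MultiChannelKMeans` seeds
channel *c* with `random_state + c` so channels are decoupled but
reproducible.

The real-time decision is nearest-centroid per channel under Euclidean
distance, ties broken toward the lowest cluster index — implemented as
an explicit argmin rather than a library `predict` so the tie-break is
pinned.  Centroid tables round-trip through a plain-text exchange
format at full `repr` precision, so exported-then-imported models
reproduce assignments bit-identically.

## Sort clusters, enrichment, selection

Candidate sort criteria are all conjunctions (logical AND) of
single-channel clusters from two different channels — C(4,2)·6·6 = 216
candidates at the defaults; the order generalises.  Against reference
labels, each candidate c is scored per population P by the enrichment

    x(P, c) = ( N(P,c) / N(·,c) ) / ( N(P,·) / N(·,·) ),

with ceiling x_max(P) = N(·,·)/N(P,·) attained by a pure-P cluster.
Useful identities (all property-tested): x = 1 for the whole-sample
cluster, Σ_P x(P,c)·N(P,·) = N(·,·) for any non-empty c, and
0 ≤ x ≤ x_max.

Selection per population uses two rankings: (A) top clusters by x (ties
to the larger cluster) and (B) clusters with x ≥ threshold_frac · x_max
ordered by size descending, threshold_frac defaulting to 0.75 (0.67 is
the live-cell variant).  Because maximally enriched clusters can be
tiny — unusable for sorting due to dilution — the final pick prefers
ranking-B entries of size ≥ min_size_frac (default 1% of events), then
falls back to ranking A, deduplicated, top_n = 3 per population.  The
interleaving rule is this package's design choice; the two rankings and
the threshold fractions are the method's.  Empty clusters have
undefined (NaN) enrichment and are never selected.  Cluster sizes are
reported both as fractions of all events and of singlet-gated events
when a singlet mask is supplied.

## Virtual sorter

A discrete-event model of a catcher-tube sorter.  Timing defaults:
decision latency ≤10 µs (well under the travel time, so ignored in the
event algebra), actuation delay 200 µs after the trigger, engage
plateau 400 µs, disengage ramp 400 µs (deflecting nothing by default —
the tube is assumed clear of the stream; configurable), travel time
300 µs from interrogation point to sort point, mechanical refractory
3.33 ms.

Rules: a full-match trigger at time t engages the tube over
[t + 200 µs, t + 600 µs] if the previous engagement is at least one
refractory period old; otherwise the trigger is dropped (not queued — a
piezo actuator cannot re-arm mid-cycle).  Any event whose sort-point
arrival t + 300 µs falls inside an engaged interval is deflected,
target and coincident contaminant alike.  Purity is tallied over
deflected events; yield is deflected full-matches over all full-match
triggers.

The refractory default reproduces the ~300 cycles/s mechanical ceiling
(1/3.33 ms ≈ 300 s⁻¹) even though delay + ramps sum to less — the
ceiling is mechanical, not timing arithmetic.  Consequences verified in
the tests: saturated cycle rate → 1/refractory; purity is monotonically
degraded by coincidences as the Poisson event rate grows
(50 → 3000 s⁻¹); at rates far below 1/refractory the sorted set equals
the full-match membership exactly.

Re-analysis applies the same enrichment statistic to the deflected
sample versus the pre-sort stream, mirroring how a sorted tube would be
re-measured.

## File formats

The instrument's true binary layouts are undocumented, so the package
defines its own versioned little-endian layouts (magic `MAPP` for
pulses, `MAPW` for coefficients; float32 samples; streamed reading) and
treats foreign layouts as pluggable adapters.  Truncation or bad magic
raises a format error naming the byte offset — never a silent partial
read.  FCS output is FCS 3.1 float32 list mode with standard
`$PnN/$PnB/$PnE/$PnR`, `$DATATYPE/F`, `$BYTEORD/1,2,3,4` keywords; the
reader also accepts FCS 3.0.  Writers are deterministic byte-for-byte.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 10⁴
events (≈4 s end to end), the sorter-physics checks at 6–30 × 10³
triggers, and oracle comparisons at 10²–10³ cases; these sizes put
binomial error comfortably below the asserted margins while keeping
runs quick.  k-means determinism is by fixed seed; permuted inputs are
only required to reach the same inertia within tolerance, since label
numbering is arbitrary.  Gates use half-open intervals so adjacent
gates tile without double-counting.  Events with zero pulse width are
excluded from singlet gating rather than treated as errors.

## Known limitations

- The simulator's phenomenological bell is not a scattering model;
  absolute coefficient values carry no physical meaning.
- Enrichment has no significance test attached; ranking on small
  clusters is noisy and guarded only by the size floor.
- The sorter model drops refractory-window triggers instead of
  queueing, and does not extend an engagement on a mid-plateau match;
  both are plausible hardware behaviours but unverified.
- FCS support is list-mode float only: no analysis segment,
  compensation, or spillover.
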