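# Methods

## The container and its invariants

One recording — one HDF5 file. The root holds `epos` (N×2 unit positions,
µm), `sCount` (per-train spike counts), `spikes` (all spike times in
seconds, trains concatenated in unit order, each train sorted ascending),
`array` (layout label) and optionally `names`. Unit *j* (1-based) occupies
elements *a*..*b* of `spikes` with *a* = 1 + Σ_{i<j} sCount[i] and
*b* = *a* + sCount[j] − 1; an empty train gives *b* < *a*. `unit_slice`
exposes exactly this 1-based inclusive convention (the documentation
convention for the format), while the reader slices with the equivalent
0-based half-open range internally.

`/meta` holds key, species, age (integer postnatal days; 0 = birth,
negative = embryonic, sentinel 500 = adult, passed through unchanged),
genotype and cond. Absent genotype/cond materialise as `"wt"` / `"ctl"`.
Vocabulary for species/array labels is an **open** string set: the
validator logs a warning for unseen labels but does not fail them, because
condition and genotype strings in real repositories are effectively free
text.

`/summary` caches N, duration, frate and totalspikes so inventory tools
can avoid reading the (much larger) spike vector. Duration is the maximum
spike time rounded **up** to a whole second; `frate[i] = sCount[i] /
duration`, so `frate · duration = sCount` holds exactly in floating point
(an integer divided and re-multiplied by the same integer). `totalspikes`
is Σ sCount — the total number of spikes, which is what the name says and
the only reading that adds information beyond N. With zero spikes the
duration is undefined; `compute_summary` then requires an explicit
duration override and otherwise raises, rather than writing a silent 0
that would poison every rate downstream.

Reading is tolerant, writing is strict: the reader transposes a (2, N)
`epos` written by a column-major environment (an ambiguous 2×2 is taken
as-is), applies metadata defaults and recomputes a missing summary; the
writer refuses any recording that fails validation and always emits N×2
positions, float64 times, int64 counts and variable-length UTF-8 strings —
which is why round trips are bit-exact.

## Correlation index

For spike trains *a*, *b* observed for *T* seconds,

    CI(a, b) = N_ab(Δt) · T / (N_a · N_b · 2Δt)

with N_ab(Δt) the number of pairs (s ∈ a, t ∈ b) with |s − t| ≤ Δt
(closed window). Under independence the expected pair count is
N_a · N_b · 2Δt / T, so E[CI] = 1; the statistic is symmetric and
invariant to a common time shift. Default Δt = 50 ms, the conventional
window for retinal-wave work. *T* is taken from the summary duration (the
whole-second ceiling), keeping one source of truth between the cache and
the analyses.

Pairs involving an empty train get CI = NaN, never 0 — a 0 would read as
anti-correlation. All N(N−1)/2 pairs are produced, including pairs of
units assigned the same array position (distance 0). Distances are
Euclidean in the electrode plane. Binning uses left-closed right-open
intervals [k·w, (k+1)·w), w = 100 µm by default; NaN pairs are dropped
from bin means and empty bins are omitted.

`coincidence_count` uses vectorised bisection (`np.searchsorted` of each
spike's window edges into the other train), O(n log m); tests compare it
exhaustively against O(n·m) brute-force enumeration.

## Burst detection

The detector is a parameterised ISI-threshold method: maximal runs of
consecutive spikes with every ISI ≤ `max_isi` (0.3 s), runs shorter than
`min_spikes` (3) discarded, surviving runs merged when separated by less
than `merge_interval` (0.5 s). Duration is last-spike minus first-spike.
A merged burst's spike count includes any isolated spikes its span
swallowed, preserving the invariant that a burst's spikes are consecutive
in the train. Published cross-laboratory burst comparisons do not share a
single standardised detector, and reported burst counts vary by orders of
magnitude between laboratories; the parameters here are therefore explicit
knobs, with defaults chosen so that compact wave bursts are recovered
exactly on planted fixtures (gaps larger than both `max_isi` and
`merge_interval` guarantee exact recovery). Duration CDFs are the plain
empirical distribution k/n at the k-th smallest duration.

## Wave simulator

The generator exists to give every analysis a schema-conformant input with
the right statistical structure: episodic population-rate peaks,
distance-decaying pairwise CI, per-unit bursts over sparse background.
The model: wave initiation times are a homogeneous Poisson process at
`wave_rate` (default 0.02 /s, one wave per ~50 s), origins uniform on the
array bounding box; each wave is a circular front of constant speed
`speed` (200 µm/s); when the front reaches a unit, the unit fires a
Poisson burst at `burst_rate` (30 Hz) for `burst_duration` (1 s) unless it
was activated within the last `refractory` seconds; background firing is
Poisson at `background_rate` (0.05 Hz) throughout. Defaults describe a
30-minute recording on the 60-electrode, 100 µm-pitch array.

The refractory default is 5 s: long relative to one burst (so a unit is
not re-triggered by the same front as it sweeps past) and short relative
to the ~50 s inter-wave interval (so consecutive waves are not
suppressed).

What the model deliberately omits: wave-front curvature changes, finite
wave extent, wave–wave collisions, refractory-biased propagation
direction, developmental parameter drift, and spike-sorting artifacts
(each simulated unit sits exactly on its electrode, so no two units share
a position and no pair is closer than the electrode pitch). Passing tests
therefore demonstrate that the *statistics pipeline* behaves correctly on
data with wave-like structure — not that the model reproduces retinal
biophysics, nor the absolute CI magnitudes or burst counts of any real
recording. In real sorted data the median burst duration is typically
near 0.1 s; the simulator's default 1 s wave bursts make detection easy
to verify, and shorter bursts can be produced by lowering
`burst_duration`.

All randomness flows through one `numpy.random.Generator` seeded from the
mandatory `seed` parameter; fixed parameters give byte-identical output.
Spike times are truncated to [0, T); ties are kept in stable order.

## Array layouts

Five layouts are generated: 8×8 square lattices at 100 or 200 µm pitch
with the four corner sites absent (60 electrodes, the classic MCS
geometry), a full 64×64 lattice at 42 µm (4096 electrodes, APS-style
high-density arrays), and triangular lattices with 60 µm
nearest-neighbour spacing trimmed to the 61 or 512 sites nearest the
patch centre (hexagonal arrays). Positions are non-negative µm with a
deterministic site order.

## Numerical and design choices

- **Zero CI on log axes.** Figure exports draw CI = 0 at half the smallest
  positive CI and flag the floored points in the export, so log-scale
  panels stay drawable without hiding zeros.
- **Figure testing surface.** Every plot returns (and can write) a
  machine-readable export of exactly the plotted numbers; tests compare
  those, never pixels, because rendering backends differ.
- **Catalog determinism.** Directory scans sort lexicographically by path;
  contingency-table cells always sum to the number of rows (a partition),
  and age columns sort ascending so the adult sentinel 500 lands last.
- **Error taxonomy.** Unreadable files raise I/O errors; schema problems
  raise `SchemaError` (reader) or return coded `Violation`s (validator);
  analysis preconditions (N < 2 for pairs, empty inputs for binning/CDFs)
  raise `ValueError`.

## Problem sizes in the test suite

Round-trip and property tests use recordings of up to ~20 units and a few
hundred spikes; oracle comparisons use trains of up to 200 spikes; the
calibration test uses 200 replicate 1 Hz / 1000 s Poisson pairs; the
wave-decay test runs the full 1800 s default simulation on the
60-electrode array for five seeds. These sizes exercise every code path
while keeping the whole suite under a minute on one CPU.

## Known limitations

- The validator checks structure and internal consistency, not scientific
  plausibility (it will not flag a biologically absurd firing rate).
- The CI implementation makes no small-sample correction; for very short
  recordings or very sparse trains the statistic is noisy, and the NaN
  convention only covers the fully-empty case.
- The burst detector is single-train only; array-wide (network) burst
  detection is out of scope.
- No converters for laboratory-specific source formats are provided; data
  must already be in the HDF5 schema.
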