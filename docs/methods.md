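# Methods

This note documents the model behind scarfkit, the conventions it fixes
where event-level eye-tracking exports are ambiguous, what the synthetic
recordings emulate, and the numerical choices that make results
reproducible. It states no empirical result the test suite and
`scripts/acceptance.py` do not themselves compute.

## Segment model and time conventions

The atom is one timestamped eye-movement event with a set of AOI hits.
All intervals are half-open `[start, end)` in milliseconds, held at full
floating precision internally and rounded only at export. Half-open
intervals make adjacent events (a fixation ending exactly where a saccade
begins) non-overlapping and keep duration sums exact; a zero-length
segment is therefore ill-formed and rejected at canonicalization.

The **trial** — one participant on one stimulus — is the scope of every
derived quantity. Its **onset** is the minimum event start and its end the
maximum event end. Exports disagree about zero references (recording
start, stimulus onset, arbitrary device clocks), so all latencies are
onset-referenced; this is the only definition that is invariant across the
supported dialects. Time-range filters clip partially overlapping segments
at the window bounds rather than dropping them; whether interactive tools
clip or drop is generally undocumented, so clipping is this package's own
documented choice (it preserves the total-duration accounting that the
geometry invariants rely on).

Overlapping AOI hits are a *set on one segment*, never duplicated rows.
This is what makes dwell sums double-count-free: a fixation hitting
`{A, B}` contributes its full duration to A and to B but only once to
each.

Non-destructive editing is pointer-based: merging AOIs sets a
`merged_into` pointer in the registry (pointers form a forest; cycles are
rejected) and every consumer resolves hits through the pointers, so
unmerge is an exact inverse and the underlying segments are never touched.
The AOI registry is a single flat namespace; the per-stimulus view that a
dashboard shows is derived from the segments, since merge, recolour, and
legend operations are stimulus-agnostic.

## Metrics

Per (participant, stimulus, AOI), over **fixation-category segments
only**: time to first fixation (TTFF), fixation count, dwell time, and
average fixation duration (= dwell / count). Saccades and "other" events
render in scarf plots but enter no metric; whether an AOI visit's interior
saccades should count toward dwell is not standardized, and the
fixation-only definition matches how the metric names are used in vendor
analysis software. Absent values (an AOI never fixated) are represented as
absent — `None` in records, empty CSV cells — because 0 is a legal TTFF.

**Interval reconstruction.** Exports in the interval-split style round
timestamps to whole milliseconds and deliver one recording as several
presentation intervals (common in mobile eye-tracking, where a stimulus
can reappear). Each interval parses as its own trial
(`"<stimulus>#<k>"`); unification sums counts and dwell, re-weights the
average by count, and takes `TTFF = min_i(offset_i + TTFF_i)` with
`offset_i` the interval onset relative to the earliest interval onset.
Because intervals break at event boundaries (the stimulus is absent
between presentations, so no fixation straddles a boundary), counts are
preserved exactly; rounding each boundary by at most 0.5 ms bounds every
reconstructed temporal metric within ±1 ms of the direct full-precision
value. Dwell is a per-event sum, so its rounding error compounds at up to
1 ms per fixation; tests bound it by `count × 1 ms` rather than
pretending it obeys the per-metric bound.

**Rasterization oracle.** The independent check divides each trial into
cells of a chosen resolution, assigns each cell to the fixation covering
its start time, and reads all four metrics off the cell array (dwell =
cells × resolution, TTFF = first owning cell, count = distinct owning
fixations). With integer boundaries at 1 ms resolution it reproduces the
analytic path exactly; otherwise each temporal quantity is off by at most
one cell. The oracle shares no interval arithmetic with the metrics
implementation.

## Dialects and the streaming reader

Proprietary vendor layouts are not reverse-engineered byte-for-byte.
Instead the package defines four fully specified dialects that carry the
behaviours that actually matter for correctness: two documented generic
CSV layouts (`generic_long`, one row per event; `generic_interval`, one
row per AOI visit with explicit bounds — it cannot represent saccades, a
documented lossy write), an event-per-row vendor-style dialect
(`begaze_like`, tab-separated, capitalised event names, visibility shipped
as separate files) and the interval-split integer-ms dialect
(`tobii_like`) described above. Detection is purely structural: the header
tokens plus delimiter identify exactly one dialect; filenames are never
consulted. Delimiter sniffing is restricted to comma, semicolon, and tab,
decided on the header line; decimal separator is the dot only (locale
sniffing is error-prone and the constraint is documented instead).

The reader is chunked with bounded memory: between chunks only the
carry-over partial line is retained (`meta.max_carry_bytes` instruments
the peak), so the parse result is identical for every chunk decomposition
of the same bytes. Malformed rows are skipped-and-counted by default and
raise with their 1-based line number in strict mode; duplicate identical
rows collapse with a counter. Writers are byte-stable (fixed column order,
LF, no quoting — identifiers containing the delimiter are rejected at
write time), which is what makes round-trip identity a byte-level test.

AOI visibility files carry `(aoi, stimulus, start, end)` rows and no scope
column — the caller assigns one file per participant or one global file,
mirroring how such files are exported. Participant-scoped intervals
override the global schedule entirely for that participant; an AOI with no
schedule at all defaults to always visible, so the visibility query is
total. Overlapping same-AOI intervals are merged on read.

## Scarf geometry

Geometry is resolution-independent: rectangles in timeline coordinates
with sub-band indices, fill colours, and hover metadata (AOI display name,
original absolute time range, duration — mode-independent). One row per
participant in registry order. The three timelines are absolute
(milliseconds from trial onset), relative (0–100 % of trial duration —
trial duration, not recording duration, so rows always span exactly
[0, 100]), and ordinal (one unit per rendered segment, fixations and
saccades alike by default, with a fixations-only flag). Overlap sub-bands
are ordered by AOI registry index for deterministic ties; untracked
inter-segment gaps render as empty space, not as a filled style.
Visibility bands are appended below each row in absolute and relative
modes; in ordinal mode time intervals have no meaningful image, so
requesting the layer there is an error rather than a silent guess. The
default palette is a fixed 12-colour categorical cycle assigned at AOI
registration order, overridable per AOI.

## Transitions

Within each trial the fixation sequence is taken in time order (saccades
skipped without breaking the chain); each consecutive pair adds one count
for every element of the Cartesian product of the two AOI sets.
Self-transitions and the no-AOI pseudo-label are excluded by default —
the usual convention in eye-movement transition analysis — and both are
exposed as flags since tools differ. Transitions never cross trial or
participant boundaries.

## Exports and sessions

Metrics and events CSVs use RFC 4180 with fixed column order and
milliseconds to three decimals; the events CSV is the `generic_long`
dialect and re-imports loss-free. The ScanGraph-style export maps each
merge-resolved AOI to one character of a 62-character alphabet
(`#<char>=<name>` header lines, then `<participant>\t<sequence>`);
no-AOI fixations are skipped, overlaps transcribe as the
lowest-registry-index AOI with a warning, and consecutive-duplicate
collapsing is off by default behind a flag. The exact input grammar of
the external comparison tool is not normative here; the dialect is
specified above and versioned by a format constant.

Sessions are single canonical-JSON documents: UTF-8, sorted keys,
shortest-round-trip float representation, embedding the full canonical
data, panels (kind, filter, mode, options, layout slot), parse metadata,
and the tool version. Canonical serialization is what upgrades "round
trip preserves every queryable value" to byte-level equality of
`save → load → save`. Unknown fields are preserved on re-save; a missing
version field is a schema error (reported with a JSON-pointer path), a
mismatched one warns and loads best-effort.

## Synthetic recordings

The generator emulates event-level exports, not oculomotor physiology:
each trial is a gap-free alternating fixation/saccade train from 0 ms,
with fixation durations uniform on 100–400 ms and saccades on 20–80 ms —
the typical ranges for scene viewing — over 5 participants × 10 stimuli
× 4 AOIs and 3-second trials by default (~50 trials, ~10 fixations per
trial). Each fixation is unassigned with probability 0.1, otherwise hits
one uniformly chosen AOI plus, with probability 0.1, a second one
(overlap). Visibility windows appear per (AOI, stimulus) with density
0.5, with occasional participant-scoped overrides. A trailing event that
the trial clip would make shorter than 1 ms is not emitted: real
event-level exports contain no sub-millisecond fixations, and such an
artifact would vanish under integer rounding by construction rather than
by any property of the method. Interval cut points are sampled from event
boundaries because a presentation interval ends when the stimulus
disappears — between events — which is precisely why interval-split
exports preserve fixation counts.

Ground-truth metrics are accumulated event by event *during* generation,
so comparing them against the metrics layer is a cross-check of two
independent computations, not a tautology.

What passing tests on these fixtures does **not** show: robustness to
malformed real-world vendor quirks beyond the modelled ones (mixed
encodings, locale decimal commas, quoting), realistic saccade dynamics,
or gaze-coordinate-level processing (AOI hits arrive pre-assigned; there
is no fixation detection or AOI geometry here, by design).

## Problem sizes and numerical choices

The validation suites run 200 randomized datasets (~50 trials each) for
oracle equivalence, 200 for the reconstruction contract, a 50-dataset
round-trip sweep, 100 seeds of geometry properties, and 1000 brute-force
transition cases; the acceptance script uses 100/100/25 datasets per
block. These sizes give tens of thousands of AOI–participant comparisons
per run while keeping a full run in seconds. Floating-point comparisons
use exact equality where the computation is algebraically exact (counts,
sorting, clipping at shared bounds), 1e-9–1e-12 tolerances for sums of
floats, the 1-cell bound for rasterization, and the ±1 ms contract for
integer-rounded reconstruction. Rounding to integer milliseconds uses
Python's round-half-even consistently on both the write and the expected
sides. Seeds derive from a single integer everywhere (`numpy`
`default_rng`); the CLI, fixtures, and acceptance script accept it
explicitly.

## Known limitations

- Six proprietary vendor formats are represented by four fully specified
  dialects capturing their documented hard parts, not by byte-exact
  parsers for the originals.
- `generic_interval` cannot carry saccades (lossy by design, with a
  strict-mode refusal).
- Ambiguous stimulus assignment has no interactive resolution; strict
  mode errors instead.
- Rendering targets static images; interactivity (hover, drag) is a UI
  concern — the geometry carries the metadata a UI would need.
- Group statistics stop at per-group means in bar summaries; inferential
  statistics are out of scope and expected to run on the exported CSVs.
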