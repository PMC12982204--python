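# scarfkit

Headless AOI-sequence analytics for eye-tracking event data: parse
delimited gaze-event exports into a canonical segment model, compute the
standard AOI metrics, and build scarf plots, transition matrices, and
aggregate bar summaries — as a Python library and a `scarfkit` command-line
tool, with fully reproducible session and data exports.

## Who this is for

Researchers working with *areas of interest* (AOIs): semantic regions of a
stimulus onto which gaze has already been mapped, so the data arrive as
timestamped events (fixations, saccades) each carrying a set of AOI hits.
scarfkit is for pipelines and batch analysis where a browser tool does not
fit — scripted figure generation, CI-checked metric computation, or
treating any categorical event sequence (not just gaze) as a scarf
timeline.

## The model

Events live on a half-open millisecond timeline: a segment occupies
`[start, end)`, so adjacent events never overlap and duration sums are
exact. A trial is one participant on one stimulus; its onset is the
earliest event start, its end the latest event end. Per
(participant, stimulus, AOI) the four standard metrics are, over
fixation-category segments only:

- **TTFF** `= min start(fixations hitting a) − onset` — time to first fixation;
- **fixation count** `n(a)` — number of fixations hitting AOI `a`;
- **dwell time** `D(a) = Σ duration(fixations hitting a)`;
- **average fixation duration** `D(a) / n(a)`.

A fixation hitting *k* overlapping AOIs carries a *set* of hits on one
segment: it contributes its full duration and one count to each AOI, and
scarf plots render it as *k* stacked sub-bands (or one overlap-coloured
rectangle). Scarf geometry supports three timelines — absolute (ms),
relative (0–100 % of the trial), ordinal (one unit per segment) — and
dynamic AOIs via per-participant or global visibility schedules.
Transition matrices count consecutive-fixation moves `a → b` within each
trial, fanning out over overlap sets.

Vendor-style exports that round timestamps to whole milliseconds and split
one recording into several presentation intervals are handled by parsing
each interval as its own trial and reconstructing unified values
(`counts` add, `dwell` adds, `avg` re-weights by count,
`TTFF = min(offset + TTFF_i)`); a rasterization oracle and a
brute-force transition counter verify both computation paths.

## Worked example

```python
from scarfkit import (GazeSegment, canonicalize, compute_aoi_metrics,
                      export_metrics_csv, transition_matrix)

ds = canonicalize([
    GazeSegment("P1", "map", 0, 100, "fixation", {"legend"}),
    GazeSegment("P1", "map", 100, 120, "saccade"),
    GazeSegment("P1", "map", 120, 300, "fixation", {"title"}),
    GazeSegment("P1", "map", 300, 350, "fixation", {"legend"}),
])
print(export_metrics_csv(compute_aoi_metrics(ds)))
print(transition_matrix(ds).to_csv())
```

prints

```
participant,stimulus,aoi,time_to_first_fixation_ms,fixation_count,avg_fixation_duration_ms,dwell_time_ms
P1,map,legend,0.000,2,75.000,150.000
P1,map,title,120.000,1,180.000,180.000

from\to,legend,title
legend,0,1
title,1,0
```

The `legend` AOI is fixated twice (at 0 ms and 300 ms) for 100 + 50 ms, so
TTFF is 0 ms from trial onset, dwell 150 ms, and the average fixation
75 ms; `title` is reached after 120 ms. The gaze moved `legend → title`
once and back once; the 20 ms saccade is rendered in scarf plots but
excluded from metrics and does not break the transition chain.

The same analysis from the shell, on a synthetic corpus:

```
scarfkit fixtures --seed 7 -o demo/
scarfkit metrics demo/recording_generic_long.csv -o metrics.csv
scarfkit scarf demo/recording_generic_long.csv --stimulus S01 \
    --mode relative -o scarf.svg
scarfkit transitions demo/recording_generic_long.csv --heatmap -o matrix.png
```

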