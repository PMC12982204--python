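"""Deterministic synthetic recordings for testing every other module.

The generator emulates event-level eye-tracker exports: each trial is an
alternating fixation/saccade train starting at t = 0 ms, with fixation AOI
assignment controlled by explicit probabilities for no-AOI fixations and
for overlapping (two-AOI) hits, and optional visibility windows for the
dynamic-AOI layer.  It deliberately covers the edge cases that make
parsing fragile in the wild: off-by-one boundaries (adjacent half-open
segments), overlapping AOI assignments, and integer-rounded timestamps.

Ground-truth AOI metrics are accumulated *during* generation, event by
event, independently of :mod:`scarfkit.aoi_metrics`, so comparing the two
is a genuine cross-check of independent computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .aoi_metrics import AoiMetricsRecord
from .core_model import (
    GLOBAL_SCOPE,
    GazeDataset,
    GazeSegment,
    ValidationError,
    VisibilityInterval,
    VisibilitySchedule,
    canonicalize,
)
from .formats_io import DIALECTS, write_dialect, write_visibility

__all__ = [
    "FixtureSpec",
    "generate",
    "random_cuts",
    "split_and_round",
    "write_dialect",
    "fixture_corpus",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic recording; the seed fixes everything."""

    n_participants: int = 5
    n_stimuli: int = 10
    n_aois: int = 4
    trial_duration_ms: float = 3000.0
    fixation_duration_range: tuple = (100.0, 400.0)
    saccade_duration_range: tuple = (20.0, 80.0)
    overlap_probability: float = 0.1
    no_aoi_probability: float = 0.1
    visibility_density: float = 0.5
    integer_ms: bool = False
    group_labels: tuple = ("expert", "novice")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_probability", "no_aoi_probability", "visibility_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("fixation_duration_range", "saccade_duration_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValidationError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if self.fixation_duration_range[0] > self.trial_duration_ms:
            raise ValidationError(
                "impossible spec: minimum fixation duration exceeds the trial duration"
            )
        if min(self.n_participants, self.n_stimuli, self.n_aois) < 1:
            raise ValidationError("need at least one participant, stimulus, and AOI")


def _round(x: float, integer: bool) -> float:
    return float(round(x)) if integer else x


def generate(spec: FixtureSpec) -> tuple[GazeDataset, list[AoiMetricsRecord]]:
    """Generate a canonical dataset plus by-construction ground truth.

    Every trial starts at 0 ms and alternates fixations and saccades until
    the trial duration is reached (the last event is clipped to it).  The
    returned metrics records are accumulated incrementally while events
    are emitted — not via :func:`scarfkit.aoi_metrics.compute_aoi_metrics`.
    """
    rng = np.random.default_rng(spec.seed)
    participants = [f"P{i + 1:02d}" for i in range(spec.n_participants)]
    stimuli = [f"S{i + 1:02d}" for i in range(spec.n_stimuli)]
    aois = [f"AOI_{chr(65 + i)}" if i < 26 else f"AOI_{i}" for i in range(spec.n_aois)]

    segments: list[GazeSegment] = []
    truth: dict[tuple, list] = {}  # (pid, stim, aoi) -> [ttff, count, dwell]

    for pid in participants:
        for stim in stimuli:
            t = 0.0
            fixation_next = True
            while t < spec.trial_duration_ms:
                lo, hi = (
                    spec.fixation_duration_range
                    if fixation_next
                    else spec.saccade_duration_range
                )
                dur = _round(float(rng.uniform(lo, hi)), spec.integer_ms)
                end = min(t + dur, spec.trial_duration_ms)
                if end - t < 1.0:
                    # never emit a sub-millisecond event at the trial clip;
                    # real event-level exports contain no such fixations
                    break
                if fixation_next:
                    hit: frozenset = frozenset()
                    if rng.random() >= spec.no_aoi_probability:
                        first = aois[int(rng.integers(spec.n_aois))]
                        chosen = {first}
                        if spec.n_aois > 1 and rng.random() < spec.overlap_probability:
                            second = first
                            while second == first:
                                second = aois[int(rng.integers(spec.n_aois))]
                            chosen.add(second)
                        hit = frozenset(chosen)
                    segments.append(GazeSegment(pid, stim, t, end, "fixation", hit))
                    for aoi in hit:
                        slot = truth.setdefault((pid, stim, aoi), [t, 0, 0.0])
                        slot[1] += 1
                        slot[2] += end - t
                else:
                    segments.append(GazeSegment(pid, stim, t, end, "saccade"))
                t = end
                fixation_next = not fixation_next

    visibility = _generate_visibility(spec, rng, participants, stimuli, aois)
    dataset = canonicalize(segments, visibility=visibility)
    labels = spec.group_labels
    if labels:
        dataset = dataset.with_groups(
            {pid: labels[i % len(labels)] for i, pid in enumerate(participants)}
        )
    records = [
        AoiMetricsRecord(pid, stim, aoi, ttff, count, dwell / count, dwell)
        for (pid, stim, aoi), (ttff, count, dwell) in sorted(truth.items())
    ]
    return dataset, records


def _generate_visibility(spec, rng, participants, stimuli, aois):
    if spec.visibility_density <= 0:
        return None
    intervals = []
    for stim in stimuli:
        for aoi in aois:
            if rng.random() < spec.visibility_density:
                a = float(rng.uniform(0, spec.trial_duration_ms * 0.5))
                b = float(rng.uniform(a + 1.0, spec.trial_duration_ms))
                intervals.append(VisibilityInterval(aoi, stim, a, b, GLOBAL_SCOPE))
                if rng.random() < spec.visibility_density / 2:
                    pid = participants[int(rng.integers(len(participants)))]
                    a2 = float(rng.uniform(0, spec.trial_duration_ms * 0.5))
                    b2 = float(rng.uniform(a2 + 1.0, spec.trial_duration_ms))
                    intervals.append(VisibilityInterval(aoi, stim, a2, b2, pid))
    return VisibilitySchedule(intervals) if intervals else None


def random_cuts(
    dataset: GazeDataset, seed: int = 0, max_cuts: int = 2
) -> dict[tuple[str, str], list]:
    """Random interior cut points per trial, for interval-split writes.

    Cuts are sampled from event boundaries: a presentation interval ends
    when the stimulus disappears, between events, so a single fixation
    never straddles two intervals (which is what keeps reconstructed
    fixation counts exact in interval-split exports).
    """
    rng = np.random.default_rng(seed)
    cuts = {}
    for (pid, stim), segs in dataset.trials():
        onset = min(s.start for s in segs)
        boundaries = sorted({s.start for s in segs} - {onset})
        k = min(int(rng.integers(0, max_cuts + 1)), len(boundaries))
        picked = rng.choice(len(boundaries), size=k, replace=False) if k else []
        cuts[(pid, stim)] = sorted(boundaries[int(i)] for i in picked)
    return cuts


def split_and_round(
    dataset: GazeDataset, cuts: dict[tuple[str, str], list]
) -> GazeDataset:
    """In-memory image of a tobii_like write: the expected parse result.

    Each trial is cut into presentation intervals, every piece's timestamps
    are rounded to whole milliseconds (pieces that round to zero length are
    dropped), and each interval becomes its own trial under the stimulus id
    ``"<stimulus>#<k>"`` — exactly the precision the tobii_like dialect
    documents.  ``parse(write_dialect(d, "tobii_like", cuts=c))`` equals
    ``split_and_round(d, c)``.
    """
    out: list[GazeSegment] = []
    for (pid, stim), segs in dataset.trials():
        onset = min(s.start for s in segs)
        end = max(s.end for s in segs)
        trial_cuts = sorted(c for c in cuts.get((pid, stim), ()) if onset < c < end)
        bounds = [onset, *trial_cuts, end]
        for k in range(len(bounds) - 1):
            for seg in segs:
                piece = seg.clipped(bounds[k], bounds[k + 1])
                if piece is None:
                    continue
                a, b = float(round(piece.start)), float(round(piece.end))
                if b <= a:
                    continue
                out.append(
                    GazeSegment(pid, f"{stim}#{k + 1}", a, b, seg.category, seg.aoi_ids)
                )
    return canonicalize(out)


def fixture_corpus(directory, spec: FixtureSpec = FixtureSpec()) -> dict[str, str]:
    """Write a complete fixture corpus (all dialects + visibility files).

    Returns a mapping of logical name to the file path written.  The
    generic_interval file is a documented lossy write (saccades dropped);
    the tobii_like file uses seed-derived interval cuts.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate(spec)
    paths = {}
    for dialect in DIALECTS:
        ext = "tsv" if DIALECTS[dialect].delimiter == "\t" else "csv"
        p = directory / f"recording_{dialect}.{ext}"
        if dialect == "tobii_like":
            write_dialect(dataset, dialect, p, cuts=random_cuts(dataset, spec.seed))
        elif dialect == "generic_interval":
            write_dialect(dataset, dialect, p, strict=False)
        else:
            write_dialect(dataset, dialect, p)
        paths[dialect] = str(p)
    if dataset.visibility is not None:
        p = directory / "aoi_visibility_global.csv"
        write_visibility(dataset.visibility, p, scope=GLOBAL_SCOPE)
        paths["visibility_global"] = str(p)
        for scope in sorted({iv.scope for iv in dataset.visibility.intervals}):
            if scope == GLOBAL_SCOPE:
                continue
            p = directory / f"aoi_visibility_{scope}.csv"
            write_visibility(dataset.visibility, p, scope=scope)
            paths[f"visibility_{scope}"] = str(p)
    from .render_export import export_metrics_csv

    p = directory / "ground_truth_metrics.csv"
    export_metrics_csv(truth, p)
    paths["ground_truth"] = str(p)
    return paths
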