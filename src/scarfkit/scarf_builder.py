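"""Resolution-independent scarf-plot geometry.

A scarf plot stacks one row per participant; within a row, coloured
rectangles encode the AOI attended over time.  The builder produces pure
geometry (x-ranges, sub-band indices, colours, hover metadata) under one of
three timeline modes:

* **absolute** — x in milliseconds from trial onset;
* **relative** — x normalised to 0..100 % of the trial's duration;
* **ordinal**  — each segment occupies one unit of x, encoding order only.

A segment hitting *k* overlapping AOIs either renders as *k* equally tall
stacked sub-band rectangles (``split_overlaps=True``) or as a single
rectangle in a reserved overlap colour.  When a visibility schedule is
attached, per-AOI visibility bands are appended below each row, honouring
the participant-over-global override rule.  Every rectangle carries the
original absolute time range and duration regardless of mode, so hover
metadata survives projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .core_model import GazeDataset, GazeSegment, ValidationError

__all__ = [
    "TIMELINE_MODES",
    "OVERLAP_COLOR",
    "NO_AOI_COLOR",
    "SACCADE_COLOR",
    "OTHER_COLOR",
    "ScarfRect",
    "ScarfRow",
    "ScarfGeometry",
    "project_segment",
    "build_scarf",
    "legend",
]

TIMELINE_MODES = ("absolute", "relative", "ordinal")

OVERLAP_COLOR = "#7b7b7b"
NO_AOI_COLOR = "#d9d9d9"
SACCADE_COLOR = "#3b3b3b"
OTHER_COLOR = "#efefef"


@dataclass(frozen=True)
class ScarfRect:
    """One rectangle of scarf geometry with its hover metadata."""

    x0: float
    x1: float
    sub_band: int
    color: str
    label: str  # AOI display name or style-class name
    category: str
    t0_ms: float  # original absolute time range, mode-independent
    t1_ms: float

    @property
    def duration_ms(self) -> float:
        return self.t1_ms - self.t0_ms


@dataclass(frozen=True)
class ScarfRow:
    participant_id: str
    rects: tuple
    #: ``(aoi_id, rects)`` pairs, one per scheduled AOI, registry order.
    visibility: tuple = ()

    @property
    def n_sub_bands(self) -> int:
        return max((r.sub_band + 1 for r in self.rects), default=1)


@dataclass(frozen=True)
class ScarfGeometry:
    mode: str
    stimulus_id: str
    rows: tuple
    domain: tuple  # (0, max ms) | (0, 100) | (0, max segment count)

    def iter_rects(self) -> Iterator[ScarfRect]:
        for row in self.rows:
            yield from row.rects

    def to_jsonable(self) -> dict:
        return {
            "mode": self.mode,
            "stimulus_id": self.stimulus_id,
            "domain": list(self.domain),
            "rows": [
                {
                    "participant_id": row.participant_id,
                    "rects": [{**vars(r), "duration_ms": r.duration_ms} for r in row.rects],
                    "visibility": [
                        {"aoi_id": aoi, "rects": [{**vars(r), "duration_ms": r.duration_ms} for r in rects]}
                        for aoi, rects in row.visibility
                    ],
                }
                for row in self.rows
            ],
        }


def project_segment(
    segment: GazeSegment, mode: str, trial_context: tuple[float, float, int]
) -> tuple[float, float]:
    """Project one segment onto the x-axis of the chosen timeline mode.

    ``trial_context`` is ``(onset, trial_end, ordinal_index)``.  Absolute
    mode subtracts the onset; relative mode linearly maps the trial to
    0..100; ordinal mode gives the segment a unit-width slot at its index.
    """
    onset, trial_end, index = trial_context
    if mode == "absolute":
        return segment.start - onset, segment.end - onset
    if mode == "relative":
        span = trial_end - onset
        if span <= 0:
            raise ValidationError(
                f"degenerate trial (zero duration) for participant "
                f"{segment.participant_id!r}: relative mode undefined"
            )
        return (
            100.0 * (segment.start - onset) / span,
            100.0 * (segment.end - onset) / span,
        )
    if mode == "ordinal":
        return float(index), float(index + 1)
    raise ValidationError(f"unknown timeline mode {mode!r}; valid: {TIMELINE_MODES}")


def _segment_style(dataset: GazeDataset, seg: GazeSegment, split: bool):
    """Yield ``(sub_band, color, label)`` for one segment."""
    if seg.category == "saccade":
        yield 0, SACCADE_COLOR, "saccade"
        return
    if seg.category == "other":
        yield 0, OTHER_COLOR, "other"
        return
    aois = sorted(dataset.resolved_aoi_ids(seg), key=dataset.aoi_index)
    if not aois:
        yield 0, NO_AOI_COLOR, "no AOI"
    elif len(aois) == 1 or split:
        for i, aoi in enumerate(aois):
            a = dataset.aois[aoi]
            yield i, a.color, a.display_name
    else:
        yield 0, OVERLAP_COLOR, " + ".join(
            dataset.aois[a].display_name for a in aois
        )


def build_scarf(
    dataset: GazeDataset,
    mode: str = "absolute",
    *,
    stimulus_id: str | None = None,
    show_visibility: bool = False,
    split_overlaps: bool = True,
    ordinal_fixations_only: bool = False,
) -> ScarfGeometry:
    """Build scarf geometry for one stimulus of a dataset view.

    One row per participant (registry order) that has a trial for the
    stimulus.  ``ordinal_fixations_only`` restricts ordinal slots to
    fixations; by default every rendered segment occupies one unit.
    Visibility bands require a time axis and are rejected in ordinal mode.
    """
    if mode not in TIMELINE_MODES:
        raise ValidationError(f"unknown timeline mode {mode!r}; valid: {TIMELINE_MODES}")
    if stimulus_id is None:
        if len(dataset.stimuli) != 1:
            raise ValidationError(
                f"dataset view has stimuli {list(dataset.stimuli)}; "
                "pass stimulus_id= or filter to one stimulus"
            )
        stimulus_id = dataset.stimuli[0]
    elif stimulus_id not in dataset.stimuli:
        raise ValidationError(
            f"unknown stimulus {stimulus_id!r}; valid: {list(dataset.stimuli)}"
        )
    if show_visibility and mode == "ordinal":
        raise ValidationError("visibility bands need a time axis; use absolute or relative mode")

    trials = {
        key[0]: segs for key, segs in dataset.trials() if key[1] == stimulus_id
    }
    if mode == "relative":
        degenerate = [
            p
            for p, segs in trials.items()
            if max(s.end for s in segs) <= min(s.start for s in segs)
        ]
        if degenerate:
            raise ValidationError(
                f"degenerate trial(s) for participants {degenerate}: "
                "relative mode undefined"
            )

    schedule = dataset.visibility
    scheduled = (
        [a for a in schedule.scheduled_aois(stimulus_id) if a in dataset.aois]
        if (show_visibility and schedule is not None)
        else []
    )

    rows = []
    for pid in dataset.participants:
        segs = trials.get(pid)
        if not segs:
            continue
        onset = min(s.start for s in segs)
        trial_end = max(s.end for s in segs)
        rects = []
        ordinal = 0
        for seg in segs:
            if (
                mode == "ordinal"
                and ordinal_fixations_only
                and seg.category != "fixation"
            ):
                continue
            x0, x1 = project_segment(seg, mode, (onset, trial_end, ordinal))
            ordinal += 1
            for sub, color, label in _segment_style(dataset, seg, split_overlaps):
                rects.append(
                    ScarfRect(x0, x1, sub, color, label, seg.category, seg.start, seg.end)
                )

        vis_bands = []
        for aoi in scheduled:
            spans = schedule.intervals_for(aoi, pid, stimulus_id, (onset, trial_end))
            band = []
            for a, b in spans:
                vseg = GazeSegment(pid, stimulus_id, a, b, "other")
                x0, x1 = project_segment(vseg, mode, (onset, trial_end, 0))
                band.append(
                    ScarfRect(
                        x0, x1, 0, dataset.aois[aoi].color,
                        dataset.aois[aoi].display_name, "visibility", a, b,
                    )
                )
            vis_bands.append((aoi, tuple(band)))
        rows.append(ScarfRow(pid, tuple(rects), tuple(vis_bands)))

    if mode == "relative":
        domain = (0.0, 100.0)
    elif mode == "ordinal":
        domain = (0.0, float(max((row.rects[-1].x1 for row in rows if row.rects), default=0.0)))
    else:
        domain = (
            0.0,
            max(
                (
                    max(s.end for s in segs) - min(s.start for s in segs)
                    for segs in trials.values()
                ),
                default=0.0,
            ),
        )
    return ScarfGeometry(mode=mode, stimulus_id=stimulus_id, rows=tuple(rows), domain=domain)


def legend(dataset: GazeDataset, *, stimulus_id: str | None = None) -> list[tuple[str, str, str]]:
    """Stable legend entries ``(display name, color, style class)``.

    Merge-resolved AOIs that occur in the view come first in registry
    order; reserved style classes (no-AOI, saccade, other) follow, included
    only when present in the view.
    """
    segs = [
        s
        for s in dataset.segments
        if stimulus_id is None or s.stimulus_id == stimulus_id
    ]
    present = {a for s in segs for a in dataset.resolved_aoi_ids(s)}
    entries = [
        (a.display_name, a.color, "aoi")
        for a in dataset.effective_aois()
        if a.aoi_id in present
    ]
    if any(s.category == "fixation" and not s.aoi_ids for s in segs):
        entries.append(("no AOI", NO_AOI_COLOR, "no_aoi"))
    if any(s.category == "saccade" for s in segs):
        entries.append(("saccade", SACCADE_COLOR, "saccade"))
    if any(s.category == "other" for s in segs):
        entries.append(("other", OTHER_COLOR, "other"))
    return entries
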