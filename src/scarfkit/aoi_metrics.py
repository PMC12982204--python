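"""AOI-level fixation metrics.

Per (participant, stimulus, AOI) the four standard metrics are computed
from fixation-category segments only:

* **time to first fixation (TTFF)** — latency from trial onset (the minimum
  start over *all* of the trial's events) to the start of the first fixation
  hitting the AOI; absent when the AOI is never fixated;
* **fixation count** — number of fixations hitting the AOI;
* **average fixation duration** — dwell / count; absent when count is 0;
* **dwell time** — summed duration of fixations hitting the AOI.

A fixation hitting *k* overlapping AOIs contributes its full duration (and
one count) to each of them — overlap is a set on one segment, so nothing is
double-counted within a single AOI.

Two further operations support vendor exports that slice one recording into
several presentation intervals: :func:`reconstruct_interval_metrics` unifies
per-interval records into one value per AOI-participant pair, and
:func:`metrics_oracle` provides an independent brute-force check by
rasterizing trials into fixed-resolution cells.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import GazeDataset, ValidationError

__all__ = [
    "AoiMetricsRecord",
    "BarSummary",
    "compute_aoi_metrics",
    "reconstruct_interval_metrics",
    "unify_split_trials",
    "metrics_oracle",
    "summarize_by_group",
]


@dataclass(frozen=True)
class AoiMetricsRecord:
    participant_id: str
    stimulus_id: str
    aoi_id: str
    time_to_first_fixation: float | None
    fixation_count: int
    avg_fixation_duration: float | None
    dwell_time: float

    def __post_init__(self) -> None:
        absent = self.fixation_count == 0
        if absent != (self.time_to_first_fixation is None) or absent != (
            self.avg_fixation_duration is None
        ):
            raise ValidationError(
                "fixation_count == 0 must coincide with absent TTFF and "
                f"absent average duration (got {self})"
            )


def _record_order(dataset: GazeDataset):
    aoi_pos = {k: i for i, k in enumerate(dataset.aois)}
    part_pos = {k: i for i, k in enumerate(dataset.participants)}
    stim_pos = {k: i for i, k in enumerate(dataset.stimuli)}

    def key(r: AoiMetricsRecord):
        return (
            part_pos.get(r.participant_id, len(part_pos)),
            stim_pos.get(r.stimulus_id, len(stim_pos)),
            aoi_pos.get(r.aoi_id, len(aoi_pos)),
        )

    return key


def compute_aoi_metrics(
    dataset: GazeDataset, *, include_zero: bool = False
) -> list[AoiMetricsRecord]:
    """Compute the four AOI metrics for every trial in the dataset view.

    Records are emitted for every (participant, stimulus, AOI) with at
    least one fixation; ``include_zero=True`` adds zero-count records for
    registered AOIs that were never fixated in a trial (TTFF and average
    duration absent, dwell 0).  AOI ids are merge-resolved, so a merged AOI
    reports the union of its members.
    """
    acc: dict[tuple[str, str, str], list] = {}  # -> [ttff, count, dwell]
    trial_keys = []
    for (pid, stim), segs in dataset.trials():
        trial_keys.append((pid, stim))
        onset = min(s.start for s in segs)
        for seg in segs:
            if seg.category != "fixation":
                continue
            for aoi in dataset.resolved_aoi_ids(seg):
                slot = acc.setdefault((pid, stim, aoi), [math.inf, 0, 0.0])
                slot[0] = min(slot[0], seg.start - onset)
                slot[1] += 1
                slot[2] += seg.duration

    records = [
        AoiMetricsRecord(pid, stim, aoi, ttff, count, dwell / count, dwell)
        for (pid, stim, aoi), (ttff, count, dwell) in acc.items()
    ]
    if include_zero:
        effective = [a.aoi_id for a in dataset.effective_aois()]
        for pid, stim in trial_keys:
            for aoi in effective:
                if (pid, stim, aoi) not in acc:
                    records.append(AoiMetricsRecord(pid, stim, aoi, None, 0, None, 0.0))
    records.sort(key=_record_order(dataset))
    return records


def reconstruct_interval_metrics(
    records: Sequence[AoiMetricsRecord],
    offsets: Sequence[float],
    *,
    stimulus_id: str | None = None,
) -> AoiMetricsRecord:
    """Unify per-interval metrics into one AOI-participant record.

    ``offsets[i]`` is interval *i*'s onset relative to the unified trial
    onset, so the unified TTFF is ``min_i(offset_i + ttff_i)``; counts and
    dwell add, and the average re-weights by count.  All records must share
    the participant and AOI; ``stimulus_id`` names the unified stimulus
    (default: the first record's).
    """
    if not records:
        raise ValidationError("reconstruct_interval_metrics: empty input")
    if len(offsets) != len(records):
        raise ValidationError(
            f"got {len(records)} records but {len(offsets)} offsets"
        )
    pid, aoi = records[0].participant_id, records[0].aoi_id
    for r in records:
        if (r.participant_id, r.aoi_id) != (pid, aoi):
            raise ValidationError(
                f"mismatched keys: ({r.participant_id}, {r.aoi_id}) vs ({pid}, {aoi})"
            )
    count = sum(r.fixation_count for r in records)
    dwell = sum(r.dwell_time for r in records)
    ttff_candidates = [
        off + r.time_to_first_fixation
        for off, r in zip(offsets, records)
        if r.time_to_first_fixation is not None
    ]
    ttff = min(ttff_candidates) if ttff_candidates else None
    avg = (
        sum(r.avg_fixation_duration * r.fixation_count for r in records if r.fixation_count)
        / count
        if count
        else None
    )
    return AoiMetricsRecord(
        pid,
        stimulus_id if stimulus_id is not None else records[0].stimulus_id,
        aoi,
        ttff,
        count,
        avg,
        dwell,
    )


def unify_split_trials(dataset: GazeDataset) -> list[AoiMetricsRecord]:
    """Metrics for interval-split exports, reconstructed per base stimulus.

    For datasets parsed from interval-split dialects (trials named
    ``"<stimulus>#<k>"``), computes per-interval metrics, derives each
    interval's onset offset from the data (interval onset minus the
    earliest onset across the stimulus' intervals), and unifies records via
    :func:`reconstruct_interval_metrics`.  Trials without an interval
    suffix pass through unchanged.
    """
    from .formats_io import split_stimulus_interval

    onsets: dict[tuple[str, str], float] = {}
    for (pid, stim), segs in dataset.trials():
        onsets[(pid, stim)] = min(s.start for s in segs)
    base_onset: dict[tuple[str, str], float] = {}
    for (pid, stim), onset in onsets.items():
        base, k = split_stimulus_interval(stim)
        key = (pid, base)
        base_onset[key] = min(base_onset.get(key, math.inf), onset)

    grouped: dict[tuple[str, str, str], list] = defaultdict(list)
    for r in compute_aoi_metrics(dataset):
        base, k = split_stimulus_interval(r.stimulus_id)
        offset = onsets[(r.participant_id, r.stimulus_id)] - base_onset[(r.participant_id, base)]
        grouped[(r.participant_id, base, r.aoi_id)].append((offset, r))

    out = []
    for (pid, base, aoi), items in grouped.items():
        items.sort(key=lambda x: x[0])
        out.append(
            reconstruct_interval_metrics(
                [r for _, r in items], [o for o, _ in items], stimulus_id=base
            )
        )
    out.sort(key=lambda r: (r.participant_id, r.stimulus_id, r.aoi_id))
    return out


def metrics_oracle(dataset: GazeDataset, resolution: float = 1.0) -> list[AoiMetricsRecord]:
    """Brute-force metrics by rasterizing each trial into fixed cells.

    The trial ``[onset, end)`` is divided into cells of ``resolution`` ms;
    cell *i* belongs to the fixation whose interval covers the cell's start
    time.  Dwell is cells x resolution, TTFF the first owning cell's start,
    and the count the number of distinct fixations owning at least one
    cell.  With integer boundaries at 1 ms resolution this reproduces the
    analytic metrics exactly; otherwise it deviates by at most one cell.
    """
    if resolution <= 0:
        raise ValidationError(f"resolution must be > 0, got {resolution}")
    records = []
    for (pid, stim), segs in dataset.trials():
        onset = min(s.start for s in segs)
        n_cells = math.ceil((max(s.end for s in segs) - onset) / resolution - 1e-12)
        # owner[i] = index of the fixation covering cell i's start time
        # (same-category segments never overlap, so ownership is unique)
        owner = np.full(n_cells, -1, dtype=np.int64)
        fixations = [s for s in segs if s.category == "fixation"]
        for idx, seg in enumerate(fixations):
            i0 = math.ceil((seg.start - onset) / resolution - 1e-12)
            i1 = math.ceil((seg.end - onset) / resolution - 1e-12)
            owner[i0:i1] = idx
        aois = sorted({a for s in fixations for a in dataset.resolved_aoi_ids(s)})
        for aoi in aois:
            hitters = np.array(
                [i for i, s in enumerate(fixations) if aoi in dataset.resolved_aoi_ids(s)]
            )
            cells = np.isin(owner, hitters)
            n_hit = int(cells.sum())
            if n_hit == 0:
                continue
            count = len(np.unique(owner[cells]))
            dwell = n_hit * resolution
            ttff = float(np.argmax(cells)) * resolution
            records.append(
                AoiMetricsRecord(pid, stim, aoi, ttff, count, dwell / count, dwell)
            )
    records.sort(key=_record_order(dataset))
    return records


# ---------------------------------------------------------------------------
# Aggregate (bar-plot) summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarSummary:
    """Per-(group, AOI) means of the three aggregate metrics.

    ``rows`` maps ``(group_label, aoi_id)`` to ``(mean dwell ms, mean
    fixation count, mean TTFF ms | None)``; the TTFF mean is taken over the
    participants that fixated the AOI at all.
    """

    groups: tuple
    aois: tuple
    rows: dict


def summarize_by_group(dataset: GazeDataset, *, include_zero: bool = True) -> BarSummary:
    """Aggregate AOI metrics across participants within each group.

    Participants without a group label form the ``"(ungrouped)"`` group.
    Dwell and count average over all of a group's trials (zero when the AOI
    was not fixated, so exposure differences show); TTFF averages only over
    trials where the AOI was fixated.
    """
    records = compute_aoi_metrics(dataset, include_zero=include_zero)
    group_of = {
        pid: (p.group_label or "(ungrouped)") for pid, p in dataset.participants.items()
    }
    dwell: dict[tuple[str, str], list] = defaultdict(list)
    counts: dict[tuple[str, str], list] = defaultdict(list)
    ttff: dict[tuple[str, str], list] = defaultdict(list)
    for r in records:
        key = (group_of.get(r.participant_id, "(ungrouped)"), r.aoi_id)
        dwell[key].append(r.dwell_time)
        counts[key].append(r.fixation_count)
        if r.time_to_first_fixation is not None:
            ttff[key].append(r.time_to_first_fixation)

    groups = tuple(dict.fromkeys(group_of[p] for p in dataset.participants))
    aois = tuple(a.aoi_id for a in dataset.effective_aois())
    rows = {}
    for g in groups:
        for a in aois:
            key = (g, a)
            if key not in dwell:
                continue
            n = len(dwell[key])
            rows[key] = (
                sum(dwell[key]) / n,
                sum(counts[key]) / n,
                (sum(ttff[key]) / len(ttff[key])) if ttff[key] else None,
            )
    return BarSummary(groups=groups, aois=aois, rows=rows)
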