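"""Canonical domain model for AOI-sequence data.

The atom of every analysis is a :class:`GazeSegment`: one timestamped
eye-movement event (fixation, saccade, or other) on one participant/stimulus
trial, carrying the *set* of AOIs it hits.  Segments live on a half-open
millisecond timeline ``[start, end)`` so that adjacent events (a fixation
ending exactly where a saccade begins) never overlap and duration sums are
exact.  A :class:`GazeDataset` is an ordered, validated collection of
segments together with AOI / participant / stimulus registries.

Editing operations (AOI merging, filtering) are non-destructive: they return
a new dataset *view* that shares the underlying segments, so every edit is
reversible and the original data can always be recovered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "CATEGORIES",
    "DEFAULT_PALETTE",
    "ValidationError",
    "GazeSegment",
    "AoiDefinition",
    "ParticipantRecord",
    "ParseMetadata",
    "ViewFilter",
    "VisibilityInterval",
    "VisibilitySchedule",
    "GazeDataset",
    "canonicalize",
    "merge_aois",
    "unmerge_aois",
    "apply_filter",
]

#: Recognised event categories.  Everything that is neither a fixation nor a
#: saccade (blinks, unclassified samples, vendor-specific events) maps to
#: ``"other"`` at parse time.
CATEGORIES = ("fixation", "saccade", "other")

#: Fixed 12-colour categorical palette assigned to AOIs at registration
#: order; individual AOIs can be recoloured afterwards.
DEFAULT_PALETTE = (
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f", "#edc948",
    "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac", "#1170aa", "#a3cce9",
)

_HEX_DIGITS = set("0123456789abcdefABCDEF")


class ValidationError(ValueError):
    """Raised when input data violate the canonical dataset invariants."""


def _check_color(color: str) -> str:
    if (
        not isinstance(color, str)
        or len(color) != 7
        or color[0] != "#"
        or any(c not in _HEX_DIGITS for c in color[1:])
    ):
        raise ValidationError(f"invalid colour {color!r}: expected 6-digit hex like '#4e79a7'")
    return color


@dataclass(frozen=True)
class GazeSegment:
    """One eye-movement event with its AOI hits.

    ``aoi_ids`` may be empty ("no AOI hit") or contain several AOIs when
    regions overlap on the stimulus; overlapping hits are a *set* on one
    segment, never duplicated rows, so dwell sums never double-count.
    """

    participant_id: str
    stimulus_id: str
    start: float
    end: float
    category: str
    aoi_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "aoi_ids", frozenset(self.aoi_ids))
        object.__setattr__(self, "start", float(self.start))
        object.__setattr__(self, "end", float(self.end))

    @property
    def duration(self) -> float:
        return self.end - self.start

    def clipped(self, t0: float, t1: float) -> "GazeSegment | None":
        """Intersection with ``[t0, t1)``; ``None`` if empty."""
        a, b = max(self.start, t0), min(self.end, t1)
        if b <= a:
            return None
        if a == self.start and b == self.end:
            return self
        return replace(self, start=a, end=b)


@dataclass
class AoiDefinition:
    """AOI registry entry.

    ``merged_into`` is a non-destructive merge pointer: when set, every
    occurrence of this AOI resolves to the target for display and metrics,
    while the underlying segments keep the original id.  Pointers form a
    forest (cycles are rejected), so merges nest and unmerge exactly.
    """

    aoi_id: str
    display_name: str
    color: str
    merged_into: str | None = None
    #: True for merge targets created on the fly; dropped again on unmerge.
    synthetic: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        _check_color(self.color)


@dataclass
class ParticipantRecord:
    participant_id: str
    display_name: str
    group_label: str | None = None


@dataclass
class ParseMetadata:
    """Provenance of a parsed file, kept with the dataset and the session."""

    source_filename: str = "<memory>"
    detected_dialect: str = "canonical"
    file_size_bytes: int = 0
    parse_duration_ms: float = 0.0
    tool_version: str = ""
    skipped_rows: int = 0
    duplicate_rows: int = 0
    max_carry_bytes: int = 0

    def __post_init__(self) -> None:
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__


@dataclass(frozen=True)
class ViewFilter:
    """Composable, non-destructive dataset filter (intersection semantics).

    ``time_range`` is a half-open ``[t0, t1)`` window on the segment
    timeline (milliseconds); partially overlapping segments are clipped at
    its bounds, not dropped.
    """

    stimulus_id: str | None = None
    group_label: str | None = None
    aoi_ids: frozenset | None = None
    time_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.aoi_ids is not None:
            object.__setattr__(self, "aoi_ids", frozenset(self.aoi_ids))
        if self.time_range is not None:
            t0, t1 = self.time_range
            if not t1 > t0:
                raise ValidationError(f"time_range must satisfy t1 > t0, got [{t0}, {t1})")
            object.__setattr__(self, "time_range", (float(t0), float(t1)))

    @property
    def is_empty(self) -> bool:
        return (
            self.stimulus_id is None
            and self.group_label is None
            and self.aoi_ids is None
            and self.time_range is None
        )


# ---------------------------------------------------------------------------
# Visibility schedules (dynamic AOIs)
# ---------------------------------------------------------------------------

#: Scope constant for intervals that apply to every participant.
GLOBAL_SCOPE = "global"


@dataclass(frozen=True)
class VisibilityInterval:
    """One half-open interval during which a dynamic AOI is visible."""

    aoi_id: str
    stimulus_id: str
    start: float
    end: float
    scope: str = GLOBAL_SCOPE  # "global" or a participant id

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValidationError(
                f"visibility interval for AOI {self.aoi_id!r} has end <= start "
                f"([{self.start}, {self.end}))"
            )


def _merge_spans(spans: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(spans):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


@dataclass
class VisibilitySchedule:
    """Per-AOI visibility intervals, global or per participant.

    Participant-scoped intervals *override* the global schedule for that
    participant entirely.  An AOI with no intervals at all (under either
    scope) defaults to always visible, so the visibility query is total.
    """

    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = self._normalized(self.intervals)

    @staticmethod
    def _normalized(intervals: Iterable[VisibilityInterval]) -> list:
        by_key: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
        for iv in intervals:
            by_key.setdefault((iv.aoi_id, iv.stimulus_id, iv.scope), []).append(
                (iv.start, iv.end)
            )
        out = []
        for (aoi, stim, scope), spans in sorted(by_key.items()):
            for a, b in _merge_spans(spans):
                out.append(VisibilityInterval(aoi, stim, a, b, scope))
        return out

    def merged_with(self, other: "VisibilitySchedule") -> "VisibilitySchedule":
        return VisibilitySchedule(self.intervals + other.intervals)

    def _spans(self, aoi_id: str, stimulus_id: str, participant_id: str | None):
        """Effective spans for (aoi, stimulus, participant); None = no schedule."""
        part = [
            (iv.start, iv.end)
            for iv in self.intervals
            if iv.aoi_id == aoi_id
            and iv.stimulus_id == stimulus_id
            and iv.scope == participant_id
        ]
        if part:
            return part
        glob = [
            (iv.start, iv.end)
            for iv in self.intervals
            if iv.aoi_id == aoi_id
            and iv.stimulus_id == stimulus_id
            and iv.scope == GLOBAL_SCOPE
        ]
        if glob:
            return glob
        # Scheduled only for *other* participants (or not at all): the
        # always-visible default applies to this participant.
        return None

    def visible(self, aoi_id: str, participant_id: str, t: float, stimulus_id: str) -> bool:
        spans = self._spans(aoi_id, stimulus_id, participant_id)
        if spans is None:
            return True
        return any(a <= t < b for a, b in spans)

    def scheduled_aois(self, stimulus_id: str) -> list[str]:
        """AOIs with any interval for this stimulus, in first-seen order."""
        seen: dict[str, None] = {}
        for iv in self.intervals:
            if iv.stimulus_id == stimulus_id:
                seen.setdefault(iv.aoi_id)
        return list(seen)

    def intervals_for(
        self,
        aoi_id: str,
        participant_id: str,
        stimulus_id: str,
        trial: tuple[float, float],
    ) -> list[tuple[float, float]]:
        """Visible spans clipped to the trial window; whole trial if unscheduled."""
        spans = self._spans(aoi_id, stimulus_id, participant_id)
        if spans is None:
            return [trial]
        t0, t1 = trial
        out = []
        for a, b in _merge_spans(spans):
            a, b = max(a, t0), min(b, t1)
            if b > a:
                out.append((a, b))
        return out


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class GazeDataset:
    """Canonical, ordered AOI-sequence dataset.

    Segments are sorted by ``(participant, stimulus, start, end)``; within a
    trial, same-category segments never overlap.  Equality compares the
    queryable content (segments and registries) but not parse provenance.
    """

    segments: tuple = ()
    aois: dict = field(default_factory=dict)
    participants: dict = field(default_factory=dict)
    stimuli: tuple = ()
    visibility: VisibilitySchedule | None = None
    meta: ParseMetadata = field(default_factory=ParseMetadata, compare=False)

    # -- registry helpers ---------------------------------------------------

    def resolve_aoi(self, aoi_id: str) -> str:
        """Follow merge pointers to the effective AOI id."""
        seen = set()
        while aoi_id in self.aois and self.aois[aoi_id].merged_into is not None:
            if aoi_id in seen:
                raise ValidationError(f"AOI merge pointers contain a cycle at {aoi_id!r}")
            seen.add(aoi_id)
            aoi_id = self.aois[aoi_id].merged_into
        return aoi_id

    def resolved_aoi_ids(self, segment: GazeSegment) -> frozenset:
        return frozenset(self.resolve_aoi(a) for a in segment.aoi_ids)

    def effective_aois(self) -> list[AoiDefinition]:
        """Registry entries that are merge roots, in registration order."""
        return [a for a in self.aois.values() if a.merged_into is None]

    def aoi_index(self, aoi_id: str) -> int:
        """Registration index of an AOI (used for deterministic tie-breaks)."""
        for i, k in enumerate(self.aois):
            if k == aoi_id:
                return i
        raise KeyError(aoi_id)

    # -- trial helpers ------------------------------------------------------

    def trials(self) -> Iterator[tuple[tuple[str, str], list]]:
        """Yield ``((participant, stimulus), segments)`` in canonical order."""
        key = None
        bucket: list = []
        for seg in self.segments:
            k = (seg.participant_id, seg.stimulus_id)
            if k != key:
                if bucket:
                    yield key, bucket
                key, bucket = k, []
            bucket.append(seg)
        if bucket:
            yield key, bucket

    def trial_bounds(self, participant_id: str, stimulus_id: str) -> tuple[float, float]:
        """``(onset, end)`` = min start / max end over the trial's segments."""
        segs = [
            s
            for s in self.segments
            if s.participant_id == participant_id and s.stimulus_id == stimulus_id
        ]
        if not segs:
            raise KeyError((participant_id, stimulus_id))
        return min(s.start for s in segs), max(s.end for s in segs)

    def stimuli_of(self, participant_id: str) -> list[str]:
        return [
            s
            for s in self.stimuli
            if any(
                g.participant_id == participant_id and g.stimulus_id == s
                for g in self.segments
            )
        ]

    # -- mutation-free rebuilds ---------------------------------------------

    def with_visibility(self, schedule: VisibilitySchedule | None) -> "GazeDataset":
        return replace(self, visibility=schedule)

    def with_groups(self, groups: Mapping[str, str | None]) -> "GazeDataset":
        """Assign participant group labels (non-destructive)."""
        parts = dict(self.participants)
        for pid, label in groups.items():
            if pid not in parts:
                raise ValidationError(
                    f"unknown participant {pid!r}; known: {sorted(parts)}"
                )
            parts[pid] = replace(parts[pid], group_label=label)
        return replace(self, participants=parts)

    def recolor_aoi(self, aoi_id: str, color: str) -> "GazeDataset":
        if aoi_id not in self.aois:
            raise ValidationError(f"unknown AOI {aoi_id!r}; known: {sorted(self.aois)}")
        aois = dict(self.aois)
        aois[aoi_id] = replace(aois[aoi_id], color=_check_color(color))
        return replace(self, aois=aois)

    def rename_stimulus(self, stimulus_id: str, new_id: str) -> "GazeDataset":
        if stimulus_id not in self.stimuli:
            raise ValidationError(f"unknown stimulus {stimulus_id!r}")
        segs = tuple(
            replace(s, stimulus_id=new_id) if s.stimulus_id == stimulus_id else s
            for s in self.segments
        )
        stimuli = tuple(new_id if s == stimulus_id else s for s in self.stimuli)
        vis = self.visibility
        if vis is not None:
            vis = VisibilitySchedule(
                [
                    replace(iv, stimulus_id=new_id)
                    if iv.stimulus_id == stimulus_id
                    else iv
                    for iv in vis.intervals
                ]
            )
        return replace(self, segments=segs, stimuli=stimuli, visibility=vis)


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------


def _sort_key(seg: GazeSegment):
    return (seg.participant_id, seg.stimulus_id, seg.start, seg.end, seg.category)


def canonicalize(
    raw_segments: Iterable[GazeSegment],
    aois: Mapping[str, AoiDefinition] | None = None,
    participants: Mapping[str, ParticipantRecord] | None = None,
    stimuli: Sequence[str] | None = None,
    *,
    strict: bool = False,
    visibility: VisibilitySchedule | None = None,
    meta: ParseMetadata | None = None,
) -> GazeDataset:
    """Build a validated :class:`GazeDataset` from raw segments.

    Segments are sorted, exact duplicates collapsed, and missing registry
    entries auto-registered (participants and stimuli always; AOIs only in
    lenient mode -- ``strict=True`` rejects AOI references that are absent
    from the supplied registry).  Zero- or negative-duration segments and
    unknown categories are validation errors naming the offending entry.
    """
    segs = list(raw_segments)
    for i, seg in enumerate(segs):
        if not isinstance(seg, GazeSegment):
            raise ValidationError(f"segment {i}: expected GazeSegment, got {type(seg).__name__}")
        if seg.category not in CATEGORIES:
            raise ValidationError(
                f"segment {i}: category {seg.category!r} not in {CATEGORIES}"
            )
        if not seg.end > seg.start:
            raise ValidationError(
                f"segment {i}: zero or negative duration [{seg.start}, {seg.end}) "
                f"(half-open intervals require end > start)"
            )
        if not (math.isfinite(seg.start) and math.isfinite(seg.end)) or seg.start < 0:
            raise ValidationError(f"segment {i}: non-finite or negative timestamps")

    segs.sort(key=_sort_key)
    deduped: list[GazeSegment] = []
    for seg in segs:
        if deduped and seg == deduped[-1]:
            continue
        deduped.append(seg)

    # same-category overlap check within each trial
    last_end: dict[tuple[str, str, str], float] = {}
    for seg in deduped:
        k = (seg.participant_id, seg.stimulus_id, seg.category)
        if k in last_end and seg.start < last_end[k]:
            raise ValidationError(
                f"overlapping {seg.category} segments in trial "
                f"({seg.participant_id}, {seg.stimulus_id}) at t={seg.start}"
            )
        last_end[k] = max(last_end.get(k, -math.inf), seg.end)

    aoi_reg: dict[str, AoiDefinition] = dict(aois) if aois else {}
    part_reg: dict[str, ParticipantRecord] = dict(participants) if participants else {}
    stim_list: list[str] = list(stimuli) if stimuli else []

    for seg in deduped:
        if seg.participant_id not in part_reg:
            part_reg[seg.participant_id] = ParticipantRecord(
                seg.participant_id, seg.participant_id
            )
        if seg.stimulus_id not in stim_list:
            stim_list.append(seg.stimulus_id)
        for aoi in sorted(seg.aoi_ids):
            if aoi not in aoi_reg:
                if strict and aois is not None:
                    raise ValidationError(
                        f"unknown AOI {aoi!r} in strict mode; registered: {sorted(aoi_reg)}"
                    )
                aoi_reg[aoi] = AoiDefinition(
                    aoi, aoi, DEFAULT_PALETTE[len(aoi_reg) % len(DEFAULT_PALETTE)]
                )

    return GazeDataset(
        segments=tuple(deduped),
        aois=aoi_reg,
        participants=part_reg,
        stimuli=tuple(stim_list),
        visibility=visibility,
        meta=meta or ParseMetadata(),
    )


# ---------------------------------------------------------------------------
# Non-destructive editing
# ---------------------------------------------------------------------------


def merge_aois(dataset: GazeDataset, target: str, members: Iterable[str]) -> GazeDataset:
    """Point ``members`` at ``target`` so every occurrence resolves to it.

    The underlying segments are untouched; :func:`unmerge_aois` restores the
    original exactly.  ``target`` may be a new AOI (registered on the fly) or
    an existing one.  A merge that would create a cycle is rejected.
    """
    members = list(members)
    aois = dict(dataset.aois)
    for m in members:
        if m not in aois:
            raise ValidationError(f"unknown AOI {m!r}; known: {sorted(aois)}")
    if target not in aois:
        aois[target] = AoiDefinition(
            target, target, DEFAULT_PALETTE[len(aois) % len(DEFAULT_PALETTE)], synthetic=True
        )
    for m in members:
        if m == target:
            raise ValidationError(f"cannot merge AOI {m!r} into itself")
        aois[m] = replace(aois[m], merged_into=target)

    merged = replace(dataset, aois=aois)
    # cycle check: resolving every id must terminate
    for a in aois:
        merged.resolve_aoi(a)
    return merged


def unmerge_aois(dataset: GazeDataset, target: str) -> GazeDataset:
    """Undo :func:`merge_aois` for ``target``; exact inverse."""
    aois = dict(dataset.aois)
    changed = False
    for k, a in list(aois.items()):
        if a.merged_into == target:
            aois[k] = replace(a, merged_into=None)
            changed = True
    if not changed:
        raise ValidationError(f"no AOIs are merged into {target!r}")
    if (
        target in aois
        and aois[target].synthetic
        and not any(target in s.aoi_ids for s in dataset.segments)
    ):
        del aois[target]
    return replace(dataset, aois=aois)


def apply_filter(dataset: GazeDataset, view_filter: ViewFilter) -> GazeDataset:
    """Non-destructive filtered view (new dataset; original untouched).

    Criteria intersect: a segment is kept iff it matches the stimulus, its
    participant carries the group label, its *resolved* AOI set intersects
    the AOI subset, and it overlaps the time range (clipped at the bounds).
    """
    f = view_filter
    if f.stimulus_id is not None and f.stimulus_id not in dataset.stimuli:
        raise ValidationError(
            f"unknown stimulus {f.stimulus_id!r}; valid: {list(dataset.stimuli)}"
        )
    if f.group_label is not None:
        known = sorted(
            {p.group_label for p in dataset.participants.values() if p.group_label}
        )
        if f.group_label not in known:
            raise ValidationError(f"unknown group {f.group_label!r}; valid: {known}")
    if f.aoi_ids is not None:
        resolved = {dataset.resolve_aoi(a) for a in dataset.aois}
        bad = set(f.aoi_ids) - resolved - set(dataset.aois)
        if bad:
            raise ValidationError(
                f"unknown AOI(s) {sorted(bad)}; valid: {sorted(resolved)}"
            )

    kept: list[GazeSegment] = []
    for seg in dataset.segments:
        if f.stimulus_id is not None and seg.stimulus_id != f.stimulus_id:
            continue
        if f.group_label is not None:
            part = dataset.participants.get(seg.participant_id)
            if part is None or part.group_label != f.group_label:
                continue
        if f.aoi_ids is not None and not (dataset.resolved_aoi_ids(seg) & f.aoi_ids):
            continue
        if f.time_range is not None:
            seg = seg.clipped(*f.time_range)
            if seg is None:
                continue
        kept.append(seg)

    participants = {
        k: v
        for k, v in dataset.participants.items()
        if f.group_label is None or v.group_label == f.group_label
    }
    stimuli = (
        tuple(s for s in dataset.stimuli if s == f.stimulus_id)
        if f.stimulus_id is not None
        else dataset.stimuli
    )
    return replace(
        dataset,
        segments=tuple(kept),
        participants=participants,
        stimuli=stimuli,
    )
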