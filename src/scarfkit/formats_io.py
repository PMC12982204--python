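"""Streaming readers and writers for AOI-sequence exports.

Format detection is structural: the header line alone (tokens + delimiter)
identifies the dialect, never the filename.  Four dialects are supported:

``generic_long``
    One row per event: ``participant,stimulus,timestamp_ms,duration_ms,
    category,aoi``.  An empty ``aoi`` field means "no AOI hit"; a segment
    hitting several overlapping AOIs is written as repeated rows sharing
    the same timestamps, merged back into one segment's AOI set on read.
``generic_interval``
    One row per AOI visit with explicit bounds: ``participant;stimulus;aoi;
    interval_start;interval_end;event``.  Cannot represent saccades.
``begaze_like``
    Event-per-row vendor-style export (tab-separated, BeGaze-flavoured
    headers, capitalised event names, ``-`` for unclassified events);
    AOI visibility ships as separate files.
``tobii_like``
    Interval-split vendor-style export: timestamps rounded to whole
    milliseconds and each trial cut into numbered presentation intervals,
    so one logical AOI visit may arrive as several adjacent rows.  Each
    interval parses as its own trial (stimulus id ``"<stimulus>#<k>"``);
    the metrics layer reconstructs unified values across intervals.

The reader is chunked with bounded memory: between chunks only the
carry-over partial line is retained, so output is identical for every chunk
decomposition of the same bytes and peak retained input is one record.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .core_model import (
    CATEGORIES,
    GLOBAL_SCOPE,
    GazeDataset,
    GazeSegment,
    ParseMetadata,
    ValidationError,
    VisibilityInterval,
    VisibilitySchedule,
    canonicalize,
)

__all__ = [
    "DIALECTS",
    "DialectDescriptor",
    "UnknownFormatError",
    "ParseError",
    "detect_dialect",
    "parse",
    "parse_visibility",
    "write_dialect",
    "write_visibility",
    "split_stimulus_interval",
]

DEFAULT_CHUNK_SIZE = 64 * 1024
_DELIMITERS = (",", ";", "\t")


class UnknownFormatError(ValueError):
    """Header does not match any known dialect signature."""


class ParseError(ValueError):
    """Malformed content inside a recognised dialect (strict mode)."""


@dataclass(frozen=True)
class DialectDescriptor:
    dialect_id: str
    signature: tuple
    delimiter: str


DIALECTS: dict[str, DialectDescriptor] = {
    d.dialect_id: d
    for d in (
        DialectDescriptor(
            "generic_long",
            ("participant", "stimulus", "timestamp_ms", "duration_ms", "category", "aoi"),
            ",",
        ),
        DialectDescriptor(
            "generic_interval",
            ("participant", "stimulus", "aoi", "interval_start", "interval_end", "event"),
            ";",
        ),
        DialectDescriptor(
            "begaze_like",
            (
                "Participant",
                "Stimulus",
                "Event Start Trial Time [ms]",
                "Event End Trial Time [ms]",
                "Category",
                "AOI Name",
            ),
            "\t",
        ),
        DialectDescriptor(
            "tobii_like",
            (
                "Recording",
                "Presented Stimulus",
                "Interval",
                "Event Type",
                "Event Start [ms]",
                "Event End [ms]",
                "AOI Hit",
            ),
            "\t",
        ),
    )
}

_VISIBILITY_HEADER = ("aoi", "stimulus", "start_ms", "end_ms")

_BEGAZE_CATEGORY = {"Fixation": "fixation", "Saccade": "saccade", "-": "other"}
_BEGAZE_CATEGORY_OUT = {v: k for k, v in _BEGAZE_CATEGORY.items()}
_TOBII_CATEGORY = {"Fixation": "fixation", "Saccade": "saccade", "Unclassified": "other"}
_TOBII_CATEGORY_OUT = {v: k for k, v in _TOBII_CATEGORY.items()}


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_dialect(first_chunk: str) -> DialectDescriptor:
    """Identify the dialect from the header line by internal structure.

    The chunk must contain at least the complete header line.  Detection
    compares the ordered header tokens against each dialect signature for
    each candidate delimiter; signatures are pairwise distinct so at most
    one dialect can match.
    """
    header = first_chunk.split("\n", 1)[0].rstrip("\r")
    matches = []
    for d in DIALECTS.values():
        if tuple(t.strip() for t in header.split(d.delimiter)) == d.signature:
            matches.append(d)
    if len(matches) > 1:  # pragma: no cover - signatures are disjoint
        raise AssertionError(f"ambiguous header matches {[d.dialect_id for d in matches]}")
    if not matches:
        found = {delim: header.split(delim) for delim in _DELIMITERS if delim in header}
        raise UnknownFormatError(
            f"unrecognized format: header {header!r} (tokens by delimiter: {found}) "
            f"matches none of {sorted(DIALECTS)}"
        )
    return matches[0]


# ---------------------------------------------------------------------------
# Chunked line iteration (bounded carry-over)
# ---------------------------------------------------------------------------


def _is_pathlike(source) -> bool:
    if isinstance(source, Path):
        return True
    return isinstance(source, str) and "\n" not in source and Path(source).exists()


def _chunks_of(source, chunk_size: int) -> Iterator[str]:
    if _is_pathlike(source):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            while True:
                chunk = fh.read(chunk_size)
                if not chunk:
                    return
                yield chunk
        return
    if isinstance(source, str):
        for i in range(0, len(source), chunk_size):
            yield source[i : i + chunk_size]
        return
    if hasattr(source, "read"):
        while True:
            chunk = source.read(chunk_size)
            if not chunk:
                return
            yield chunk
        return
    yield from source


class _LineStream:
    """Yield complete lines from text chunks, retaining only the carry-over.

    ``max_carry`` records the peak size of the partial-line buffer between
    chunks, instrumenting the bounded-memory contract.
    """

    def __init__(self, chunks: Iterable[str]):
        self._chunks = chunks
        self.max_carry = 0
        self.total_bytes = 0

    def __iter__(self) -> Iterator[str]:
        carry = ""
        for chunk in self._chunks:
            self.total_bytes += len(chunk.encode("utf-8"))
            carry += chunk
            *lines, carry = carry.split("\n")
            self.max_carry = max(self.max_carry, len(carry))
            for line in lines:
                yield line.rstrip("\r")
        if carry:
            yield carry.rstrip("\r")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _check_delimiter(line: str, expected: str, n_fields: int, lineno: int) -> None:
    for delim in _DELIMITERS:
        if delim != expected and len(line.split(delim)) == n_fields:
            raise UnknownFormatError(
                f"unrecognized format: line {lineno} uses delimiter {delim!r} "
                f"where {expected!r} was detected"
            )


def _float(value: str, what: str, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"line {lineno}: invalid {what} {value!r}") from None


def parse(
    source,
    dialect: str | DialectDescriptor | None = None,
    *,
    strict: bool = False,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    source_filename: str | None = None,
) -> GazeDataset:
    """Parse a delimited export into a canonical :class:`GazeDataset`.

    ``source`` may be a path, an open text file, a string of file content,
    or any iterable of text chunks; chunks may split records arbitrarily
    and the result is identical for every chunking of the same bytes.
    ``dialect`` is auto-detected from the header when omitted.

    In strict mode a malformed row raises :class:`ParseError` with its
    1-based line number; in lenient mode it is skipped and counted in
    ``meta.skipped_rows``.  Duplicate identical rows collapse with a count
    in ``meta.duplicate_rows``.
    """
    t0 = time.perf_counter()
    if _is_pathlike(source):
        source_filename = source_filename or Path(source).name
    stream = _LineStream(_chunks_of(source, chunk_size))
    lines = iter(stream)

    header = next(lines, None)
    if header is None:
        raise UnknownFormatError("unrecognized format: empty input")
    detected = detect_dialect(header)
    if dialect is not None:
        wanted = dialect if isinstance(dialect, DialectDescriptor) else DIALECTS[dialect]
        if wanted.dialect_id != detected.dialect_id:
            raise UnknownFormatError(
                f"header is {detected.dialect_id!r}, not requested {wanted.dialect_id!r}"
            )
    d = detected
    n_fields = len(d.signature)

    # key -> (aoi set) accumulation so repeated rows merge into one segment
    rows: dict[tuple, set] = {}
    seen: set = set()  # parsed (key, aoi) pairs, for duplicate-row collapsing
    skipped = 0
    duplicates = 0

    for lineno, line in enumerate(lines, start=2):
        if not line:
            continue
        fields = line.split(d.delimiter)
        if len(fields) != n_fields:
            _check_delimiter(line, d.delimiter, n_fields, lineno)
            if strict:
                raise ParseError(
                    f"line {lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            skipped += 1
            continue
        try:
            key, aoi = _parse_row(d.dialect_id, fields, lineno)
        except ParseError:
            if strict:
                raise
            skipped += 1
            continue
        if (key, aoi) in seen:
            duplicates += 1
            continue
        seen.add((key, aoi))
        bucket = rows.setdefault(key, set())
        if aoi:
            bucket.add(aoi)

    segments = [
        GazeSegment(p, s, start, end, category, frozenset(aois))
        for (p, s, start, end, category), aois in rows.items()
    ]
    meta = ParseMetadata(
        source_filename=source_filename or "<memory>",
        detected_dialect=d.dialect_id,
        file_size_bytes=stream.total_bytes,
        parse_duration_ms=(time.perf_counter() - t0) * 1000.0,
        skipped_rows=skipped,
        duplicate_rows=duplicates,
        max_carry_bytes=stream.max_carry,
    )
    dataset = canonicalize(segments, meta=meta)
    dataset.meta.parse_duration_ms = (time.perf_counter() - t0) * 1000.0
    return dataset


def _parse_row(dialect_id: str, f: list, lineno: int) -> tuple[tuple, str]:
    """Return ``((participant, stimulus, start, end, category), aoi)``."""
    if dialect_id == "generic_long":
        p, s, ts, dur, cat, aoi = (x.strip() for x in f)
        if cat not in CATEGORIES:
            raise ParseError(f"line {lineno}: unknown category {cat!r}")
        start = _float(ts, "timestamp_ms", lineno)
        end = start + _float(dur, "duration_ms", lineno)
        return (p, s, start, end, cat), aoi
    if dialect_id == "generic_interval":
        p, s, aoi, a, b, event = (x.strip() for x in f)
        if event not in ("fixation", "other"):
            raise ParseError(f"line {lineno}: unknown event {event!r}")
        return (p, s, _float(a, "interval_start", lineno), _float(b, "interval_end", lineno), event), aoi
    if dialect_id == "begaze_like":
        p, s, a, b, cat, aoi = (x.strip() for x in f)
        if cat not in _BEGAZE_CATEGORY:
            raise ParseError(f"line {lineno}: unknown Category {cat!r}")
        return (
            p,
            s,
            _float(a, "start time", lineno),
            _float(b, "end time", lineno),
            _BEGAZE_CATEGORY[cat],
        ), aoi
    if dialect_id == "tobii_like":
        p, s, interval, etype, a, b, aoi = (x.strip() for x in f)
        if etype not in _TOBII_CATEGORY:
            raise ParseError(f"line {lineno}: unknown Event Type {etype!r}")
        try:
            k = int(interval)
        except ValueError:
            raise ParseError(f"line {lineno}: invalid Interval {interval!r}") from None
        start = _float(a, "start time", lineno)
        end = _float(b, "end time", lineno)
        if start != int(start) or end != int(end):
            raise ParseError(f"line {lineno}: timestamps must be whole milliseconds")
        return (p, f"{s}#{k}", start, end, _TOBII_CATEGORY[etype]), aoi
    raise AssertionError(dialect_id)  # pragma: no cover


def split_stimulus_interval(stimulus_id: str) -> tuple[str, int | None]:
    """Split a tobii_like interval-qualified stimulus id ``"S#3"`` -> ``("S", 3)``."""
    base, sep, k = stimulus_id.rpartition("#")
    if sep and k.isdigit():
        return base, int(k)
    return stimulus_id, None


# ---------------------------------------------------------------------------
# Visibility files
# ---------------------------------------------------------------------------


def parse_visibility(
    source,
    scope: str = GLOBAL_SCOPE,
    *,
    strict: bool = False,
    known_aois: Iterable[str] | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> VisibilitySchedule:
    """Parse an AOI-visibility file (``aoi,stimulus,start_ms,end_ms``).

    ``scope`` is ``"global"`` or a participant id; visibility exports carry
    no scope column, so the caller assigns one file per participant (or one
    global file) exactly as the source software exports them.  Overlapping
    same-AOI intervals are merged.  An empty file yields a schedule under
    which every AOI defaults to always visible.
    """
    stream = _LineStream(_chunks_of(source, chunk_size))
    lines = iter(stream)
    header = next(lines, None)
    if header is None:
        return VisibilitySchedule([])
    if tuple(t.strip() for t in header.split(",")) != _VISIBILITY_HEADER:
        raise UnknownFormatError(
            f"unrecognized visibility header {header!r}; expected "
            f"{','.join(_VISIBILITY_HEADER)}"
        )
    known = set(known_aois) if known_aois is not None else None
    intervals = []
    for lineno, line in enumerate(lines, start=2):
        if not line:
            continue
        fields = [x.strip() for x in line.split(",")]
        if len(fields) != 4:
            raise ParseError(f"line {lineno}: expected 4 fields, got {len(fields)}")
        aoi, stim, a, b = fields
        start = _float(a, "start_ms", lineno)
        end = _float(b, "end_ms", lineno)
        if end <= start:
            raise ValidationError(
                f"line {lineno}: visibility interval end <= start ([{start}, {end}))"
            )
        if strict and known is not None and aoi not in known:
            raise ValidationError(
                f"line {lineno}: unknown AOI {aoi!r} in strict mode; known: {sorted(known)}"
            )
        intervals.append(VisibilityInterval(aoi, stim, start, end, scope))
    return VisibilitySchedule(intervals)


# ---------------------------------------------------------------------------
# Writers (byte-stable: fixed column order, LF, no trailing delimiter)
# ---------------------------------------------------------------------------


def _fmt_ms(x: float) -> str:
    return str(int(x)) if x == int(x) else repr(x)


def _check_field(value: str, delimiter: str) -> str:
    if delimiter in value or "\n" in value or "\r" in value:
        raise ValidationError(
            f"identifier {value!r} contains the delimiter or a newline and "
            f"cannot be written to this dialect"
        )
    return value


def _sorted_aois(dataset: GazeDataset, aoi_ids: frozenset) -> list[str]:
    order = {k: i for i, k in enumerate(dataset.aois)}
    return sorted(aoi_ids, key=lambda a: order.get(a, len(order)))


def write_dialect(
    dataset: GazeDataset,
    dialect: str,
    path=None,
    *,
    cuts: Mapping[tuple[str, str], Iterable[float]] | None = None,
    strict: bool = True,
) -> str:
    """Serialize a dataset to one of the supported dialects.

    Returns the file content (and writes it to ``path`` when given).  The
    output is byte-stable: canonical segment order, fixed columns, LF line
    endings, no trailing delimiter.

    ``generic_interval`` cannot represent saccade events; with
    ``strict=True`` they raise, otherwise they are silently dropped (the
    documented lossy write).  ``tobii_like`` rounds every timestamp to
    whole milliseconds and splits each trial into presentation intervals at
    ``cuts[(participant, stimulus)]`` (default: one interval per trial);
    pieces that round to zero length are dropped.
    """
    d = DIALECTS[dialect]
    lines = [d.delimiter.join(d.signature)]

    if dialect == "tobii_like":
        lines += _tobii_rows(dataset, cuts or {})
    else:
        for seg in dataset.segments:
            aois = _sorted_aois(dataset, seg.aoi_ids) or [""]
            for aoi in aois:
                row = _format_row(dialect, seg, aoi, strict)
                if row is None:
                    break
                lines.append(d.delimiter.join(_check_field(x, d.delimiter) for x in row))

    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="")
    return text


def _format_row(dialect: str, seg: GazeSegment, aoi: str, strict: bool):
    if dialect == "generic_long":
        return (
            seg.participant_id,
            seg.stimulus_id,
            _fmt_ms(seg.start),
            _fmt_ms(seg.duration),
            seg.category,
            aoi,
        )
    if dialect == "generic_interval":
        if seg.category == "saccade":
            if strict:
                raise ValidationError(
                    "generic_interval cannot represent saccade events; "
                    "use strict=False to drop them (lossy write)"
                )
            return None
        return (
            seg.participant_id,
            seg.stimulus_id,
            aoi,
            _fmt_ms(seg.start),
            _fmt_ms(seg.end),
            seg.category,
        )
    if dialect == "begaze_like":
        return (
            seg.participant_id,
            seg.stimulus_id,
            _fmt_ms(seg.start),
            _fmt_ms(seg.end),
            _BEGAZE_CATEGORY_OUT[seg.category],
            aoi,
        )
    raise AssertionError(dialect)  # pragma: no cover


def _tobii_rows(dataset: GazeDataset, cuts: Mapping) -> list[str]:
    d = DIALECTS["tobii_like"]
    out = []
    for (pid, stim), segs in dataset.trials():
        onset = min(s.start for s in segs)
        end = max(s.end for s in segs)
        trial_cuts = sorted(c for c in cuts.get((pid, stim), ()) if onset < c < end)
        bounds = [onset, *trial_cuts, end]
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            for seg in segs:
                piece = seg.clipped(lo, hi)
                if piece is None:
                    continue
                a, b = round(piece.start), round(piece.end)
                if b <= a:
                    continue  # rounded away, documented loss
                for aoi in _sorted_aois(dataset, seg.aoi_ids) or [""]:
                    out.append(
                        d.delimiter.join(
                            _check_field(x, d.delimiter)
                            for x in (
                                pid,
                                stim,
                                str(k + 1),
                                _TOBII_CATEGORY_OUT[seg.category],
                                str(a),
                                str(b),
                                aoi,
                            )
                        )
                    )
    return out


def write_visibility(schedule: VisibilitySchedule, path=None, *, scope: str | None = None) -> str:
    """Write the intervals of one scope as a visibility CSV."""
    lines = [",".join(_VISIBILITY_HEADER)]
    for iv in schedule.intervals:
        if scope is not None and iv.scope != scope:
            continue
        lines.append(
            ",".join(
                _check_field(x, ",")
                for x in (iv.aoi_id, iv.stimulus_id, _fmt_ms(iv.start), _fmt_ms(iv.end))
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="")
    return text
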