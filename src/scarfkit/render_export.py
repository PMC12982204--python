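"""Publication exports: images, CSV tables, ScanGraph files, sessions.

Rendering is deterministic: fixed fonts and a fixed SVG hash salt make the
same geometry produce byte-identical SVG twice, and raster outputs scale
linearly with DPI (style dimensions are reference pixels at 96 dpi).

Sessions are single canonical-JSON documents (UTF-8, sorted keys,
shortest-round-trip floats) that embed the full canonical data, the panel
layout, parse metadata, and the tool version, so loading one never requires
the original export files and ``save -> load -> save`` is byte-identical.
Unknown fields from future versions are preserved on re-save.
"""

from __future__ import annotations

import csv
import io
import json
import string
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from . import __version__
from .aoi_metrics import AoiMetricsRecord, BarSummary, summarize_by_group
from .core_model import (
    AoiDefinition,
    GazeDataset,
    GazeSegment,
    ParseMetadata,
    ParticipantRecord,
    ValidationError,
    ViewFilter,
    VisibilityInterval,
    VisibilitySchedule,
)
from .scarf_builder import ScarfGeometry, legend as scarf_legend
from .transitions import TransitionMatrix

__all__ = [
    "RenderStyle",
    "Panel",
    "WorkspaceSession",
    "SessionSchemaError",
    "render",
    "export_metrics_csv",
    "export_events_csv",
    "export_scangraph",
    "save_session",
    "load_session",
    "dataset_to_jsonable",
    "dataset_from_jsonable",
]

SESSION_FORMAT = "scarfkit-session/1"
SCANGRAPH_FORMAT_VERSION = 1  # compatible-intent dialect, versioned
_SCANGRAPH_ALPHABET = string.ascii_lowercase + string.ascii_uppercase + string.digits
_REFERENCE_DPI = 96.0

matplotlib.rcParams["svg.hashsalt"] = "scarfkit"
matplotlib.rcParams["font.family"] = "DejaVu Sans"


@dataclass(frozen=True)
class RenderStyle:
    """Raster/vector output options (dimensions in reference px at 96 dpi)."""

    dpi: int = 150
    margins: tuple = (12, 12, 12, 12)  # top, right, bottom, left
    row_height: int = 28
    font_size: int = 10
    fmt: str = "png"  # png | jpg | webp | svg
    content_width: int = 760

    def __post_init__(self) -> None:
        if self.dpi < 72:
            raise ValidationError(f"dpi must be >= 72, got {self.dpi}")
        if any(m < 0 for m in self.margins):
            raise ValidationError(f"margins must be >= 0, got {self.margins}")
        if self.fmt not in ("png", "jpg", "webp", "svg"):
            raise ValidationError(
                f"unsupported format {self.fmt!r}; supported: png, jpg, webp, svg"
            )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_AXIS_LABEL = {
    "absolute": "time from trial onset [ms]",
    "relative": "trial time [%]",
    "ordinal": "segment order",
}


def _figure(style: RenderStyle, content_height: float):
    top, right, bottom, left = style.margins
    # quantize to whole inches so pixel dimensions are exactly inches x dpi
    # for every integer dpi (doubling dpi doubles the raster exactly)
    import math

    w_in = math.ceil((style.content_width + left + right) / _REFERENCE_DPI)
    h_in = math.ceil((content_height + top + bottom) / _REFERENCE_DPI)
    fig = plt.figure(figsize=(w_in, h_in))
    ax = fig.add_axes(
        (
            left / (w_in * _REFERENCE_DPI),
            bottom / (h_in * _REFERENCE_DPI),
            style.content_width / (w_in * _REFERENCE_DPI),
            content_height / (h_in * _REFERENCE_DPI),
        )
    )
    ax.tick_params(labelsize=style.font_size * 0.8)
    return fig, ax


def _render_scarf(geometry: ScarfGeometry, style: RenderStyle, dataset=None):
    n_rows = max(len(geometry.rows), 1)
    vis_bands = max((len(r.visibility) for r in geometry.rows), default=0)
    row_units = 1.0 + 0.25 * vis_bands + 0.15
    fig, ax = _figure(style, style.row_height * row_units * n_rows + 40)

    y = 0.0
    yticks, ylabels = [], []
    for row in geometry.rows:
        n_sub = row.n_sub_bands
        for r in row.rects:
            h = 1.0 / n_sub if r.category == "fixation" else (1.0 if r.sub_band == 0 else 0)
            y0 = y + (r.sub_band / n_sub if r.category == "fixation" else 0.0)
            if r.category == "saccade":
                y0, h = y + 0.35, 0.3
            ax.add_patch(
                Rectangle((r.x0, y0), r.x1 - r.x0, h, facecolor=r.color, linewidth=0)
            )
        yticks.append(y + 0.5)
        ylabels.append(row.participant_id)
        vy = y + 1.05
        for _aoi, rects in row.visibility:
            for r in rects:
                ax.add_patch(
                    Rectangle((r.x0, vy), r.x1 - r.x0, 0.18, facecolor=r.color, linewidth=0)
                )
            vy += 0.25
        y += row_units

    ax.set_xlim(geometry.domain if geometry.domain[1] > 0 else (0, 1))
    ax.set_ylim(max(y, 1.0), 0)  # first participant on top
    ax.set_yticks(yticks, ylabels, fontsize=style.font_size)
    ax.set_xlabel(_AXIS_LABEL[geometry.mode], fontsize=style.font_size)
    if dataset is not None:
        entries = scarf_legend(dataset, stimulus_id=geometry.stimulus_id)
        handles = [Rectangle((0, 0), 1, 1, facecolor=c) for _, c, _ in entries]
        if handles:
            ax.legend(
                handles,
                [name for name, _, _ in entries],
                loc="upper left",
                bbox_to_anchor=(1.01, 1.0),
                fontsize=style.font_size * 0.8,
                frameon=False,
            )
    return fig


def _render_matrix(matrix: TransitionMatrix, style: RenderStyle):
    n = max(len(matrix.aoi_order), 1)
    fig, ax = _figure(style, max(26 * n + 40, 140))
    im = ax.imshow(matrix.counts, cmap="viridis")
    ax.set_xticks(range(n), matrix.aoi_order, fontsize=style.font_size * 0.8, rotation=45)
    ax.set_yticks(range(n), matrix.aoi_order, fontsize=style.font_size * 0.8)
    ax.set_xlabel("to AOI", fontsize=style.font_size)
    ax.set_ylabel("from AOI", fontsize=style.font_size)
    vmax = matrix.counts.max() if matrix.counts.size else 0
    for i in range(len(matrix.aoi_order)):
        for j in range(len(matrix.aoi_order)):
            v = int(matrix.counts[i, j])
            ax.text(
                j, i, str(v), ha="center", va="center",
                color="white" if vmax and v < 0.6 * vmax else "black",
                fontsize=style.font_size * 0.75,
            )
    fig.colorbar(im, ax=ax, shrink=0.8)
    return fig


_BAR_METRICS = (("dwell time [ms]", 0), ("fixation count", 1), ("time to first fixation [ms]", 2))


def _render_bars(summary: BarSummary, style: RenderStyle):
    import math

    fig, axes = plt.subplots(
        1, 3,
        figsize=(
            math.ceil((style.content_width + sum(style.margins[1::2])) / _REFERENCE_DPI),
            math.ceil(260 / _REFERENCE_DPI),
        ),
    )
    n_groups = max(len(summary.groups), 1)
    width = 0.8 / n_groups
    for ax, (title, mi) in zip(axes, _BAR_METRICS):
        for gi, g in enumerate(summary.groups):
            xs, hs = [], []
            for ai, a in enumerate(summary.aois):
                row = summary.rows.get((g, a))
                v = row[mi] if row else None
                xs.append(ai + gi * width - 0.4 + width / 2)
                hs.append(0.0 if v is None else v)
            ax.bar(xs, hs, width=width, label=g)
        ax.set_xticks(range(len(summary.aois)), summary.aois, fontsize=style.font_size * 0.7)
        ax.set_title(title, fontsize=style.font_size * 0.85)
        ax.tick_params(labelsize=style.font_size * 0.7)
    if summary.groups:
        axes[-1].legend(fontsize=style.font_size * 0.7, frameon=False)
    fig.tight_layout()
    return fig


def render(obj, style: RenderStyle = RenderStyle(), *, dataset: GazeDataset | None = None) -> bytes:
    """Render scarf geometry, a transition matrix, or a bar summary.

    Returns encoded image bytes in ``style.fmt``.  Passing the originating
    ``dataset`` adds an AOI legend to scarf plots.  Output is deterministic
    for fixed inputs; doubling ``dpi`` doubles raster pixel dimensions.
    """
    if isinstance(obj, ScarfGeometry):
        fig = _render_scarf(obj, style, dataset)
    elif isinstance(obj, TransitionMatrix):
        fig = _render_matrix(obj, style)
    elif isinstance(obj, BarSummary):
        fig = _render_bars(obj, style)
    elif isinstance(obj, GazeDataset):
        fig = _render_bars(summarize_by_group(obj), style)
    else:
        raise ValidationError(f"cannot render object of type {type(obj).__name__}")

    buf = io.BytesIO()
    kwargs = {"format": style.fmt, "dpi": style.dpi}
    if style.fmt == "svg":
        kwargs["metadata"] = {"Date": None}
    fig.savefig(buf, **kwargs)
    plt.close(fig)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# CSV exports
# ---------------------------------------------------------------------------


def _ms(x: float | None) -> str:
    return "" if x is None else f"{x:.3f}"


def export_metrics_csv(records: Sequence[AoiMetricsRecord], path=None) -> str:
    """AOI-metrics table; milliseconds with 3 decimals, absent values empty.

    Absent is distinct from zero: a TTFF of 0 ms is a legal value, so a
    never-fixated AOI exports empty TTFF/average cells, not zeros.
    """
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(
        [
            "participant", "stimulus", "aoi",
            "time_to_first_fixation_ms", "fixation_count",
            "avg_fixation_duration_ms", "dwell_time_ms",
        ]
    )
    for r in records:
        w.writerow(
            [
                r.participant_id, r.stimulus_id, r.aoi_id,
                _ms(r.time_to_first_fixation), r.fixation_count,
                _ms(r.avg_fixation_duration), _ms(r.dwell_time),
            ]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="")
    return text


def export_events_csv(dataset: GazeDataset, path=None) -> str:
    """Raw event table in the generic_long layout; re-imports loss-free."""
    from .formats_io import write_dialect

    return write_dialect(dataset, "generic_long", path)


# ---------------------------------------------------------------------------
# ScanGraph export
# ---------------------------------------------------------------------------


def export_scangraph(
    dataset: GazeDataset,
    path=None,
    *,
    stimulus_id: str | None = None,
    collapse_repeats: bool = False,
) -> str:
    """Per-participant AOI character sequences for scanpath comparison.

    Header lines map each merge-resolved AOI to a single character
    (``#a=Name``); each body line is ``participant<TAB>sequence`` with one
    character per fixation in time order.  No-AOI fixations are skipped; a
    fixation hitting several AOIs is transcribed as the AOI with the lowest
    registry index (a warning reports how many were resolved this way).
    ``collapse_repeats`` collapses consecutive duplicate characters.
    """
    if stimulus_id is None:
        if len(dataset.stimuli) != 1:
            raise ValidationError(
                f"dataset view has stimuli {list(dataset.stimuli)}; "
                "pass stimulus_id= or filter to one stimulus"
            )
        stimulus_id = dataset.stimuli[0]

    aois = [a.aoi_id for a in dataset.effective_aois()]
    if len(aois) > len(_SCANGRAPH_ALPHABET):
        raise ValidationError(
            f"{len(aois)} AOIs exceed the {len(_SCANGRAPH_ALPHABET)}-character "
            "alphabet; merge AOIs to reduce the count"
        )
    char_of = dict(zip(aois, _SCANGRAPH_ALPHABET))

    lines = [f"#{char_of[a]}={dataset.aois[a].display_name}" for a in aois]
    n_overlap = 0
    for pid in dataset.participants:
        seq = []
        for seg in dataset.segments:
            if (
                seg.participant_id != pid
                or seg.stimulus_id != stimulus_id
                or seg.category != "fixation"
            ):
                continue
            hits = sorted(dataset.resolved_aoi_ids(seg), key=dataset.aoi_index)
            if not hits:
                continue
            if len(hits) > 1:
                n_overlap += 1
            c = char_of[hits[0]]
            if collapse_repeats and seq and seq[-1] == c:
                continue
            seq.append(c)
        lines.append(f"{pid}\t{''.join(seq)}")
    if n_overlap:
        warnings.warn(
            f"{n_overlap} overlapping fixation(s) transcribed as their "
            "lowest-registry-index AOI",
            stacklevel=2,
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="")
    return text


# ---------------------------------------------------------------------------
# Session save / load
# ---------------------------------------------------------------------------


class SessionSchemaError(ValueError):
    """Schema violation; the message carries the JSON-pointer path."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


@dataclass
class Panel:
    """One dashboard panel: a visualization kind plus its view state."""

    kind: str  # scarf | transitions | barplot
    view_filter: ViewFilter = field(default_factory=ViewFilter)
    mode: str = "absolute"
    options: dict = field(default_factory=dict)
    layout_slot: int = 0
    extras: dict = field(default_factory=dict, compare=False)


@dataclass
class WorkspaceSession:
    """Full analytic state: datasets, panels, provenance, version."""

    datasets: dict  # name -> GazeDataset
    panels: list = field(default_factory=list)
    tool_version: str = __version__
    extras: dict = field(default_factory=dict, compare=False)


def dataset_to_jsonable(dataset: GazeDataset) -> dict:
    return {
        "segments": [
            {
                "participant_id": s.participant_id,
                "stimulus_id": s.stimulus_id,
                "start": s.start,
                "end": s.end,
                "category": s.category,
                "aoi_ids": sorted(s.aoi_ids),
            }
            for s in dataset.segments
        ],
        "aois": [
            {
                "aoi_id": a.aoi_id,
                "display_name": a.display_name,
                "color": a.color,
                "merged_into": a.merged_into,
                "synthetic": a.synthetic,
            }
            for a in dataset.aois.values()
        ],
        "participants": [
            {
                "participant_id": p.participant_id,
                "display_name": p.display_name,
                "group_label": p.group_label,
            }
            for p in dataset.participants.values()
        ],
        "stimuli": list(dataset.stimuli),
        "visibility": None
        if dataset.visibility is None
        else [
            {
                "aoi_id": iv.aoi_id,
                "stimulus_id": iv.stimulus_id,
                "start": iv.start,
                "end": iv.end,
                "scope": iv.scope,
            }
            for iv in dataset.visibility.intervals
        ],
        "meta": {
            "source_filename": dataset.meta.source_filename,
            "detected_dialect": dataset.meta.detected_dialect,
            "file_size_bytes": dataset.meta.file_size_bytes,
            "parse_duration_ms": dataset.meta.parse_duration_ms,
            "tool_version": dataset.meta.tool_version,
        },
    }


def dataset_from_jsonable(doc: dict, pointer: str = "") -> GazeDataset:
    for key in ("segments", "aois", "participants", "stimuli"):
        if key not in doc:
            raise SessionSchemaError(f"{pointer}/{key}", "missing required field")
    segments = tuple(
        GazeSegment(
            s["participant_id"], s["stimulus_id"], s["start"], s["end"],
            s["category"], frozenset(s["aoi_ids"]),
        )
        for s in doc["segments"]
    )
    aois = {
        a["aoi_id"]: AoiDefinition(
            a["aoi_id"], a["display_name"], a["color"],
            a.get("merged_into"), a.get("synthetic", False),
        )
        for a in doc["aois"]
    }
    participants = {
        p["participant_id"]: ParticipantRecord(
            p["participant_id"], p["display_name"], p.get("group_label")
        )
        for p in doc["participants"]
    }
    visibility = None
    if doc.get("visibility") is not None:
        visibility = VisibilitySchedule(
            [
                VisibilityInterval(
                    v["aoi_id"], v["stimulus_id"], v["start"], v["end"], v["scope"]
                )
                for v in doc["visibility"]
            ]
        )
    m = doc.get("meta", {})
    meta = ParseMetadata(
        source_filename=m.get("source_filename", "<session>"),
        detected_dialect=m.get("detected_dialect", "session"),
        file_size_bytes=m.get("file_size_bytes", 0),
        parse_duration_ms=m.get("parse_duration_ms", 0.0),
        tool_version=m.get("tool_version", __version__),
    )
    return GazeDataset(
        segments=segments,
        aois=aois,
        participants=participants,
        stimuli=tuple(doc["stimuli"]),
        visibility=visibility,
        meta=meta,
    )


def _filter_to_jsonable(f: ViewFilter) -> dict:
    return {
        "stimulus_id": f.stimulus_id,
        "group_label": f.group_label,
        "aoi_ids": None if f.aoi_ids is None else sorted(f.aoi_ids),
        "time_range": None if f.time_range is None else list(f.time_range),
    }


def _filter_from_jsonable(doc: dict) -> ViewFilter:
    return ViewFilter(
        stimulus_id=doc.get("stimulus_id"),
        group_label=doc.get("group_label"),
        aoi_ids=None if doc.get("aoi_ids") is None else frozenset(doc["aoi_ids"]),
        time_range=None if doc.get("time_range") is None else tuple(doc["time_range"]),
    )


def save_session(workspace: WorkspaceSession, path=None) -> str:
    """Serialize a workspace to canonical JSON (sorted keys, UTF-8, LF)."""
    doc = dict(workspace.extras)
    doc.update(
        {
            "format": SESSION_FORMAT,
            "version": workspace.tool_version,
            "datasets": {
                name: dataset_to_jsonable(ds) for name, ds in workspace.datasets.items()
            },
            "panels": [
                {
                    **p.extras,
                    "kind": p.kind,
                    "filter": _filter_to_jsonable(p.view_filter),
                    "mode": p.mode,
                    "options": p.options,
                    "layout_slot": p.layout_slot,
                }
                for p in workspace.panels
            ],
        }
    )
    text = json.dumps(doc, sort_keys=True, ensure_ascii=False, separators=(",", ":")) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="")
    return text


_PANEL_KEYS = {"kind", "filter", "mode", "options", "layout_slot"}


def load_session(source) -> WorkspaceSession:
    """Load a session document (path, file object, or JSON text).

    Schema violations raise :class:`SessionSchemaError` with the JSON
    pointer of the offending node.  A version mismatch against the running
    tool version warns and loads best-effort; unknown fields are kept and
    written back by :func:`save_session`.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise SessionSchemaError("", f"not valid JSON: {e}") from None
    if not isinstance(doc, dict):
        raise SessionSchemaError("", f"expected object, got {type(doc).__name__}")
    if "version" not in doc:
        raise SessionSchemaError("/version", "missing required field")
    if not isinstance(doc["version"], str):
        raise SessionSchemaError("/version", "must be a string")
    if doc["version"] != __version__:
        warnings.warn(
            f"session was saved by version {doc['version']}, this is "
            f"{__version__}; loading best-effort",
            stacklevel=2,
        )
    if not isinstance(doc.get("datasets"), dict):
        raise SessionSchemaError("/datasets", "missing or not an object")
    if not isinstance(doc.get("panels"), list):
        raise SessionSchemaError("/panels", "missing or not an array")

    datasets = {
        name: dataset_from_jsonable(d, f"/datasets/{name}")
        for name, d in doc["datasets"].items()
    }
    panels = []
    for i, p in enumerate(doc["panels"]):
        if not isinstance(p, dict) or "kind" not in p:
            raise SessionSchemaError(f"/panels/{i}/kind", "missing required field")
        panels.append(
            Panel(
                kind=p["kind"],
                view_filter=_filter_from_jsonable(p.get("filter", {})),
                mode=p.get("mode", "absolute"),
                options=p.get("options", {}),
                layout_slot=p.get("layout_slot", 0),
                extras={k: v for k, v in p.items() if k not in _PANEL_KEYS},
            )
        )
    extras = {k: v for k, v in doc.items() if k not in ("format", "version", "datasets", "panels")}
    return WorkspaceSession(
        datasets=datasets, panels=panels, tool_version=doc["version"], extras=extras
    )
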