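"""Timeline projection and scarf geometry invariants."""

import math

import pytest

from scarfkit import (
    GazeSegment,
    ValidationError,
    ViewFilter,
    apply_filter,
    build_scarf,
    legend,
    merge_aois,
    project_segment,
    unmerge_aois,
)
from scarfkit.scarf_builder import NO_AOI_COLOR, OVERLAP_COLOR, SACCADE_COLOR

from conftest import make_dataset


class TestProjection:
    def test_relative_linear_map(self):
        seg = GazeSegment("P", "S", 120, 300, "fixation", {"A"})
        assert project_segment(seg, "relative", (0, 500, 0)) == (24.0, 60.0)

    def test_relative_full_trial_spans_0_100(self):
        seg = GazeSegment("P", "S", 100, 600, "fixation", {"A"})
        assert project_segment(seg, "relative", (100, 600, 0)) == (0.0, 100.0)

    def test_ordinal_unit_width(self):
        seg = GazeSegment("P", "S", 0, 50, "fixation", {"A"})
        assert project_segment(seg, "ordinal", (0, 500, 2)) == (2.0, 3.0)

    def test_absolute_subtracts_onset(self):
        seg = GazeSegment("P", "S", 150, 250, "fixation", {"A"})
        assert project_segment(seg, "absolute", (100, 500, 0)) == (50.0, 150.0)

    def test_degenerate_trial_rejected_in_relative(self):
        seg = GazeSegment("P", "S", 100, 200, "fixation", {"A"})
        with pytest.raises(ValidationError, match="degenerate"):
            project_segment(seg, "relative", (100, 100, 0))


class TestBuildScarf:
    def test_simple_trial_rect_colors(self):
        ds = make_dataset(
            [
                ("P1", "S", 0, 100, "fixation", {"A"}),
                ("P1", "S", 100, 120, "saccade", ()),
                ("P1", "S", 120, 300, "fixation", {"B"}),
            ]
        )
        g = build_scarf(ds, "absolute")
        (row,) = g.rows
        assert len(row.rects) == 3
        colors = [r.color for r in row.rects]
        assert colors[0] == ds.aois["A"].color
        assert colors[1] == SACCADE_COLOR
        assert colors[2] == ds.aois["B"].color

    def test_overlap_split_stacks_sub_bands(self):
        ds = make_dataset([("P1", "S", 0, 100, "fixation", {"A", "B"})])
        g = build_scarf(ds, "absolute", split_overlaps=True)
        rects = g.rows[0].rects
        assert len(rects) == 2
        assert {r.sub_band for r in rects} == {0, 1}
        assert len({(r.x0, r.x1) for r in rects}) == 1  # same x-range

    def test_overlap_unsplit_single_rect(self):
        ds = make_dataset([("P1", "S", 0, 100, "fixation", {"A", "B"})])
        g = build_scarf(ds, "absolute", split_overlaps=False)
        (rect,) = g.rows[0].rects
        assert rect.color == OVERLAP_COLOR

    def test_split_toggle_changes_only_sub_band_structure(self, small_fixture):
        ds, _ = small_fixture
        view = apply_filter(ds, ViewFilter(stimulus_id="S01"))
        split = build_scarf(view, "absolute", split_overlaps=True)
        merged = build_scarf(view, "absolute", split_overlaps=False)
        for rs, rm in zip(split.rows, merged.rows):
            assert {(r.x0, r.x1) for r in rs.rects} == {(r.x0, r.x1) for r in rm.rects}
            assert {(r.t0_ms, r.t1_ms) for r in rs.rects} == {(r.t0_ms, r.t1_ms) for r in rm.rects}

    def test_no_aoi_fixation_reserved_style(self):
        ds = make_dataset([("P1", "S", 0, 100, "fixation", ())])
        (rect,) = build_scarf(ds, "absolute").rows[0].rects
        assert rect.color == NO_AOI_COLOR and rect.label == "no AOI"

    def test_relative_rows_span_0_100(self, small_fixture):
        ds, _ = small_fixture
        g = build_scarf(ds, "relative", stimulus_id="S02")
        assert g.domain == (0.0, 100.0)
        for row in g.rows:
            assert math.isclose(min(r.x0 for r in row.rects), 0.0, abs_tol=1e-9)
            assert math.isclose(max(r.x1 for r in row.rects), 100.0, abs_tol=1e-9)

    def test_ordinal_row_width_equals_segment_count(self, small_fixture):
        ds, _ = small_fixture
        g = build_scarf(ds, "ordinal", stimulus_id="S01")
        for row in g.rows:
            n_segments = len(
                [
                    s
                    for s in ds.segments
                    if s.participant_id == row.participant_id and s.stimulus_id == "S01"
                ]
            )
            assert max(r.x1 for r in row.rects) == n_segments

    def test_absolute_bar_length_equals_summed_durations(self, small_fixture):
        ds, _ = small_fixture
        g = build_scarf(ds, "absolute", stimulus_id="S01")
        for row in g.rows:
            covered = sum(
                r.x1 - r.x0 for r in row.rects if r.sub_band == 0
            )
            total = sum(
                s.duration
                for s in ds.segments
                if s.participant_id == row.participant_id and s.stimulus_id == "S01"
            )
            assert math.isclose(covered, total, rel_tol=1e-12)

    def test_metadata_keeps_original_time_range_in_every_mode(self, small_fixture):
        ds, _ = small_fixture
        for mode in ("absolute", "relative", "ordinal"):
            g = build_scarf(ds, mode, stimulus_id="S01")
            for r in g.iter_rects():
                assert r.duration_ms == r.t1_ms - r.t0_ms > 0

    def test_filter_then_build_equals_build_then_clip(self, plain_fixture):
        """Time-range filtering commutes with geometric clipping (absolute)."""
        ds, _ = plain_fixture
        t0, t1 = 500.0, 1500.0
        filtered = build_scarf(
            apply_filter(ds, ViewFilter(stimulus_id="S01", time_range=(t0, t1))), "absolute"
        )
        full = build_scarf(apply_filter(ds, ViewFilter(stimulus_id="S01")), "absolute")
        # trials start at 0, so clipping geometry x to [t0, t1) and shifting
        # to the filtered onset must reproduce the filtered build
        for row_f, row_c in zip(filtered.rows, full.rows):
            clipped = [
                (max(r.x0, t0), min(r.x1, t1), r.sub_band, r.color)
                for r in row_c.rects
                if min(r.x1, t1) > max(r.x0, t0)
            ]
            onset = min(x0 for x0, *_ in clipped)
            shifted = [(x0 - onset, x1 - onset, sb, c) for x0, x1, sb, c in clipped]
            got = [(r.x0, r.x1, r.sub_band, r.color) for r in row_f.rects]
            assert got == shifted

    def test_merge_unmerge_identity_on_geometry(self, small_fixture):
        ds, _ = small_fixture
        before = build_scarf(ds, "absolute", stimulus_id="S01")
        restored = build_scarf(
            unmerge_aois(merge_aois(ds, "X", ["AOI_A", "AOI_B"]), "X"),
            "absolute",
            stimulus_id="S01",
        )
        assert before == restored

    def test_visibility_bands_per_participant_override(self):
        from scarfkit import parse_visibility

        ds = make_dataset(
            [
                ("P1", "S", 0, 400, "fixation", {"A"}),
                ("P2", "S", 0, 400, "fixation", {"A"}),
            ]
        )
        sched = parse_visibility("aoi,stimulus,start_ms,end_ms\nA,S,0,100\n", scope="P1")
        g = build_scarf(ds.with_visibility(sched), "absolute", show_visibility=True)
        bands = {row.participant_id: row.visibility for row in g.rows}
        (aoi1, rects1), = bands["P1"]
        assert [(r.x0, r.x1) for r in rects1] == [(0.0, 100.0)]
        (aoi2, rects2), = bands["P2"]
        assert [(r.x0, r.x1) for r in rects2] == [(0.0, 400.0)]  # default: whole trial

    def test_visibility_layer_off_means_no_bands(self, small_fixture):
        ds, _ = small_fixture
        g = build_scarf(ds, "absolute", stimulus_id="S01", show_visibility=False)
        assert all(row.visibility == () for row in g.rows)

    def test_visibility_in_ordinal_mode_rejected(self, small_fixture):
        ds, _ = small_fixture
        with pytest.raises(ValidationError, match="time axis"):
            build_scarf(ds, "ordinal", stimulus_id="S01", show_visibility=True)

    def test_multi_stimulus_view_needs_explicit_stimulus(self, small_fixture):
        ds, _ = small_fixture
        with pytest.raises(ValidationError, match="stimulus"):
            build_scarf(ds, "absolute")


class TestLegend:
    def test_aois_plus_present_special_classes(self):
        ds = make_dataset(
            [
                ("P1", "S", 0, 100, "fixation", {"A"}),
                ("P1", "S", 100, 120, "saccade", ()),
                ("P1", "S", 120, 200, "fixation", {"B"}),
            ]
        )
        entries = legend(ds)
        assert [(name, cls) for name, _, cls in entries] == [
            ("A", "aoi"),
            ("B", "aoi"),
            ("saccade", "saccade"),
        ]

    def test_merge_aware(self):
        ds = make_dataset(
            [
                ("P1", "S", 0, 100, "fixation", {"A"}),
                ("P1", "S", 100, 120, "saccade", ()),
                ("P1", "S", 120, 200, "fixation", {"B"}),
            ]
        )
        merged = merge_aois(ds, "AB", ["A", "B"])
        assert [name for name, _, _ in legend(merged)] == ["AB", "saccade"]

    def test_empty_dataset_empty_legend(self):
        from scarfkit import canonicalize

        assert legend(canonicalize([])) == []
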