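"""Fixation metrics, the rasterization oracle, and interval reconstruction."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from scarfkit import (
    AoiMetricsRecord,
    ValidationError,
    compute_aoi_metrics,
    metrics_oracle,
    reconstruct_interval_metrics,
    unify_split_trials,
)
from scarfkit.fixtures import FixtureSpec, generate, random_cuts

from conftest import make_dataset


def by_key(records):
    return {(r.participant_id, r.stimulus_id, r.aoi_id): r for r in records}


def assert_records_match(a, b, *, temporal_tol=0.0):
    da, db = by_key(a), by_key(b)
    assert da.keys() == db.keys()
    for k in da:
        ra, rb = da[k], db[k]
        assert ra.fixation_count == rb.fixation_count, k
        # per-event quantization error accumulates in the dwell sum
        dwell_tol = max(temporal_tol * ra.fixation_count, 1e-9)
        assert math.isclose(ra.dwell_time, rb.dwell_time, abs_tol=dwell_tol), k
        for attr in ("time_to_first_fixation", "avg_fixation_duration"):
            va, vb = getattr(ra, attr), getattr(rb, attr)
            assert (va is None) == (vb is None), k
            if va is not None:
                assert abs(va - vb) <= max(temporal_tol, 1e-9), (k, attr, va, vb)


class TestComputeMetrics:
    def test_worked_example(self, worked_example):
        recs = by_key(compute_aoi_metrics(worked_example))
        a = recs[("P1", "S", "A")]
        assert (a.time_to_first_fixation, a.fixation_count) == (0, 2)
        assert (a.avg_fixation_duration, a.dwell_time) == (75, 150)
        b = recs[("P1", "S", "B")]
        assert (b.time_to_first_fixation, b.fixation_count) == (120, 1)
        assert (b.avg_fixation_duration, b.dwell_time) == (180, 180)

    def test_worked_example_against_oracle(self, worked_example):
        assert_records_match(
            compute_aoi_metrics(worked_example), metrics_oracle(worked_example, 1.0)
        )

    def test_ttff_zero_when_first_event_hits(self):
        ds = make_dataset([("P1", "S", 500, 600, "fixation", {"A"})])
        (rec,) = compute_aoi_metrics(ds)
        assert rec.time_to_first_fixation == 0  # onset-referenced, not absolute

    def test_never_fixated_aoi_zero_record_on_request(self):
        from scarfkit import AoiDefinition

        ds = make_dataset(
            [("P1", "S", 0, 100, "fixation", {"A"})],
            aois={
                "A": AoiDefinition("A", "A", "#4e79a7"),
                "B": AoiDefinition("B", "B", "#f28e2b"),
            },
        )
        recs = by_key(compute_aoi_metrics(ds, include_zero=True))
        b = recs[("P1", "S", "B")]
        assert b.fixation_count == 0 and b.dwell_time == 0
        assert b.time_to_first_fixation is None and b.avg_fixation_duration is None

    def test_saccades_and_other_excluded(self):
        ds = make_dataset(
            [
                ("P1", "S", 0, 100, "saccade", ()),
                ("P1", "S", 100, 200, "other", ()),
                ("P1", "S", 200, 300, "fixation", {"A"}),
            ]
        )
        (rec,) = compute_aoi_metrics(ds)
        assert rec.dwell_time == 100
        assert rec.time_to_first_fixation == 200  # onset at 0 from the saccade

    def test_overlap_counts_fully_toward_each_aoi(self):
        ds = make_dataset([("P1", "S", 0, 100, "fixation", {"A", "B"})])
        recs = by_key(compute_aoi_metrics(ds))
        assert recs[("P1", "S", "A")].dwell_time == 100
        assert recs[("P1", "S", "B")].dwell_time == 100

    def test_invariant_avg_times_count_equals_dwell(self, small_fixture):
        ds, _ = small_fixture
        for r in compute_aoi_metrics(ds):
            assert math.isclose(
                r.avg_fixation_duration * r.fixation_count, r.dwell_time, rel_tol=1e-9
            )

    def test_inconsistent_record_rejected(self):
        with pytest.raises(ValidationError):
            AoiMetricsRecord("P", "S", "A", None, 2, 75.0, 150.0)

    def test_ground_truth_cross_check(self, small_fixture):
        ds, truth = small_fixture
        assert_records_match(compute_aoi_metrics(ds), truth)

    def test_conservation_without_overlap(self):
        ds, _ = generate(
            FixtureSpec(n_participants=2, n_stimuli=2, seed=9, overlap_probability=0.0)
        )
        recs = compute_aoi_metrics(ds)
        dwell_sum = sum(r.dwell_time for r in recs)
        fix_time = sum(s.duration for s in ds.segments if s.category == "fixation")
        unassigned = sum(
            s.duration for s in ds.segments if s.category == "fixation" and not s.aoi_ids
        )
        assert math.isclose(dwell_sum + unassigned, fix_time, rel_tol=1e-12)

    def test_monotonicity_adding_fixation(self):
        base = [("P1", "S", 0, 100, "fixation", {"A"}), ("P1", "S", 150, 250, "fixation", {"B"})]
        before = by_key(compute_aoi_metrics(make_dataset(base)))[("P1", "S", "A")]
        grown = by_key(
            compute_aoi_metrics(make_dataset(base + [("P1", "S", 300, 400, "fixation", {"A"})]))
        )[("P1", "S", "A")]
        assert grown.fixation_count >= before.fixation_count
        assert grown.dwell_time >= before.dwell_time
        assert grown.time_to_first_fixation <= before.time_to_first_fixation


class TestOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_integer_boundaries(self, seed):
        ds, _ = generate(
            FixtureSpec(n_participants=2, n_stimuli=3, seed=seed, integer_ms=True)
        )
        assert_records_match(compute_aoi_metrics(ds), metrics_oracle(ds, 1.0))

    @pytest.mark.parametrize("seed", range(3))
    def test_oracle_within_resolution_fractional_boundaries(self, seed):
        ds, _ = generate(FixtureSpec(n_participants=2, n_stimuli=2, seed=seed))
        assert_records_match(
            compute_aoi_metrics(ds), metrics_oracle(ds, 1.0), temporal_tol=1.0
        )

    def test_empty_view_empty_list(self):
        from scarfkit import canonicalize

        assert metrics_oracle(canonicalize([]), 1.0) == []

    def test_bad_resolution_rejected(self, worked_example):
        with pytest.raises(ValidationError, match="resolution"):
            metrics_oracle(worked_example, 0)


class TestReconstruction:
    def test_documented_two_interval_example(self):
        i1 = AoiMetricsRecord("P", "S#1", "A", 0.0, 2, 75.0, 150.0)
        i2 = AoiMetricsRecord("P", "S#2", "A", 10.0, 1, 60.0, 60.0)
        u = reconstruct_interval_metrics([i1, i2], [0.0, 500.0], stimulus_id="S")
        assert u.fixation_count == 3
        assert u.dwell_time == 210
        assert u.avg_fixation_duration == 70
        assert u.time_to_first_fixation == 0

    def test_single_interval_is_identity(self):
        r = AoiMetricsRecord("P", "S", "A", 5.0, 2, 75.0, 150.0)
        assert reconstruct_interval_metrics([r], [0.0]) == r

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            reconstruct_interval_metrics([], [])

    def test_mismatched_keys_rejected(self):
        r1 = AoiMetricsRecord("P", "S", "A", 0.0, 1, 50.0, 50.0)
        r2 = AoiMetricsRecord("P", "S", "B", 0.0, 1, 50.0, 50.0)
        with pytest.raises(ValidationError, match="mismatched"):
            reconstruct_interval_metrics([r1, r2], [0.0, 100.0])

    @given(st.integers(min_value=0, max_value=50))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_split_and_reconstruct_exact_at_full_precision(self, seed):
        """Cutting trials anywhere and unifying reproduces direct metrics."""
        ds, _ = generate(
            FixtureSpec(n_participants=2, n_stimuli=1, seed=seed, group_labels=(), visibility_density=0)
        )
        cuts = random_cuts(ds, seed=seed + 1)
        split = split_dataset_exact(ds, cuts)
        assert_records_match(unify_split_trials(split), compute_aoi_metrics(ds))

    @pytest.mark.parametrize("seed", range(8))
    def test_rounded_interval_reconstruction_within_1ms(self, seed):
        """Integer-ms interval-split exports reconstruct within +-1 ms."""
        from scarfkit import parse, write_dialect

        ds, _ = generate(
            FixtureSpec(n_participants=2, n_stimuli=2, seed=seed, group_labels=(), visibility_density=0)
        )
        cuts = random_cuts(ds, seed=seed)
        parsed = parse(write_dialect(ds, "tobii_like", cuts=cuts))
        assert_records_match(
            unify_split_trials(parsed), compute_aoi_metrics(ds), temporal_tol=1.0
        )


def split_dataset_exact(ds, cuts):
    """Split trials at cut points without rounding (full precision)."""
    return split_and_round_no_rounding(ds, cuts)


def split_and_round_no_rounding(dataset, cuts):
    from scarfkit import GazeSegment, canonicalize

    out = []
    for (pid, stim), segs in dataset.trials():
        onset = min(s.start for s in segs)
        end = max(s.end for s in segs)
        trial_cuts = sorted(c for c in cuts.get((pid, stim), ()) if onset < c < end)
        bounds = [onset, *trial_cuts, end]
        for k in range(len(bounds) - 1):
            for seg in segs:
                piece = seg.clipped(bounds[k], bounds[k + 1])
                if piece is not None:
                    out.append(
                        GazeSegment(
                            pid, f"{stim}#{k + 1}", piece.start, piece.end,
                            seg.category, seg.aoi_ids,
                        )
                    )
    return canonicalize(out)
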