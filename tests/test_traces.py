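"""Neutroid-to-trace linking, culling, splitting and hull recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chargite import (
    Neutroid,
    TraceBuilderConfig,
    build_neutromer_traces,
    cull_short_traces,
    detect_features,
    extract_hulls,
    split_traces,
)

from conftest import make_trace


def n(mz, scan, intensity=10.0):
    return Neutroid(mz=mz, rt=float(scan), intensity=intensity, scan_index=scan)


def by_scan(*neutroids):
    out = {}
    for x in neutroids:
        out.setdefault(x.scan_index, []).append(x)
    return out


def trace_mzs(traces):
    return [[x.mz for x in t.neutroids] for t in traces]


class TestLinking:
    def test_within_tolerance_joins(self):
        # 0.0017 Th at 500 Th is 3.4 ppm, inside the 7 ppm window
        traces = build_neutromer_traces(by_scan(n(500.0000, 0), n(500.0017, 1)))
        assert trace_mzs(traces) == [[500.0000, 500.0017]]

    def test_outside_tolerance_separates(self):
        # 0.0040 Th at 500 Th is 8.0 ppm, outside the window
        traces = build_neutromer_traces(by_scan(n(500.0000, 0), n(500.0040, 1)))
        assert trace_mzs(traces) == [[500.0000], [500.0040]]

    def test_penultimate_scan_bridges_one_gap(self):
        traces = build_neutromer_traces(by_scan(n(500.0000, 0), n(500.0010, 2)))
        assert trace_mzs(traces) == [[500.0000, 500.0010]]

    def test_two_missing_scans_never_bridge(self):
        traces = build_neutromer_traces(by_scan(n(500.0000, 0), n(500.0010, 3)))
        assert trace_mzs(traces) == [[500.0000], [500.0010]]

    def test_closest_in_ppm_wins(self):
        # 500.0005 is 1.0 ppm from the 500.0000 trace and 3.0 ppm from 500.0020
        traces = build_neutromer_traces(
            by_scan(n(500.0000, 0), n(500.0020, 0), n(500.0005, 1))
        )
        assert trace_mzs(traces) == [[500.0000, 500.0005], [500.0020]]

    def test_contention_reassigns_loser(self):
        # Both scan-1 neutroids are within tolerance of the single open trace;
        # the closer one claims it and the other opens a new trace.
        traces = build_neutromer_traces(
            by_scan(n(500.0000, 0), n(500.0004, 1), n(500.0015, 1))
        )
        assert trace_mzs(traces) == [[500.0000, 500.0004], [500.0015]]

    def test_duplicate_neutroid_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_neutromer_traces(by_scan(n(500.0, 0), n(500.0, 0)))

    def test_reference_mz_is_most_recent_member(self):
        # drift: each step is 3 ppm from the previous member but the third
        # point is ~6 ppm from the first; last-member referencing keeps it
        traces = build_neutromer_traces(
            by_scan(n(500.0000, 0), n(500.0015, 1), n(500.0030, 2))
        )
        assert trace_mzs(traces) == [[500.0000, 500.0015, 500.0030]]


class TestCull:
    def test_threshold_at_two(self):
        traces = [make_trace([1.0]), make_trace([1.0, 2.0]), make_trace([1.0] * 5)]
        assert [len(t) for t in cull_short_traces(traces)] == [2, 5]

    def test_all_singletons_culled(self):
        assert cull_short_traces([make_trace([1.0])] * 3) == []

    def test_min_length_one_is_identity(self):
        traces = [make_trace([1.0]), make_trace([1.0, 2.0])]
        cfg = TraceBuilderConfig(min_trace_length=1)
        assert cull_short_traces(traces, cfg) == traces


class TestSplit:
    def test_boundary_ratio_triggers(self):
        # minimum 10.0, lesser flanking maximum 13.0: 13.0 / 1.3 = 10.0 -> split
        traces = split_traces([make_trace([5, 13.1, 10.0, 13.0, 6])])
        assert [[x.intensity for x in t.neutroids] for t in traces] == [
            [5, 13.1],
            [10.0, 13.0, 6],
        ]

    def test_above_boundary_does_not_trigger(self):
        traces = split_traces([make_trace([5, 13.1, 10.1, 13.0, 6])])
        assert [len(t) for t in traces] == [5]

    def test_monotone_trace_unchanged(self):
        traces = split_traces([make_trace([1.0, 2.0, 3.0, 4.0])])
        assert [len(t) for t in traces] == [4]

    def test_minimum_joins_right_segment(self):
        (left, right) = split_traces([make_trace([5, 13.1, 10.0, 13.0, 6])])
        assert right.neutroids[0].intensity == 10.0

    def test_iterative_splitting(self):
        profile = [5, 20.0, 2.0, 20.0, 2.0, 20.0, 5]
        traces = split_traces([make_trace(profile)])
        assert [[x.intensity for x in t.neutroids] for t in traces] == [
            [5, 20.0],
            [2.0, 20.0],
            [2.0, 20.0, 5],
        ]

    def test_short_segments_culled_after_split(self):
        # splitting strands a singleton right segment -> culled
        traces = split_traces([make_trace([13.1, 10.0, 13.0, 1.0, 13.2, 13.0])])
        total = sum(len(t) for t in traces)
        assert total <= 6
        for t in traces:
            assert len(t) >= 2


class TestExtractHulls:
    def test_hulls_follow_traces(self, small_run):
        run, _ = small_run
        result = detect_features(run)
        hulls = extract_hulls(result.traces, run)
        assert len(hulls) == len(result.traces)
        for trace, hull in zip(result.traces, hulls):
            assert [h.scan_index for h in hull.instantaneous_hulls] == [
                x.scan_index for x in trace.neutroids
            ]
            # hull point intensities sum to the trace's neutroid intensities
            for x, h in zip(trace.neutroids, hull.instantaneous_hulls):
                assert h.intensity.sum() == pytest.approx(x.intensity, rel=1e-12)

    def test_unsourced_neutroid_matches_by_mz(self, small_run):
        run, _ = small_run
        result = detect_features(run)
        stripped = [
            make_trace_like(t) for t in result.traces[:2]
        ]
        hulls = extract_hulls(stripped, run)
        assert all(len(h) == len(t) for h, t in zip(hulls, stripped))

    def test_missing_source_is_an_error(self, small_run):
        run, _ = small_run
        ghost = make_trace([5.0, 6.0], mz=777.777)
        with pytest.raises(ValueError, match="no source hull"):
            extract_hulls([ghost], run)

    def test_empty_input(self, small_run):
        run, _ = small_run
        assert extract_hulls([], run) == []


def make_trace_like(trace):
    from chargite import NeutromerTrace

    return NeutromerTrace(
        neutroids=[
            Neutroid(mz=x.mz, rt=x.rt, intensity=x.intensity, scan_index=x.scan_index)
            for x in trace.neutroids
        ],
        trace_id=trace.trace_id,
    )


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@st.composite
def random_neutroid_scans(draw):
    n_scans = draw(st.integers(min_value=1, max_value=8))
    out = {}
    for s in range(n_scans):
        if draw(st.booleans()):
            continue  # missing scan
        mzs = draw(
            st.lists(
                st.floats(min_value=400.0, max_value=401.0),
                min_size=0,
                max_size=4,
                unique=True,
            )
        )
        out[s] = [n(mz, s, intensity=draw(st.floats(1.0, 100.0))) for mz in mzs]
    return out


@given(scans=random_neutroid_scans())
@settings(deadline=None, max_examples=150)
def test_partition_property(scans):
    """Every input neutroid lands in at most one trace; no trace invents members."""
    inputs = {(x.scan_index, x.mz) for v in scans.values() for x in v}
    cfg = TraceBuilderConfig(min_trace_length=1)
    traces = split_traces(build_neutromer_traces(scans, cfg), cfg)
    seen = []
    for t in traces:
        for x in t.neutroids:
            seen.append((x.scan_index, x.mz))
    assert len(seen) == len(set(seen))
    assert set(seen) <= inputs


@given(scans=random_neutroid_scans())
@settings(deadline=None, max_examples=150)
def test_gap_law(scans):
    """No surviving trace spans a gap of more than max_gap_scans+1 scan indices."""
    cfg = TraceBuilderConfig(min_trace_length=1)
    for t in build_neutromer_traces(scans, cfg):
        idx = [x.scan_index for x in t.neutroids]
        assert all(b - a <= cfg.max_gap_scans + 1 for a, b in zip(idx, idx[1:]))


@given(scans=random_neutroid_scans(), seed=st.integers(0, 2**16))
@settings(deadline=None, max_examples=100)
def test_determinism_under_permutation(scans, seed):
    rng = np.random.default_rng(seed)
    shuffled = {
        s: list(rng.permutation(len(v)))
        for s, v in scans.items()
    }
    permuted = {s: [scans[s][i] for i in shuffled[s]] for s in scans}
    a = build_neutromer_traces(scans)
    b = build_neutromer_traces(permuted)
    assert trace_mzs(a) == trace_mzs(b)


def test_broken_elution_yields_two_traces():
    """A species absent for two consecutive scans cannot remain one trace."""
    scans = by_scan(
        n(600.0, 0), n(600.0, 1), n(600.0, 2),
        n(600.0, 5), n(600.0, 6),
    )
    traces = build_neutromer_traces(scans)
    assert [len(t) for t in traces] == [3, 2]
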