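"""Assembly of neutroids into neutromer traces across retention time.

Scans are processed in order. Each neutroid joins the open trace whose
reference m/z (the m/z of the trace's most recently added neutroid) is nearest
in ppm, provided it is within the linking tolerance and the trace last gained
a neutroid in the previous or penultimate scan (one missing scan may be
bridged). Otherwise the neutroid opens a new trace. Traces that end up with
fewer than the minimum number of neutroids are culled, and traces that were
erroneously merged are split wherever an interior intensity minimum falls at
or below 1/split_ratio of the lesser of its two flanking local maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .centroid import CentroiderConfig, centroid_run
from .model import InstantaneousNeutromerHull, Neutroid, NeutromerHull, NeutromerTrace, RawRun

__all__ = [
    "TraceBuilderConfig",
    "build_neutromer_traces",
    "cull_short_traces",
    "split_traces",
    "extract_hulls",
]

# Relative slack on the split-rule comparison so the exact-ratio boundary case
# ("less than or equal to") survives float rounding of lesser_max / split_ratio.
_SPLIT_REL_EPS = 1e-12


@dataclass(frozen=True)
class TraceBuilderConfig:
    """Linking, culling and splitting parameters.

    ppm_tol
        Maximum relative m/z difference (ppm) for a neutroid to join a trace.
    max_gap_scans
        Number of missing scans a trace may bridge (1 means a neutroid in scan
        n may continue a trace last seen in scan n-2).
    min_trace_length
        Traces with fewer neutroids are culled.
    split_ratio
        A trace splits at an interior minimum whose intensity is at most
        (lesser flanking local maximum) / split_ratio.
    """

    ppm_tol: float = 7.0
    max_gap_scans: int = 1
    min_trace_length: int = 2
    split_ratio: float = 1.3

    def __post_init__(self) -> None:
        if not self.ppm_tol > 0:
            raise ValueError("ppm_tol must be positive")
        if self.max_gap_scans < 0:
            raise ValueError("max_gap_scans must be >= 0")
        if self.min_trace_length < 1:
            raise ValueError("min_trace_length must be >= 1")
        if not self.split_ratio > 1:
            raise ValueError("split_ratio must be > 1")


class _OpenTrace:
    __slots__ = ("neutroids", "order")

    def __init__(self, neutroid: Neutroid, order: int) -> None:
        self.neutroids = [neutroid]
        self.order = order  # creation order, for deterministic output

    @property
    def last(self) -> Neutroid:
        return self.neutroids[-1]


def _ppm(mz: float, ref: float) -> float:
    return abs(mz - ref) / ref * 1e6


def build_neutromer_traces(
    neutroids_by_scan: Mapping[int, Sequence[Neutroid]],
    config: TraceBuilderConfig | None = None,
) -> list[NeutromerTrace]:
    """Link neutroids across scans into neutromer traces.

    Within a scan, neutroids are considered in ascending m/z. Each claims the
    eligible open trace nearest in ppm; if two neutroids contend for the same
    trace the closer one wins and the loser is reconsidered against the
    remaining traces (greedy with reinsertion). Each trace accepts at most one
    neutroid per scan. The result is deterministic under any permutation of
    the neutroids within a scan.
    """
    config = config or TraceBuilderConfig()
    window = config.max_gap_scans + 1  # a match may reach back this many scans
    open_traces: list[_OpenTrace] = []
    closed: list[_OpenTrace] = []
    counter = 0

    for scan_index in sorted(neutroids_by_scan):
        neutroids = sorted(neutroids_by_scan[scan_index], key=lambda n: n.mz)
        for a, b in zip(neutroids, neutroids[1:]):
            if a.mz == b.mz:
                raise ValueError(
                    f"duplicate neutroid at scan {scan_index}, mz {a.mz}"
                )
        # Retire traces that can no longer be extended.
        still_open: list[_OpenTrace] = []
        for t in open_traces:
            (closed if scan_index - t.last.scan_index > window else still_open).append(t)
        open_traces = still_open

        candidates = [t for t in open_traces if t.last.scan_index < scan_index]
        # trace -> (neutroid position, ppm distance) claims; greedy with reinsertion.
        claims: dict[int, tuple[int, float]] = {}
        excluded: dict[int, set[int]] = {i: set() for i in range(len(neutroids))}
        pending = list(range(len(neutroids)))
        assigned: dict[int, int] = {}  # neutroid position -> candidate index
        while pending:
            i = pending.pop(0)
            n = neutroids[i]
            best_j, best_ppm = -1, float("inf")
            for j, t in enumerate(candidates):
                if j in excluded[i]:
                    continue
                d = _ppm(n.mz, t.last.mz)
                if d <= config.ppm_tol and d < best_ppm:
                    best_j, best_ppm = j, d
            if best_j < 0:
                continue  # opens a new trace below
            if best_j not in claims or best_ppm < claims[best_j][1]:
                if best_j in claims:
                    loser = claims[best_j][0]
                    excluded[loser].add(best_j)
                    del assigned[loser]
                    pending.append(loser)
                claims[best_j] = (i, best_ppm)
                assigned[i] = best_j
            else:
                excluded[i].add(best_j)
                pending.append(i)
        for i, n in enumerate(neutroids):
            j = assigned.get(i)
            if j is None:
                open_traces.append(_OpenTrace(n, counter))
                counter += 1
            else:
                candidates[j].neutroids.append(n)

    closed.extend(open_traces)
    closed.sort(key=lambda t: t.order)
    return [
        NeutromerTrace(neutroids=t.neutroids, trace_id=f"t{k:05d}")
        for k, t in enumerate(closed)
    ]


def cull_short_traces(
    traces: Sequence[NeutromerTrace], config: TraceBuilderConfig | None = None
) -> list[NeutromerTrace]:
    """Discard traces shorter than min_trace_length, preserving input order."""
    config = config or TraceBuilderConfig()
    return [t for t in traces if len(t) >= config.min_trace_length]


def _split_points(intensities: Sequence[float], ratio: float) -> int:
    """Position of the first (leftmost) interior minimum that triggers a split, or -1.

    Local extrema are taken on runs of equal intensity (plateaus collapse to
    their leftmost member); a minimum is eligible only when flanked by a local
    maximum on each side.
    """
    vals: list[float] = []
    starts: list[int] = []
    for i, v in enumerate(intensities):
        if not vals or v != vals[-1]:
            vals.append(v)
            starts.append(i)
    n = len(vals)
    for r in range(1, n - 1):
        if not (vals[r] < vals[r - 1] and vals[r] < vals[r + 1]):
            continue
        # nearest flanking local maxima (runs strictly above both their neighbors)
        left_max = right_max = None
        for q in range(r - 1, -1, -1):
            lo = vals[q - 1] if q > 0 else float("-inf")
            if vals[q] > lo and vals[q] > vals[q + 1]:
                left_max = vals[q]
                break
        for q in range(r + 1, n):
            hi = vals[q + 1] if q < n - 1 else float("-inf")
            if vals[q] > hi and vals[q] > vals[q - 1]:
                right_max = vals[q]
                break
        if left_max is None or right_max is None:
            continue
        lesser = min(left_max, right_max)
        if vals[r] <= (lesser / ratio) * (1.0 + _SPLIT_REL_EPS):
            return starts[r]
    return -1


def split_traces(
    traces: Sequence[NeutromerTrace], config: TraceBuilderConfig | None = None
) -> list[NeutromerTrace]:
    """Split erroneously merged traces at deep interior intensity minima.

    Splitting is applied iteratively (segments are re-examined) and the
    minimum neutroid joins the right-hand segment. Surviving segments are
    re-subjected to the length cull.
    """
    config = config or TraceBuilderConfig()
    out: list[NeutromerTrace] = []
    for trace in traces:
        segments: list[list[Neutroid]] = []
        stack = [list(trace.neutroids)]
        while stack:
            seg = stack.pop(0)
            p = _split_points([n.intensity for n in seg], config.split_ratio)
            if p < 0:
                segments.append(seg)
            else:
                stack.insert(0, seg[p:])  # minimum joins the right-hand segment
                stack.insert(0, seg[:p])
        if len(segments) == 1:
            out.append(trace)
        else:
            for k, seg in enumerate(segments):
                out.append(NeutromerTrace(neutroids=seg, trace_id=f"{trace.trace_id}/s{k}"))
    return cull_short_traces(out, config)


def extract_hulls(
    traces: Sequence[NeutromerTrace],
    run: RawRun,
    config: CentroiderConfig | None = None,
) -> list[NeutromerHull]:
    """Recover the raw-point neutromer hulls behind each trace.

    Uses the hull recorded on each neutroid when present; otherwise re-detects
    hulls in the source run and matches by scan index and centroid m/z.
    """
    config = config or CentroiderConfig()
    out: list[NeutromerHull] = []
    recomputed: dict[int, list[Neutroid]] | None = None
    for trace in traces:
        hulls: list[InstantaneousNeutromerHull] = []
        for n in trace.neutroids:
            if n.source is not None:
                hulls.append(n.source)
                continue
            if recomputed is None:
                recomputed = centroid_run(run, config)
            match = None
            for cand in recomputed.get(n.scan_index, []):
                if abs(cand.mz - n.mz) <= 1e-9 * max(1.0, n.mz):
                    match = cand.source
                    break
            if match is None:
                raise ValueError(
                    f"no source hull found for neutroid at scan {n.scan_index}, mz {n.mz}"
                )
            hulls.append(match)
        out.append(NeutromerHull(instantaneous_hulls=hulls, trace_id=trace.trace_id))
    return out
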