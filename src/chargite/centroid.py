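"""Per-scan peak detection and centroiding.

Each profile-mode scan is segmented into instantaneous neutromer hulls by
searching for local intensity maxima along m/z and extending each maximum
left and right until the intensity either drops to zero or reaches a local
minimum. A separating local-minimum point belongs to neither adjacent hull,
so summed hull intensity is conserved exactly against the points assigned.

Each hull is then centroided into a neutroid: the m/z is the intensity-weighted
mean of the member points (the one- and two-point cases reduce to the point
itself and to the two-point weighted average), and the intensity is by default
the sum of the member intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import InstantaneousNeutromerHull, Neutroid, RawRun, Scan

__all__ = [
    "CentroiderConfig",
    "detect_instantaneous_hulls",
    "centroid_hull",
    "centroid_run",
]


@dataclass(frozen=True)
class CentroiderConfig:
    """Peak-detection settings.

    min_points
        Hulls with fewer member points are discarded.
    intensity_floor
        Points at or below this intensity are treated as zero (baseline gate).
    intensity_mode
        How a neutroid's intensity summarizes its hull: ``"sum"`` of member
        point intensities (default; makes intensity-conservation laws exact)
        or ``"apex"`` height.
    """

    min_points: int = 1
    intensity_floor: float = 0.0
    intensity_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        if self.intensity_mode not in ("sum", "apex"):
            raise ValueError("intensity_mode must be 'sum' or 'apex'")


def _runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress consecutive equal values into runs; return (start_indices, run_values)."""
    n = values.size
    starts = np.flatnonzero(np.concatenate(([True], values[1:] != values[:-1])))
    return starts, values[starts]


def detect_instantaneous_hulls(
    scan: Scan, config: CentroiderConfig | None = None
) -> list[InstantaneousNeutromerHull]:
    """Segment one scan into instantaneous neutromer hulls.

    A local maximum is a run of equal intensity strictly greater than both
    neighboring runs (scan edges count as valleys; an equal-intensity plateau
    collapses to its leftmost point as the apex). The hull extends from the
    apex run in both directions, stopping before the first zero-intensity run
    and before any local-minimum run; such separator runs join neither hull.
    """
    config = config or CentroiderConfig()
    if len(scan) == 0:
        return []
    inten = np.where(scan.intensity > config.intensity_floor, scan.intensity, 0.0)
    starts, vals = _runs(inten)
    nruns = vals.size
    ends = np.append(starts[1:], inten.size)  # run r covers [starts[r], ends[r])

    def left_val(r: int) -> float:
        return vals[r - 1] if r > 0 else -np.inf  # edge counts as a valley

    def right_val(r: int) -> float:
        return vals[r + 1] if r < nruns - 1 else -np.inf

    is_max = [
        vals[r] > 0 and vals[r] > left_val(r) and vals[r] > right_val(r)
        for r in range(nruns)
    ]
    # Separators: zero runs, and interior local-minimum runs.
    is_sep = [
        vals[r] == 0
        or (0 < r < nruns - 1 and vals[r] < vals[r - 1] and vals[r] < vals[r + 1])
        for r in range(nruns)
    ]

    hulls: list[InstantaneousNeutromerHull] = []
    for r in range(nruns):
        if not is_max[r]:
            continue
        lo_run = r
        while lo_run > 0 and not is_sep[lo_run - 1]:
            lo_run -= 1
        hi_run = r
        while hi_run < nruns - 1 and not is_sep[hi_run + 1]:
            hi_run += 1
        lo, hi = int(starts[lo_run]), int(ends[hi_run])
        if hi - lo < config.min_points:
            continue
        hulls.append(
            InstantaneousNeutromerHull(
                scan_index=scan.scan_index,
                rt=scan.rt,
                mz=scan.mz[lo:hi].copy(),
                intensity=inten[lo:hi].copy(),
                apex_index=int(starts[r]) - lo,
                start_index=lo,
            )
        )
    return hulls


def centroid_hull(
    hull: InstantaneousNeutromerHull, config: CentroiderConfig | None = None
) -> Neutroid:
    """Centroid one hull into a neutroid (intensity-weighted mean m/z)."""
    config = config or CentroiderConfig()
    total = float(hull.intensity.sum())
    if total <= 0:
        raise ValueError("cannot centroid a hull with zero total intensity")
    if len(hull) == 1:
        mz = float(hull.mz[0])  # a one-point peak is its own centroid
    else:
        mz = float(np.dot(hull.mz, hull.intensity) / total)
        # guard the hull-membership invariant against last-ULP rounding
        mz = min(max(mz, float(hull.mz[0])), float(hull.mz[-1]))
    intensity = total if config.intensity_mode == "sum" else float(hull.intensity[hull.apex_index])
    return Neutroid(mz=mz, rt=hull.rt, intensity=intensity, scan_index=hull.scan_index, source=hull)


def centroid_run(
    run: RawRun, config: CentroiderConfig | None = None
) -> dict[int, list[Neutroid]]:
    """Centroid every scan of a run; returns scan_index -> neutroids ascending in m/z.

    Centroid-mode runs pass through: each point above the intensity floor
    becomes a neutroid unchanged (its hull is the single point).
    """
    config = config or CentroiderConfig()
    out: dict[int, list[Neutroid]] = {}
    for scan in run.scans:
        if run.mode == "centroid":
            neutroids = []
            for j in range(len(scan)):
                if scan.intensity[j] <= config.intensity_floor:
                    continue
                hull = InstantaneousNeutromerHull(
                    scan_index=scan.scan_index,
                    rt=scan.rt,
                    mz=scan.mz[j : j + 1].copy(),
                    intensity=scan.intensity[j : j + 1].copy(),
                    apex_index=0,
                    start_index=j,
                )
                neutroids.append(centroid_hull(hull, config))
        else:
            hulls = detect_instantaneous_hulls(scan, config)
            neutroids = [centroid_hull(h, config) for h in hulls]
            neutroids.sort(key=lambda n: n.mz)
        out[scan.scan_index] = neutroids
    return out
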