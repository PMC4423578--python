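"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from chargite import Neutroid, NeutromerTrace, Scan

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


# ---------------------------------------------------------------------------
# Independent brute-force segmentation oracle.
#
# Point-by-point restatement of the peak-boundary rule, written with explicit
# loops and plateau scans rather than the run-compression the implementation
# uses: a hull grows outward from each apex until the next point is zero or
# belongs to an interior local-minimum plateau, which joins neither hull.
# ---------------------------------------------------------------------------


def _plateau(values, i):
    """(start, end) inclusive of the equal-intensity plateau containing i."""
    lo = i
    while lo - 1 >= 0 and values[lo - 1] == values[i]:
        lo -= 1
    hi = i
    while hi + 1 < len(values) and values[hi + 1] == values[i]:
        hi += 1
    return lo, hi


def _is_minimum_point(values, i):
    lo, hi = _plateau(values, i)
    if lo == 0 or hi == len(values) - 1:
        return False  # edge plateaus are valleys, not separator minima
    return values[lo - 1] > values[i] and values[hi + 1] > values[i]


def brute_force_hulls(intensities, floor=0.0, min_points=1):
    """All (start, stop) half-open hull spans of a scan, with apex positions.

    Returns a list of (start, stop, apex) triples sorted by start.
    """
    values = [v if v > floor else 0.0 for v in intensities]
    n = len(values)
    out = []
    for i in range(n):
        if values[i] == 0.0:
            continue
        lo, hi = _plateau(values, i)
        if lo != i:
            continue  # apex is the leftmost plateau member
        left = values[lo - 1] if lo > 0 else None
        right = values[hi + 1] if hi + 1 < n else None
        if (left is not None and left >= values[i]) or (
            right is not None and right >= values[i]
        ):
            continue  # not a local maximum
        a, b = lo, hi
        while a - 1 >= 0 and values[a - 1] != 0.0 and not _is_minimum_point(values, a - 1):
            a -= 1
        while b + 1 < n and values[b + 1] != 0.0 and not _is_minimum_point(values, b + 1):
            b += 1
        if b - a + 1 >= min_points:
            out.append((a, b + 1, i))
    return sorted(out)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def make_scan(intensities, scan_index=0, rt=0.0, mz_start=400.0, mz_step=0.01):
    """A scan with the given intensity profile on a uniform m/z ladder."""
    intensities = np.asarray(intensities, dtype=float)
    mz = mz_start + mz_step * np.arange(intensities.size)
    return Scan(scan_index=scan_index, rt=rt, mz=mz, intensity=intensities)


def make_trace(intensities, mz=500.0, rt0=0.0, rt_step=1.0, trace_id="t"):
    """A trace with one neutroid per scan carrying the given intensities."""
    neutroids = [
        Neutroid(mz=mz, rt=rt0 + i * rt_step, intensity=float(v), scan_index=i)
        for i, v in enumerate(intensities)
    ]
    return NeutromerTrace(neutroids=neutroids, trace_id=trace_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_run():
    """A tiny noise-free simulated run with one molecule at charges 1 and 2."""
    from chargite import MoleculeSpec, SimulationConfig, simulate_run

    config = SimulationConfig(
        molecules=(
            MoleculeSpec(
                neutral_mass=999.0,
                charges=(1, 2),
                elution_apex=60.0,
                elution_sigma=5.0,
                peak_height=1e5,
                isotope_abundances=(1.0, 0.5, 0.2),
            ),
        ),
        rt_end=120.0,
        scan_interval=1.0,
        mz_min=200.0,
        mz_max=1100.0,
        resolving_power=60000.0,
        seed=11,
    )
    return simulate_run(config)
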