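"""Typed data model for MS1 signal provenance.

The model makes the provenance of a precursor-level (MS1) signal explicit.
Reading from the raw data upward:

* a :class:`RawPoint` is one profile-mode (m/z, intensity) sample;
* a :class:`Scan` is one MS1 spectrum at a retention time;
* an :class:`InstantaneousNeutromerHull` is the contiguous run of raw points
  under a single isotopic species in a single scan;
* a :class:`Neutroid` is that hull centroided to one (m/z, RT, intensity) tuple;
* a :class:`NeutromerTrace` is the neutroids of one isotopic species linked
  through retention time;
* a :class:`ChargiteTrace` is the set of neutromer traces of one molecule at
  one charge state z, spaced ~1/z apart in m/z;
* a :class:`MolecularDistributionTrace` collects the chargites of one molecule
  across charge states.

Any reduction of these objects (summing through RT, slicing a scan, summing
isotopes, combining charge states) yields a :class:`ProjectedEntity` whose
``provenance`` records, in application order, exactly which reductions were
applied — so that the reduced tuple never loses the description of the data
structure it came from.
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "RawPoint",
    "Scan",
    "RawRun",
    "InstantaneousNeutromerHull",
    "Neutroid",
    "NeutromerHull",
    "NeutromerTrace",
    "ChargiteTrace",
    "MolecularDistributionTrace",
    "ProjectedEntity",
    "RT_MODES",
    "project_rt",
    "project_rt_entities",
]

#: Retention-time reduction modes: sum through RT, apex slice, mean, single-scan slice.
RT_MODES = ("integrated", "max", "average", "instantaneous")


@dataclass(frozen=True)
class RawPoint:
    """One profile-mode sample: m/z in thomson, intensity in (arbitrary) counts."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"RawPoint mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"RawPoint intensity must be >= 0, got {self.intensity}")


@dataclass
class Scan:
    """One MS1 spectrum: parallel m/z / intensity arrays, strictly ascending in m/z."""

    scan_index: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("Scan mz and intensity must be 1-D arrays of equal length")
        if self.rt < 0:
            raise ValueError(f"Scan rt must be non-negative, got {self.rt}")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"Scan {self.scan_index}: m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError(f"Scan {self.scan_index}: intensities must be >= 0")
        if self.mz.size and not np.all(self.mz > 0):
            raise ValueError(f"Scan {self.scan_index}: m/z values must be positive")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def points(self) -> Iterator[RawPoint]:
        for m, i in zip(self.mz, self.intensity):
            yield RawPoint(float(m), float(i))


@dataclass
class RawRun:
    """A sequence of MS1 scans ordered by retention time.

    ``mode`` distinguishes profile spectra (continuous peak sampling, the input
    the centroider expects) from already-centroided spectra (one point per peak).
    """

    scans: list[Scan]
    mode: str = "profile"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("profile", "centroid"):
            raise ValueError(f"RawRun mode must be 'profile' or 'centroid', got {self.mode!r}")
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("RawRun scan retention times must be strictly increasing")
        for expect, scan in enumerate(self.scans):
            if scan.scan_index != expect:
                raise ValueError(
                    f"RawRun scan_index must be contiguous from 0; got {scan.scan_index} at position {expect}"
                )

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class InstantaneousNeutromerHull:
    """Contiguous raw points under one isotopic species in one scan.

    ``apex_index`` is the position of the local intensity maximum within
    ``mz``/``intensity``; ``start_index`` records where the slice begins in the
    source scan (bookkeeping for contiguity and hull recovery).
    """

    scan_index: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    apex_index: int
    start_index: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.size == 0:
            raise ValueError("InstantaneousNeutromerHull must contain at least one point")
        if not 0 <= self.apex_index < self.mz.size:
            raise ValueError("apex_index out of range")
        if np.any(self.intensity > self.intensity[self.apex_index]):
            raise ValueError("apex_index must point at the maximum-intensity member")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class Neutroid:
    """An instantaneous centroided neutromer hull: one (m/z, RT, intensity) tuple."""

    mz: float
    rt: float
    intensity: float
    scan_index: int
    source: Optional[InstantaneousNeutromerHull] = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if not self.intensity > 0:
            raise ValueError(f"Neutroid intensity must be positive, got {self.intensity}")
        if self.source is not None:
            lo, hi = float(self.source.mz.min()), float(self.source.mz.max())
            if not lo <= self.mz <= hi:
                raise ValueError(
                    f"Neutroid mz {self.mz} outside its source hull span [{lo}, {hi}]"
                )


@dataclass
class NeutromerHull:
    """The raw-point (hull) form of a neutromer trace: its instantaneous hulls in scan order."""

    instantaneous_hulls: list[InstantaneousNeutromerHull]
    trace_id: str = ""

    def __post_init__(self) -> None:
        idx = [h.scan_index for h in self.instantaneous_hulls]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("NeutromerHull: at most one instantaneous hull per scan, in scan order")

    def __len__(self) -> int:
        return len(self.instantaneous_hulls)


@dataclass
class NeutromerTrace:
    """Neutroids of one isotopic species linked through retention time."""

    neutroids: list[Neutroid]
    trace_id: str = ""

    def __post_init__(self) -> None:
        idx = [n.scan_index for n in self.neutroids]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("NeutromerTrace neutroids must be strictly ascending in scan_index")

    def __len__(self) -> int:
        return len(self.neutroids)

    @property
    def mz(self) -> float:
        """Intensity-weighted mean m/z over member neutroids."""
        w = np.array([n.intensity for n in self.neutroids])
        m = np.array([n.mz for n in self.neutroids])
        return float(np.dot(w, m) / w.sum())

    @property
    def integrated_intensity(self) -> float:
        return float(sum(n.intensity for n in self.neutroids))

    @property
    def apex_rt(self) -> float:
        """RT of the maximum-intensity neutroid (earliest scan on ties)."""
        best = max(self.neutroids, key=lambda n: (n.intensity, -n.scan_index))
        return best.rt

    @property
    def rt_span(self) -> tuple[float, float]:
        return (self.neutroids[0].rt, self.neutroids[-1].rt)


@dataclass
class ChargiteTrace:
    """Signal of one molecule at one charge state: neutromer traces spaced ~Δiso/z apart.

    ``z == 0`` marks a singleton chargite whose charge could not be determined
    (no isotope partner found).
    """

    z: int
    neutromer_traces: list[NeutromerTrace]
    monoisotopic_mz: float
    chargite_id: str = ""

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("ChargiteTrace z must be >= 0 (0 = undetermined)")
        if not self.neutromer_traces:
            raise ValueError("ChargiteTrace must contain at least one neutromer trace")

    def __len__(self) -> int:
        return len(self.neutromer_traces)

    @property
    def integrated_intensity(self) -> float:
        return float(sum(t.integrated_intensity for t in self.neutromer_traces))

    @property
    def rt_span(self) -> tuple[float, float]:
        lo = min(t.rt_span[0] for t in self.neutromer_traces)
        hi = max(t.rt_span[1] for t in self.neutromer_traces)
        return (lo, hi)

    def neutral_mass(self, proton_mass: float) -> float:
        if self.z < 1:
            raise ValueError("neutral mass undefined for a chargite with undetermined charge")
        return self.z * (self.monoisotopic_mz - proton_mass)


@dataclass
class MolecularDistributionTrace:
    """The chargites of one molecule across charge states, with a consensus neutral mass (Da)."""

    chargites: list[ChargiteTrace]
    neutral_mass: float
    molecule_id: str = ""

    def __post_init__(self) -> None:
        if not self.chargites:
            raise ValueError("MolecularDistributionTrace must contain at least one chargite")
        zs = [c.z for c in self.chargites]
        if len(set(zs)) != len(zs):
            raise ValueError("MolecularDistributionTrace chargites must have distinct z")

    def __len__(self) -> int:
        return len(self.chargites)

    @property
    def integrated_intensity(self) -> float:
        return float(sum(c.integrated_intensity for c in self.chargites))


@dataclass(frozen=True)
class ProjectedEntity:
    """A reduced (m/z, RT, intensity) tuple carrying its reduction provenance.

    ``provenance`` lists qualifier tags in application order, e.g.
    ``("deisotoped", "integrated")`` for a chargite summed first through the
    isotope dimension and then through RT.
    """

    mz: float
    rt: float
    intensity: float
    provenance: tuple[str, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("ProjectedEntity provenance must be non-empty")
        if len(set(self.provenance)) != len(self.provenance):
            raise ValueError(f"ProjectedEntity provenance tags must be unique: {self.provenance}")


# ---------------------------------------------------------------------------
# RT-dimension qualifiers
# ---------------------------------------------------------------------------


def _reduce_rt(
    mzs: np.ndarray,
    rts: np.ndarray,
    ints: np.ndarray,
    mode: str,
    rt: Optional[float],
) -> tuple[float, float, float]:
    """Apply one RT qualifier to parallel (mz, rt, intensity) member arrays.

    integrated: intensity is the sum; m/z and RT are intensity-weighted means.
    max: the member tuple of greatest intensity (earliest scan on ties).
    average: intensity is the arithmetic mean; m/z and RT as for integrated.
    instantaneous: the member tuple at the requested RT.
    """
    if mode not in RT_MODES:
        raise ValueError(f"unknown RT mode {mode!r}; expected one of {RT_MODES}")
    total = float(ints.sum())
    if mode in ("integrated", "average"):
        if total > 0:
            wmz = float(np.dot(ints, mzs) / total)
            wrt = float(np.dot(ints, rts) / total)
        else:  # all-zero member intensities: fall back to unweighted means
            wmz, wrt = float(mzs.mean()), float(rts.mean())
        value = total if mode == "integrated" else total / len(ints)
        return (wmz, wrt, value)
    if mode == "max":
        i = int(np.argmax(ints))  # np.argmax returns the first maximum: earliest scan wins
        return (float(mzs[i]), float(rts[i]), float(ints[i]))
    # instantaneous
    if rt is None:
        raise ValueError("mode='instantaneous' requires an rt")
    hits = np.nonzero(rts == rt)[0]
    if hits.size == 0:
        nearest = float(rts[int(np.argmin(np.abs(rts - rt)))])
        raise ValueError(
            f"no member at rt={rt}; nearest available rt is {nearest}"
        )
    i = int(hits[0])
    return (float(mzs[i]), float(rts[i]), float(ints[i]))


def project_rt(
    entity,
    mode: str,
    rt: Optional[float] = None,
):
    """Reduce a trace through the RT dimension.

    For a :class:`NeutromerTrace` returns one :class:`ProjectedEntity`; for a
    :class:`ChargiteTrace` the qualifier is applied per constituent neutromer
    trace and the projections are returned in isotope order (k = 0, 1, ...).
    The qualifier tag is appended to the result's provenance.
    """
    if isinstance(entity, ChargiteTrace):
        return [project_rt(t, mode, rt) for t in entity.neutromer_traces]
    if not isinstance(entity, NeutromerTrace):
        raise TypeError(f"project_rt expects NeutromerTrace or ChargiteTrace, got {type(entity)}")
    if not entity.neutroids:
        raise ValueError("cannot project an empty trace")
    mzs = np.array([n.mz for n in entity.neutroids])
    rts = np.array([n.rt for n in entity.neutroids])
    ints = np.array([n.intensity for n in entity.neutroids])
    mz, out_rt, inten = _reduce_rt(mzs, rts, ints, mode, rt)
    return ProjectedEntity(mz, out_rt, inten, (mode,), source_id=entity.trace_id)


def project_rt_entities(
    entities: Sequence[ProjectedEntity],
    mode: str,
    rt: Optional[float] = None,
) -> ProjectedEntity:
    """Apply an RT qualifier to per-scan projected entities (e.g. a deisotoped chargite).

    All members must share provenance; the new tag is appended in application
    order.
    """
    if not entities:
        raise ValueError("cannot project an empty entity sequence")
    base = entities[0].provenance
    if any(e.provenance != base for e in entities):
        raise ValueError("members must share provenance before an RT reduction")
    if mode in base:
        raise ValueError(f"RT qualifier {mode!r} already present in provenance {base}")
    mzs = np.array([e.mz for e in entities])
    rts = np.array([e.rt for e in entities])
    ints = np.array([e.intensity for e in entities])
    mz, out_rt, inten = _reduce_rt(mzs, rts, ints, mode, rt)
    return ProjectedEntity(mz, out_rt, inten, base + (mode,), source_id=entities[0].source_id)
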