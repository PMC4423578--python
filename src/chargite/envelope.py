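"""Isotope-envelope and charge-state grouping, and the m/z-dimension qualifiers.

Neutromer traces are grouped into chargite traces by looking, from an
intensity-ranked seed, for co-eluting traces at m/z offsets of k * Δiso / z
(Δiso defaults to the 13C-12C mass difference, 1.003355 Da); the charge state
that explains the most traces wins. Chargites whose implied neutral masses
M = z * (monoisotopic m/z - proton mass) agree, and that co-elute, merge into
molecular distribution traces.

The two m/z qualifiers operate on these groups: *deisotoped* sums a chargite's
member intensities through the isotope dimension per scan (anchored at the
monoisotopic m/z), and *reduced* combines a molecule's chargites at the lowest
common charge state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import (
    ChargiteTrace,
    MolecularDistributionTrace,
    NeutromerTrace,
    ProjectedEntity,
    project_rt_entities,
)

__all__ = [
    "EnvelopeConfig",
    "group_chargites",
    "deisotope",
    "group_molecules",
    "reduce_molecule",
]

#: CODATA proton mass in Da.
PROTON_MASS = 1.007276466812

#: 13C - 12C mass difference in Da, the conventional isotope spacing.
ISOTOPE_SPACING = 1.003355


@dataclass(frozen=True)
class EnvelopeConfig:
    """Grouping parameters.

    isotope_spacing
        Mass difference between successive isotopic species (Da). The default
        is the 13C-12C difference; set 1.0 to reproduce the idealized
        "m/z 1/z apart" convention.
    charge_range
        Inclusive (min, max) charge states tried when grouping.
    grouping_ppm_tol
        Tolerance on the predicted isotope-partner m/z (ppm).
    rt_overlap_min
        Minimum RT-span overlap fraction (|intersection| / |shorter span|,
        half-open spans) for traces or chargites to be considered co-eluting.
    proton_mass
        Mass of the charge carrier (Da).
    molecule_mass_tol_ppm
        Tolerance on implied neutral masses when merging chargites into
        molecules (ppm).
    """

    isotope_spacing: float = ISOTOPE_SPACING
    charge_range: tuple[int, int] = (1, 5)
    grouping_ppm_tol: float = 10.0
    rt_overlap_min: float = 0.5
    proton_mass: float = PROTON_MASS
    molecule_mass_tol_ppm: float = 10.0

    def __post_init__(self) -> None:
        if not self.isotope_spacing > 0:
            raise ValueError("isotope_spacing must be positive")
        lo, hi = self.charge_range
        if lo < 1 or hi < lo:
            raise ValueError("charge_range must be a non-empty interval of positive charges")
        if not 0 < self.rt_overlap_min <= 1:
            raise ValueError("rt_overlap_min must be in (0, 1]")


def _rt_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Overlap fraction of two half-open RT spans, relative to the shorter span."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    shorter = min(a[1] - a[0], b[1] - b[0])
    if shorter <= 0:
        # Degenerate (single-scan) span: overlap is membership of the point.
        point = a[0] if a[1] - a[0] <= b[1] - b[0] else b[0]
        other = b if a[1] - a[0] <= b[1] - b[0] else a
        if other[1] - other[0] <= 0:
            return 1.0 if a[0] == b[0] else 0.0
        return 1.0 if other[0] <= point < other[1] else 0.0
    return max(0.0, inter) / shorter


def group_chargites(
    traces: Sequence[NeutromerTrace], config: EnvelopeConfig | None = None
) -> list[ChargiteTrace]:
    """Group neutromer traces into chargite traces by isotope spacing.

    Seeds are taken in descending order of integrated intensity (ties: lower
    m/z). For each candidate charge z, isotope partners are collected walking
    outward from the seed at offsets +-k * isotope_spacing / z (nearest in ppm
    within tolerance, co-eluting); the z explaining the most traces wins, ties
    going to the larger z. Traces with no partner at any z become singleton
    chargites with z = 0 (undetermined).
    """
    config = config or EnvelopeConfig()
    order = sorted(
        range(len(traces)),
        key=lambda i: (-traces[i].integrated_intensity, traces[i].mz, i),
    )
    unassigned = set(range(len(traces)))
    chargites: list[ChargiteTrace] = []

    def find_partner(expected_mz: float, seed_span, taken: set[int]) -> Optional[int]:
        best, best_ppm = None, float("inf")
        for i in sorted(unassigned):
            if i in taken:
                continue
            t = traces[i]
            d = abs(t.mz - expected_mz) / expected_mz * 1e6
            if (
                d <= config.grouping_ppm_tol
                and d < best_ppm
                and _rt_overlap(t.rt_span, seed_span) >= config.rt_overlap_min
            ):
                best, best_ppm = i, d
        return best

    for seed_idx in order:
        if seed_idx not in unassigned:
            continue
        seed = traces[seed_idx]
        best_z, best_members = 0, {0: seed_idx}
        for z in range(config.charge_range[0], config.charge_range[1] + 1):
            members = {0: seed_idx}
            taken = {seed_idx}
            for direction in (+1, -1):
                k = direction
                while True:
                    expected = seed.mz + k * config.isotope_spacing / z
                    if expected <= 0:
                        break
                    hit = find_partner(expected, seed.rt_span, taken)
                    if hit is None:
                        break
                    members[k] = hit
                    taken.add(hit)
                    k += direction
            if len(members) > len(best_members) or (
                len(members) == len(best_members) > 1 and z > best_z
            ):
                best_z, best_members = z, members
        ks = sorted(best_members)
        member_traces = [traces[best_members[k]] for k in ks]
        z = best_z if len(member_traces) > 1 else 0
        chargites.append(
            ChargiteTrace(
                z=z,
                neutromer_traces=member_traces,
                monoisotopic_mz=member_traces[0].mz,
                chargite_id=f"c{len(chargites):05d}",
            )
        )
        unassigned -= set(best_members.values())
    return chargites


def deisotope(
    chargite: ChargiteTrace, rt_mode: Optional[str] = None, rt: Optional[float] = None
) -> list[ProjectedEntity] | ProjectedEntity:
    """Sum a chargite's intensities through the isotope (m/z) dimension.

    Returns one tuple per scan, anchored at the monoisotopic m/z and tagged
    ``deisotoped``. When ``rt_mode`` is given the per-scan tuples are further
    reduced through RT (e.g. ``rt_mode="integrated"`` yields a single
    integrated deisotoped chargite tuple).
    """
    if not chargite.neutromer_traces:
        raise ValueError("cannot deisotope an empty chargite")
    per_scan: dict[int, tuple[float, float]] = {}  # scan_index -> (rt, intensity)
    for trace in chargite.neutromer_traces:
        for n in trace.neutroids:
            rt_i, inten = per_scan.get(n.scan_index, (n.rt, 0.0))
            per_scan[n.scan_index] = (rt_i, inten + n.intensity)
    entities = [
        ProjectedEntity(
            mz=chargite.monoisotopic_mz,
            rt=per_scan[s][0],
            intensity=per_scan[s][1],
            provenance=("deisotoped",),
            source_id=chargite.chargite_id,
        )
        for s in sorted(per_scan)
    ]
    if rt_mode is None:
        return entities
    return project_rt_entities(entities, rt_mode, rt)


def group_molecules(
    chargites: Sequence[ChargiteTrace], config: EnvelopeConfig | None = None
) -> list[MolecularDistributionTrace]:
    """Merge chargites implying the same neutral mass into molecular distribution traces.

    Only chargites with a determined charge (z >= 1) participate. The neutral
    mass of a chargite is M = z * (monoisotopic m/z - proton mass); chargites
    agreeing within tolerance and co-eluting merge, and the consensus mass is
    the intensity-weighted mean of the members' implied masses.
    """
    config = config or EnvelopeConfig()
    pool = [c for c in chargites if c.z >= 1]
    order = sorted(
        range(len(pool)),
        key=lambda i: (-pool[i].integrated_intensity, pool[i].monoisotopic_mz, i),
    )
    unassigned = set(range(len(pool)))
    molecules: list[MolecularDistributionTrace] = []
    for seed_idx in order:
        if seed_idx not in unassigned:
            continue
        seed = pool[seed_idx]
        seed_mass = seed.neutral_mass(config.proton_mass)
        members = [seed_idx]
        # At most one chargite per charge state; nearest implied mass wins.
        best_by_z: dict[int, tuple[float, int]] = {}
        for i in sorted(unassigned - {seed_idx}):
            c = pool[i]
            if c.z == seed.z:
                continue
            mass = c.neutral_mass(config.proton_mass)
            d_ppm = abs(mass - seed_mass) / seed_mass * 1e6
            if (
                d_ppm <= config.molecule_mass_tol_ppm
                and _rt_overlap(c.rt_span, seed.rt_span) >= config.rt_overlap_min
            ):
                if c.z not in best_by_z or d_ppm < best_by_z[c.z][0]:
                    best_by_z[c.z] = (d_ppm, i)
        members.extend(i for _d, i in best_by_z.values())
        member_chargites = sorted((pool[i] for i in members), key=lambda c: c.z)
        weights = [c.integrated_intensity for c in member_chargites]
        masses = [c.neutral_mass(config.proton_mass) for c in member_chargites]
        consensus = sum(w * m for w, m in zip(weights, masses)) / sum(weights)
        molecules.append(
            MolecularDistributionTrace(
                chargites=member_chargites,
                neutral_mass=consensus,
                molecule_id=f"m{len(molecules):05d}",
            )
        )
        unassigned -= set(members)
    return molecules


def reduce_molecule(
    molecule: MolecularDistributionTrace,
    config: EnvelopeConfig | None = None,
    rt_mode: Optional[str] = None,
    rt: Optional[float] = None,
    z_target: Optional[int] = None,
) -> list[ProjectedEntity] | ProjectedEntity:
    """Combine a molecule's chargites at the lowest common charge state.

    Each chargite is first deisotoped; the per-scan tuples are re-coordinated
    to m/z' = (M + z* * proton_mass) / z*, where z* is the smallest member
    charge (or ``z_target`` when given), and summed per scan across chargites.
    The result is tagged ``deisotoped, reduced`` (and further by ``rt_mode``
    if given).
    """
    config = config or EnvelopeConfig()
    if any(c.z < 1 for c in molecule.chargites):
        raise ValueError("cannot reduce a molecule containing a chargite of undetermined charge")
    z_star = z_target if z_target is not None else min(c.z for c in molecule.chargites)
    if z_star < 1:
        raise ValueError("target charge must be >= 1")
    mz_reduced = (molecule.neutral_mass + z_star * config.proton_mass) / z_star
    # Scans are shared across a run, so the RT value identifies the scan.
    per_scan: dict[float, tuple[float, float]] = {}
    for c in molecule.chargites:
        for e in deisotope(c):
            rt_i, inten = per_scan.get(e.rt, (e.rt, 0.0))
            per_scan[e.rt] = (rt_i, inten + e.intensity)
    entities = [
        ProjectedEntity(
            mz=mz_reduced,
            rt=per_scan[s][0],
            intensity=per_scan[s][1],
            provenance=("deisotoped", "reduced"),
            source_id=molecule.molecule_id,
        )
        for s in sorted(per_scan)
    ]
    if rt_mode is None:
        return entities
    return project_rt_entities(entities, rt_mode, rt)
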