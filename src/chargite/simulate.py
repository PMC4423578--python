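"""Profile-mode MS1 run simulation with ground truth.

The simulator renders, for each molecule, charge state and isotopic species,
a Gaussian chromatographic elution profile sampled at the scan times, and in
each scan a Gaussian m/z peak (FWHM = m/z / resolving power) sampled on a
uniform m/z grid whose spacing is one quarter of the narrowest peak width, so
every peak carries at least ~4 profile points for the centroider to work on.
Contributions are accumulated on the shared grid; an optional constant
baseline is added under the peaks and optional Poisson counting noise is
applied with a fixed seed.

Alongside the run, a ground-truth table records every simulated neutromer
trace (molecule, z, isotope index, theoretical m/z, elution apex and the total
sampled intensity), so that detection results can be scored for recall and
precision with :func:`truth_match`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .envelope import ISOTOPE_SPACING, PROTON_MASS
from .model import NeutromerTrace, RawRun, Scan

__all__ = [
    "MoleculeSpec",
    "SimulationConfig",
    "GroundTruthTable",
    "isotope_distribution",
    "simulate_run",
    "truth_match",
    "MatchReport",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class MoleculeSpec:
    """One simulated charge-accepting unit (e.g. a peptide).

    peak_height is the profile-point amplitude (counts) of the most abundant
    isotope at the elution apex; other isotopes scale by their relative
    abundance.
    """

    neutral_mass: float
    charges: tuple[int, ...]
    elution_apex: float
    elution_sigma: float
    peak_height: float
    isotope_abundances: Optional[tuple[float, ...]] = None
    molecule_id: str = ""

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError("neutral_mass must be positive")
        if not self.charges or any(z < 1 for z in self.charges):
            raise ValueError("charges must be positive integers")
        if not self.elution_sigma > 0:
            raise ValueError("elution_sigma must be positive")
        if self.isotope_abundances is not None:
            ab = tuple(self.isotope_abundances)
            if not ab or any(not 0 < a <= 1 for a in ab):
                raise ValueError("isotope abundances must lie in (0, 1]")
            if max(ab) != 1.0:
                raise ValueError("isotope abundances must be normalized to max = 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level simulation settings (times in seconds, m/z in Th)."""

    molecules: tuple[MoleculeSpec, ...]
    rt_start: float = 0.0
    rt_end: float = 600.0
    scan_interval: float = 1.0
    mz_min: float = 200.0
    mz_max: float = 2100.0
    resolving_power: float = 60000.0
    baseline_level: float = 0.0
    noise_model: str = "none"  # "none" | "poisson"
    elution_shape: str = "gaussian"  # "gaussian" | "emg" (exponential tailing)
    emg_tau: float = 3.0  # exponential tail constant (s), elution_shape="emg" only
    seed: int = 0
    isotope_lambda_per_kda: float = 0.6
    isotope_spacing: float = ISOTOPE_SPACING
    proton_mass: float = PROTON_MASS
    mz_window_sigmas: float = 4.5
    rt_window_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if not self.scan_interval > 0:
            raise ValueError("scan_interval must be positive")
        if not self.resolving_power > 0:
            raise ValueError("resolving_power must be positive")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError("noise_model must be 'none' or 'poisson'")
        if self.elution_shape not in ("gaussian", "emg"):
            raise ValueError("elution_shape must be 'gaussian' or 'emg'")
        if not self.mz_max > self.mz_min > 0:
            raise ValueError("mz range must satisfy 0 < mz_min < mz_max")


class GroundTruthTable:
    """Per-trace ground truth: one row per (molecule, charge, isotope index).

    Columns: molecule_id, neutral_mass, z, isotope_index, mz, rt_apex,
    abundance, total_intensity (total sampled profile intensity of the trace).
    """

    COLUMNS = [
        "molecule_id",
        "neutral_mass",
        "z",
        "isotope_index",
        "mz",
        "rt_apex",
        "abundance",
        "total_intensity",
    ]

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ground truth table missing columns: {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroundTruthTable":
        return cls(pd.read_csv(path, sep="\t"))


def isotope_distribution(
    neutral_mass: float, config: SimulationConfig | None = None
) -> np.ndarray:
    """Relative isotope abundances (max = 1) for a molecule of the given mass.

    A Poisson profile with lambda = isotope_lambda_per_kda * mass / 1000 Da
    stands in for the elemental isotope pattern: heavier molecules carry more
    heavy-isotope signal. Fine isotopic structure (isoneutromers) is
    deliberately collapsed into one species per neutron count. The vector is
    truncated where the probability falls below 1e-3 of its maximum.
    """
    if not neutral_mass > 0:
        raise ValueError("neutral_mass must be positive")
    config = config or SimulationConfig(molecules=())
    lam = config.isotope_lambda_per_kda * neutral_mass / 1000.0
    if lam == 0:
        return np.array([1.0])
    k = np.arange(64)
    pmf = stats.poisson.pmf(k, lam)
    keep = np.flatnonzero(pmf >= 1e-3 * pmf.max())
    pmf = pmf[: keep[-1] + 1]
    return pmf / pmf.max()


def _molecule_abundances(mol: MoleculeSpec, config: SimulationConfig) -> np.ndarray:
    if mol.isotope_abundances is not None:
        return np.asarray(mol.isotope_abundances, dtype=float)
    return isotope_distribution(mol.neutral_mass, config)


def theoretical_mz(
    neutral_mass: float, z: int, k: int, config: SimulationConfig
) -> float:
    """m/z of isotope k of a molecule at charge z: (M + k*Δiso + z*mp) / z."""
    return (neutral_mass + k * config.isotope_spacing + z * config.proton_mass) / z


def simulate_run(config: SimulationConfig) -> tuple[RawRun, GroundTruthTable]:
    """Render a profile-mode MS1 run and its ground-truth table.

    Identical configs (including seed) produce bit-identical runs. Raises if
    any simulated species falls outside the m/z range, listing the offenders.
    """
    grid_spacing = (config.mz_min / config.resolving_power) / 4.0
    scan_times = np.arange(config.rt_start, config.rt_end, config.scan_interval)
    rng = np.random.default_rng(config.seed)

    # Expand molecules into per-trace species and validate the m/z range.
    species = []  # (mol_id, mol, z, k, mz, height)
    offenders = []
    for mi, mol in enumerate(config.molecules):
        mol_id = mol.molecule_id or f"sim{mi:03d}"
        abund = _molecule_abundances(mol, config)
        for z in mol.charges:
            for k, a in enumerate(abund):
                mz = theoretical_mz(mol.neutral_mass, z, k, config)
                sigma_mz = mz / (config.resolving_power * _FWHM_PER_SIGMA)
                margin = config.mz_window_sigmas * sigma_mz
                if mz - margin < config.mz_min or mz + margin > config.mz_max:
                    offenders.append(f"{mol_id} z={z} k={k} mz={mz:.4f}")
                    continue
                species.append((mol_id, mol, z, k, mz, mol.peak_height * a, a))
    if offenders:
        raise ValueError(
            "simulated species outside the m/z range: " + "; ".join(offenders)
        )

    def elution_factor(mol: MoleculeSpec, t: float) -> float:
        """Unit-peak elution profile value at time t (Gaussian or EMG tailing)."""
        dt = t - mol.elution_apex
        if config.elution_shape == "gaussian":
            if abs(dt) > config.rt_window_sigmas * mol.elution_sigma:
                return 0.0
            return math.exp(-0.5 * (dt / mol.elution_sigma) ** 2)
        # EMG: exponential tail of constant tau; window widened on the right
        if dt < -config.rt_window_sigmas * mol.elution_sigma or dt > (
            config.rt_window_sigmas * mol.elution_sigma + 8.0 * config.emg_tau
        ):
            return 0.0
        dist = stats.exponnorm(
            K=config.emg_tau / mol.elution_sigma,
            loc=mol.elution_apex,
            scale=mol.elution_sigma,
        )
        peak = _emg_peaks.setdefault(
            (mol.elution_apex, mol.elution_sigma),
            float(
                dist.pdf(
                    np.linspace(
                        mol.elution_apex - 4 * mol.elution_sigma,
                        mol.elution_apex + 4 * mol.elution_sigma + 8 * config.emg_tau,
                        512,
                    )
                ).max()
            ),
        )
        return float(dist.pdf(t)) / peak

    _emg_peaks: dict[tuple[float, float], float] = {}
    totals = [0.0] * len(species)  # noise-free sampled intensity per trace
    scans: list[Scan] = []
    for si, t in enumerate(scan_times):
        acc: dict[int, float] = {}
        for sp_idx, (_, mol, z, k, mz, height, _) in enumerate(species):
            factor = elution_factor(mol, float(t))
            if factor <= 0.0:
                continue
            el = height * factor
            sigma_mz = mz / (config.resolving_power * _FWHM_PER_SIGMA)
            half = config.mz_window_sigmas * sigma_mz
            i_lo = int(math.ceil((mz - half - config.mz_min) / grid_spacing))
            i_hi = int(math.floor((mz + half - config.mz_min) / grid_spacing))
            idx = np.arange(i_lo, i_hi + 1)
            grid_mz = config.mz_min + idx * grid_spacing
            vals = el * np.exp(-0.5 * ((grid_mz - mz) / sigma_mz) ** 2)
            totals[sp_idx] += float(vals.sum())
            for i, v in zip(idx, vals):
                acc[int(i)] = acc.get(int(i), 0.0) + float(v)
        idx_sorted = np.array(sorted(acc), dtype=np.int64)
        inten = np.array([acc[int(i)] for i in idx_sorted], dtype=np.float64)
        if config.baseline_level > 0:
            # Baseline is local chemical background under the sampled peaks.
            inten = inten + config.baseline_level
        if config.noise_model == "poisson" and inten.size:
            inten = rng.poisson(inten).astype(np.float64)
        scans.append(
            Scan(
                scan_index=si,
                rt=float(t),
                mz=config.mz_min + idx_sorted * grid_spacing,
                intensity=inten,
            )
        )

    rows = [
        {
            "molecule_id": mol_id,
            "neutral_mass": mol.neutral_mass,
            "z": z,
            "isotope_index": k,
            "mz": mz,
            "rt_apex": mol.elution_apex,
            "abundance": a,
            "total_intensity": totals[sp_idx],
        }
        for sp_idx, (mol_id, mol, z, k, mz, _h, a) in enumerate(species)
    ]
    truth = GroundTruthTable(pd.DataFrame(rows, columns=GroundTruthTable.COLUMNS))
    run = RawRun(
        scans=scans,
        mode="profile",
        metadata={"source": "chargite.simulate", "seed": config.seed},
    )
    return run, truth


@dataclass
class MatchReport:
    """Scoring of detected traces against simulated ground truth."""

    df: pd.DataFrame  # truth rows + recovered / det_mz / ppm_error / intensity_ratio
    recall: float
    precision: float
    n_truth: int
    n_detected: int


def truth_match(
    traces: Sequence[NeutromerTrace],
    truth: GroundTruthTable,
    ppm_tol: float = 5.0,
    rt_tol: float = 10.0,
) -> MatchReport:
    """Greedily match ground-truth traces to detected traces, nearest in m/z.

    Truth rows are visited in descending intensity; each claims the unmatched
    detected trace nearest in ppm within ppm_tol whose apex RT lies within
    rt_tol of the true apex. Each side matches at most once.
    """
    det = [(t.mz, t.apex_rt, t.integrated_intensity) for t in traces]
    taken: set[int] = set()
    records = []
    order = truth.df.sort_values(
        ["total_intensity", "mz"], ascending=[False, True]
    ).index
    results = {}
    for ri in order:
        row = truth.df.loc[ri]
        best, best_ppm = None, float("inf")
        for j, (mz, apex, _inten) in enumerate(det):
            if j in taken:
                continue
            d = abs(mz - row.mz) / row.mz * 1e6
            if d <= ppm_tol and d < best_ppm and abs(apex - row.rt_apex) <= rt_tol:
                best, best_ppm = j, d
        if best is None:
            results[ri] = (False, np.nan, np.nan, np.nan)
        else:
            taken.add(best)
            mz, _apex, inten = det[best]
            signed_ppm = (mz - row.mz) / row.mz * 1e6
            ratio = inten / row.total_intensity if row.total_intensity > 0 else np.nan
            results[ri] = (True, mz, signed_ppm, ratio)
    for ri in truth.df.index:
        rec, mz, ppm, ratio = results[ri]
        records.append(
            {"recovered": rec, "det_mz": mz, "ppm_error": ppm, "intensity_ratio": ratio}
        )
    report = pd.concat([truth.df, pd.DataFrame(records, index=truth.df.index)], axis=1)
    n_matched = int(report["recovered"].sum())
    recall = n_matched / len(truth.df) if len(truth.df) else 0.0
    precision = n_matched / len(det) if det else (1.0 if n_matched == 0 and not len(truth.df) else 0.0)
    return MatchReport(
        df=report,
        recall=recall,
        precision=precision,
        n_truth=len(truth.df),
        n_detected=len(det),
    )
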