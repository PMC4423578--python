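"""The synthetic-run generator and its ground-truth scoring."""

import math

import numpy as np
import pytest

from chargite import (
    GroundTruthTable,
    MoleculeSpec,
    SimulationConfig,
    detect_features,
    isotope_distribution,
    simulate_run,
    truth_match,
)


def config(**overrides):
    defaults = dict(
        molecules=(
            MoleculeSpec(999.0, (1,), 30.0, 4.0, 1e5, isotope_abundances=(1.0, 0.5)),
        ),
        rt_end=60.0,
        scan_interval=1.0,
        mz_min=800.0,
        mz_max=1100.0,
        resolving_power=60000.0,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestIsotopeDistribution:
    def test_tiny_mass_degenerates_to_monoisotopic(self):
        dist = isotope_distribution(1e-6, config())
        assert dist.tolist() == [1.0]

    def test_poisson_shape_at_half_lambda(self):
        # lambda = 0.5: pmf ratios to the k=0 term are 0.5^k / k!
        cfg = config(isotope_lambda_per_kda=0.6)
        dist = isotope_distribution(0.5 / 0.6 * 1000.0, cfg)
        expected = [1.0, 0.5, 0.125, 0.5**3 / 6, 0.5**4 / 24]
        assert dist.tolist() == pytest.approx(expected, rel=1e-9)

    def test_explicit_abundances_pass_through(self):
        run, truth = simulate_run(config())
        assert truth.df.abundance.tolist() == [1.0, 0.5]

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            isotope_distribution(0.0, config())


class TestSimulateRun:
    def test_ground_truth_counts_and_recovery(self):
        run, truth = simulate_run(config())
        assert len(truth) == 2
        result = detect_features(run)
        assert len(result.traces) == 2
        assert [(c.z, len(c)) for c in result.chargites] == [(1, 2)]

    def test_identical_seeds_are_bit_identical(self):
        cfg = config(noise_model="poisson", baseline_level=5.0)
        run1, _ = simulate_run(cfg)
        run2, _ = simulate_run(cfg)
        for a, b in zip(run1.scans, run2.scans):
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_different_seed_changes_noise(self):
        run1, _ = simulate_run(config(noise_model="poisson"))
        run2, _ = simulate_run(config(noise_model="poisson", seed=8))
        assert any(
            not np.array_equal(a.intensity, b.intensity)
            for a, b in zip(run1.scans, run2.scans)
        )

    def test_noise_free_total_intensity_matches_truth(self):
        run, truth = simulate_run(config())
        total_run = sum(s.intensity.sum() for s in run.scans)
        assert total_run == pytest.approx(truth.df.total_intensity.sum(), rel=1e-12)

    def test_out_of_range_molecule_rejected_with_offenders(self):
        bad = config(molecules=(
            MoleculeSpec(2000.0, (1,), 30.0, 4.0, 1e5, isotope_abundances=(1.0,)),
        ))
        with pytest.raises(ValueError, match="z=1 k=0"):
            simulate_run(bad)

    def test_theoretical_mz_formula(self):
        cfg = config()
        run, truth = simulate_run(cfg)
        for row in truth.df.itertuples():
            expected = (
                row.neutral_mass + row.isotope_index * cfg.isotope_spacing
                + row.z * cfg.proton_mass
            ) / row.z
            assert row.mz == pytest.approx(expected, rel=1e-12)

    def test_profile_peaks_have_enough_points(self):
        run, _ = simulate_run(config())
        apex_scan = max(run.scans, key=lambda s: s.intensity.sum())
        # each peak must carry >= 4 grid points for the centroider
        from chargite import detect_instantaneous_hulls

        hulls = detect_instantaneous_hulls(apex_scan)
        assert hulls and all(len(h) >= 4 for h in hulls)


class TestTruthMatch:
    def test_perfect_detection(self):
        run, truth = simulate_run(config())
        result = detect_features(run)
        report = truth_match(result.traces, truth)
        assert report.recall == 1.0 and report.precision == 1.0
        assert report.df.recovered.all()

    def test_empty_detection_has_zero_recall(self):
        _, truth = simulate_run(config())
        report = truth_match([], truth)
        assert report.recall == 0.0

    def test_spurious_trace_lowers_precision_only(self):
        from conftest import make_trace

        run, truth = simulate_run(config())
        result = detect_features(run)
        spurious = make_trace([5.0, 6.0], mz=900.0)
        report = truth_match(result.traces + [spurious], truth)
        assert report.recall == 1.0
        assert report.precision == pytest.approx(2 / 3)

    def test_tsv_round_trip(self, tmp_path):
        _, truth = simulate_run(config())
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        again = GroundTruthTable.from_tsv(path)
        assert np.allclose(again.df.mz, truth.df.mz)
        assert again.df.molecule_id.tolist() == truth.df.molecule_id.tolist()
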