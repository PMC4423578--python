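"""Chargite and molecule grouping, deisotoping and charge reduction."""

import numpy as np
import pytest

from chargite import (
    ChargiteTrace,
    EnvelopeConfig,
    MolecularDistributionTrace,
    MoleculeSpec,
    PROTON_MASS,
    SimulationConfig,
    deisotope,
    detect_features,
    group_chargites,
    group_molecules,
    project_rt,
    reduce_molecule,
    simulate_run,
)

from conftest import make_trace


def co_eluting(mzs, heights=None, length=5):
    heights = heights or [100.0] * len(mzs)
    return [
        make_trace([h] * length, mz=mz, trace_id=f"t{i}")
        for i, (mz, h) in enumerate(zip(mzs, heights))
    ]


class TestGroupChargites:
    def test_half_spacing_identifies_z2(self):
        traces = co_eluting([500.0000, 500.5017, 501.0034], heights=[100, 60, 20])
        (c,) = group_chargites(traces)
        assert c.z == 2 and len(c) == 3
        assert c.monoisotopic_mz == pytest.approx(500.0000, abs=1e-6)

    def test_grouping_tolerance_boundary(self):
        # z=3 partner predicted at 500.334452; observed 500.330 is ~8.9 ppm off:
        # inside the 10 ppm default, outside a 7 ppm tolerance
        traces = co_eluting([500.000, 500.330])
        grouped = group_chargites(traces, EnvelopeConfig(grouping_ppm_tol=10.0))
        assert [c.z for c in grouped] == [3]
        strict = group_chargites(co_eluting([500.000, 500.330]),
                                 EnvelopeConfig(grouping_ppm_tol=7.0))
        assert [c.z for c in strict] == [0, 0]

    def test_unit_spacing_identifies_z1(self):
        traces = co_eluting([600.0, 601.003355])
        (c,) = group_chargites(traces)
        assert c.z == 1 and len(c) == 2

    def test_disjoint_rt_does_not_group(self):
        a = make_trace([100.0] * 5, mz=600.0, rt0=0.0, trace_id="a")
        b = make_trace([100.0] * 5, mz=601.003355, rt0=100.0, trace_id="b")
        grouped = group_chargites([a, b])
        assert sorted(c.z for c in grouped) == [0, 0]

    def test_lone_trace_is_singleton_with_undetermined_charge(self):
        (c,) = group_chargites([make_trace([10.0, 20.0], mz=700.0)])
        assert c.z == 0 and len(c) == 1

    def test_seed_order_is_deterministic_under_permutation(self):
        traces = co_eluting(
            [500.0000, 500.5017, 501.0034, 800.0, 801.003355],
            heights=[100, 60, 20, 90, 50],
        )
        a = group_chargites(traces)
        b = group_chargites(traces[::-1])
        assert [(c.z, round(c.monoisotopic_mz, 6), len(c)) for c in a] == [
            (c.z, round(c.monoisotopic_mz, 6), len(c)) for c in b
        ]

    def test_member_spacing_invariant(self):
        traces = co_eluting([500.0000, 500.5017, 501.0034])
        cfg = EnvelopeConfig()
        (c,) = group_chargites(traces, cfg)
        for k, t in enumerate(c.neutromer_traces):
            expected = c.monoisotopic_mz + k * cfg.isotope_spacing / c.z
            assert abs(t.mz - expected) / expected * 1e6 <= cfg.grouping_ppm_tol


class TestDeisotope:
    def test_per_scan_sum_at_monoisotopic_mz(self):
        traces = co_eluting([500.0000, 500.5017, 501.0034], heights=[60, 30, 10], length=1)
        (c,) = group_chargites(traces)
        (e,) = deisotope(c)
        assert e.mz == pytest.approx(500.0000, abs=1e-6)
        assert e.intensity == pytest.approx(100.0)
        assert e.provenance == ("deisotoped",)

    def test_single_isotope_identity(self):
        c = ChargiteTrace(1, [make_trace([5.0, 7.0], mz=600.0)], 600.0)
        entities = deisotope(c)
        assert [e.intensity for e in entities] == [5.0, 7.0]

    def test_deisotope_then_integrate_commutes_with_sum(self):
        traces = co_eluting([500.0000, 500.5017], heights=[60, 30])
        (c,) = group_chargites(traces)
        combined = deisotope(c, rt_mode="integrated")
        per_trace = sum(e.intensity for e in project_rt(c, "integrated"))
        assert combined.intensity == pytest.approx(per_trace, rel=1e-12)
        assert combined.provenance == ("deisotoped", "integrated")


class TestGroupMolecules:
    def test_matching_neutral_masses_merge(self):
        c1 = ChargiteTrace(1, [make_trace([50.0] * 5, mz=1001.007276)], 1001.007276, "c1")
        c2 = ChargiteTrace(2, [make_trace([90.0] * 5, mz=501.007276)], 501.007276, "c2")
        (m,) = group_molecules([c1, c2])
        assert len(m) == 2
        assert m.neutral_mass == pytest.approx(1000.0, abs=1e-5)

    def test_disjoint_rt_spans_stay_separate(self):
        c1 = ChargiteTrace(1, [make_trace([50.0] * 5, mz=1001.007276, rt0=0.0)],
                           1001.007276, "c1")
        c2 = ChargiteTrace(2, [make_trace([90.0] * 5, mz=501.007276, rt0=500.0)],
                           501.007276, "c2")
        assert len(group_molecules([c1, c2])) == 2

    def test_mass_mismatch_stays_separate(self):
        mz_off = (1000.0 * (1 + 50e-6) + PROTON_MASS)  # 50 ppm heavier
        c1 = ChargiteTrace(1, [make_trace([50.0] * 5, mz=1001.007276)], 1001.007276, "c1")
        c2 = ChargiteTrace(2, [make_trace([90.0] * 5, mz=(mz_off + PROTON_MASS) / 2)],
                           (mz_off + PROTON_MASS) / 2, "c2")
        assert len(group_molecules([c1, c2])) == 2

    def test_undetermined_charge_excluded(self):
        c = ChargiteTrace(0, [make_trace([5.0, 5.0], mz=700.0)], 700.0)
        assert group_molecules([c]) == []


class TestReduceMolecule:
    def test_closed_form_mass_arithmetic(self):
        # z=2 at monoisotopic 500.50: M = 2*(500.50 - 1.007276466812) = 998.985447
        c = ChargiteTrace(2, [make_trace([70.0, 30.0], mz=500.50)], 500.50, "c")
        m = MolecularDistributionTrace([c], c.neutral_mass(PROTON_MASS), "m")
        entities = reduce_molecule(m, z_target=1)
        assert entities[0].mz == pytest.approx(999.992724, abs=1e-6)
        assert entities[0].provenance == ("deisotoped", "reduced")

    def test_own_charge_is_identity(self):
        c = ChargiteTrace(2, [make_trace([70.0, 30.0], mz=500.50)], 500.50, "c")
        m = MolecularDistributionTrace([c], c.neutral_mass(PROTON_MASS), "m")
        entities = reduce_molecule(m)
        assert entities[0].mz == pytest.approx(500.50, abs=1e-9)
        assert [e.intensity for e in entities] == [70.0, 30.0]

    def test_cross_charge_intensity_conservation(self):
        c1 = ChargiteTrace(1, [make_trace([70.0], mz=1001.007276)], 1001.007276, "c1")
        c2 = ChargiteTrace(2, [make_trace([30.0], mz=501.007276)], 501.007276, "c2")
        (m,) = group_molecules([c1, c2])
        (e,) = reduce_molecule(m)
        assert e.intensity == pytest.approx(100.0, rel=1e-12)

    def test_undetermined_charge_rejected(self):
        c = ChargiteTrace(0, [make_trace([5.0, 5.0], mz=700.0)], 700.0)
        m = MolecularDistributionTrace([c], 0.0, "m")
        with pytest.raises(ValueError, match="undetermined"):
            reduce_molecule(m)


def test_simulated_multicharge_molecule_round_trips():
    """Simulating at z in {1,2} and regrouping recovers the neutral mass."""
    config = SimulationConfig(
        molecules=(
            MoleculeSpec(1234.5, (1, 2), 50.0, 5.0, 1e5, isotope_abundances=(1.0, 0.7)),
        ),
        rt_end=100.0,
        mz_min=200.0,
        mz_max=1400.0,
        seed=5,
    )
    run, _ = simulate_run(config)
    result = detect_features(run)
    assert len(result.molecules) == 1
    got = result.molecules[0].neutral_mass
    assert abs(got - 1234.5) / 1234.5 * 1e6 < EnvelopeConfig().molecule_mass_tol_ppm
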