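"""Reduce traces with the RT and m/z qualifiers while keeping provenance.

A neutromer trace can be summed through RT (integrated), sliced at its apex
(max), averaged, or sliced at one scan (instantaneous); a chargite can be
summed through the isotope dimension (deisotoped) and a molecule combined at
its lowest common charge state (reduced). Every reduction appends a qualifier
tag, and the tag chain renders as the human-readable nomenclature term.
"""

from chargite import (
    ChargiteTrace,
    MolecularDistributionTrace,
    Neutroid,
    NeutromerTrace,
    PROTON_MASS,
    deisotope,
    project_rt,
    reduce_molecule,
    term_string,
)

trace = NeutromerTrace(
    [
        Neutroid(mz=500.0, rt=10.0, intensity=2.0, scan_index=0),
        Neutroid(mz=500.0, rt=11.0, intensity=5.0, scan_index=1),
        Neutroid(mz=500.0, rt=12.0, intensity=3.0, scan_index=2),
    ],
    trace_id="demo",
)

for mode, rt in (("integrated", None), ("max", None), ("average", None),
                 ("instantaneous", 12.0)):
    e = project_rt(trace, mode, rt)
    term = term_string("neutromer_trace", e.provenance)
    print(f"{term:38s} mz={e.mz:.1f}  rt={e.rt:5.2f} s  intensity={e.intensity:.3f}")

# two isotopes of one chargite at z=2, deisotoped then integrated
k0 = NeutromerTrace([Neutroid(500.0, 10.0, 60.0, 0), Neutroid(500.0, 11.0, 40.0, 1)], "k0")
k1 = NeutromerTrace([Neutroid(500.5017, 10.0, 30.0, 0), Neutroid(500.5017, 11.0, 20.0, 1)], "k1")
chargite = ChargiteTrace(z=2, neutromer_traces=[k0, k1], monoisotopic_mz=500.0, chargite_id="c0")
combined = deisotope(chargite, rt_mode="integrated")
print(f"{term_string('chargite_trace', combined.provenance):38s} "
      f"mz={combined.mz:.4f}  intensity={combined.intensity:.1f}")

# the same chargite as a molecule, reduced to z=1
molecule = MolecularDistributionTrace([chargite], chargite.neutral_mass(PROTON_MASS), "m0")
reduced = reduce_molecule(molecule, z_target=1, rt_mode="integrated")
print(f"{term_string('molecular_distribution_trace', reduced.provenance):38s} "
      f"mz={reduced.mz:.6f}  intensity={reduced.intensity:.1f}")

# intensities are conserved by every m/z reduction (150.0 throughout); the
# reduced coordinate is the singly-protonated m/z of the same neutral mass.
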