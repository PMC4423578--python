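# chargite

An executable nomenclature for MS1 signal provenance, with the reference
LC-MS feature-extraction pipeline that produces it and a profile-mode run
simulator with ground truth.

## The problem

Precursor-level (MS1) mass-spectrometry signal lives on three axes — m/z,
retention time (RT), intensity — and almost every object people extract from
it ("feature", "peak", "isotope pattern", "XIC") is named ambiguously: the
same word covers a raw profile region, its centroid, an RT-extended trace and
an RT-summed tuple. That ambiguity leaks into algorithm descriptions and
makes pipelines hard to compare or reimplement.

`chargite` makes the provenance of each signal object explicit and typed:

| term | object |
| --- | --- |
| **raw point** | one profile sample (m/z, intensity) in one scan |
| **instantaneous neutromer hull** | the contiguous raw points under one isotopic species in one scan |
| **neutroid** | that hull centroided: one (m/z, RT, intensity) tuple |
| **neutromer trace** | the neutroids of one isotopic species linked through RT |
| **chargite trace** | the neutromer traces of one molecule at one charge state *z*, spaced Δ/z in m/z |
| **molecular distribution trace** | a molecule's chargites across charge states |

Reductions carry *qualifiers* instead of overwriting the object's identity:
**integrated** (summed through RT), **max** (apex slice), **average**,
**instantaneous** (one scan) on the RT axis; **deisotoped** (summed through
the isotope dimension) and **reduced** (charge states combined at the lowest
common *z*) on the m/z axis. An "integrated deisotoped chargite trace" is a
single tuple that still tells you exactly where it came from. A lexicon
module validates qualifier chains and round-trips them through the
human-readable terms.

## The reference pipeline

The detection algorithm is the classic profile-mode procedure, stated here in
the nomenclature:

1. **Centroiding** — per scan, local intensity maxima along m/z seed 2-D
   peaks; each extends outward until intensity reaches zero or a local
   minimum (separator points join neither peak). The centroid m/z is the
   intensity-weighted mean of the member points, `Σ mᵢIᵢ / Σ Iᵢ`.
2. **Trace building** — each neutroid within **7 ppm** of an open trace in
   the previous or penultimate scan (one missing scan may be bridged) joins
   the nearest trace in ppm; others open new traces. Traces with fewer than
   **2** neutroids are culled.
3. **Splitting** — a trace splits at any interior intensity minimum that is
   ≤ **1/1.3** of the lesser of its two flanking local maxima.
4. **Envelope grouping** — co-eluting traces spaced `k·Δiso/z`
   (Δiso = 1.003355 Da) form a chargite at the charge *z* explaining the most
   traces; chargites whose implied neutral masses
   `M = z·(m/z_mono − m_proton)` agree within 10 ppm merge into molecules.

A bundled simulator renders profile-mode runs (Gaussian elution × Gaussian
m/z peaks on a grid of ≥ 4 points per peak width, optional baseline and
Poisson noise, fixed seed) together with a per-trace ground-truth table, so
every stage is testable end to end.

## Worked example

`python examples/simulate_and_detect.py` simulates one 999 Da molecule at
charges 1 and 2 with three isotopic species and runs the pipeline:

```
scans simulated:        120
ground-truth traces:    6
neutromer traces found: 6
chargite traces:        z=1 (3 isotopes), z=2 (3 isotopes)
molecules:              1
consensus neutral mass: 999.000000 Da
trace recall:           1.000
trace precision:        1.000
worst centroid error:   1.87e-04 ppm
```

All six simulated isotope traces are recovered, grouped into the two true
chargites, and merged into one molecule whose consensus neutral mass lands on
the simulated 999 Da to sub-ppb accuracy. See also
`examples/projection_qualifiers.py` (RT/m-z qualifiers and term strings) and
`examples/mzml_and_feature_tables.py` (bit-exact mzML round-trips and
nomenclature-labeled feature tables).

The same workflow is available from the shell:

```bash
chargite simulate --config sim.toml --out run.mzML --truth truth.tsv
chargite detect run.mzML --out features.tsv
chargite project features.tsv --mode integrated --out integrated.tsv
chargite evaluate features.tsv truth.tsv
```

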