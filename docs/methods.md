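# Methods

This note records the model behind `chargite`, the defaults and the numerical
and design choices made where the underlying procedure is stated loosely in
the literature, and what the bundled simulator does and does not emulate.

## Signal model

An MS1 run is a sequence of scans at strictly increasing retention times
(seconds internally; minute-valued mzML files are converted on read), each a
strictly m/z-ascending sequence of non-negative profile samples. The object
hierarchy — instantaneous neutromer hull → neutroid → neutromer trace →
chargite trace → molecular distribution trace — is enforced by constructor
invariants (hull apex dominance, per-scan uniqueness, ascending scan indices,
distinct charge states per molecule). Every reduction returns a
`ProjectedEntity` whose provenance tuple lists qualifier tags in application
order; the lexicon renders a chain most-recent-qualifier-first ("integrated
deisotoped chargite trace") and parsing prefers the longest entity-kind
match, so the one inherent collision ("instantaneous neutromer hull" is
itself a kind) resolves to the kind.

All sequences are 0-based. RT spans are half-open `[start, end)` wherever
spans are compared; a degenerate (single-scan) span overlaps another span iff
its point lies inside it.

## Centroiding

A local maximum is a run of equal intensities strictly greater than both
neighboring runs; scan edges count as valleys and a plateau's apex is its
leftmost point, which makes segmentation deterministic. Hull boundaries stop
*before* the first zero point and *before* any interior local-minimum run;
separator minima belong to neither neighbor. Excluding the separator is a
choice (the classic prose does not say); it is what makes per-scan intensity
conservation exact: the summed neutroid intensity equals the summed intensity
of exactly the points assigned to hulls.

A neutroid's m/z is the intensity-weighted mean of its hull points (the one-
and two-point peaks degenerate to the point itself and the two-point weighted
average). Its intensity is by default the *sum* of the hull point intensities
— again so conservation laws hold exactly; apex height is available as
`CentroiderConfig(intensity_mode="apex")` but is not the tested default. The
weighted mean is clipped into `[min mz, max mz]` of the hull to keep the
membership invariant under last-ULP float rounding.

## Trace building

Parameters (`TraceBuilderConfig`): linking tolerance 7 ppm; one bridgeable
missing scan (a neutroid in scan *n* may continue a trace last seen in
*n−2*); minimum trace length 2; split ratio 1.3.

Matching is forward-only: scans are processed in order and each neutroid
joins the open trace nearest in ppm, referenced to the trace's *most recently
added* neutroid (running means would drift-correct but are not what the
classic per-scan comparison does). Contention is resolved greedily with
reinsertion — the closer neutroid keeps the trace, the loser is reconsidered
against the remaining candidates — which makes the result invariant to the
order of neutroids within a scan. A trace accepts at most one neutroid per
scan; duplicate neutroids (same scan, same m/z) are an error.

Splitting evaluates raw neutroid intensities with no smoothing. An interior
minimum (plateau-leftmost, strict inequalities, as in centroiding) triggers
when `I_min ≤ lesser_flanking_max / 1.3`; the comparison carries a 1e-12
relative slack so the exact-ratio boundary case of the ≤ rule is not lost to
the float rounding of the division. The minimum neutroid joins the
right-hand segment (the rule is silent on the side; right was fixed for
determinism), splitting recurses on both segments until quiescent, and the
segments are re-culled.

## Envelope grouping

Parameters (`EnvelopeConfig`): isotope spacing 1.003355 Da (the ¹³C−¹²C mass
difference; set 1.0 to reproduce the idealized "1/z apart" convention),
charges 1–5, partner tolerance 10 ppm, RT-overlap ≥ 0.5 of the shorter span,
proton mass 1.007276466812 Da, molecule mass tolerance 10 ppm.

Chargite seeding is greedy by descending integrated intensity (ties: lower
m/z, then input order). For each candidate z the partner walk extends
outward (k = ±1, ±2, …) from the seed at `k·Δiso/z` and stops at the first
miss; the z explaining the most traces wins, ties to the larger z (the more
parsimonious spacing). Traces with no partner at any z are reported as
singleton chargites with z = 0 (undetermined); they are excluded from
molecule grouping and charge reduction, which require a determined charge.

Deisotoping sums member intensities per scan at the monoisotopic m/z (the
conventional anchor; the lowest-k member). Charge reduction deisotopes first
— the reduced coordinate `m/z' = (M + z*·m_p)/z*` has no isotope structure —
then sums per scan across chargites; z\* defaults to the lowest member charge
and can be overridden (`z_target`). A molecule admits at most one chargite
per charge state; when several same-z chargites match a seed mass, the
nearest in ppm wins. Consensus neutral mass is the intensity-weighted mean
of members' implied masses.

## Simulator

The simulator emulates: per-molecule isotopic envelopes at one or more
charge states; Gaussian chromatographic elution (apex, sigma, height);
Gaussian m/z peak shapes with FWHM = m/z / R on a uniform grid whose spacing
is (FWHM at the low m/z edge)/4, guaranteeing ≥ 4 profile points per peak;
additive baseline; Poisson counting noise from a seeded generator
(bit-identical runs for identical configs). Isotope abundances are either
given explicitly (normalized to max 1) or drawn from a Poisson profile with
λ = 0.6·M/kDa, truncated below 1e-3 of its mode — a deliberate stand-in for
elemental fine structure. Peaks are evaluated within ±4.5 σ in m/z and
±4 σ in RT; the ground-truth "total intensity" is the exact sum of the
sampled (noise-free) profile values, so intensity-recovery comparisons are
not confounded by window truncation.

What it does **not** emulate, and what passing tests therefore do not show:
isoneutromer fine structure (collapsed into one species per neutron count),
isotopomers (not resolvable in MS1 at all), peak tailing (EMG elution exists
behind a config flag but is untested surface), m/z-dependent noise
heteroscedasticity, co-eluting chimeric envelopes, baseline drift. The
baseline, when enabled, is added on the sampled peak-support points (a local
chemical background); a full-grid baseline would remove the zero gaps that
separate hulls and is not what the detection model assumes. Real data will
violate several of these idealizations at once; perfect recovery on the
simulator validates the bookkeeping and the rule arithmetic, not robustness
to real chromatography.

## Validation problem sizes

The reference recovery study uses 10 molecules (uniform 400–2000 Da, ≥ 5 Da
apart), charges {1, 2}, three isotopic species (relative abundances 1.0 /
0.6 / 0.25), R = 60,000, 1 s scans over ~9.5 min, noise off, with every
cross-molecule trace pair ≥ 0.4 Th apart (≥ 10 peak widths) and apexes 52 s
apart (≥ 13 elution sigmas). Under these conditions the pipeline recovers
100% of traces, chargites and molecules with centroid errors below 1e-3 ppm
and integrated-intensity errors below 0.01%. Property suites run on
randomized fixtures: 1,000 random scans against a brute-force segmenter,
100-fixture conservation checks at 1e-9 relative tolerance, and
hypothesis-driven invariants (partition, gap law, permutation determinism,
provenance round-trips).

## Known limitations

The trace builder is forward-only and single-pass; a bidirectional variant
(discarding centroids unmatched to the two previous *or two next* scans)
would rescue some edge cases at trace starts. Charge assignment counts
spacing partners only — no averagine-style envelope-shape scoring — so
singleton traces are honestly reported as z = 0 rather than guessed.
Overlapping-envelope deconvolution is out of scope. The mzML layer is a
minimal, self-contained reader/writer (MS1, 64-bit uncompressed by default;
the reader also accepts 32-bit and zlib-compressed arrays) validated against
the Bioconductor mzR parser in the test suite; it does not aim to cover
vendor idiosyncrasies, chromatogram lists or indexed mzML wrappers.
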