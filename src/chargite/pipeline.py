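"""End-to-end feature detection: raw run -> traces -> chargites -> molecules."""

from __future__ import annotations

from dataclasses import dataclass, field

from .centroid import CentroiderConfig, centroid_run
from .envelope import EnvelopeConfig, group_chargites, group_molecules
from .model import ChargiteTrace, MolecularDistributionTrace, Neutroid, NeutromerTrace, RawRun
from .traces import TraceBuilderConfig, build_neutromer_traces, cull_short_traces, split_traces

__all__ = ["DetectionResult", "detect_features"]


@dataclass
class DetectionResult:
    """Everything the reference pipeline extracts from one run."""

    run: RawRun
    neutroids_by_scan: dict[int, list[Neutroid]]
    traces: list[NeutromerTrace]
    chargites: list[ChargiteTrace]
    molecules: list[MolecularDistributionTrace] = field(default_factory=list)


def detect_features(
    run: RawRun,
    centroider: CentroiderConfig | None = None,
    tracing: TraceBuilderConfig | None = None,
    envelope: EnvelopeConfig | None = None,
) -> DetectionResult:
    """Run the reference pipeline: centroid every scan, link neutroids into
    neutromer traces, cull and split them, then group isotope envelopes into
    chargites and charge states into molecules."""
    centroider = centroider or CentroiderConfig()
    tracing = tracing or TraceBuilderConfig()
    envelope = envelope or EnvelopeConfig()
    neutroids_by_scan = centroid_run(run, centroider)
    traces = build_neutromer_traces(neutroids_by_scan, tracing)
    traces = cull_short_traces(traces, tracing)
    traces = split_traces(traces, tracing)
    chargites = group_chargites(traces, envelope)
    molecules = group_molecules(chargites, envelope)
    return DetectionResult(
        run=run,
        neutroids_by_scan=neutroids_by_scan,
        traces=traces,
        chargites=chargites,
        molecules=molecules,
    )
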