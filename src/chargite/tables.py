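"""Feature tables named by the nomenclature.

A feature table has one row per entity (or per neutroid, for the per-scan
form), labeled with its entity kind and the human-readable provenance term
validated against the lexicon. Tables serialize to TSV or JSON with a fixed
column vocabulary and a deterministic row order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import lexicon
from .model import ProjectedEntity
from .pipeline import DetectionResult

__all__ = [
    "COLUMNS",
    "detection_table",
    "projected_table",
    "write_feature_table",
    "read_feature_table",
]

COLUMNS = [
    "entity_kind",
    "provenance",
    "mz",
    "rt",
    "intensity",
    "z",
    "isotope_index",
    "scan_index",
    "trace_id",
    "chargite_id",
    "molecule_id",
]


def detection_table(result: DetectionResult) -> pd.DataFrame:
    """Per-neutroid feature table for a detection result.

    Each row is one neutroid with the ids of the trace, chargite and molecule
    it belongs to (empty where unassigned), so traces can be re-projected from
    the table alone.
    """
    trace_to_chargite: dict[str, tuple[str, int, int]] = {}
    for c in result.chargites:
        for k, t in enumerate(c.neutromer_traces):
            trace_to_chargite[t.trace_id] = (c.chargite_id, c.z, k)
    chargite_to_molecule = {
        c.chargite_id: m.molecule_id for m in result.molecules for c in m.chargites
    }
    rows = []
    for t in result.traces:
        cid, z, k = trace_to_chargite.get(t.trace_id, ("", 0, -1))
        mid = chargite_to_molecule.get(cid, "")
        for n in t.neutroids:
            rows.append(
                {
                    "entity_kind": "neutroid",
                    "provenance": lexicon.term_string("neutroid"),
                    "mz": n.mz,
                    "rt": n.rt,
                    "intensity": n.intensity,
                    "z": z,
                    "isotope_index": k,
                    "scan_index": n.scan_index,
                    "trace_id": t.trace_id,
                    "chargite_id": cid,
                    "molecule_id": mid,
                }
            )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df.sort_values(["entity_kind", "mz", "rt"], kind="mergesort").reset_index(drop=True)


def projected_table(
    entities: Sequence[ProjectedEntity], entity_kind: str
) -> pd.DataFrame:
    """Table of projected entities; provenance chains are lexicon-validated."""
    rows = []
    for e in entities:
        lexicon.validate_chain(entity_kind, e.provenance)
        rows.append(
            {
                "entity_kind": entity_kind,
                "provenance": lexicon.term_string(entity_kind, e.provenance),
                "mz": e.mz,
                "rt": e.rt,
                "intensity": e.intensity,
                "z": 0,
                "isotope_index": -1,
                "scan_index": -1,
                "trace_id": e.source_id,
                "chargite_id": "",
                "molecule_id": "",
            }
        )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df.sort_values(["entity_kind", "mz", "rt"], kind="mergesort").reset_index(drop=True)


def write_feature_table(df: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a feature table as TSV or JSON (records orientation).

    Every provenance string is re-validated against the lexicon before
    writing; an unlicensed chain raises :class:`chargite.lexicon.LexiconError`.
    """
    for term in df.get("provenance", pd.Series(dtype=str)):
        lexicon.parse_term(term)
    path = Path(path)
    ordered = df.sort_values(["entity_kind", "mz", "rt"], kind="mergesort").reset_index(drop=True)
    if fmt == "tsv":
        ordered.to_csv(path, sep="\t", index=False, columns=COLUMNS)
    elif fmt == "json":
        payload = ordered[COLUMNS].to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown feature-table format {fmt!r}")


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV or JSON feature table back into a DataFrame."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()), columns=COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    for col in ("trace_id", "chargite_id", "molecule_id"):
        if col in df.columns:
            df[col] = df[col].astype(str).replace("nan", "")
    return df
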