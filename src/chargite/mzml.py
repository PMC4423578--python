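"""mzML reading and writing for MS1 profile/centroid runs.

A minimal, self-contained mzML 1.1.0 layer (lxml): the writer stores m/z and
intensity as uncompressed 64-bit little-endian arrays so a write -> read
round-trip is bit-exact; the reader handles 32/64-bit floats with optional
zlib compression, keeps only MS-level-1 spectra, and normalizes scan start
times to seconds.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path

import numpy as np
from lxml import etree

from .model import RawRun, Scan

__all__ = ["read_mzml", "write_mzml", "MzmlError"]

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS accessions used by this layer.
_ACC_MS1 = "MS:1000579"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_CENTROID = "MS:1000127"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


class MzmlError(ValueError):
    """Malformed or unusable mzML input."""


def _encode(array: np.ndarray) -> str:
    data = np.asarray(array, dtype="<f8").tobytes()
    return base64.b64encode(data).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", "MS")
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", value)
    for k, v in attrs.items():
        el.set(k, v)


def write_mzml(run: RawRun, path) -> None:
    """Serialize a run as mzML (MS1 spectra, 64-bit arrays, no compression)."""
    root = etree.Element("mzML", nsmap={None: _NS})
    root.set("version", "1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cv_list,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdl = etree.SubElement(root, "fileDescription")
    fc = etree.SubElement(fdl, "fileContent")
    _cv(fc, _ACC_MS1, "MS1 spectrum")
    run_el = etree.SubElement(root, "run", id=str(run.metadata.get("source", "chargite-run")))
    spec_list = etree.SubElement(run_el, "spectrumList", count=str(len(run.scans)))
    mode_cv = (
        (_ACC_PROFILE, "profile spectrum")
        if run.mode == "profile"
        else (_ACC_CENTROID, "centroid spectrum")
    )
    for scan in run.scans:
        spec = etree.SubElement(
            spec_list,
            "spectrum",
            index=str(scan.scan_index),
            id=f"scan={scan.scan_index}",
            defaultArrayLength=str(len(scan)),
        )
        _cv(spec, _ACC_MS1, "MS1 spectrum")
        _cv(spec, _ACC_MS_LEVEL, "ms level", "1")
        _cv(spec, *mode_cv)
        scan_list = etree.SubElement(spec, "scanList", count="1")
        scan_el = etree.SubElement(scan_list, "scan")
        _cv(
            scan_el,
            _ACC_SCAN_START,
            "scan start time",
            repr(scan.rt),
            unitCvRef="UO",
            unitAccession="UO:0000010",
            unitName="second",
        )
        bda_list = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, array in (
            (_ACC_MZ_ARRAY, "m/z array", scan.mz),
            (_ACC_INTENSITY_ARRAY, "intensity array", scan.intensity),
        ):
            encoded = _encode(array)
            bda = etree.SubElement(
                bda_list, "binaryDataArray", encodedLength=str(len(encoded))
            )
            _cv(bda, _ACC_F64, "64-bit float")
            _cv(bda, _ACC_NO_COMPRESSION, "no compression")
            _cv(bda, accession, name)
            etree.SubElement(bda, "binary").text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def _tag(el) -> str:
    return etree.QName(el).localname


def _accessions(el) -> dict[str, str]:
    """accession -> value for the cvParams directly under ``el``."""
    return {
        c.get("accession"): c.get("value", "")
        for c in el
        if _tag(c) == "cvParam"
    }


def _decode_binary_array(bda) -> np.ndarray:
    acc = _accessions(bda)
    text = ""
    for child in bda:
        if _tag(child) == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in acc:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in acc else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _scan_start_seconds(spectrum_el) -> float:
    for scan_list in spectrum_el.iterchildren():
        if _tag(scan_list) != "scanList":
            continue
        for scan in scan_list.iterchildren():
            if _tag(scan) != "scan":
                continue
            for cv in scan.iterchildren():
                if _tag(cv) == "cvParam" and cv.get("accession") == _ACC_SCAN_START:
                    value = float(cv.get("value"))
                    unit = (cv.get("unitName") or "").lower()
                    if "minute" in unit:
                        value *= 60.0
                    return value
    raise MzmlError("spectrum without a scan start time")


def read_mzml(path) -> RawRun:
    """Read MS-level-1 spectra from an mzML file into a :class:`RawRun`.

    Retention times are normalized to seconds (minute-valued files converted);
    the run mode is taken from the spectrum-type declaration. Raises
    :class:`MzmlError` when the file has no MS1 spectra or is malformed (the
    parser error names the file location).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[tuple[float, np.ndarray, np.ndarray]] = []
    modes: list[str] = []
    try:
        context = etree.iterparse(str(path), events=("end",), tag=f"{{{_NS}}}spectrum")
        for _event, spec in context:
            acc = _accessions(spec)
            ms_level = acc.get(_ACC_MS_LEVEL)
            is_ms1 = ms_level == "1" or (ms_level is None and _ACC_MS1 in acc)
            if is_ms1:
                mz = inten = None
                for bda_list in spec.iterchildren():
                    if _tag(bda_list) != "binaryDataArrayList":
                        continue
                    for bda in bda_list.iterchildren():
                        if _tag(bda) != "binaryDataArray":
                            continue
                        arr_acc = _accessions(bda)
                        if _ACC_MZ_ARRAY in arr_acc:
                            mz = _decode_binary_array(bda)
                        elif _ACC_INTENSITY_ARRAY in arr_acc:
                            inten = _decode_binary_array(bda)
                if mz is None or inten is None:
                    raise MzmlError(
                        f"spectrum {spec.get('id')!r} lacks m/z or intensity arrays"
                    )
                if _ACC_PROFILE in acc:
                    modes.append("profile")
                elif _ACC_CENTROID in acc:
                    modes.append("centroid")
                entries.append((_scan_start_seconds(spec), mz, inten))
            spec.clear()
    except etree.XMLSyntaxError as exc:
        raise MzmlError(f"malformed mzML in {path}: {exc}") from exc
    if not entries:
        raise MzmlError(f"no MS1 spectra found in {path}")
    entries.sort(key=lambda e: e[0])
    scans = [
        Scan(scan_index=i, rt=rt, mz=mz, intensity=inten)
        for i, (rt, mz, inten) in enumerate(entries)
    ]
    mode = modes[0] if modes else "profile"
    return RawRun(scans=scans, mode=mode, metadata={"source": str(path)})
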