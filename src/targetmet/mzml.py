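"""Minimal centroided-mzML reader/writer built on the standard library.

Implements the subset of the PSI mzML 1.1 schema needed for targeted
quantification: MS1/MS2 centroid spectra, retention times, polarity,
precursor m/z and collision energy, 64-bit uncompressed or zlib binary
arrays. Retention times are minutes everywhere in this package.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "MSRun", "read_mzml", "write_mzml", "MzmlError"]

_NS = "http://psi.hupo.org/ms/mzml"

# CV accessions used
_ACC_MS1 = "MS:1000579"
_ACC_MSN = "MS:1000580"
_ACC_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_POS = "MS:1000130"
_ACC_NEG = "MS:1000129"
_ACC_RT = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CE = "MS:1000045"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_NOCOMP = "MS:1000576"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


class MzmlError(ValueError):
    """Raised for unreadable, truncated or unsupported mzML content."""


@dataclass
class Spectrum:
    """One centroided spectrum.

    rt is in minutes; mz must be strictly ascending and the two arrays
    equal length.
    """

    rt: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str | None = None  # "+", "-" or None
    precursor_mz: float | None = None
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.rt < 0:
            raise ValueError(f"negative retention time {self.rt}")
        if self.ms_level not in (1, 2):
            raise ValueError(f"unsupported MS level {self.ms_level}")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z array must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass
class MSRun:
    """An ordered list of spectra with non-decreasing retention time."""

    run_id: str
    spectra: list[Spectrum] = field(default_factory=list)
    polarity: str | None = None
    scan_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectrum retention times must be non-decreasing")

    @property
    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    @property
    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


def _encode_array(values: np.ndarray, compress: bool) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=np.float64))
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def _decode_array(text: str, dtype: str, compressed: bool) -> np.ndarray:
    try:
        raw = base64.b64decode(text.encode("ascii"), validate=True)
        if compressed:
            raw = zlib.decompress(raw)
    except Exception as exc:  # noqa: BLE001 - normalize to I/O error
        raise MzmlError(f"undecodable binary array: {exc}") from exc
    np_dtype = "<f8" if dtype == "f64" else "<f4"
    return np.frombuffer(raw, dtype=np_dtype).astype(np.float64)


def _cv(parent: ET.Element, accession: str, name: str, value: str = "",
        unit: tuple[str, str, str] | None = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit is not None:
        attrs["unitCvRef"], attrs["unitAccession"], attrs["unitName"] = unit
    ET.SubElement(parent, "cvParam", attrs)


_MINUTE = ("UO", "UO:0000031", "minute")


def write_mzml(run: MSRun, path: str, compress: bool = False) -> None:
    """Serialize a run to mzML. Arrays are 64-bit little-endian floats."""
    root = ET.Element("mzML", {
        "xmlns": _NS,
        "version": "1.1.0",
        "id": run.run_id,
    })
    flist = ET.SubElement(root, "fileDescription")
    content = ET.SubElement(flist, "fileContent")
    _cv(content, _ACC_MS1, "MS1 spectrum")
    _cv(content, _ACC_CENTROID, "centroid spectrum")
    run_el = ET.SubElement(root, "run", {"id": run.run_id})
    spec_list = ET.SubElement(
        run_el, "spectrumList", {"count": str(len(run.spectra))}
    )
    for i, spec in enumerate(run.spectra):
        s_el = ET.SubElement(spec_list, "spectrum", {
            "index": str(i),
            "id": f"scan={i + 1}",
            "defaultArrayLength": str(spec.mz.size),
        })
        _cv(s_el, _ACC_LEVEL, "ms level", str(spec.ms_level))
        _cv(s_el, _ACC_CENTROID, "centroid spectrum")
        pol = spec.polarity or run.polarity
        if pol == "+":
            _cv(s_el, _ACC_POS, "positive scan")
        elif pol == "-":
            _cv(s_el, _ACC_NEG, "negative scan")
        scans = ET.SubElement(s_el, "scanList", {"count": "1"})
        scan = ET.SubElement(scans, "scan")
        _cv(scan, _ACC_RT, "scan start time", repr(spec.rt), _MINUTE)
        if spec.ms_level == 2:
            precs = ET.SubElement(s_el, "precursorList", {"count": "1"})
            prec = ET.SubElement(precs, "precursor")
            ions = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            ion = ET.SubElement(ions, "selectedIon")
            _cv(ion, _ACC_SELECTED_MZ, "selected ion m/z",
                repr(spec.precursor_mz if spec.precursor_mz is not None else 0.0))
            act = ET.SubElement(prec, "activation")
            if spec.collision_energy is not None:
                _cv(act, _ACC_CE, "collision energy", repr(spec.collision_energy))
        arrays = ET.SubElement(
            s_el, "binaryDataArrayList", {"count": "2"}
        )
        for acc, name, values in (
            (_ACC_MZ_ARRAY, "m/z array", spec.mz),
            (_ACC_INT_ARRAY, "intensity array", spec.intensity),
        ):
            encoded = _encode_array(values, compress)
            arr = ET.SubElement(arrays, "binaryDataArray", {
                "encodedLength": str(len(encoded)),
            })
            _cv(arr, _ACC_F64, "64-bit float")
            _cv(arr, _ACC_ZLIB if compress else _ACC_NOCOMP,
                "zlib compression" if compress else "no compression")
            _cv(arr, acc, name)
            ET.SubElement(arr, "binary").text = encoded
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _params(el: ET.Element) -> dict[str, str]:
    out = {}
    for child in el:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


def _iter_all(el: ET.Element, name: str):
    for child in el.iter():
        if _local(child.tag) == name:
            yield child


def read_mzml(path: str) -> MSRun:
    """Parse a centroided mzML file into an :class:`MSRun`.

    Profile-mode spectra are rejected; an empty spectrum list is an error.
    """
    try:
        tree = ET.parse(path)
    except (ET.ParseError, OSError) as exc:
        raise MzmlError(f"cannot read mzML file {path!r}: {exc}") from exc
    root = tree.getroot()
    run_el = next(_iter_all(root, "run"), None)
    run_id = run_el.get("id", "run") if run_el is not None else "run"
    spectra: list[Spectrum] = []
    run_polarity: str | None = None
    for s_el in _iter_all(root, "spectrum"):
        own = _params(s_el)
        if _ACC_PROFILE in own:
            raise MzmlError(
                "profile-mode spectra are unsupported; centroid the data first"
            )
        level = int(own.get(_ACC_LEVEL, "1"))
        polarity = "+" if _ACC_POS in own else "-" if _ACC_NEG in own else None
        if polarity is not None:
            run_polarity = run_polarity or polarity
        rt = 0.0
        for scan in _iter_all(s_el, "scan"):
            for child in scan:
                if (_local(child.tag) == "cvParam"
                        and child.get("accession") == _ACC_RT):
                    rt = float(child.get("value", "0"))
                    if child.get("unitName") == "second":
                        rt /= 60.0
        precursor_mz = None
        collision_energy = None
        for ion in _iter_all(s_el, "selectedIon"):
            p = _params(ion)
            if _ACC_SELECTED_MZ in p:
                precursor_mz = float(p[_ACC_SELECTED_MZ])
        for act in _iter_all(s_el, "activation"):
            p = _params(act)
            if _ACC_CE in p:
                collision_energy = float(p[_ACC_CE])
        mz = intensity = None
        for arr in _iter_all(s_el, "binaryDataArray"):
            p = _params(arr)
            dtype = "f64" if _ACC_F64 in p else "f32"
            compressed = _ACC_ZLIB in p
            binary = next(_iter_all(arr, "binary"), None)
            text = (binary.text or "") if binary is not None else ""
            values = _decode_array(text, dtype, compressed)
            if _ACC_MZ_ARRAY in p:
                mz = values
            elif _ACC_INT_ARRAY in p:
                intensity = values
        if mz is None or intensity is None:
            raise MzmlError(f"spectrum in {path!r} lacks m/z or intensity array")
        spectra.append(Spectrum(
            rt=rt, ms_level=level, mz=mz, intensity=intensity,
            polarity=polarity, precursor_mz=precursor_mz,
            collision_energy=collision_energy,
        ))
    if not spectra:
        raise MzmlError(f"no spectra in mzML file {path!r}")
    return MSRun(run_id=run_id, spectra=spectra, polarity=run_polarity)
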