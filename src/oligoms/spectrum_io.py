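"""mzML reading/writing and MS2 preprocessing (intensity filtering,
deisotoping) for centroided negative-mode data.

The mzML layer is a small self-contained implementation covering the subset
of mzML 1.1 needed here: centroided spectra, scan times, precursor selected
ion m/z + charge state, 32/64-bit float binary arrays with optional zlib
compression.  Charge states are stored as magnitudes in the file (as vendor
converters do) and signed by scan polarity on read.
"""

from __future__ import annotations

import base64
import struct
import warnings
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .chem_core import C13_C12_DELTA

__all__ = [
    "Peak",
    "MS2Spectrum",
    "MzMLError",
    "read_mzml",
    "write_mzml",
    "filter_peaks",
    "deisotope",
]


class MzMLError(ValueError):
    pass


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class MS2Spectrum:
    """A centroided spectrum (MS level 1 or 2) with sorted peaks."""

    native_id: str
    ms_level: int = 2
    retention_time: float = 0.0           # seconds
    precursor_mz: float = 0.0
    precursor_charge: int = 0             # negative; 0 = unknown
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_charges: Optional[np.ndarray] = None  # set by deisotoping; 0 unknown
    polarity: Optional[str] = None        # "negative" | "positive" | None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise MzMLError("m/z and intensity arrays differ in length")
        order = np.argsort(self.mz, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if self.peak_charges is not None:
                self.peak_charges = np.asarray(self.peak_charges)[order]

    @property
    def peaks(self) -> List[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return len(self.mz)


# -- binary array helpers -----------------------------------------------------

_ACC_MZ = "MS:1000514"
_ACC_INT = "MS:1000515"
_ACC_64 = "MS:1000523"
_ACC_32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NONE = "MS:1000576"
_ACC_MSLEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_NEG = "MS:1000129"
_ACC_POS = "MS:1000130"
_ACC_RT = "MS:1000016"
_ACC_SELMZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _decode_array(text: str, bits: int, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(text.strip()) if text.strip() else b""
    if compressed:
        raw = zlib.decompress(raw)
    dtype = "<f8" if bits == 64 else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cvparams(elem) -> Dict[str, str]:
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.get("value", "")
    return out


def _iter_named(elem, name):
    for child in elem.iter():
        if _local(child.tag) == name:
            yield child


# -- reading ------------------------------------------------------------------

def read_mzml(path, ms_levels: Sequence[int] = (1, 2)) -> List[MS2Spectrum]:
    """Read centroided spectra from an mzML file.

    Profile spectra are rejected; MS2 spectra without precursor information
    are skipped with a warning; positive-polarity MS2 spectra are rejected
    (the engine is negative-mode only).
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MzMLError(f"malformed mzML file {path}: {exc}") from exc
    root = tree.getroot()
    spectra: List[MS2Spectrum] = []
    for spec_el in _iter_named(root, "spectrum"):
        params = _cvparams(spec_el)
        ms_level = int(params.get(_ACC_MSLEVEL, "0") or 0)
        if ms_level not in ms_levels:
            continue
        if _ACC_PROFILE in params:
            raise MzMLError(
                f"spectrum {spec_el.get('id')!r} is profile data; "
                "centroided input is required")
        polarity = None
        if _ACC_NEG in params:
            polarity = "negative"
        elif _ACC_POS in params:
            polarity = "positive"

        rt = 0.0
        for scan_el in _iter_named(spec_el, "scan"):
            sp = _cvparams(scan_el)
            if _ACC_RT in sp:
                val = float(sp[_ACC_RT])
                unit = None
                for child in scan_el:
                    if child.get("accession") == _ACC_RT:
                        unit = child.get("unitName")
                rt = val * 60.0 if unit == "minute" else val
            if polarity is None:
                if _ACC_NEG in sp:
                    polarity = "negative"
                elif _ACC_POS in sp:
                    polarity = "positive"

        prec_mz, prec_z = 0.0, 0
        have_precursor = False
        for ion_el in _iter_named(spec_el, "selectedIon"):
            ip = _cvparams(ion_el)
            if _ACC_SELMZ in ip:
                prec_mz = float(ip[_ACC_SELMZ])
                have_precursor = True
            if _ACC_CHARGE in ip:
                prec_z = int(float(ip[_ACC_CHARGE]))

        if ms_level >= 2:
            if polarity == "positive":
                raise MzMLError(
                    f"spectrum {spec_el.get('id')!r} is positive mode; "
                    "the engine handles negative mode only")
            if not have_precursor:
                warnings.warn(
                    f"MS2 spectrum {spec_el.get('id')!r} lacks precursor "
                    "information; skipped")
                continue

        arrays: Dict[str, np.ndarray] = {}
        for arr_el in _iter_named(spec_el, "binaryDataArray"):
            ap = _cvparams(arr_el)
            bits = 64 if _ACC_64 in ap else 32
            compressed = _ACC_ZLIB in ap
            text = ""
            for child in arr_el:
                if _local(child.tag) == "binary":
                    text = child.text or ""
            data = _decode_array(text, bits, compressed)
            if _ACC_MZ in ap:
                arrays["mz"] = data
            elif _ACC_INT in ap:
                arrays["intensity"] = data
        mz = arrays.get("mz", np.empty(0))
        inten = arrays.get("intensity", np.empty(0))

        charge = prec_z
        if charge > 0 and polarity == "negative":
            charge = -charge
        spectra.append(MS2Spectrum(
            native_id=spec_el.get("id", f"index={spec_el.get('index')}"),
            ms_level=ms_level,
            retention_time=rt,
            precursor_mz=prec_mz,
            precursor_charge=charge,
            mz=mz,
            intensity=inten,
            polarity=polarity,
        ))
    return spectra


# -- writing (fixture-grade, uncompressed 64-bit) -----------------------------

def _cv(parent, accession, name, value="", unit=None):
    el = ET.SubElement(parent, "cvParam",
                       cvRef="MS", accession=accession, name=name, value=value)
    if unit:
        el.set("unitName", unit)
        el.set("unitCvRef", "UO")
    return el


def write_mzml(spectra: Iterable[MS2Spectrum], path) -> None:
    """Write a minimal, standards-shaped mzML 1.1 document."""
    spectra = list(spectra)
    root = ET.Element("mzML", xmlns="http://psi.hupo.org/ms/mzml",
                      version="1.1.0")
    run = ET.SubElement(root, "run", id="run")
    slist = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
    for idx, spec in enumerate(spectra):
        sp = ET.SubElement(slist, "spectrum", index=str(idx),
                           id=spec.native_id,
                           defaultArrayLength=str(len(spec)))
        _cv(sp, _ACC_MSLEVEL, "ms level", str(spec.ms_level))
        _cv(sp, _ACC_CENTROID, "centroid spectrum")
        if spec.polarity != "positive":
            _cv(sp, _ACC_NEG, "negative scan")
        else:
            _cv(sp, _ACC_POS, "positive scan")
        scan_list = ET.SubElement(sp, "scanList", count="1")
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, _ACC_RT, "scan start time",
            f"{spec.retention_time:.6f}", unit="second")
        if spec.ms_level >= 2:
            plist = ET.SubElement(sp, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            ilist = ET.SubElement(prec, "selectedIonList", count="1")
            ion = ET.SubElement(ilist, "selectedIon")
            _cv(ion, _ACC_SELMZ, "selected ion m/z", f"{spec.precursor_mz:.8f}")
            if spec.precursor_charge != 0:
                _cv(ion, _ACC_CHARGE, "charge state",
                    str(abs(spec.precursor_charge)))
        alist = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for accession, name, values in ((_ACC_MZ, "m/z array", spec.mz),
                                        (_ACC_INT, "intensity array",
                                         spec.intensity)):
            encoded = _encode_array(np.asarray(values, dtype=float))
            arr = ET.SubElement(alist, "binaryDataArray",
                                encodedLength=str(len(encoded)))
            _cv(arr, _ACC_64, "64-bit float")
            _cv(arr, _ACC_NONE, "no compression")
            _cv(arr, accession, name)
            ET.SubElement(arr, "binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


# -- preprocessing ------------------------------------------------------------

def filter_peaks(spectrum: MS2Spectrum, mode: str = "relative_threshold",
                 threshold: float = 0.0) -> MS2Spectrum:
    """Intensity filtering; idempotent.

    ``relative_threshold``: keep peaks with intensity >= threshold x base
    peak.  ``top_n_per_100Th``: keep the ``threshold`` most intense peaks in
    each non-overlapping 100 Th window.
    """
    if len(spectrum) == 0:
        return spectrum
    if mode == "relative_threshold":
        if threshold <= 0.0:
            return spectrum
        cutoff = threshold * spectrum.intensity.max()
        keep = spectrum.intensity >= cutoff
    elif mode == "top_n_per_100Th":
        n = int(threshold)
        keep = np.zeros(len(spectrum), dtype=bool)
        windows = (spectrum.mz // 100.0).astype(int)
        for win in np.unique(windows):
            idx = np.where(windows == win)[0]
            if len(idx) <= n:
                keep[idx] = True
            else:
                best = idx[np.argsort(spectrum.intensity[idx])[-n:]]
                keep[best] = True
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    charges = (spectrum.peak_charges[keep]
               if spectrum.peak_charges is not None else None)
    return replace(spectrum, mz=spectrum.mz[keep],
                   intensity=spectrum.intensity[keep], peak_charges=charges)


def deisotope(spectrum: MS2Spectrum, fragment_tol_ppm: float = 10.0,
              max_charge: int = 4) -> MS2Spectrum:
    """Collapse isotope envelopes to their monoisotopic peak.

    Peak series spaced by ``1.00335/z`` (C13-C12) within tolerance, with
    non-increasing intensities beyond the first member, are merged into the
    lightest peak (summed intensity) and annotated with the charge magnitude.
    Unmatched peaks are kept with charge 0 (unknown).  Never increases the
    peak count; total intensity is conserved.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(spectrum)
    if n == 0:
        return replace(spectrum, peak_charges=np.empty(0, dtype=int))
    mz = spectrum.mz
    inten = spectrum.intensity
    consumed = np.zeros(n, dtype=bool)
    out_mz: List[float] = []
    out_int: List[float] = []
    out_z: List[int] = []
    for i in range(n):
        if consumed[i]:
            continue
        best_cluster: List[int] = [i]
        best_z = 0
        for z in range(max_charge, 0, -1):
            cluster = [i]
            expect = mz[i]
            while True:
                expect_next = expect + C13_C12_DELTA / z
                tol = expect_next * fragment_tol_ppm * 1e-6
                lo = np.searchsorted(mz, expect_next - tol)
                hi = np.searchsorted(mz, expect_next + tol)
                cand = [j for j in range(lo, hi) if not consumed[j]]
                if not cand:
                    break
                j = min(cand, key=lambda k: abs(mz[k] - expect_next))
                if inten[j] > inten[cluster[-1]] and len(cluster) >= 2:
                    break  # intensities must be non-increasing past the apex
                cluster.append(j)
                expect = mz[j]
            if len(cluster) > len(best_cluster):
                best_cluster = cluster
                best_z = z
        if len(best_cluster) >= 2:
            for j in best_cluster:
                consumed[j] = True
            out_mz.append(mz[i])
            out_int.append(float(sum(inten[j] for j in best_cluster)))
            out_z.append(best_z)
        else:
            consumed[i] = True
            out_mz.append(mz[i])
            out_int.append(float(inten[i]))
            out_z.append(0)
    return replace(spectrum, mz=np.array(out_mz), intensity=np.array(out_int),
                   peak_charges=np.array(out_z, dtype=int))
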