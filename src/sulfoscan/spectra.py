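"""Tandem-mass-spectrum data model and MGF/mzML readers.

A :class:`Spectrum` is one centroided MS2 scan with its precursor and
activation metadata; a :class:`Run` is an ordered collection with unique
scan ids.  MGF is the primary interchange format (activation type and
collision energy are carried as ``ACTIVATION=`` / ``ENERGY=`` header
keys); mzML reading is minimal — MS2 scans only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator

import base64
import xml.etree.ElementTree as ET
import zlib

import numpy as np
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

ACTIVATION_TYPES = ("HCD", "CID", "ETD", "EThcD", "ETciD", "UVPD")


@dataclass
class Spectrum:
    """One centroided MS2 scan.

    ``energy`` is normalized collision energy in percent for collisional
    activation (irradiation time in ms for UVPD).  Peaks are stored as
    parallel arrays with m/z strictly ascending.
    """

    scan_id: int
    precursor_mz: float
    precursor_z: int | None
    mz: np.ndarray
    intensity: np.ndarray
    rt: float = 0.0
    activation: str = "HCD"
    energy: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) == 0):
                raise ValueError("duplicate peak m/z values")
        if self.precursor_z is not None and not 1 <= self.precursor_z <= 8:
            raise ValueError(f"precursor charge {self.precursor_z} outside [1, 8]")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An ordered list of spectra from one acquisition."""

    spectra: list[Spectrum] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.scan_id for s in self.spectra]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate scan_ids in run")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def by_scan(self) -> dict[int, Spectrum]:
        return {s.scan_id: s for s in self.spectra}


def base_peak_and_tic(s: Spectrum) -> tuple[float, float]:
    """Base-peak intensity and total ion current (summed intensity)."""
    if s.n_peaks == 0:
        raise ValueError(f"spectrum {s.scan_id} has no peaks")
    return float(s.intensity.max()), float(s.intensity.sum())


_SCAN_RE = re.compile(r"scan[=:\s]*(\d+)", re.IGNORECASE)


def _scan_from_params(params: dict, fallback: int) -> int:
    if "scans" in params:
        return int(str(params["scans"]).split("-")[0])
    title = str(params.get("title", ""))
    m = _SCAN_RE.search(title)
    if m:
        return int(m.group(1))
    return fallback


def read_mgf(path) -> Run:
    """Read an MGF file into a :class:`Run`.

    Honors PEPMASS, CHARGE, RTINSECONDS, TITLE/SCANS; optional
    ACTIVATION and ENERGY keys carry the trigger-relevant metadata.
    Peaks are sorted ascending on read.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader, start=1):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"MGF block {i} in {path} lacks PEPMASS")
            charge = params.get("charge")
            z = int(charge[0]) if charge else None
            spectra.append(
                Spectrum(
                    scan_id=_scan_from_params(params, fallback=i),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_z=z,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    rt=float(params.get("rtinseconds", 0.0)),
                    activation=str(params.get("activation", "HCD")),
                    energy=float(params["energy"]) if "energy" in params else None,
                )
            )
    return Run(spectra=spectra, provenance=f"mgf:{path}")


def write_mgf(run: Run, path) -> None:
    """Write a run back to MGF with fixed numeric formatting.

    The output is byte-stable: the same run always serializes to the
    same file (m/z to 5 decimals, intensity to 3).
    """
    with open(path, "w") as fh:
        for s in run:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE=scan={s.scan_id}\n")
            fh.write(f"SCANS={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.5f}\n")
            if s.precursor_z is not None:
                fh.write(f"CHARGE={s.precursor_z}+\n")
            fh.write(f"RTINSECONDS={s.rt:.3f}\n")
            fh.write(f"ACTIVATION={s.activation}\n")
            if s.energy is not None:
                fh.write(f"ENERGY={s.energy:g}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {inten:.3f}\n")
            fh.write("END IONS\n")


# -- minimal mzML reading -------------------------------------------------
# A purpose-built MS2-only extractor on stdlib XML: it handles centroided
# scans, 32/64-bit float peak arrays (plain or zlib-compressed base64),
# precursor m/z + charge, the common activation cvParams and scan start
# time.  Everything else in the standard is out of scope.

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

_ACTIVATION_CV = {
    "beam-type collision-induced dissociation": "HCD",
    "electron transfer dissociation": "ETD",
    "collision-induced dissociation": "CID",
    "photodissociation": "UVPD",
}


def _cvparams(elem) -> dict[str, dict]:
    return {
        cv.get("name"): cv.attrib
        for cv in elem.findall(f"{_MZML_NS}cvParam")
    }


def _decode_binary_array(bda) -> np.ndarray | None:
    params = _cvparams(bda)
    binary = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").encode())
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float), params


def read_mzml_minimal(path) -> Run:
    """Minimal mzML reader: centroided MS2 scans only.

    MS1 scans are skipped; MS2 scans without a precursor, or recorded in
    profile mode, are skipped with a logged warning.  Missing charge is
    tolerated (``precursor_z = None``).
    """
    spectra: list[Spectrum] = []
    index = 0
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if elem.tag != f"{_MZML_NS}spectrum":
            continue
        index += 1
        params = _cvparams(elem)
        if params.get("ms level", {}).get("value") != "2":
            elem.clear()
            continue
        if "profile spectrum" in params:
            logger.warning("skipping profile-mode spectrum %s", elem.get("id"))
            elem.clear()
            continue
        precursor = elem.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor"
        )
        ion = precursor.find(
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        ) if precursor is not None else None
        ion_params = _cvparams(ion) if ion is not None else {}
        if "selected ion m/z" not in ion_params:
            logger.warning("skipping MS2 without precursor: %s", elem.get("id"))
            elem.clear()
            continue
        prec_mz = float(ion_params["selected ion m/z"]["value"])
        z = ion_params.get("charge state", {}).get("value")

        activation, energy = "HCD", None
        act = precursor.find(f"{_MZML_NS}activation")
        if act is not None:
            act_params = _cvparams(act)
            for cv_name, kind in _ACTIVATION_CV.items():
                if cv_name in act_params:
                    activation = kind
                    break
            if "collision energy" in act_params:
                energy = float(act_params["collision energy"]["value"])

        rt = 0.0
        scan_meta = elem.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
        if scan_meta is not None:
            sp = _cvparams(scan_meta)
            if "scan start time" in sp:
                rt = float(sp["scan start time"]["value"])
                if sp["scan start time"].get("unitName") == "minute":
                    rt *= 60.0

        mz = intensity = None
        for bda in elem.findall(
            f"{_MZML_NS}binaryDataArrayList/{_MZML_NS}binaryDataArray"
        ):
            arr, bparams = _decode_binary_array(bda)
            if "m/z array" in bparams:
                mz = arr
            elif "intensity array" in bparams:
                intensity = arr
        if mz is None or intensity is None:
            logger.warning("skipping MS2 without peak arrays: %s", elem.get("id"))
            elem.clear()
            continue
        spectra.append(
            Spectrum(
                scan_id=_scan_from_params({"title": elem.get("id", "")}, index),
                precursor_mz=prec_mz,
                precursor_z=int(z) if z is not None else None,
                mz=mz,
                intensity=intensity,
                rt=rt,
                activation=activation,
                energy=energy,
            )
        )
        elem.clear()
    return Run(spectra=spectra, provenance=f"mzml:{path}")
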