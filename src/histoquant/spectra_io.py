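"""Spectrum and table I/O: mzML input, a JSON peak-list dialect, TSV tables.

The JSON dialect is the canonical fixture format for synthetic data: a
versioned, human-diffable list of spectra, each with level, peaks and
(for MS2) precursor linkage.  mzML is read by a small built-in parser.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PEAKLIST_VERSION = "1.0"

ABUNDANCE_COLUMNS = ["family", "proteoform", "sample", "condition", "tissue", "abundance_percent"]

CONDITIONS = ("TN", "RT", "SC")
TISSUES = ("BAT", "liver")


@dataclass
class Precursor:
    mz: float
    charge: int
    isolation_window_da: float = 3.4


@dataclass
class SpectrumPeakList:
    """One centroided spectrum: (m/z, intensity, optional charge) peaks."""

    level: Literal["MS1", "MS2"]
    scan_id: str
    mz: list[float]
    intensity: list[float]
    charge: list[int | None] = field(default_factory=list)
    precursor: Precursor | None = None
    family_hint: Literal["H3", "H4", "unknown"] = "unknown"

    def __post_init__(self) -> None:
        if not self.charge:
            self.charge = [None] * len(self.mz)
        if not (len(self.mz) == len(self.intensity) == len(self.charge)):
            raise ValueError(f"scan {self.scan_id}: peak arrays differ in length")
        if any(i < 0 for i in self.intensity):
            raise ValueError(f"scan {self.scan_id}: negative intensity")
        if self.level == "MS2" and self.precursor is None:
            raise ValueError(f"MS2 scan {self.scan_id} lacks a precursor")
        order = sorted(range(len(self.mz)), key=lambda i: self.mz[i])
        if order != list(range(len(self.mz))):
            logger.warning("scan %s: peaks were not m/z-sorted; sorting", self.scan_id)
            self.mz = [self.mz[i] for i in order]
            self.intensity = [self.intensity[i] for i in order]
            self.charge = [self.charge[i] for i in order]

    @property
    def n_peaks(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class RunManifest:
    """Sample bookkeeping: tissue/condition labels and technical replicates."""

    rows: tuple[dict, ...]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rows:
            key = (r["sample"], r["replicate"])
            if key in seen:
                raise ValueError(f"duplicate (sample, replicate) {key}")
            seen.add(key)
            if r["condition"] not in CONDITIONS:
                raise ValueError(f"unknown condition {r['condition']!r}")
            if r["tissue"] not in TISSUES:
                raise ValueError(f"unknown tissue {r['tissue']!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({"samples": [dict(r) for r in manifest.rows]}))


def read_manifest(path: str | Path) -> RunManifest:
    raw = yaml.safe_load(Path(path).read_text())
    return RunManifest(tuple(raw["samples"]))


def _spectrum_to_dict(s: SpectrumPeakList) -> dict:
    d = {
        "level": s.level,
        "scan_id": s.scan_id,
        "family_hint": s.family_hint,
        "peaks": [
            {"mz": mz, "intensity": it, **({"charge": z} if z is not None else {})}
            for mz, it, z in zip(s.mz, s.intensity, s.charge)
        ],
    }
    if s.precursor is not None:
        d["precursor"] = asdict(s.precursor)
    return d


def write_spectra_json(spectra: Sequence[SpectrumPeakList], path: str | Path) -> None:
    doc = {"version": PEAKLIST_VERSION, "spectra": [_spectrum_to_dict(s) for s in spectra]}
    Path(path).write_text(json.dumps(doc, indent=1))


def _spectrum_from_dict(d: dict) -> SpectrumPeakList:
    peaks = d.get("peaks", [])
    prec = d.get("precursor")
    return SpectrumPeakList(
        level=d["level"],
        scan_id=d["scan_id"],
        mz=[p["mz"] for p in peaks],
        intensity=[p["intensity"] for p in peaks],
        charge=[p.get("charge") for p in peaks],
        precursor=Precursor(**prec) if prec else None,
        family_hint=d.get("family_hint", "unknown"),
    )


def read_spectra(path: str | Path, format: Literal["json", "mzml"] = "json") -> list[SpectrumPeakList]:
    """Read spectra from the JSON peak-list dialect or from mzML."""
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text())
        if "version" not in doc:
            raise ValueError(f"{path}: peak-list file lacks a 'version' field")
        return [_spectrum_from_dict(d) for d in doc["spectra"]]
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown format {format!r}")


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
_CV = {
    "ms_level": "MS:1000511",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "float64": "MS:1000523",
    "float32": "MS:1000521",
    "zlib": "MS:1000574",
    "no_compression": "MS:1000576",
    "selected_mz": "MS:1000744",
    "charge_state": "MS:1000041",
}


def _decode_binary_array(node) -> list[float]:
    import base64
    import struct
    import zlib

    accessions = {cv.get("accession") for cv in node.iter(f"{_MZML_NS}cvParam")}
    raw = base64.b64decode((node.findtext(f"{_MZML_NS}binary") or "").strip())
    if _CV["zlib"] in accessions:
        raw = zlib.decompress(raw)
    fmt = "f" if _CV["float32"] in accessions else "d"
    width = 4 if fmt == "f" else 8
    return list(struct.unpack(f"<{len(raw) // width}{fmt}", raw))


def _read_mzml(path: Path) -> list[SpectrumPeakList]:
    # small self-contained reader (centroided spectra, float arrays,
    # no-compression or zlib); precursor charge defaults to 1 when absent
    from lxml import etree

    tree = etree.parse(str(path))
    out = []
    for spectrum in tree.iter(f"{_MZML_NS}spectrum"):
        level = 1
        for cv in spectrum.findall(f"{_MZML_NS}cvParam"):
            if cv.get("accession") == _CV["ms_level"]:
                level = int(cv.get("value"))
        scan_id = spectrum.get("id", str(len(out)))
        mz, inten = [], []
        for arr in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
            accessions = {cv.get("accession") for cv in arr.findall(f"{_MZML_NS}cvParam")}
            if _CV["mz_array"] in accessions:
                mz = _decode_binary_array(arr)
            elif _CV["intensity_array"] in accessions:
                inten = _decode_binary_array(arr)
        prec = None
        if level >= 2:
            ion = spectrum.find(
                f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
                f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
            )
            if ion is None:
                raise ValueError(f"MS2 scan {scan_id} lacks precursor information")
            sel_mz, charge = None, 1
            for cv in ion.findall(f"{_MZML_NS}cvParam"):
                if cv.get("accession") == _CV["selected_mz"]:
                    sel_mz = float(cv.get("value"))
                elif cv.get("accession") == _CV["charge_state"]:
                    charge = int(cv.get("value"))
            if sel_mz is None:
                raise ValueError(f"MS2 scan {scan_id} lacks a selected ion m/z")
            prec = Precursor(mz=sel_mz, charge=charge)
        out.append(
            SpectrumPeakList(
                level="MS1" if level == 1 else "MS2",
                scan_id=scan_id,
                mz=mz,
                intensity=inten,
                precursor=prec,
            )
        )
    return out


def write_abundance_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a normalized abundance table as TSV (columns fixed, row order stable)."""
    missing = set(ABUNDANCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"abundance table missing columns {sorted(missing)}")
    sums = table.groupby(["sample", "family"])["abundance_percent"].sum()
    bad = sums[(sums - 100.0).abs() > 1e-6]
    if not bad.empty:
        raise ValueError(f"table not normalized to 100 per (sample, family): {bad.to_dict()}")
    out = table[ABUNDANCE_COLUMNS].sort_values(["family", "sample", "proteoform"], kind="stable")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str})
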