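"""Reading and writing of spectra, peak lists, designs, and the marker fixture.

Spectra travel as two-column text (m/z, intensity in mV); mzML is supported
read-only for interchange. Peak tables and experiment designs are CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "RawSpectrum",
    "MarkerFixture",
    "read_spectrum",
    "write_spectrum",
    "load_marker_fixture",
    "read_peaklist_csv",
    "write_peaklist_csv",
]


@dataclass(frozen=True)
class Condition:
    """One exposure condition: toxin, concentration (with units), control flag."""

    toxin: str
    concentration: float = 0.0
    units: str = ""
    is_control: bool = False

    @property
    def key(self) -> str:
        if self.is_control:
            return "control"
        return f"{self.toxin}:{self.concentration:g}"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.key


CONTROL = Condition("control", 0.0, "", True)


@dataclass
class RawSpectrum:
    """A single profile spectrum on a strictly increasing m/z grid.

    Intensities are in millivolts as delivered by a linear-mode TOF detector.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    condition: Condition | None = None
    replicate_index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if self.mz.size != self.intensity.size:
            raise ValueError(
                f"length mismatch: {self.mz.size} m/z values vs "
                f"{self.intensity.size} intensities"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.mz.size and self.mz[0] < 0:
            raise ValueError("negative masses are not physical")
        if not np.all(np.isfinite(self.intensity)) or not np.all(np.isfinite(self.mz)):
            raise ValueError("spectrum contains non-finite values")

    def __len__(self) -> int:
        return self.mz.size

    def with_intensity(self, intensity: np.ndarray) -> "RawSpectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))

    def with_mz(self, mz: np.ndarray) -> "RawSpectrum":
        return replace(self, mz=np.asarray(mz, dtype=float))


def write_spectrum(spectrum: RawSpectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column whitespace-delimited text.

    Metadata (sample id, condition, replicate) is stored in '#' header lines
    so a round-trip through :func:`read_spectrum` restores it.
    """
    path = Path(path)
    cond = spectrum.condition
    lines = [f"# sample_id={spectrum.sample_id}", f"# replicate={spectrum.replicate_index}"]
    if cond is not None:
        lines.append(
            f"# condition={cond.toxin};{cond.concentration!r};{cond.units};{int(cond.is_control)}"
        )
    for key, value in spectrum.metadata.items():
        lines.append(f"# meta:{key}={value}")
    body = "\n".join(
        f"{m:.6f}\t{i:.6f}" for m, i in zip(spectrum.mz, spectrum.intensity)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def _parse_text_spectrum(path: Path) -> RawSpectrum:
    meta: dict = {}
    sample_id = path.stem
    replicate = 0
    condition = None
    rows: list[tuple[float, float]] = []
    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("#"):
            content = line.lstrip("#").strip()
            if content.startswith("sample_id="):
                sample_id = content.split("=", 1)[1]
            elif content.startswith("replicate="):
                replicate = int(content.split("=", 1)[1])
            elif content.startswith("condition="):
                toxin, conc, units, isctl = content.split("=", 1)[1].split(";")
                condition = Condition(toxin, float(conc), units, bool(int(isctl)))
            elif content.startswith("meta:"):
                key, value = content[5:].split("=", 1)
                meta[key] = value
            continue
        fields = re.split(r"[\s,]+", line)
        if len(fields) < 2:
            raise ValueError(
                f"{path}: expected two columns (m/z, intensity), got {line!r}"
            )
        try:
            rows.append((float(fields[0]), float(fields[1])))
        except ValueError:
            # a single non-numeric header line is tolerated and skipped
            if rows:
                raise ValueError(f"{path}: malformed data line {line!r}")
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    return RawSpectrum(
        mz=arr[order, 0],
        intensity=arr[order, 1],
        sample_id=sample_id,
        condition=condition,
        replicate_index=replicate,
        metadata=meta,
    )


def _decode_binary_array(element, ns: str) -> np.ndarray:
    """Decode one mzML <binaryDataArray>: 32/64-bit floats, optional zlib."""
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in element.findall(f"{ns}cvParam")
    }
    binary = element.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectrum(path: Path) -> RawSpectrum:
    """Minimal mzML reader: first profile spectrum, m/z + intensity arrays.

    Covers the plain interchange subset (64/32-bit floats, optional zlib);
    vendor-specific extensions are out of scope.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = "{%s}" % root.nsmap[None] if None in root.nsmap else ""
    spectrum_el = root.find(f".//{ns}spectrum")
    if spectrum_el is None:
        raise ValueError(f"{path}: no spectra found in mzML file")
    arrays = {}
    for bda in spectrum_el.findall(f".//{ns}binaryDataArray"):
        accessions = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
        data = _decode_binary_array(bda, ns)
        if "MS:1000514" in accessions:
            arrays["mz"] = data
        elif "MS:1000515" in accessions:
            arrays["intensity"] = data
    if set(arrays) != {"mz", "intensity"}:
        raise ValueError(f"{path}: spectrum lacks m/z or intensity arrays")
    order = np.argsort(arrays["mz"], kind="stable")
    return RawSpectrum(
        mz=arrays["mz"][order],
        intensity=arrays["intensity"][order],
        sample_id=str(spectrum_el.get("id", path.stem)),
    )


def read_spectrum(path: str | Path, format: str | None = None) -> RawSpectrum:
    """Read one spectrum from two-column text or mzML (profile mode).

    Parameters
    ----------
    path : file to read.
    format : 'txt' or 'mzml'; inferred from the suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "txt"
    format = format.lower()
    if format == "txt":
        return _parse_text_spectrum(path)
    if format == "mzml":
        return _parse_mzml_spectrum(path)
    raise ValueError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# Marker fixture (the published 15-peak panel)
# ---------------------------------------------------------------------------

TOXINS = ("copper_sulfate", "acridine", "bnf")


@dataclass
class MarkerFixture:
    """The published panel of 15 marker peaks A-O with per-toxin annotations.

    Each toxin cell holds a direction ('up', 'down' or 'none') and a
    significance mark ('*', '**' or 'none').
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"label", "mass"} | {f"direction_{t}" for t in TOXINS} | {
            f"mark_{t}" for t in TOXINS
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"fixture missing columns: {sorted(missing)}")
        if self.table["label"].duplicated().any():
            raise ValueError("duplicate peak labels in fixture")
        if not self.table["mass"].is_monotonic_increasing:
            raise ValueError("fixture masses must increase with label order")

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    @property
    def masses(self) -> np.ndarray:
        return self.table["mass"].to_numpy(dtype=float)

    def marked_labels(self, toxin: str) -> set[str]:
        """Labels whose significance mark is not 'none' for the given toxin."""
        if toxin not in TOXINS:
            raise KeyError(f"unknown toxin {toxin!r}; expected one of {TOXINS}")
        sel = self.table[f"mark_{toxin}"] != "none"
        return set(self.table.loc[sel, "label"])

    def direction(self, label: str, toxin: str) -> str:
        row = self.table[self.table["label"] == label]
        if row.empty:
            raise KeyError(f"unknown peak label {label!r}")
        return str(row[f"direction_{toxin}"].iloc[0])

    @property
    def toxins(self) -> tuple[str, ...]:
        return TOXINS


def _split_annotation(cell: str) -> tuple[str, str]:
    cell = (cell or "").strip()
    if not cell:
        return "none", "none"
    direction = "up" if cell.startswith("up") else "down"
    mark = "**" if cell.endswith("**") else "*"
    return direction, mark


def load_marker_fixture() -> MarkerFixture:
    """Load the packaged 15-peak marker panel with all 45 annotations."""
    with resources.files("toxprint.data").joinpath("table2_markers.csv").open() as fh:
        raw = pd.read_csv(fh, keep_default_na=False)
    out = {"label": raw["label"], "mass": raw["mass"].astype(float)}
    for toxin in TOXINS:
        parsed = [_split_annotation(c) for c in raw[toxin]]
        out[f"direction_{toxin}"] = [p[0] for p in parsed]
        out[f"mark_{toxin}"] = [p[1] for p in parsed]
    return MarkerFixture(pd.DataFrame(out))


# ---------------------------------------------------------------------------
# Peak list CSV round-trip
# ---------------------------------------------------------------------------

def write_peaklist_csv(peaklist, path: str | Path) -> Path:
    """Write a PeakList as CSV (sample_id, mass, abundance_mV, snr)."""
    path = Path(path)
    df = peaklist.to_frame()
    df.to_csv(path, index=False)
    return path


def read_peaklist_csv(path: str | Path):
    """Read a peak list written by :func:`write_peaklist_csv`."""
    from .peaks import Peak, PeakList

    df = pd.read_csv(path)
    peaks = [
        Peak(mass=row.mass, abundance=row.abundance_mV, snr=row.snr)
        for row in df.itertuples()
    ]
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else ""
    return PeakList(sample_id=sample_id, condition=None, peaks=peaks)


def write_design_csv(design, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "toxin": c.toxin,
            "concentration": c.concentration,
            "units": c.units,
            "is_control": int(c.is_control),
        }
        for c in design.conditions
    ]
    df = pd.DataFrame(rows)
    df["replicates"] = design.replicates
    df.to_csv(path, index=False)
    return path
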