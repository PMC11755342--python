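"""Spectrum containers, mzML/CSV IO, scan averaging, and window integration.

A :class:`SpectrumSeries` is the ordered list of scans of one LC-MS (or
direct-infusion) run.  Spectra are kept as raw (m/z, intensity) arrays —
profile or centroid — with no peak picking, mirroring a "no peak picking"
mzML conversion; all quantification downstream works directly on these
arrays.

The mzML reader is a compact streaming parser (lxml iterparse) covering the
subset of mzML 1.1 that quantification needs: MS1 spectra, 32/64-bit float
arrays, zlib or uncompressed encoding, scan start times in minutes or
seconds, centroid/profile flags.  Writing emits a minimal mzML document
(64-bit float arrays, base64, no compression) that round-trips through this
reader, plus a simple CSV stick-spectrum dialect (``scan_id, rt_min, mz,
intensity``) for hand-editable fixtures.
"""

from __future__ import annotations

import base64
import logging
import struct
import zlib
from dataclasses import dataclass, field
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Scan",
    "SpectrumSeries",
    "MzWindow",
    "SpectrumParseError",
    "read_spectra",
    "write_mzml",
    "write_csv",
    "average_scans",
    "integrate_window",
]


class SpectrumParseError(ValueError):
    """Raised for malformed spectrum files; carries the offending scan index."""


@dataclass
class Scan:
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    centroid: bool = False
    ms_level: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("m/z and intensity arrays must be 1-D, equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        d = np.diff(self.mz)
        if np.any(d <= 0):
            logger.warning("scan at %.3f min has unsorted m/z; sorting", self.rt_min)
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError("duplicate m/z values within one scan")


@dataclass
class SpectrumSeries:
    scans: list[Scan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError("a spectrum series needs at least one scan")
        rts = [s.rt_min for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    def __getitem__(self, i) -> Scan:
        return self.scans[i]

    @property
    def rt(self) -> np.ndarray:
        return np.array([s.rt_min for s in self.scans])

    def select(
        self,
        scans: tuple[int, int] | None = None,
        rt: tuple[float, float] | None = None,
    ) -> list[int]:
        """Scan indices by half-open index range or closed RT interval (min)."""
        if scans is not None and rt is not None:
            raise ValueError("give a scan range or an RT interval, not both")
        if rt is not None:
            lo, hi = rt
            idx = [i for i, s in enumerate(self.scans) if lo <= s.rt_min <= hi]
        elif scans is not None:
            start, stop = scans
            if start < 0 or stop > len(self.scans) or start >= stop:
                raise ValueError(
                    f"scan range {scans} outside series of {len(self.scans)} scans"
                )
            idx = list(range(start, stop))
        else:
            idx = list(range(len(self.scans)))
        if not idx:
            raise ValueError("selection matches no scans")
        return idx


@dataclass(frozen=True)
class MzWindow:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"empty m/z window [{self.lower}, {self.upper}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def overlaps(self, other: "MzWindow") -> bool:
        return self.lower < other.upper and other.lower < self.upper


# ---------------------------------------------------------------------------
# reading

def read_spectra(path, fmt: str | None = None) -> SpectrumSeries:
    """Read an mzML file or CSV stick-spectrum file into a SpectrumSeries."""
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.lower().endswith(".csv") else "mzml"
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _decode_binary_array(bda: etree._Element) -> np.ndarray:
    accessions = set()
    payload = b""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            accessions.add(child.get("accession", ""))
        elif name == "binary" and child.text:
            payload = base64.b64decode(child.text.strip())
    if "MS:1000574" in accessions:  # zlib compression
        payload = zlib.decompress(payload)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    arr = np.frombuffer(payload, dtype=dtype).astype(float)
    kind = (
        "mz"
        if "MS:1000514" in accessions
        else "intensity"
        if "MS:1000515" in accessions
        else None
    )
    return kind, np.array(arr)  # copy: iterparse reuses buffers


def _parse_spectrum(elem: etree._Element, index: int) -> Scan | None:
    ms_level = 1
    centroid = False
    rt_min = 0.0
    arrays: dict[str, np.ndarray] = {}
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(child.get("value", "1"))
            elif acc == "MS:1000127":
                centroid = True
            elif acc == "MS:1000016":
                rt = float(child.get("value", "0"))
                if child.get("unitName", "minute") == "second":
                    rt /= 60.0
                rt_min = rt
        elif name == "binaryDataArray":
            kind, arr = _decode_binary_array(child)
            if kind:
                arrays[kind] = arr
    if ms_level != 1:
        return None
    if "mz" not in arrays or "intensity" not in arrays:
        raise SpectrumParseError(
            f"spectrum at index {index} lacks m/z or intensity array"
        )
    return Scan(
        rt_min=rt_min,
        mz=arrays["mz"],
        intensity=arrays["intensity"],
        centroid=centroid,
        ms_level=ms_level,
    )


def _read_mzml(path: str) -> SpectrumSeries:
    scans = []
    index = -1
    try:
        for _, elem in etree.iterparse(path, tag="{*}spectrum"):
            index += 1
            scan = _parse_spectrum(elem, index)
            if scan is not None:
                scans.append(scan)
            elem.clear(keep_tail=True)
    except SpectrumParseError:
        raise
    except Exception as exc:  # XML syntax / base64 / struct failures
        raise SpectrumParseError(
            f"cannot parse mzML file {path} (near scan index {index + 1}): {exc}"
        ) from exc
    if not scans:
        raise SpectrumParseError(f"no MS1 scans in {path}")
    return SpectrumSeries(scans)


def _read_csv(path: str) -> SpectrumSeries:
    df = pd.read_csv(path)
    required = {"scan_id", "rt_min", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise SpectrumParseError(
            f"stick-spectrum CSV needs columns {sorted(required)}"
        )
    scans = []
    for sid, grp in df.groupby("scan_id", sort=True):
        rts = grp["rt_min"].unique()
        if len(rts) != 1:
            raise SpectrumParseError(f"scan {sid} has conflicting retention times")
        scans.append(
            Scan(
                rt_min=float(rts[0]),
                mz=grp["mz"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                centroid=True,
            )
        )
    scans.sort(key=lambda s: s.rt_min)
    return SpectrumSeries(scans)


# ---------------------------------------------------------------------------
# writing

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{arr.size}d", *np.asarray(arr, dtype=float))
    ).decode("ascii")


_ARRAY_CV = {
    "mz": '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" '
    'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
    "intensity": '<cvParam cvRef="MS" accession="MS:1000515" '
    'name="intensity array" unitCvRef="MS" unitAccession="MS:1000131" '
    'unitName="number of detector counts"/>',
}


def write_mzml(series: SpectrumSeries, path) -> None:
    """Write a minimal mzML 1.1.0 document (uncompressed 64-bit floats)."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass '
        'Spectrometry Ontology" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="http://ontologies.berkeleybop.org/uo.obo"/>',
        "</cvList>",
        '<run id="run1">',
        f'<spectrumList count="{len(series)}">',
    ]
    for i, scan in enumerate(series):
        mode = (
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
            if scan.centroid
            else '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum"/>'
        )
        parts += [
            f'<spectrum index="{i}" id="{escape(f"scan={i + 1}")}" '
            f'defaultArrayLength="{scan.mz.size}">',
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{scan.ms_level}"/>',
            mode,
            '<scanList count="1">',
            "<scan>",
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt_min!r}" unitCvRef="UO" unitAccession="UO:0000031" '
            'unitName="minute"/>',
            "</scan>",
            "</scanList>",
            '<binaryDataArrayList count="2">',
        ]
        for kind, arr in (("mz", scan.mz), ("intensity", scan.intensity)):
            payload = _b64(arr)
            parts += [
                f'<binaryDataArray encodedLength="{len(payload)}">',
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>',
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>',
                _ARRAY_CV[kind],
                f"<binary>{payload}</binary>",
                "</binaryDataArray>",
            ]
        parts += ["</binaryDataArrayList>", "</spectrum>"]
    parts += ["</spectrumList>", "</run>", "</mzML>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def write_csv(series: SpectrumSeries, path) -> None:
    rows = []
    for i, scan in enumerate(series):
        rows.append(
            pd.DataFrame(
                {
                    "scan_id": i,
                    "rt_min": scan.rt_min,
                    "mz": scan.mz,
                    "intensity": scan.intensity,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# averaging and integration

def average_scans(
    series: SpectrumSeries,
    scans: tuple[int, int] | None = None,
    rt: tuple[float, float] | None = None,
    grid: np.ndarray | None = None,
) -> Scan:
    """Average selected scans onto a common m/z grid.

    Each scan is linearly interpolated onto ``grid`` (default: the first
    selected scan's native grid, the conventional choice when the instrument
    grid is stable) and the interpolants are averaged arithmetically.
    """
    idx = series.select(scans, rt)
    chosen = [series[i] for i in idx]
    if grid is None:
        grid = chosen[0].mz
    grid = np.asarray(grid, dtype=float)
    acc = np.zeros_like(grid)
    for scan in chosen:
        acc += np.interp(grid, scan.mz, scan.intensity, left=0.0, right=0.0)
    return Scan(
        rt_min=float(np.mean([s.rt_min for s in chosen])),
        mz=grid,
        intensity=acc / len(chosen),
        centroid=chosen[0].centroid,
    )


def _integrate_scan(scan: Scan, w: MzWindow) -> float:
    mz, inten = scan.mz, scan.intensity
    if scan.centroid:
        sel = (mz >= w.lower) & (mz <= w.upper)
        return float(inten[sel].sum())
    # profile: trapezoid on the native grid, clipped to the window with
    # interpolated boundary ordinates
    lo = max(w.lower, mz[0])
    hi = min(w.upper, mz[-1])
    if lo >= hi:
        return 0.0
    inner = (mz > lo) & (mz < hi)
    xs = np.concatenate(([lo], mz[inner], [hi]))
    ys = np.concatenate(
        (
            [np.interp(lo, mz, inten)],
            inten[inner],
            [np.interp(hi, mz, inten)],
        )
    )
    return float(np.trapezoid(ys, xs))


def integrate_window(
    obj: Scan | SpectrumSeries,
    w: MzWindow,
    scans: tuple[int, int] | None = None,
    rt: tuple[float, float] | None = None,
) -> float:
    """Extracted ion current inside an m/z window.

    Profile scans are integrated by the trapezoidal rule on the native grid;
    centroid scans by stick summation.  For a series, per-scan currents are
    summed over the selected scans (an EICC integral).  Always >= 0.
    """
    if isinstance(obj, Scan):
        return _integrate_scan(obj, w)
    idx = obj.select(scans, rt)
    return float(sum(_integrate_scan(obj[i], w) for i in idx))
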