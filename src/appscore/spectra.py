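"""Spectrum I/O and the four method-specific spectral filters.

Each scoring function expects its own preprocessed view of the raw MS/MS
spectrum.  A filter maps peak intensities onto the mass grid and applies a
method-specific transform; a spectrum that retains too little signal is
declared *null* and excluded from searching.  The filter constants below are
documented, simplified defaults that capture the character of each method's
published preprocessing; they are config-exposed and are not claimed to be
vendor replicas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import DEFAULT_RESOLUTION, PROTON, mass_to_index

logger = logging.getLogger(__name__)

METHODS = ("raid", "hyperscore", "xcorr", "kscore")

__all__ = [
    "METHODS",
    "RawSpectrum",
    "ProcessedSpectrum",
    "FilterParams",
    "read_spectra",
    "preprocess",
    "spectral_correlation",
]


@dataclass(frozen=True)
class RawSpectrum:
    """A centroided MS2 scan: peak list plus precursor information."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            object.__setattr__(
                self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
            )
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")

    @property
    def parent_mass(self) -> float:
        """Neutral precursor mass derived from m/z and charge."""
        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON


@dataclass(frozen=True)
class ProcessedSpectrum:
    """Filter output: grid-binned, transformed intensities for one method."""

    method: str
    parent_mass: float
    binned: dict[int, float]
    resolution: float = DEFAULT_RESOLUTION
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.is_null and self.binned:
            raise ValueError("null spectrum must have empty bins")
        if any(not math.isfinite(v) for v in self.binned.values()):
            raise ValueError("non-finite binned intensity")

    def dense(self, size: int) -> np.ndarray:
        out = np.zeros(size, dtype=float)
        for idx, val in self.binned.items():
            if 0 <= idx < size:
                out[idx] = val
        return out


@dataclass(frozen=True)
class FilterParams:
    """Config-exposed constants of the four filtering front-ends."""

    raid_norm: float = 10000.0
    hyperscore_top_peaks: int = 50
    hyperscore_norm: float = 100.0
    xcorr_windows: int = 10
    xcorr_norm: float = 50.0
    xcorr_offset_band: int = 75
    min_nonzero_bins: int = 5


def read_spectra(path, format: str | None = None) -> list[RawSpectrum]:
    """Read MS2 spectra from an MGF or mzML file.

    Records lacking a charge assignment default to 2+ (logged).  Malformed
    records are skipped with a warning; an empty file gives an empty list.
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        format = "mzml" if lower.endswith(("mzml", "mzml.gz")) else "mgf"
    if format not in ("mgf", "mzml"):
        raise ValueError(f"unknown spectrum format {format!r}")
    spectra: list[RawSpectrum] = []
    if format == "mgf":
        from pyteomics import mgf

        with mgf.read(path, use_index=False) as reader:
            for i, rec in enumerate(reader):
                spec = _from_mgf_record(rec, i)
                if spec is not None:
                    spectra.append(spec)
    else:
        for i, rec in enumerate(_iter_mzml_ms2(path)):
            spec = _from_mzml_record(rec, i)
            if spec is not None:
                spectra.append(spec)
    return spectra


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (base64; optional zlib)."""
    import base64
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    dtype = np.float64
    compressed = False
    kind = None
    for cv in bda.findall(f"{ns}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = np.float32
        elif acc == "MS:1000523":
            dtype = np.float64
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
    binary = bda.find(f"{ns}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype)


def _iter_mzml_ms2(path):
    """Minimal mzML 1.1 MS2 reader (lxml): yields dicts shaped like
    pyteomics spectrum records."""
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    for _event, elem in etree.iterparse(path, tag=f"{ns}spectrum"):
        ms_level = None
        for cv in elem.findall(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000511":
                ms_level = int(cv.get("value"))
        if ms_level != 2:
            elem.clear()
            continue
        rec = {"id": elem.get("id")}
        ion = elem.find(
            f"{ns}precursorList/{ns}precursor/{ns}selectedIonList/"
            f"{ns}selectedIon"
        )
        if ion is not None:
            for cv in ion.findall(f"{ns}cvParam"):
                acc = cv.get("accession")
                if acc == "MS:1000744":
                    rec["selected ion m/z"] = float(cv.get("value"))
                elif acc == "MS:1000041":
                    rec["charge state"] = int(cv.get("value"))
        for bda in elem.findall(
            f"{ns}binaryDataArrayList/{ns}binaryDataArray"
        ):
            kind, arr = _decode_binary_array(bda)
            if kind == "mz":
                rec["m/z array"] = arr
            elif kind == "intensity":
                rec["intensity array"] = arr
        elem.clear()
        yield rec


def _from_mgf_record(rec, index: int) -> RawSpectrum | None:
    params = rec.get("params", {})
    try:
        pepmass = params["pepmass"][0]
        title = str(params.get("title", f"scan_{index}"))
        charge_field = params.get("charge")
        if charge_field:
            charge = int(charge_field[0])
        else:
            charge = 2
            logger.warning("spectrum %s lacks CHARGE; defaulting to 2+", title)
        peaks = tuple(
            zip(
                (float(x) for x in rec["m/z array"]),
                (float(y) for y in rec["intensity array"]),
            )
        )
        return RawSpectrum(title, float(pepmass), charge, peaks)
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        logger.warning("skipping malformed MGF record %d: %s", index, exc)
        return None


def _from_mzml_record(rec, index: int) -> RawSpectrum | None:
    try:
        sid = str(rec.get("id", f"scan_{index}"))
        mz = float(rec["selected ion m/z"])
        charge = rec.get("charge state")
        if charge is None:
            charge = 2
            logger.warning("spectrum %s lacks charge; defaulting to 2+", sid)
        peaks = tuple(
            zip(
                (float(x) for x in rec["m/z array"]),
                (float(y) for y in rec["intensity array"]),
            )
        )
        return RawSpectrum(sid, mz, int(charge), peaks)
    except (KeyError, IndexError, TypeError, ValueError) as exc:
        logger.warning("skipping malformed mzML record %d: %s", index, exc)
        return None


def _bin_peaks(
    peaks, resolution: float, transform=None
) -> dict[int, float]:
    """Bin (m/z, intensity) pairs to the grid; collisions sum."""
    binned: dict[int, float] = {}
    for mz, inten in peaks:
        if inten <= 0:
            continue
        val = transform(inten) if transform else inten
        idx = mass_to_index(mz, resolution)
        binned[idx] = binned.get(idx, 0.0) + val
    return binned


def preprocess(
    raw: RawSpectrum,
    method: str,
    params: FilterParams | None = None,
    resolution: float = DEFAULT_RESOLUTION,
) -> ProcessedSpectrum:
    """Apply a method's spectral filter, producing a ProcessedSpectrum.

    The transforms (defaults in :class:`FilterParams`):

    raid
        drop peaks at or below the median raw intensity, rescale the
        maximum to ``raid_norm``, bin to the grid.
    hyperscore
        keep the ``hyperscore_top_peaks`` most intense peaks, rescale the
        maximum to ``hyperscore_norm``, bin.
    xcorr
        bin, split the m/z range into ``xcorr_windows`` equal windows and
        rescale each window's maximum to ``xcorr_norm``, then subtract from
        every bin the mean over the ±``xcorr_offset_band`` offset band
        (excluding offset 0) — the additive reformulation of the
        cross-correlation background.
    kscore
        unit-normalize intensities (Euclidean), take square roots, bin.

    A spectrum retaining fewer than ``min_nonzero_bins`` nonzero bins is
    returned as null.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method tag {method!r}")
    params = params or FilterParams()
    peaks = [(mz, i) for mz, i in raw.peaks if i > 0]
    parent = raw.parent_mass

    def null() -> ProcessedSpectrum:
        return ProcessedSpectrum(method, parent, {}, resolution, is_null=True)

    if not peaks:
        return null()

    if method == "raid":
        intensities = np.array([i for _, i in peaks])
        floor = float(np.median(intensities))
        kept = [(mz, i) for mz, i in peaks if i > floor]
        if not kept:
            return null()
        peak_max = max(i for _, i in kept)
        scale = params.raid_norm / peak_max
        binned = _bin_peaks(((mz, i * scale) for mz, i in kept), resolution)
    elif method == "hyperscore":
        kept = sorted(peaks, key=lambda p: p[1], reverse=True)
        kept = kept[: params.hyperscore_top_peaks]
        peak_max = kept[0][1]
        scale = params.hyperscore_norm / peak_max
        binned = _bin_peaks(((mz, i * scale) for mz, i in kept), resolution)
    elif method == "xcorr":
        binned = _bin_peaks(peaks, resolution)
        binned = _xcorr_transform(binned, params)
    else:  # kscore
        norm = math.sqrt(sum(i * i for _, i in peaks))
        binned = _bin_peaks(
            ((mz, math.sqrt(i / norm)) for mz, i in peaks), resolution
        )

    binned = {k: v for k, v in binned.items() if v != 0.0}
    if len(binned) < params.min_nonzero_bins:
        return null()
    return ProcessedSpectrum(method, parent, binned, resolution)


def _xcorr_transform(
    binned: dict[int, float], params: FilterParams
) -> dict[int, float]:
    """Window normalization followed by offset-band background subtraction."""
    if not binned:
        return {}
    lo, hi = min(binned), max(binned)
    dense = np.zeros(hi + 1, dtype=float)
    for idx, val in binned.items():
        dense[idx] = val
    span = hi - lo + 1
    width = max(1, int(math.ceil(span / params.xcorr_windows)))
    for w in range(params.xcorr_windows):
        a = lo + w * width
        b = min(hi + 1, a + width)
        if a >= b:
            break
        wmax = dense[a:b].max()
        if wmax > 0:
            dense[a:b] *= params.xcorr_norm / wmax
    # Background fold-in: y'[i] = y[i] − mean(y[i+j], j in ±band, j != 0).
    band = params.xcorr_offset_band
    padded = np.concatenate([np.zeros(band), dense, np.zeros(band)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    n = dense.size
    # window sum over [i−band, i+band] in original coordinates
    win_sum = csum[2 * band + 1 :] - csum[: n]
    background = (win_sum - dense) / (2 * band)
    out = dense - background
    # Bins inside the offset band of a peak carry (negative) background
    # values even when empty in the raw spectrum; they are part of the
    # additive cross-correlation and are kept.
    return {i: float(out[i]) for i in range(n) if out[i] != 0.0}


def spectral_correlation(a: ProcessedSpectrum, b: ProcessedSpectrum) -> float:
    """Inner product of the two unit-normalized binned spectral vectors."""
    if a.is_null or b.is_null:
        raise ValueError("cannot correlate a null spectrum")
    if a.resolution != b.resolution:
        raise ValueError("grid resolutions differ")
    na = math.sqrt(sum(v * v for v in a.binned.values()))
    nb = math.sqrt(sum(v * v for v in b.binned.values()))
    if na == 0 or nb == 0:
        raise ValueError("zero-norm spectral vector")
    dot = sum(v * b.binned.get(k, 0.0) for k, v in a.binned.items())
    return dot / (na * nb)
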