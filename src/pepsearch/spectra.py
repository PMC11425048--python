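"""Reading DDA fragment spectra, top-K peak selection, and m/z binning.

An MS2 scan is held as a :class:`RawSpectrum`. Before indexing, the K most
intense fragment peaks are kept (:func:`select_top_k`) and their m/z values
are discretized to integer bins (:func:`bin_mz`) under a
:class:`BinningScheme`. :func:`optimal_bin_width` calibrates the bin width
against the instrument's m/z error by scanning a width grid and measuring
the binning error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import PROTON

logger = logging.getLogger(__name__)

__all__ = [
    "RawSpectrum",
    "BinningScheme",
    "PeakSelection",
    "read_spectra",
    "select_top_k",
    "bin_mz",
    "optimal_bin_width",
]


@dataclass
class RawSpectrum:
    """One MS2 scan: precursor description plus a centroided peak list.

    ``peaks`` is an (n, 2) float array of (m/z, intensity), sorted
    ascending by m/z. ``precursor_neutral_mass`` is the uncharged mass
    ``charge * (precursor_mz - proton)``.
    """

    spectrum_id: int
    precursor_mz: float
    precursor_charge: int
    retention_time: float
    peaks: np.ndarray
    precursor_neutral_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=np.float64).reshape(-1, 2)
        if self.peaks.size:
            order = np.argsort(self.peaks[:, 0], kind="stable")
            self.peaks = self.peaks[order]
            if np.any(self.peaks[:, 0] <= 0):
                raise ValueError("fragment m/z values must be positive")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be a positive integer")
        if not self.precursor_neutral_mass:
            self.precursor_neutral_mass = self.precursor_charge * (
                self.precursor_mz - PROTON
            )

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.shape[0])


@dataclass(frozen=True)
class BinningScheme:
    """Half-open uniform binning of m/z: bin b covers [offset + b*w, offset + (b+1)*w)."""

    bin_width: float = 0.02
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def bin_center(self, b):
        """Representative m/z of bin ``b`` (midpoint of its interval)."""
        return self.offset + (np.asarray(b) + 0.5) * self.bin_width


@dataclass
class PeakSelection:
    """The top-K peaks of one spectrum, sorted ascending by m/z."""

    spectrum_id: int
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def n_peaks(self) -> int:
        return int(self.mz.shape[0])

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


def bin_mz(mz, scheme: BinningScheme):
    """Discretize m/z to integer bins: floor((mz - offset) / width).

    Accepts a scalar or array. Raises for m/z at or below the scheme offset
    (non-physical query).
    """
    arr = np.asarray(mz, dtype=np.float64)
    if np.any(arr <= scheme.offset):
        raise ValueError("m/z must exceed the binning offset")
    bins = np.floor((arr - scheme.offset) / scheme.bin_width).astype(np.int64)
    return int(bins) if np.isscalar(mz) else bins


def select_top_k(spectrum: RawSpectrum, k: int = 150) -> PeakSelection:
    """Keep the ``k`` most intense fragment peaks of a spectrum.

    Ties on intensity are broken toward the lower m/z. Output is re-sorted
    ascending by m/z. Spectra with fewer than ``k`` peaks are kept whole.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    peaks = spectrum.peaks
    if peaks.shape[0] > k:
        # sort by (-intensity, mz): stable selection, low-m/z wins ties
        order = np.lexsort((peaks[:, 0], -peaks[:, 1]))[:k]
        peaks = peaks[np.sort(order)]
    return PeakSelection(
        spectrum_id=spectrum.spectrum_id,
        mz=peaks[:, 0].copy(),
        intensity=peaks[:, 1].copy(),
    )


# ---------------------------------------------------------------------------
# File readers


def read_spectra(path, format: str | None = None) -> list[RawSpectrum]:
    """Read MS2 spectra from an MGF or mzML file.

    Spectrum ids are assigned in file order starting at 0 (mzML MS1 scans
    are skipped and do not consume ids). Scans without precursor m/z are
    skipped with a warning; a missing charge is assumed 2+ and logged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"spectrum file not found: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".mgf": "mgf", ".mzml": "mzml"}.get(suffix, "")
    format = format.lower()
    if format == "mgf":
        return _read_mgf(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unsupported spectrum format: {format!r}")


def _read_mgf(path: Path) -> list[RawSpectrum]:
    from pyteomics import mgf

    out: list[RawSpectrum] = []
    sid = 0
    with mgf.read(str(path), use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                logger.warning("MGF block without PEPMASS skipped")
                continue
            pre_mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = 2
                logger.warning("spectrum %d: missing CHARGE, assuming 2+", sid)
            rt = float(params.get("rtinseconds", 0.0))
            mz = np.asarray(entry["m/z array"], dtype=np.float64)
            inten = np.asarray(entry["intensity array"], dtype=np.float64)
            if mz.size == 0:
                logger.warning("spectrum %d: empty peak list", sid)
            out.append(
                RawSpectrum(
                    spectrum_id=sid,
                    precursor_mz=pre_mz,
                    precursor_charge=charge,
                    retention_time=rt,
                    peaks=np.column_stack([mz, inten]) if mz.size else np.empty((0, 2)),
                )
            )
            sid += 1
    return out


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _mzml_cvparams(element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.findall(f"{_MZML_NS}cvParam")
    }


def _mzml_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values) where kind is
    'mz', 'intensity', or None for other arrays."""
    import base64
    import zlib

    params = _mzml_cvparams(bda)
    kind = None
    if "MS:1000514" in params:
        kind = "mz"
    elif "MS:1000515" in params:
        kind = "intensity"
    dtype = "<f8" if "MS:1000523" in params else "<f4"
    node = bda.find(f"{_MZML_NS}binary")
    text = (node.text or "") if node is not None else ""
    raw = base64.b64decode(text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _read_mzml(path: Path) -> list[RawSpectrum]:
    """Minimal mzML (PSI 1.1) reader for centroided MS2 scans.

    Handles plain and indexed mzML, 32/64-bit float peak arrays, and zlib
    compression; MS1 scans are skipped. Scan times with a minute unit are
    converted to seconds.
    """
    from lxml import etree

    out: list[RawSpectrum] = []
    sid = 0
    for _, spectrum in etree.iterparse(str(path), tag=f"{_MZML_NS}spectrum"):
        params = _mzml_cvparams(spectrum)
        if params.get("MS:1000511") != "2":
            spectrum.clear()
            continue
        ion = spectrum.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        ion_params = _mzml_cvparams(ion) if ion is not None else {}
        if "MS:1000744" not in ion_params:
            logger.warning("MS2 scan without precursor information skipped")
            spectrum.clear()
            continue
        pre_mz = float(ion_params["MS:1000744"])
        if "MS:1000041" in ion_params:
            charge = int(ion_params["MS:1000041"])
        else:
            charge = 2
            logger.warning("spectrum %d: missing charge state, assuming 2+", sid)
        rt = 0.0
        scan = spectrum.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
        if scan is not None:
            for cv in scan.findall(f"{_MZML_NS}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if cv.get("unitName") == "minute":
                        rt *= 60.0
        mz = inten = np.empty(0)
        for bda in spectrum.findall(
            f"{_MZML_NS}binaryDataArrayList/{_MZML_NS}binaryDataArray"
        ):
            kind, values = _mzml_binary_array(bda)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                inten = values
        if mz.size != inten.size:
            raise IOError(f"malformed peak arrays in MS2 scan {sid} of {path}")
        out.append(
            RawSpectrum(
                spectrum_id=sid,
                precursor_mz=pre_mz,
                precursor_charge=charge,
                retention_time=rt,
                peaks=np.column_stack([mz, inten]) if mz.size else np.empty((0, 2)),
            )
        )
        sid += 1
        spectrum.clear()
    return out


# ---------------------------------------------------------------------------
# Bin-width calibration

#: Default width grid, Da: log-spaced so that step sizes stay large relative
#: to the sampling noise of the error curve (keeps the curve's single minimum
#: resolvable).
DEFAULT_WIDTH_GRID = tuple(np.geomspace(0.005, 0.1, 20))


def _flatten_mz(spectra) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        return spectra.astype(np.float64).ravel()
    parts = [np.asarray(s.mz, dtype=np.float64) for s in spectra]
    if not parts or sum(p.size for p in parts) == 0:
        raise ValueError("need at least one spectrum with at least one peak")
    return np.concatenate(parts)


def optimal_bin_width(
    spectra,
    widths: Sequence[float] | None = None,
    reference_mz: np.ndarray | None = None,
    offset: float = 0.0,
) -> tuple[float, list[tuple[float, float]]]:
    """Scan a grid of bin widths and return the error-minimizing width.

    ``spectra`` is either a flat array of observed peak m/z values or an
    iterable of :class:`PeakSelection`.

    With ``reference_mz`` (the true/theoretical m/z of each observed peak,
    same flat order), the error of width ``w`` is the matched-reconstruction
    error: a peak whose observed and reference m/z fall in the *same* bin
    contributes ``(reference - bin_center)**2`` (the residual after snapping
    to the bin grid); a peak that lands in a *different* bin than its
    reference contributes the raw measurement error ``(reference - obs)**2``
    (binning at that width failed to link the observation to its ion, so
    nothing is gained over the raw measurement). Too-narrow bins split
    observation from reference; too-wide bins quantize coarsely; the curve
    falls then rises with a single minimum near the instrument's m/z error.

    Without a reference, the error is the plain quantization error
    ``sum((obs - bin_center)**2)``, which grows ~w^2/12 per peak and is
    minimized by the smallest width on the grid.

    Returns ``(best_width, error_curve)`` where ``error_curve`` is a list of
    ``(width, total_error)``; ties on error go to the smaller width.
    """
    obs = _flatten_mz(spectra)
    if widths is None:
        widths = DEFAULT_WIDTH_GRID
    widths = [float(w) for w in widths]
    if not widths:
        raise ValueError("width grid must be non-empty")
    if any(b <= a for a, b in zip(widths, widths[1:])):
        raise ValueError("width grid must be strictly increasing")
    if reference_mz is not None:
        ref = np.asarray(reference_mz, dtype=np.float64).ravel()
        if ref.shape != obs.shape:
            raise ValueError("reference_mz must align with the observed peaks")
    curve: list[tuple[float, float]] = []
    for w in widths:
        scheme = BinningScheme(bin_width=w, offset=offset)
        b_obs = bin_mz(obs, scheme)
        centers = scheme.bin_center(b_obs)
        if reference_mz is None:
            err = float(np.sum((obs - centers) ** 2))
        else:
            b_ref = bin_mz(ref, scheme)
            matched = b_obs == b_ref
            per_peak = np.where(matched, (ref - centers) ** 2, (ref - obs) ** 2)
            err = float(per_peak.sum())
        curve.append((w, err))
    # argmin with ties to the smaller width: first minimal value wins
    best = min(curve, key=lambda we: (we[1], we[0]))[0]
    return best, curve
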