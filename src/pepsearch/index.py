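"""Inverted index over experimental spectra.

The index maps an integer fragment m/z bin to its postings: the ids and
(selected) intensities of every spectrum holding a peak in that bin. The
memory footprint is a function of the experimental side only — the number
of spectra and their selected peaks — and is independent of how many
candidate peptides are later searched against it, which is what makes the
full-database strategy feasible on desktop memory.

Internally the postings are three parallel flat arrays (bin-sorted, then
spectrum-sorted within a bin) plus a sorted unique-bin table with start
offsets, so a bin query is one binary search and one slice.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .spectra import BinningScheme, PeakSelection, bin_mz

__all__ = ["SpectrumMeta", "SpectrumIndex", "build_index", "query_bin", "index_stats"]


class SpectrumMeta(NamedTuple):
    """Per-spectrum metadata carried alongside the postings."""

    precursor_neutral_mass: float
    retention_time: float
    precursor_charge: int
    total_selected_intensity: float


@dataclass
class SpectrumIndex:
    """Bin -> postings mapping over the selected peaks of a run."""

    scheme: BinningScheme
    n_spectra: int
    bins: np.ndarray          # sorted unique int64 bins
    starts: np.ndarray        # int64, len(bins)+1, postings offsets
    spectrum_ids: np.ndarray  # int32 postings
    intensities: np.ndarray   # float64 postings
    meta: dict[int, SpectrumMeta] = field(default_factory=dict)

    # dense meta arrays for vectorized scoring
    precursor_mass: np.ndarray = field(default=None, repr=False)
    retention_time: np.ndarray = field(default=None, repr=False)
    precursor_charge: np.ndarray = field(default=None, repr=False)
    total_intensity: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.precursor_mass is None:
            self.precursor_mass = np.zeros(self.n_spectra)
            self.retention_time = np.zeros(self.n_spectra)
            self.precursor_charge = np.ones(self.n_spectra, dtype=np.int32)
            self.total_intensity = np.zeros(self.n_spectra)
            for sid, m in self.meta.items():
                self.precursor_mass[sid] = m.precursor_neutral_mass
                self.retention_time[sid] = m.retention_time
                self.precursor_charge[sid] = m.precursor_charge
                self.total_intensity[sid] = m.total_selected_intensity

    @property
    def n_postings(self) -> int:
        return int(self.spectrum_ids.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.bins.shape[0])

    def postings_range(self, bins: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized lookup: for each query bin return (found, start, end)."""
        if self.n_bins == 0:
            z = np.zeros(len(bins), dtype=np.int64)
            return np.zeros(len(bins), dtype=bool), z, z
        pos = np.searchsorted(self.bins, bins)
        pos_c = np.minimum(pos, self.n_bins - 1)
        found = self.bins[pos_c] == bins
        safe = np.where(found, pos, 0)
        starts = np.where(found, self.starts[safe], 0)
        ends = np.where(found, self.starts[safe + 1], 0)
        return found, starts, ends

    def gather(self, bins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated postings (ids, intensities) for all query bins.

        A bin queried twice contributes its postings twice; absent bins
        contribute nothing.
        """
        found, s, e = self.postings_range(np.asarray(bins, dtype=np.int64))
        s, e = s[found], e[found]
        lens = e - s
        total = int(lens.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int32), np.empty(0))
        # multi-range gather without a python loop
        cum = np.concatenate(([0], np.cumsum(lens)[:-1]))
        idx = np.repeat(s - cum, lens) + np.arange(total)
        return self.spectrum_ids[idx], self.intensities[idx]


def build_index(
    selections: Iterable[PeakSelection],
    scheme: BinningScheme,
    meta: dict[int, SpectrumMeta] | None = None,
) -> SpectrumIndex:
    """Build the inverted index from selected peak lists.

    Two selected peaks of one spectrum falling in one bin are merged into a
    single posting with their intensities summed, so total matched intensity
    is preserved.
    """
    all_bins: list[np.ndarray] = []
    all_sids: list[np.ndarray] = []
    all_int: list[np.ndarray] = []
    seen: set[int] = set()
    max_sid = -1
    auto_meta = meta is None
    meta = dict(meta) if meta else {}
    for sel in selections:
        if sel.spectrum_id in seen:
            raise ValueError(f"duplicate spectrum id {sel.spectrum_id}")
        seen.add(sel.spectrum_id)
        max_sid = max(max_sid, sel.spectrum_id)
        if auto_meta and sel.spectrum_id not in meta:
            meta[sel.spectrum_id] = SpectrumMeta(0.0, 0.0, 1, sel.total_intensity)
        if sel.n_peaks == 0:
            continue
        b = bin_mz(sel.mz, scheme)
        # merge within-spectrum bin collisions by summing intensity
        ub, inv = np.unique(b, return_inverse=True)
        inten = np.bincount(inv, weights=sel.intensity)
        all_bins.append(ub)
        all_sids.append(np.full(ub.shape[0], sel.spectrum_id, dtype=np.int32))
        all_int.append(inten)
    n_spectra = max_sid + 1
    if not all_bins:
        return SpectrumIndex(
            scheme=scheme,
            n_spectra=n_spectra,
            bins=np.empty(0, dtype=np.int64),
            starts=np.zeros(1, dtype=np.int64),
            spectrum_ids=np.empty(0, dtype=np.int32),
            intensities=np.empty(0),
            meta=meta,
        )
    bins = np.concatenate(all_bins)
    sids = np.concatenate(all_sids)
    intens = np.concatenate(all_int)
    order = np.lexsort((sids, bins))
    bins, sids, intens = bins[order], sids[order], intens[order]
    ubins, starts_idx = np.unique(bins, return_index=True)
    starts = np.concatenate([starts_idx, [bins.shape[0]]]).astype(np.int64)
    return SpectrumIndex(
        scheme=scheme,
        n_spectra=n_spectra,
        bins=ubins,
        starts=starts,
        spectrum_ids=sids,
        intensities=intens,
        meta=meta,
    )


def query_bin(
    index: SpectrumIndex, b: int, neighbor_tolerance: bool = False
) -> list[tuple[int, float]]:
    """Postings for bin ``b`` as (spectrum_id, intensity) pairs.

    With ``neighbor_tolerance`` the query also covers bins b-1 and b+1
    (for peaks straddling a bin boundary); off by default because a
    calibrated bin width already absorbs instrument error.
    """
    bins = np.array([b - 1, b, b + 1] if neighbor_tolerance else [b], dtype=np.int64)
    ids, intens = index.gather(bins)
    order = np.argsort(ids, kind="stable")
    return [(int(i), float(v)) for i, v in zip(ids[order], intens[order])]


# bytes per posting: int32 id + float64 intensity; per bin: int64 bin + int64 offset
_POSTING_BYTES = 12
_BIN_BYTES = 16
_HEADER_BYTES = 64


def index_stats(index: SpectrumIndex) -> dict[str, int]:
    """Size summary. ``estimated_bytes`` depends only on the experimental
    side (bins and postings), never on the candidate-peptide database."""
    return {
        "n_spectra": index.n_spectra,
        "n_bins": index.n_bins,
        "n_postings": index.n_postings,
        "estimated_bytes": _HEADER_BYTES
        + _BIN_BYTES * index.n_bins
        + _POSTING_BYTES * index.n_postings,
    }


# ---------------------------------------------------------------------------
# Flat binary serialization (byte-stable across runs)

_MAGIC = b"PSIDX001"


def save_index(index: SpectrumIndex, path) -> None:
    """Write the index in a flat little-endian binary layout.

    Layout: magic(8) | bin_width f64 | offset f64 | n_spectra i64 |
    n_bins i64 | n_postings i64 | bins i64[n_bins] | starts i64[n_bins+1] |
    spectrum_ids i32[n_postings] | intensities f64[n_postings] |
    meta rows (f64 mass, f64 rt, i32 charge, f64 total_int) per spectrum.
    """
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(
            struct.pack(
                "<ddqqq",
                index.scheme.bin_width,
                index.scheme.offset,
                index.n_spectra,
                index.n_bins,
                index.n_postings,
            )
        )
        fh.write(index.bins.astype("<i8").tobytes())
        fh.write(index.starts.astype("<i8").tobytes())
        fh.write(index.spectrum_ids.astype("<i4").tobytes())
        fh.write(index.intensities.astype("<f8").tobytes())
        fh.write(index.precursor_mass.astype("<f8").tobytes())
        fh.write(index.retention_time.astype("<f8").tobytes())
        fh.write(index.precursor_charge.astype("<i4").tobytes())
        fh.write(index.total_intensity.astype("<f8").tobytes())


def load_index(path) -> SpectrumIndex:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _MAGIC:
            raise IOError("not a spectrum index file")
        w, off, n_spec, n_bins, n_post = struct.unpack("<ddqqq", fh.read(40))
        bins = np.frombuffer(fh.read(8 * n_bins), dtype="<i8").copy()
        starts = np.frombuffer(fh.read(8 * (n_bins + 1)), dtype="<i8").copy()
        sids = np.frombuffer(fh.read(4 * n_post), dtype="<i4").copy()
        intens = np.frombuffer(fh.read(8 * n_post), dtype="<f8").copy()
        pm = np.frombuffer(fh.read(8 * n_spec), dtype="<f8").copy()
        rt = np.frombuffer(fh.read(8 * n_spec), dtype="<f8").copy()
        ch = np.frombuffer(fh.read(4 * n_spec), dtype="<i4").copy()
        ti = np.frombuffer(fh.read(8 * n_spec), dtype="<f8").copy()
    meta = {
        i: SpectrumMeta(float(pm[i]), float(rt[i]), int(ch[i]), float(ti[i]))
        for i in range(n_spec)
    }
    return SpectrumIndex(
        scheme=BinningScheme(bin_width=w, offset=off),
        n_spectra=n_spec,
        bins=bins,
        starts=starts,
        spectrum_ids=sids,
        intensities=intens,
        meta=meta,
        precursor_mass=pm,
        retention_time=rt,
        precursor_charge=ch,
        total_intensity=ti,
    )
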