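"""Peptide-spectrum matching over the inverted index.

For every candidate modified peptide, the theoretical b/y ion bins are
queried against the :class:`~pepsearch.index.SpectrumIndex`; matched ion
counts (Nb, Ny) and matched intensities (sum_Ib, sum_Iy) are accumulated
per spectrum; spectra below the matched-ion floor are dropped; survivors
are scored with a hyperscore (log factorial-intensity product, X!Tandem
lineage) and a fast cross-correlation score on the same bin grid
(SEQUEST/Comet lineage); and the running best match per spectrum is kept.
Precursor m/z never gates the candidate set — every peptide is scored
against every spectrum — which is what makes the search "full database";
the precursor mass difference is only reported (and optionally windowed).

:func:`naive_search_all` is a deliberately simple all-pairs reference
matcher used to validate the index path; both share the scoring functions
and must agree bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import islice
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import gammaln

from .index import SpectrumIndex
from .proteome import FragmentSet, ModifiedPeptide, fragment_ions
from .spectra import BinningScheme, PeakSelection, bin_mz

__all__ = [
    "SearchConfig",
    "PSMRecord",
    "hyperscore",
    "XcorrSpectrum",
    "xcorr_preprocess",
    "xcorr_score",
    "search_all",
    "naive_search_all",
    "narrow_window_filter",
]

_XCORR_WINDOW = 75          # background window half-width, bins
_XCORR_NORM_WINDOWS = 10    # m/z windows for intensity normalization
_XCORR_NORM_MAX = 50.0      # per-window intensity ceiling after sqrt


@dataclass(frozen=True)
class SearchConfig:
    """Tunable search parameters.

    ``mode`` selects the precursor-mass gate applied while scoring:
    ``full`` (default) keeps any candidate whose mass difference falls in
    ``delta_m_window`` Da; ``open`` is the same with a narrower Da window;
    ``narrow`` gates on ppm via ``tolerance_ppm``.
    """

    top_k: int = 150
    scheme: BinningScheme = field(default_factory=BinningScheme)
    min_matched_ions: int = 4
    fragment_charges: tuple[int, ...] = (1, 2)
    mode: str = "full"
    delta_m_window: tuple[float, float] = (-6000.0, 4500.0)
    tolerance_ppm: float = 20.0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.min_matched_ions < 1:
            raise ValueError("min_matched_ions must be >= 1")
        if self.mode not in ("full", "open", "narrow"):
            raise ValueError("mode must be full, open, or narrow")
        lo, hi = self.delta_m_window
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError("delta_m_window bounds must be finite")


@dataclass
class PSMRecord:
    """The best-scoring match of one spectrum."""

    spectrum_id: int
    peptide: ModifiedPeptide
    hyperscore: float
    xcorr: float
    n_b: int
    n_y: int
    sum_ib: float
    sum_iy: float
    delta_mass: float
    retention_time: float
    precursor_charge: int

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    @property
    def n_matched(self) -> int:
        return self.n_b + self.n_y


# ---------------------------------------------------------------------------
# Scores


def hyperscore(n_b, n_y, sum_ib, sum_iy):
    """H = ln(Nb! * Ny! * max(sum_Ib, 1) * max(sum_Iy, 1)).

    Accepts scalars or arrays. With no matched ions all terms are 1 and
    H = 0. The max(., 1) guards keep the logarithm nonnegative for weak,
    low-intensity matches.
    """
    n_b = np.asarray(n_b, dtype=np.float64)
    n_y = np.asarray(n_y, dtype=np.float64)
    sum_ib = np.asarray(sum_ib, dtype=np.float64)
    sum_iy = np.asarray(sum_iy, dtype=np.float64)
    h = (
        gammaln(n_b + 1.0)
        + gammaln(n_y + 1.0)
        + np.log(np.maximum(sum_ib, 1.0))
        + np.log(np.maximum(sum_iy, 1.0))
    )
    return float(h) if h.ndim == 0 else h


@dataclass
class XcorrSpectrum:
    """Sparse background-subtracted binned spectrum for fast xcorr.

    ``value_at(b)`` evaluates y'[b] = y[b] - mean(y[b-75 .. b+75]) where y
    is the sqrt-scaled, window-normalized binned intensity; the running
    background mean is evaluated from prefix sums so y' is defined at every
    bin without materializing a dense vector.
    """

    bins: np.ndarray        # sorted unique int64 bins with nonzero y
    values: np.ndarray      # y at those bins
    prefix: np.ndarray      # prefix sums of values, len = len(bins)+1

    def value_at(self, query_bins: np.ndarray) -> np.ndarray:
        q = np.asarray(query_bins, dtype=np.int64)
        if self.bins.size == 0:
            return np.zeros(q.shape)
        pos = np.searchsorted(self.bins, q)
        pos_c = np.minimum(pos, self.bins.size - 1)
        direct = np.where(self.bins[pos_c] == q, self.values[pos_c], 0.0)
        lo = np.searchsorted(self.bins, q - _XCORR_WINDOW, side="left")
        hi = np.searchsorted(self.bins, q + _XCORR_WINDOW, side="right")
        background = (self.prefix[hi] - self.prefix[lo]) / (2 * _XCORR_WINDOW + 1)
        return direct - background

    def dense(self, n_bins: int) -> np.ndarray:
        """Materialize y' over bins [0, n_bins) (for tests/inspection)."""
        return self.value_at(np.arange(n_bins))


def xcorr_preprocess(selection: PeakSelection, scheme: BinningScheme) -> XcorrSpectrum:
    """Prepare one spectrum for cross-correlation scoring.

    Intensities are square-rooted, then scaled so the maximum within each
    of 10 equal m/z windows (spanning the selection's m/z range) is 50;
    peaks sharing a bin are summed. The background subtraction itself is
    deferred to :meth:`XcorrSpectrum.value_at`.
    """
    if selection.n_peaks == 0:
        e = np.empty(0)
        return XcorrSpectrum(bins=np.empty(0, dtype=np.int64), values=e, prefix=np.zeros(1))
    inten = np.sqrt(np.asarray(selection.intensity, dtype=np.float64))
    mz = np.asarray(selection.mz, dtype=np.float64)
    lo, hi = float(mz.min()), float(mz.max())
    span = (hi - lo) or 1.0
    win = np.minimum(
        ((mz - lo) / span * _XCORR_NORM_WINDOWS).astype(np.int64),
        _XCORR_NORM_WINDOWS - 1,
    )
    scaled = inten.copy()
    for w in range(_XCORR_NORM_WINDOWS):
        mask = win == w
        if mask.any():
            peak = scaled[mask].max()
            if peak > 0:
                scaled[mask] *= _XCORR_NORM_MAX / peak
    b = bin_mz(mz, scheme)
    ub, inv = np.unique(b, return_inverse=True)
    y = np.bincount(inv, weights=scaled)
    return XcorrSpectrum(bins=ub, values=y, prefix=np.concatenate(([0.0], np.cumsum(y))))


def xcorr_score(
    yprime: XcorrSpectrum, fragments: FragmentSet, scheme: BinningScheme
) -> float:
    """X = sum over theoretical ions of y'[bin(ion)], rounded to 4 decimals.

    b-series ions (all charges, ascending) are summed before y-series ions;
    the search uses exactly this evaluation so scores agree bitwise across
    code paths.
    """
    zs = sorted(fragments.b_mz)
    bb = np.concatenate([bin_mz(fragments.b_mz[z], scheme) for z in zs])
    yb = np.concatenate([bin_mz(fragments.y_mz[z], scheme) for z in zs])
    total = float(np.sum(yprime.value_at(bb))) + float(np.sum(yprime.value_at(yb)))
    return round(total, 4)


# ---------------------------------------------------------------------------
# Index-driven search


@dataclass
class _Best:
    """Running best match of one spectrum; xcorr evaluated lazily."""

    peptide: ModifiedPeptide
    h: float
    n_b: int
    n_y: int
    sum_ib: float
    sum_iy: float
    x: float | None = None  # None until a tie (or the final pass) needs it


def _series_bins(cand: ModifiedPeptide, config: SearchConfig):
    """Canonical query order: b-series bins (charges ascending), then
    y-series bins. Intensity sums accumulate in exactly this order in both
    the index path and the reference matcher."""
    frags = fragment_ions(cand, charges=config.fragment_charges)
    w, off = config.scheme.bin_width, config.scheme.offset
    zs = sorted(frags.b_mz)
    bb = [np.floor((frags.b_mz[z] - off) / w).astype(np.int64) for z in zs]
    yb = [np.floor((frags.y_mz[z] - off) / w).astype(np.int64) for z in zs]
    zcodes = np.concatenate([np.full(a.size, z, dtype=np.int8) for z, a in zip(zs, bb)])
    return np.concatenate(bb), np.concatenate(yb), zcodes


def _lazy_xcorr(best: _Best, sid, yprimes, config, charge) -> float:
    if best.x is None:
        bb, yb, zc = _series_bins(best.peptide, config)
        best.x = _xcorr_bins(yprimes.get(sid), bb, yb, zc, charge)
    return best.x


def _xcorr_bins(yprime, bb, yb, zcodes, charge: int) -> float:
    if yprime is None or yprime.bins.size == 0:
        return 0.0
    keep = (zcodes < 2) | (charge >= 2)
    total = float(np.sum(yprime.value_at(bb[keep]))) + float(
        np.sum(yprime.value_at(yb[keep]))
    )
    return round(total, 4)


def search_all(
    index: SpectrumIndex,
    candidates: Iterable[ModifiedPeptide],
    config: SearchConfig,
    selections: Sequence[PeakSelection] | None = None,
    batch_size: int = 512,
) -> dict[int, PSMRecord]:
    """Match every candidate against every spectrum; best PSM per spectrum.

    ``selections`` (the same top-K peak lists the index was built from) are
    needed for cross-correlation scoring; the index itself carries only
    binned intensities. A scheme mismatch between index and selections is
    a configuration error.

    Candidates are consumed lazily in batches and their ion bins queried
    with a handful of vectorized index lookups per batch; the xcorr is only
    evaluated for hyperscore ties and for the final best match of each
    spectrum, which never changes the outcome because the per-spectrum
    reduction consults xcorr strictly after the hyperscore.

    Returns ``{spectrum_id: PSMRecord}`` with at most one record per
    spectrum. The reduction order-independent (total tie-break ordering),
    so any candidate order and batch size give the same result.
    """
    if index.scheme != config.scheme:
        raise ValueError("index BinningScheme differs from search configuration")
    n = index.n_spectra
    yprimes: dict[int, XcorrSpectrum] = {}
    if selections is not None:
        for sel in selections:
            yprimes[sel.spectrum_id] = xcorr_preprocess(sel, config.scheme)
    charge_ge2 = index.precursor_charge >= 2
    best: dict[int, _Best] = {}
    it = iter(candidates)

    while True:
        batch = list(islice(it, batch_size))
        if not batch:
            break
        nb_q: list[np.ndarray] = []   # b-series query bins
        ny_q: list[np.ndarray] = []
        zb_q: list[np.ndarray] = []   # charge code per b query bin
        cand_rows_b: list[np.ndarray] = []
        series_cache = []
        for row, cand in enumerate(batch):
            bb, yb, zc = _series_bins(cand, config)
            series_cache.append((bb, yb, zc))
            nb_q.append(bb)
            ny_q.append(yb)
            zb_q.append(zc)
            cand_rows_b.append(np.full(bb.size, row, dtype=np.int64))
        masses = np.array([c.neutral_mass for c in batch])

        def accumulate(qbins, rows, zcodes):
            """bincount matched ions over flattened (candidate, spectrum)."""
            found, s, e = index.postings_range(qbins)
            lens = (e - s) * found
            total_p = int(lens.sum())
            if total_p == 0:
                z = np.zeros(len(batch) * n)
                return z.astype(np.int64), z
            cum = np.concatenate(([0], np.cumsum(lens)[:-1]))
            idx = np.repeat(s - cum, lens) + np.arange(total_p)
            ids = index.spectrum_ids[idx].astype(np.int64)
            w = index.intensities[idx]
            zrep = np.repeat(zcodes, lens)
            keep = (zrep < 2) | charge_ge2[ids]
            key = np.repeat(rows, lens) * n + ids
            key, w = key[keep], w[keep]
            counts = np.bincount(key, minlength=len(batch) * n)
            sums = np.bincount(key, weights=w, minlength=len(batch) * n)
            return counts, sums

        qb = np.concatenate(nb_q)
        qy = np.concatenate(ny_q)
        zc_all = np.concatenate(zb_q)
        rows_all = np.concatenate(cand_rows_b)
        nb, sib = accumulate(qb, rows_all, zc_all)
        ny, siy = accumulate(qy, rows_all, zc_all)

        flat = np.nonzero(nb + ny >= config.min_matched_ions)[0]
        if flat.size == 0:
            continue
        ci, sids = np.divmod(flat, n)
        dm = index.precursor_mass[sids] - masses[ci]
        if config.mode == "narrow":
            ok = np.abs(dm) / masses[ci] * 1e6 <= config.tolerance_ppm
        else:
            lo, hi = config.delta_m_window
            ok = (dm >= lo) & (dm <= hi)
        flat, ci, sids = flat[ok], ci[ok], sids[ok]
        if flat.size == 0:
            continue
        h = np.atleast_1d(hyperscore(nb[flat], ny[flat], sib[flat], siy[flat]))

        for j in range(flat.size):
            sid = int(sids[j])
            hj = float(h[j])
            cur = best.get(sid)
            take = False
            x_new: float | None = None
            if cur is None or hj > cur.h:
                take = True
            elif hj == cur.h:
                cand = batch[int(ci[j])]
                bb, yb, zc = series_cache[int(ci[j])]
                charge = int(index.precursor_charge[sid])
                x_new = _xcorr_bins(yprimes.get(sid), bb, yb, zc, charge)
                x_cur = _lazy_xcorr(cur, sid, yprimes, config, charge)
                if x_new != x_cur:
                    take = x_new > x_cur
                else:
                    nk, ck = cand.key(), cur.peptide.key()
                    if nk != ck:
                        take = nk < ck
                    else:
                        take = (not cand.is_decoy) and cur.peptide.is_decoy
            if take:
                f = int(flat[j])
                best[sid] = _Best(
                    peptide=batch[int(ci[j])],
                    h=hj,
                    n_b=int(nb[f]),
                    n_y=int(ny[f]),
                    sum_ib=float(sib[f]),
                    sum_iy=float(siy[f]),
                    x=x_new,
                )

    out: dict[int, PSMRecord] = {}
    for sid, b in best.items():
        charge = int(index.precursor_charge[sid])
        x = _lazy_xcorr(b, sid, yprimes, config, charge)
        out[sid] = PSMRecord(
            spectrum_id=sid,
            peptide=b.peptide,
            hyperscore=b.h,
            xcorr=x,
            n_b=b.n_b,
            n_y=b.n_y,
            sum_ib=b.sum_ib,
            sum_iy=b.sum_iy,
            delta_mass=float(index.precursor_mass[sid] - b.peptide.neutral_mass),
            retention_time=float(index.retention_time[sid]),
            precursor_charge=charge,
        )
    return out


# ---------------------------------------------------------------------------
# Reference all-pairs matcher


def _better(new: PSMRecord, cur: PSMRecord | None) -> bool:
    """Total order for the per-spectrum reduction: higher hyperscore, then
    higher xcorr, then lexicographically smaller peptide key, then target
    over decoy. A total ordering makes the reduction order-independent."""
    if cur is None:
        return True
    if new.hyperscore != cur.hyperscore:
        return new.hyperscore > cur.hyperscore
    if new.xcorr != cur.xcorr:
        return new.xcorr > cur.xcorr
    nk, ck = new.peptide.key(), cur.peptide.key()
    if nk != ck:
        return nk < ck
    return (not new.peptide.is_decoy) and cur.peptide.is_decoy


def naive_search_all(
    selections: Sequence[PeakSelection],
    meta: dict[int, "SpectrumMeta"],
    candidates: Iterable[ModifiedPeptide],
    config: SearchConfig,
) -> dict[int, PSMRecord]:
    """Index-free all-pairs matcher (validation reference).

    Compares every candidate against every spectrum with per-spectrum
    dictionaries of merged bin intensities and sequential accumulation, so
    its counts, intensity sums and scores are bit-identical to
    :func:`search_all` while sharing no index machinery.
    """
    scheme = config.scheme
    spectra = []
    for sel in selections:
        m = meta[sel.spectrum_id]
        binned: dict[int, float] = {}
        if sel.n_peaks:
            for b, w in zip(bin_mz(sel.mz, scheme), sel.intensity):
                binned[int(b)] = binned.get(int(b), 0.0) + float(w)
        spectra.append(
            (sel.spectrum_id, binned, m, xcorr_preprocess(sel, scheme))
        )
    best: dict[int, PSMRecord] = {}
    for cand in candidates:
        bb, yb, zc = _series_bins(cand, config)
        for sid, binned, m, yp in spectra:
            # sequential accumulation in canonical ion order (b series over
            # ascending charges, then y series), identical to the index path
            n_b = n_y = 0
            s_ib = s_iy = 0.0
            gate2 = m.precursor_charge >= 2
            for b, z in zip(bb, zc):
                if z >= 2 and not gate2:
                    continue
                w = binned.get(int(b))
                if w is not None:
                    n_b += 1
                    s_ib += w
            for b, z in zip(yb, zc):
                if z >= 2 and not gate2:
                    continue
                w = binned.get(int(b))
                if w is not None:
                    n_y += 1
                    s_iy += w
            if n_b + n_y < config.min_matched_ions:
                continue
            dm = m.precursor_neutral_mass - cand.neutral_mass
            if config.mode == "narrow":
                if abs(dm) / cand.neutral_mass * 1e6 > config.tolerance_ppm:
                    continue
            else:
                lo, hi = config.delta_m_window
                if not (lo <= dm <= hi):
                    continue
            rec = PSMRecord(
                spectrum_id=sid,
                peptide=cand,
                hyperscore=hyperscore(n_b, n_y, s_ib, s_iy),
                xcorr=_xcorr_bins(yp, bb, yb, zc, m.precursor_charge),
                n_b=n_b,
                n_y=n_y,
                sum_ib=s_ib,
                sum_iy=s_iy,
                delta_mass=dm,
                retention_time=m.retention_time,
                precursor_charge=m.precursor_charge,
            )
            if _better(rec, best.get(sid)):
                best[sid] = rec
    return best


def narrow_window_filter(
    psms: Iterable[PSMRecord], tolerance_ppm: float
) -> list[PSMRecord]:
    """Keep PSMs whose |delta mass| is within ``tolerance_ppm`` of the
    peptide mass (post-hoc narrow-window view of a full search)."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    return [
        p
        for p in psms
        if abs(p.delta_mass) / p.peptide.neutral_mass * 1e6 <= tolerance_ppm
    ]
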