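"""Scoring functions and the index-vs-reference search equivalence."""

import math

import numpy as np
import pytest

from pepsearch.index import SpectrumMeta, build_index
from pepsearch.proteome import enumerate_modforms, fragment_ions
from pepsearch.search import (
    SearchConfig,
    XcorrSpectrum,
    hyperscore,
    naive_search_all,
    narrow_window_filter,
    search_all,
    xcorr_preprocess,
    xcorr_score,
)
from pepsearch.spectra import BinningScheme, PeakSelection, RawSpectrum, bin_mz, select_top_k
from pepsearch.synthetic import SyntheticRunSpec

from conftest import prepared_run, run_search_stage


class TestHyperscore:
    def test_no_match_is_zero(self):
        assert hyperscore(0, 0, 0.0, 0.0) == 0.0

    def test_example_value(self):
        assert hyperscore(2, 1, 10.0, 5.0) == pytest.approx(math.log(100), rel=1e-12)

    def test_equals_bruteforce_product_log(self):
        expect = math.log(math.factorial(3) * math.factorial(3) * 100 * 100)
        assert hyperscore(3, 3, 100.0, 100.0) == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_every_argument(self):
        base = hyperscore(3, 3, 100.0, 100.0)
        assert hyperscore(4, 3, 100.0, 100.0) > base
        assert hyperscore(3, 4, 100.0, 100.0) > base
        assert hyperscore(3, 3, 101.0, 100.0) > base
        assert hyperscore(3, 3, 100.0, 101.0) > base

    def test_subunit_intensity_guarded(self):
        # intensities below 1 must not drive the score negative
        assert hyperscore(1, 0, 0.5, 0.0) >= 0.0


class TestXcorr:
    def test_all_zero_spectrum(self):
        sel = PeakSelection(0, np.empty(0), np.empty(0))
        yp = xcorr_preprocess(sel, BinningScheme(1.0))
        assert np.all(yp.dense(50) == 0.0)

    def test_background_subtraction_window(self):
        # direct construction: unit mass at bin 100
        yp = XcorrSpectrum(
            bins=np.array([100]), values=np.array([1.0]),
            prefix=np.array([0.0, 1.0]),
        )
        assert yp.value_at(np.array([100]))[0] == pytest.approx(1 - 1 / 151)
        assert yp.value_at(np.array([50]))[0] == pytest.approx(-1 / 151)
        assert yp.value_at(np.array([200]))[0] == 0.0

    def test_normalization_ceiling_is_50(self):
        sel = PeakSelection(
            0, np.array([100.0, 500.0]), np.array([25.0, 81.0])
        )
        yp = xcorr_preprocess(sel, BinningScheme(1.0))
        assert yp.values.max() == pytest.approx(50.0)

    def test_background_sums_to_zero_within_edges(self):
        rng = np.random.default_rng(2)
        mz = np.sort(rng.uniform(100, 200, 30))
        sel = PeakSelection(0, mz, rng.uniform(1, 100, 30))
        scheme = BinningScheme(1.0)
        yp = xcorr_preprocess(sel, scheme)
        lo, hi = int(yp.bins.min()) - 80, int(yp.bins.max()) + 81
        dense = yp.value_at(np.arange(lo, hi))
        assert abs(dense.sum()) < 1e-8

    def test_score_equals_loop_oracle(self):
        rng = np.random.default_rng(4)
        scheme = BinningScheme(0.02)
        mz = np.sort(rng.uniform(100, 1500, 40))
        sel = PeakSelection(0, mz, rng.uniform(1, 100, 40))
        yp = xcorr_preprocess(sel, scheme)
        pep = next(enumerate_modforms("ELVISLIVESK"))
        frags = fragment_ions(pep, charges=(1, 2))
        x = xcorr_score(yp, frags, scheme)
        expect = 0.0
        for series in (frags.b_mz, frags.y_mz):
            for z in sorted(series):
                for ion in series[z]:
                    expect += float(yp.value_at(np.array([bin_mz(ion, scheme)]))[0])
        assert x == pytest.approx(expect, abs=1.1e-4)


def _ladder_spectrum(sid, pep, charge=2, rt=100.0, extra=()):
    frags = fragment_ions(pep, charges=(1,))
    mz = np.sort(np.concatenate([frags.b_mz[1], frags.y_mz[1], np.array(extra)]))
    from pepsearch.constants import PROTON

    return RawSpectrum(
        spectrum_id=sid,
        precursor_mz=(pep.neutral_mass + charge * PROTON) / charge,
        precursor_charge=charge,
        retention_time=rt,
        peaks=np.column_stack([mz, np.full(mz.size, 100.0)]),
    )


class TestSearchAll:
    def _setup(self, spectra, config=None):
        config = config or SearchConfig()
        sels = [select_top_k(s, config.top_k) for s in spectra]
        meta = {
            s.spectrum_id: SpectrumMeta(
                s.precursor_neutral_mass, s.retention_time,
                s.precursor_charge, sel.total_intensity,
            )
            for s, sel in zip(spectra, sels)
        }
        return build_index(sels, config.scheme, meta), sels, meta, config

    def test_self_match_wins(self):
        p = next(enumerate_modforms("ELVISLIVESK"))
        q = next(enumerate_modforms("AAAAGGGGWWK"))
        index, sels, meta, cfg = self._setup([_ladder_spectrum(0, p)])
        best = search_all(index, [p, q], cfg, selections=sels)
        assert best[0].peptide.sequence == "ELVISLIVESK"
        assert best[0].n_b + best[0].n_y >= 10

    def test_two_spectra_get_independent_psms(self):
        p = next(enumerate_modforms("ELVISLIVESK"))
        spectra = [_ladder_spectrum(0, p), _ladder_spectrum(1, p, rt=200.0)]
        index, sels, meta, cfg = self._setup(spectra)
        best = search_all(index, [p], cfg, selections=sels)
        assert set(best) == {0, 1}
        assert best[0].retention_time != best[1].retention_time

    def test_scheme_mismatch_is_fatal(self):
        p = next(enumerate_modforms("ELVISLIVESK"))
        index, sels, meta, cfg = self._setup([_ladder_spectrum(0, p)])
        bad = SearchConfig(scheme=BinningScheme(0.05))
        with pytest.raises(ValueError):
            search_all(index, [p], bad, selections=sels)

    def test_batch_size_invariance(self):
        spec = SyntheticRunSpec(n_proteins=6, n_spectra=30, fraction_true=0.8)
        prep = prepared_run(spec, seed=21)
        from pepsearch.proteome import stream_candidates

        cands = list(stream_candidates(prep["database"], ()))
        a = search_all(prep["index"], cands, prep["config"],
                       selections=prep["selections"], batch_size=1)
        b = search_all(prep["index"], cands, prep["config"],
                       selections=prep["selections"], batch_size=512)
        assert set(a) == set(b)
        for sid in a:
            assert a[sid].peptide.key() == b[sid].peptide.key()
            assert a[sid].hyperscore == b[sid].hyperscore
            assert a[sid].xcorr == b[sid].xcorr

    def test_candidate_order_invariance(self):
        spec = SyntheticRunSpec(n_proteins=6, n_spectra=30, fraction_true=0.8)
        prep = prepared_run(spec, seed=22)
        from pepsearch.proteome import stream_candidates

        cands = list(stream_candidates(prep["database"], ()))
        a = search_all(prep["index"], cands, prep["config"], selections=prep["selections"])
        b = search_all(prep["index"], cands[::-1], prep["config"], selections=prep["selections"])
        assert {s: r.peptide.key() for s, r in a.items()} == {
            s: r.peptide.key() for s, r in b.items()
        }

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bit_identical_to_reference_matcher(self, seed):
        spec = SyntheticRunSpec(n_proteins=6, n_spectra=25, fraction_true=0.7)
        prep = prepared_run(spec, seed=seed)
        from pepsearch.proteome import stream_candidates

        cands = list(stream_candidates(prep["database"], ()))
        a = search_all(prep["index"], cands, prep["config"], selections=prep["selections"])
        b = naive_search_all(prep["selections"], prep["meta"], cands, prep["config"])
        assert set(a) == set(b)
        for sid in a:
            ra, rb = a[sid], b[sid]
            assert ra.peptide.key() == rb.peptide.key()
            assert ra.hyperscore == rb.hyperscore
            assert ra.xcorr == rb.xcorr
            assert (ra.n_b, ra.n_y) == (rb.n_b, rb.n_y)
            assert (ra.sum_ib, ra.sum_iy) == (rb.sum_ib, rb.sum_iy)
            assert ra.delta_mass == rb.delta_mass


class TestNarrowWindow:
    def _psm(self, dm, mass=1000.0):
        from pepsearch.search import PSMRecord

        pep = next(enumerate_modforms("ELVISLIVESK"))
        pep.neutral_mass = mass
        return PSMRecord(0, pep, 1.0, 0.0, 2, 2, 10, 10, dm, 0.0, 2)

    def test_zero_delta_always_retained(self):
        assert len(narrow_window_filter([self._psm(0.0)], 0.001)) == 1

    def test_ppm_arithmetic(self):
        # 0.05 Da on 1000 Da = 50 ppm > 20 ppm
        assert narrow_window_filter([self._psm(0.05)], 20.0) == []
        assert len(narrow_window_filter([self._psm(0.01)], 20.0)) == 1

    def test_infinite_tolerance_is_identity(self):
        psms = [self._psm(d) for d in (-500.0, 0.0, 3.3, 4000.0)]
        assert narrow_window_filter(psms, float("inf")) == psms

    def test_narrow_mode_subset_of_full(self):
        spec = SyntheticRunSpec(n_proteins=8, n_spectra=40, fraction_true=0.8)
        prep = prepared_run(spec, seed=31)
        full = run_search_stage(prep)
        narrow_cfg = SearchConfig(mode="narrow", tolerance_ppm=20.0)
        prep_n = dict(prep, config=narrow_cfg)
        narrow = run_search_stage(prep_n)
        assert set(narrow) <= set(full)
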