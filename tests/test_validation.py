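"""Feature encoding, q-values, and the learned validation models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from pepsearch.constants import AA_INDEX, ALPHABET
from pepsearch.proteome import ModificationSpec, enumerate_modforms, peptide_mass
from pepsearch.search import PSMRecord
from pepsearch.validation import (
    ValidationError,
    assemble_training_set,
    compute_qvalues,
    encode_rt_features,
    final_report,
    psm_feature_matrix,
    train_discriminant,
    train_rt_model,
)

CARB = ModificationSpec("carbamidomethyl", "C", 57.021464, "fixed")


class TestRTEncoder:
    def test_dimension_is_63(self):
        for seq in ("AAK", "ELVISLIVESK", "MKWVTFISLLLLFSSAYSR"):
            assert encode_rt_features(seq).shape == (63,)

    def test_counts_for_aak(self):
        v = encode_rt_features("AAK")
        assert v[AA_INDEX["A"]] == 2 and v[AA_INDEX["K"]] == 1
        assert v[:20].sum() == 3
        assert v[20 + AA_INDEX["A"]] == 2          # first two residues: AA
        assert v[40 + AA_INDEX["A"]] == 1          # last two residues: AK
        assert v[40 + AA_INDEX["K"]] == 1
        assert v[60] == AA_INDEX["K"]
        assert v[61] == 3
        assert v[62] == pytest.approx(peptide_mass("AAK"), abs=1e-9)

    def test_terminal_blocks_sum_to_two(self):
        v = encode_rt_features("ELVISLIVESK")
        assert v[20:40].sum() == 2 and v[40:60].sum() == 2

    def test_modified_mass_shift(self):
        plain = encode_rt_features(next(enumerate_modforms("ACDK")))
        fixed = encode_rt_features(next(enumerate_modforms("ACDK", (CARB,))))
        assert fixed[62] - plain[62] == pytest.approx(57.021464, abs=1e-6)
        # composition counts unchanged by the modification
        np.testing.assert_array_equal(plain[:60], fixed[:60])

    def test_noncanonical_rejected(self):
        with pytest.raises(ValueError):
            encode_rt_features("AXK")


class TestQValues:
    def test_hand_computed_sequence(self):
        # sorted labels [T, T, D, T, D]
        df = compute_qvalues(
            [50.0, 40.0, 30.0, 20.0, 10.0],
            [False, False, True, False, True],
        )
        np.testing.assert_allclose(df["q"], [0.0, 0.0, 1 / 3, 1 / 3, 2 / 3])

    def test_all_targets_q_zero(self):
        df = compute_qvalues([3.0, 2.0, 1.0], [False] * 3)
        assert (df["q"] == 0.0).all()

    def test_ties_share_worst_q(self):
        df = compute_qvalues(
            [5.0, 5.0, 5.0, 1.0], [False, True, False, False]
        )
        tied = df[df["score"] == 5.0]["q"]
        assert tied.nunique() == 1

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(-10, 10), st.booleans()),
            min_size=1,
            max_size=200,
        )
    )
    def test_monotone_nondecreasing(self, records):
        df = compute_qvalues([r[0] for r in records], [r[1] for r in records])
        assert (np.diff(df["q"]) >= -1e-12).all()
        assert df["q"].between(0, 1).all()

    def test_matches_bruteforce_resort_oracle(self):
        rng = np.random.default_rng(9)
        n = 2000
        scores = rng.normal(size=n)
        decoy = rng.random(n) < 0.4
        df = compute_qvalues(scores, decoy)
        order = np.lexsort((np.arange(n), -scores))  # score desc (unique floats)
        d_sorted = decoy[order]
        fdrs = np.cumsum(d_sorted) / np.maximum(1, np.cumsum(~d_sorted))
        expect = [min(fdrs[i:]) for i in range(n)]
        got = df.sort_values("score", ascending=False)["q"].to_numpy()
        np.testing.assert_allclose(got, np.clip(expect, 0, 1), atol=1e-12)

    def test_peptide_level_collapse(self):
        df = compute_qvalues(
            [5.0, 4.0, 3.0],
            [False, False, True],
            keys=["PEP", "PEP", "DEC"],
            level="peptide",
        )
        assert len(df) == 2
        assert df.iloc[0]["key"] == "PEP" and df.iloc[0]["score"] == 5.0

    def test_empty_input(self):
        assert compute_qvalues([], []).empty


def _psm(sid, seq, h, decoy=False, charge=2, rt=100.0, accs=("P1",), x=0.0):
    pep = next(enumerate_modforms(seq))
    pep.is_decoy = decoy
    pep.protein_accessions = accs
    return PSMRecord(
        spectrum_id=sid, peptide=pep, hyperscore=h, xcorr=x,
        n_b=3, n_y=3, sum_ib=50.0, sum_iy=50.0, delta_mass=0.001,
        retention_time=rt, precursor_charge=charge,
    )


class TestAssembleTrainingSet:
    def test_hand_evaluated_positives(self):
        # 6 targets, 4 decoys; decoys all score below every target, so every
        # target precursor has q = 0 <= 0.01
        targets = [_psm(i, s, 50.0 - i) for i, s in enumerate(
            ["AAAAAAK", "CCCCCCK", "DDDDDDK", "EEEEEEK", "FFFFFFK", "GGGGGGK"]
        )]
        decoys = [_psm(10 + i, s, 5.0 - i, decoy=True) for i, s in enumerate(
            ["HHHHHHK", "IIIIIIK", "LLLLLLK", "MMMMMMK"]
        )]
        pos, neg = assemble_training_set(targets + decoys)
        assert {p.peptide.sequence for p in pos} == {
            t.peptide.sequence for t in targets
        }
        assert len(neg) == 4

    def test_interleaved_decoys_cut_positives(self):
        # best decoy outscores all targets: q = 1/1, 1/2, ... never <= 0.01
        records = [_psm(0, "HHHHHHK", 99.0, decoy=True)] + [
            _psm(i + 1, s, 50.0 - i)
            for i, s in enumerate(["AAAAAAK", "CCCCCCK", "DDDDDDK"])
        ]
        with pytest.raises(ValidationError):
            assemble_training_set(records)

    def test_all_decoys_is_error(self):
        with pytest.raises(ValidationError):
            assemble_training_set(
                [_psm(0, "AAAAAAK", 10.0, decoy=True)]
            )

    def test_negative_count_equals_decoy_psm_count(self):
        psms = [_psm(i, "AAAAAAK", 50.0) for i in range(5)] + [
            _psm(5 + i, "HHHHHHK", 1.0, decoy=True) for i in range(3)
        ]
        _, neg = assemble_training_set(psms)
        assert len(neg) == 3


class TestRTModel:
    def _additive_data(self, n, seed=0, sigma=30.0):
        rng = np.random.default_rng(seed)
        coeff = rng.normal(120, 40, 20)
        peps = [
            "".join(rng.choice(list(ALPHABET), size=rng.integers(7, 31)))
            for _ in range(n)
        ]
        rts = np.array(
            [sum(coeff[AA_INDEX[a]] for a in p) for p in peps]
        ) + rng.normal(0, sigma, n)
        return peps, rts

    def test_neural_model_recovers_additive_rt(self):
        # small training set; the full-size recovery bound lives in the
        # acceptance suite
        peps, rts = self._additive_data(600, seed=1)
        m = train_rt_model(peps[:500], rts[:500], seed=42)
        assert m.kind == "neural"
        r = pearsonr(m.predict(peps[500:]), rts[500:])[0]
        assert r >= 0.9

    def test_determinism_same_seed(self):
        peps, rts = self._additive_data(300, seed=2)
        m1 = train_rt_model(peps, rts, seed=7)
        m2 = train_rt_model(peps, rts, seed=7)
        np.testing.assert_array_equal(m1.predict(peps[:50]), m2.predict(peps[:50]))

    def test_constant_rt_predicts_constant(self):
        peps, _ = self._additive_data(250, seed=3)
        rts = np.full(len(peps), 1234.0)
        m = train_rt_model(peps, rts, seed=42)
        pred = m.predict(peps[:50])
        assert np.all(np.abs(pred - 1234.0) <= 1.0)

    def test_small_set_falls_back_to_linear(self):
        peps, rts = self._additive_data(60, seed=4)
        m = train_rt_model(peps, rts, seed=42)
        assert m.kind == "linear"
        assert pearsonr(m.predict(peps), rts)[0] > 0.9

    def test_tiny_set_disables_model(self):
        peps, rts = self._additive_data(10, seed=5)
        m = train_rt_model(peps, rts, seed=42)
        assert not m.enabled
        assert np.all(m.predict(peps) == 0.0)


class TestDiscriminant:
    def _feature_psms(self, n_pos, n_neg, seed=0, separable=True):
        rng = np.random.default_rng(seed)
        pos, neg = [], []
        for i in range(n_pos):
            h = rng.normal(30, 3) if separable else rng.normal(10, 5)
            x = rng.normal(3, 0.5) if separable else rng.normal(0, 1)
            pos.append(_psm(i, "AAAAAAK", float(h), x=float(x)))
        for i in range(n_neg):
            h = rng.normal(5, 2) if separable else rng.normal(10, 5)
            x = rng.normal(0, 0.5) if separable else rng.normal(0, 1)
            # same sequence in the null case so no feature carries signal
            seq = "HHHHHHK" if separable else "AAAAAAK"
            neg.append(
                _psm(n_pos + i, seq, float(h), decoy=True, x=float(x))
            )
        return pos, neg

    def test_separable_classes_high_accuracy(self):
        pos, neg = self._feature_psms(150, 100, seed=1)
        model = train_discriminant(pos, neg, None, seed=42)
        assert model.train_accuracy >= 0.99

    def test_label_noise_gives_chance_accuracy_heldout(self):
        # labels carry no signal: held-out accuracy must be near chance
        pos, neg = self._feature_psms(150, 150, seed=2, separable=False)
        model = train_discriminant(pos, neg, None, seed=42)
        pos2, neg2 = self._feature_psms(150, 150, seed=20, separable=False)
        d_pos = model.score(pos2, {})
        d_neg = model.score(neg2, {})
        acc = 0.5 * ((d_pos > 0).mean() + (d_neg <= 0).mean())
        assert 0.4 <= acc <= 0.6

    def test_scores_separate_classes(self):
        pos, neg = self._feature_psms(150, 100, seed=3)
        model = train_discriminant(pos, neg, None, seed=42)
        assert model.score(pos, {}).mean() > model.score(neg, {}).mean()

    def test_empty_class_rejected(self):
        pos, _ = self._feature_psms(10, 0, seed=4)
        with pytest.raises(ValidationError):
            train_discriminant(pos, [], None, seed=42)

    def test_feature_matrix_shape_and_finiteness(self):
        pos, neg = self._feature_psms(5, 5, seed=5)
        X = psm_feature_matrix(pos + neg, {})
        assert X.shape == (10, 16)
        assert np.isfinite(X).all()


class TestFinalReport:
    def test_toy_threshold(self):
        # sorted: T T D T D -> q = 0, 0, 1/3, 1/3, 2/3; at 0.01 two peptides
        psms = [
            _psm(0, "AAAAAAK", 50.0),
            _psm(1, "CCCCCCK", 40.0),
            _psm(2, "HHHHHHK", 30.0, decoy=True),
            _psm(3, "DDDDDDK", 20.0),
            _psm(4, "IIIIIIK", 10.0, decoy=True),
        ]
        d = np.array([p.hyperscore for p in psms])
        reports = final_report(psms, d, threshold=0.01)
        assert set(reports["peptides"]["sequence"]) == {"AAAAAAK", "CCCCCCK"}

    def test_threshold_one_keeps_all_targets(self):
        psms = [
            _psm(0, "AAAAAAK", 50.0),
            _psm(1, "CCCCCCK", 40.0),
            _psm(2, "HHHHHHK", 30.0, decoy=True),
        ]
        reports = final_report(psms, np.array([50.0, 40.0, 30.0]), threshold=1.0)
        assert len(reports["peptides"]) == 2
        assert not reports["peptides"]["key"].str.startswith("HHH").any()

    def test_shared_only_protein_flagged(self):
        psms = [
            _psm(0, "AAAAAAK", 50.0, accs=("P1", "P2")),
            _psm(1, "CCCCCCK", 40.0, accs=("P1",)),
        ]
        reports = final_report(psms, np.array([50.0, 40.0]), threshold=1.0)
        prot = reports["proteins"].set_index("key")
        assert bool(prot.loc["P2", "shared_only"])
        assert not bool(prot.loc["P1", "shared_only"])

    def test_decoys_never_reported(self):
        psms = [
            _psm(0, "AAAAAAK", 50.0),
            _psm(1, "HHHHHHK", 60.0, decoy=True, accs=("DECOY_P9",)),
        ]
        reports = final_report(psms, np.array([50.0, 60.0]), threshold=1.0)
        assert "DECOY_P9" not in set(reports["proteins"]["key"])
        assert (~reports["peptides"]["is_decoy"]).all()
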