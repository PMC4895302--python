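import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyspred.encoders import (
    BLOSUM62,
    FeatureVector,
    build_pwm,
    concat_features,
    encode_aac,
    encode_aaindex,
    encode_aapc,
    encode_binary,
    encode_blosum62,
    encode_matrix,
    encode_pssm,
    encode_pwm,
    encode_track,
    make_encoder,
)
from cyspred.io_formats import AA_ORDER, ALPHABET21, PSSMProfile, ResidueTrack

from conftest import make_fragment

# random fragment windows: center C, flanks over the 21-symbol alphabet
fragment_windows = st.integers(1, 10).flatmap(
    lambda n: st.tuples(
        st.text(alphabet=ALPHABET21, min_size=n, max_size=n),
        st.text(alphabet=ALPHABET21, min_size=n, max_size=n),
    ).map(lambda lr: lr[0] + "C" + lr[1])
)


class TestBinary:
    def test_alanine_is_first_bit(self):
        frag = make_fragment("ACC")
        vec = encode_binary(frag)
        assert vec.values[:20].tolist() == [1.0] + [0.0] * 19

    def test_cysteine_is_second_bit(self):
        frag = make_fragment("ACC")
        assert vec_block(encode_binary(frag), 1) == [0, 1] + [0] * 18

    def test_21mer_length_and_ones(self, frag21):
        vec = encode_binary(frag21)
        assert len(vec) == 420
        assert vec.values.sum() == 21

    @given(window=fragment_windows)
    @settings(max_examples=100, deadline=None)
    def test_one_hot_per_non_x_residue(self, window):
        vec = encode_binary(make_fragment(window))
        n_x = window.count("X")
        assert vec.values.sum() == len(window) - n_x
        per_residue = vec.values.reshape(len(window), 20)
        assert set(per_residue.sum(axis=1)) <= {0.0, 1.0}

    @given(a=fragment_windows)
    @settings(max_examples=50, deadline=None)
    def test_inner_product_counts_matches(self, a):
        b = a[::-1][: len(a) // 2] + "C" + a[: len(a) // 2]
        va = encode_binary(make_fragment(a)).values
        vb = encode_binary(make_fragment(b)).values
        matches = sum(
            1 for x, y in zip(a, b) if x == y and x != "X"
        )
        assert va @ vb == matches


class TestComposition:
    def test_aac_example(self, frag21):
        vec = encode_aac(frag21)
        assert len(vec) == 21
        assert vec.values[0] == pytest.approx(20 / 21)  # A
        assert vec.values[1] == pytest.approx(1 / 21)  # C
        assert vec.values[2:].sum() == 0

    def test_aapc_homopolymer(self, frag21):
        vec = encode_aapc(frag21)
        assert len(vec) == 441
        by_name = dict(zip(vec.names, vec.values))
        assert by_name["aapc:AA"] == pytest.approx(18 / 20)
        assert by_name["aapc:AC"] == pytest.approx(1 / 20)
        assert by_name["aapc:CA"] == pytest.approx(1 / 20)

    @given(window=fragment_windows)
    @settings(max_examples=100, deadline=None)
    def test_aac_and_aapc_sum_to_one(self, window):
        frag = make_fragment(window)
        assert encode_aac(frag).values.sum() == pytest.approx(1.0)
        assert encode_aapc(frag).values.sum() == pytest.approx(1.0)


class TestBlosum62:
    def test_matrix_constants(self):
        assert BLOSUM62.shape == (20, 20)
        assert np.array_equal(BLOSUM62, BLOSUM62.T)
        assert BLOSUM62.max() == 11  # W-W
        assert BLOSUM62.min() == -4

    def test_tryptophan_hits_max(self):
        frag = make_fragment("WCW")
        vec = encode_blosum62(frag)
        w_col = AA_ORDER.index("W")
        assert vec.values[w_col] == pytest.approx(1.0)

    def test_all_values_in_unit_interval(self, frag21):
        vec = encode_blosum62(frag21)
        assert len(vec) == 420
        assert vec.values.min() >= 0 and vec.values.max() <= 1

    def test_x_rows_are_zero(self):
        frag = make_fragment("XCX")
        vec = encode_blosum62(frag)
        assert vec.values[:20].sum() == 0
        assert vec.values[40:].sum() == 0


class TestPWM:
    def test_single_fragment(self, frag21):
        pwm = build_pwm([frag21])
        assert pwm.n_rows == 21
        assert pwm.matrix[0, 0] == 1.0  # A at column 0
        assert pwm.matrix[1, 10] == 1.0  # C at center

    def test_two_fragments_split_column(self):
        a = make_fragment("A" * 10 + "C" + "A" * 10)
        b = make_fragment("R" + "A" * 9 + "C" + "A" * 10)
        pwm = build_pwm([a, b])
        assert pwm.matrix[AA_ORDER.index("A"), 0] == pytest.approx(0.5)
        assert pwm.matrix[AA_ORDER.index("R"), 0] == pytest.approx(0.5)

    def test_columns_sum_to_one(self, rng):
        aa = np.array(list(ALPHABET21))
        frags = []
        for _ in range(50):
            flanks = "".join(aa[rng.integers(0, 21, 20)])
            frags.append(make_fragment(flanks[:10] + "C" + flanks[10:]))
        pwm = build_pwm(frags)
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            build_pwm([])

    def test_encode_pwm_self(self, frag21):
        pwm = build_pwm([frag21])
        vec = encode_pwm(frag21, pwm)
        assert len(vec) == 21
        assert np.all(vec.values == 1.0)

    def test_encode_pwm_unseen_residue_zero(self, frag21):
        pwm = build_pwm([frag21])
        other = make_fragment("W" + "A" * 9 + "C" + "A" * 10)
        assert encode_pwm(other, pwm).values[0] == 0.0

    def test_encode_pwm_length_mismatch(self, frag21):
        pwm = build_pwm([frag21])
        with pytest.raises(ValueError):
            encode_pwm(make_fragment("ACA"), pwm)


class TestPSSMEncoding:
    def _profile(self, length=30, fill=0.0):
        return PSSMProfile("p", np.full((length, 20), fill), AA_ORDER)

    def test_zero_score_maps_to_half(self):
        frag = make_fragment("A" * 10 + "C" + "A" * 10, center=15)
        vec = encode_pssm(frag, self._profile())
        assert len(vec) == 420
        assert np.all(vec.values == 0.5)

    def test_padding_rows_zero(self):
        frag = make_fragment("X" * 8 + "MKCAG" + "X" * 8, protein_id="p", center=3)
        vec = encode_pssm(frag, self._profile(length=5))
        assert np.all(vec.values[:160] == 0.0)  # 8 all-X rows
        assert np.all(vec.values[160:260] == 0.5)  # 5 real rows at score 0
        assert np.all(vec.values[260:] == 0.0)

    def test_monotone_in_score(self):
        frag = make_fragment("A" * 10 + "C" + "A" * 10, center=15)
        lo = encode_pssm(frag, self._profile(fill=-1.0)).values
        hi = encode_pssm(frag, self._profile(fill=2.0)).values
        assert np.all(hi > lo)

    def test_center_outside_profile_errors(self):
        frag = make_fragment("A" * 10 + "C" + "A" * 10, center=50)
        with pytest.raises(ValueError):
            encode_pssm(frag, self._profile(length=30))


class TestAAIndexEncoding:
    def test_homopolymer_constant(self, hydro_entry):
        frag = make_fragment("C" * 21)
        vec = encode_aaindex(frag, hydro_entry)
        assert len(vec) == 21
        assert len(set(vec.values.tolist())) == 1

    def test_zscore_mean_zero(self, hydro_entry):
        values = hydro_entry.vector()
        z = (values - values.mean()) / values.std()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_x_positions_zero(self, hydro_entry):
        frag = make_fragment("XCX")
        vec = encode_aaindex(frag, hydro_entry)
        assert vec.values[0] == 0.0 and vec.values[2] == 0.0

    def test_raw_mode(self, frag21, hydro_entry):
        vec = encode_aaindex(frag21, hydro_entry, normalize="raw")
        assert vec.values[0] == pytest.approx(hydro_entry.values["A"])

    def test_na_entry_errors(self, frag21):
        from cyspred.io_formats import AAIndexEntry
        entry = AAIndexEntry("NA0000001", "incomplete", {"A": 1.0}, has_na=True)
        with pytest.raises(ValueError):
            encode_aaindex(frag21, entry)


class TestTrackEncoding:
    def test_asa_scaling(self):
        frag = make_fragment("ACA", protein_id="p", center=2)
        track = ResidueTrack("p", "ASA", (50.0, 120.0, 25.0))
        vec = encode_track(frag, track)
        assert vec.values.tolist() == [0.5, 1.0, 0.25]  # >100% clipped

    def test_ss_one_hot(self):
        frag = make_fragment("ACA", protein_id="p", center=2)
        track = ResidueTrack("p", "SS", ("H", "E", "C"))
        vec = encode_track(frag, track)
        assert vec.values.reshape(3, 3).tolist() == [
            [1, 0, 0], [0, 1, 0], [0, 0, 1],
        ]

    def test_padding_positions_zero(self):
        frag = make_fragment("XXCAG", protein_id="p", center=1)
        track = ResidueTrack("p", "ASA", (40.0, 40.0, 40.0))
        vec = encode_track(frag, track)
        assert vec.values.tolist() == [0.0, 0.0, 0.4, 0.4, 0.4]

    def test_protein_mismatch_errors(self):
        frag = make_fragment("ACA", protein_id="p", center=2)
        with pytest.raises(ValueError):
            encode_track(frag, ResidueTrack("q", "ASA", (1.0, 2.0, 3.0)))


class TestConcat:
    def test_lengths_add(self, frag21, hydro_entry):
        pssm = encode_pssm(
            make_fragment("A" * 10 + "C" + "A" * 10, center=15),
            PSSMProfile("p", np.zeros((30, 20)), AA_ORDER),
        )
        blocks = [pssm] + [
            FeatureVector(
                [f"idx{i}:{n}" for n in encode_aaindex(frag21, hydro_entry).names],
                encode_aaindex(frag21, hydro_entry).values,
            )
            for i in range(12)
        ]
        combined = concat_features(blocks)
        assert len(combined) == 420 + 12 * 21

    def test_single_input_identity(self, frag21):
        vec = encode_aac(frag21)
        out = concat_features([vec])
        assert out.names == vec.names
        assert np.array_equal(out.values, vec.values)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            concat_features([])

    def test_duplicate_names_error(self, frag21):
        vec = encode_aac(frag21)
        with pytest.raises(ValueError, match="duplicate"):
            concat_features([vec, vec])


class TestRegistry:
    def test_simple_names(self, frag21):
        assert len(make_encoder("binary")(frag21)) == 420
        assert len(make_encoder("aac")(frag21)) == 21

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            make_encoder("nope")

    def test_pssm_requires_profiles(self):
        with pytest.raises(ValueError):
            make_encoder("pssm")

    def test_missing_profile_named_in_error(self, frag21):
        enc = make_encoder("pssm", profiles={})
        with pytest.raises(ValueError, match=frag21.protein_id):
            enc(frag21)

    def test_encode_matrix(self, frag21):
        X, names = encode_matrix([frag21, frag21], make_encoder("aac"))
        assert X.shape == (2, 21)
        assert len(names) == 21


def vec_block(vec, position):
    return [int(v) for v in vec.values[position * 20 : (position + 1) * 20]]
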