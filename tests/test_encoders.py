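"""The four encoding schemes: dimensions, exact values and PSSM statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nitrosite import (
    KSpacePairEncoder,
    PssmEncoder,
    PssmModel,
    SiteWindow,
    WindowFeaturizer,
    build_pssm,
    encode_combined,
    encode_kspace,
    encode_onehot,
    encode_pfr,
    encode_pssm,
    load_property_factors,
    position_symbol_pvalue,
)
from nitrosite.alphabet import AA20, ALPHABET
from nitrosite.encoders import kspace_pair_counts


def window41(center="Y"):
    return "A" * 20 + center + "A" * 20


class TestOneHot:
    def test_indicator_layout(self):
        fv = encode_onehot("-AY")
        assert len(fv.values) == 63
        blocks = fv.values.reshape(3, 21)
        assert blocks[0].argmax() == ALPHABET.index("-")
        assert blocks[1].argmax() == ALPHABET.index("A")
        assert blocks[2].argmax() == ALPHABET.index("Y")

    def test_length_41_window_is_861(self):
        assert len(encode_onehot(window41()).values) == 861

    @given(st.text(alphabet=ALPHABET, min_size=1, max_size=30))
    def test_binary_with_exactly_L_ones(self, pep):
        v = encode_onehot(pep).values
        assert set(np.unique(v)) <= {0.0, 1.0}
        assert v.sum() == len(pep)

    def test_unknown_symbol_reported_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            encode_onehot("AZA")


class TestPropertyFactors:
    def test_all_gap_window_is_zeros(self):
        assert np.all(encode_pfr("---").values == 0.0)
        assert len(encode_pfr("---").values) == 30

    def test_length_41_window_is_410(self):
        assert len(encode_pfr(window41()).values) == 410

    def test_block_equals_table_row(self):
        table = load_property_factors()
        fv = encode_pfr("A-C")
        np.testing.assert_allclose(fv.values[:10], table.loc["A"].to_numpy())
        np.testing.assert_allclose(fv.values[10:20], 0.0)
        np.testing.assert_allclose(fv.values[20:], table.loc["C"].to_numpy())

    def test_incomplete_table_rejected(self):
        table = load_property_factors().drop(index="A")
        from nitrosite import PropertyFactorEncoder

        with pytest.raises(ValueError, match="missing residues"):
            PropertyFactorEncoder(table=table).fit(["ACD"])


class TestKSpace:
    def test_three_space_pair_frequency(self):
        # ALKEY has exactly one pair with three intervening residues: A...Y
        v = encode_kspace("ALKEY", k_values=(3,)).values
        assert len(v) == 400
        idx = AA20.index("A") * 20 + AA20.index("Y")
        assert v[idx] == pytest.approx(1 / 3)  # 1 / (5 - 3 + 1)
        assert np.count_nonzero(v) == 1

    def test_adjacent_pairs(self):
        v = encode_kspace("ALKEY", k_values=(0,)).values
        for a, b in ["AL", "LK", "KE", "EY"]:
            assert v[AA20.index(a) * 20 + AA20.index(b)] == pytest.approx(1 / 6)
        assert np.count_nonzero(v) == 4

    def test_default_k_range_gives_2000(self):
        assert len(encode_kspace(window41()).values) == 2000

    def test_terminal_gaps_stripped_before_counting(self):
        gapped = encode_kspace("--ALKEY--", k_values=(0,)).values
        plain = encode_kspace("ALKEY", k_values=(0,)).values
        np.testing.assert_allclose(gapped, plain)

    def test_k_too_large_gives_zero_block(self):
        v = encode_kspace("AY", k_values=(4,)).values
        assert np.all(v == 0.0)

    @given(
        st.text(alphabet=AA20, min_size=2, max_size=12),
        st.integers(min_value=0, max_value=4),
    )
    def test_counts_match_exhaustive_enumeration(self, pep, k):
        counts = kspace_pair_counts(pep, k)
        brute = np.zeros(400)
        for i in range(len(pep)):
            for j in range(len(pep)):
                if j - i == k + 1:
                    brute[AA20.index(pep[i]) * 20 + AA20.index(pep[j])] += 1
        np.testing.assert_array_equal(counts, brute)


class TestPValue:
    def test_equal_means_give_one(self):
        assert position_symbol_pvalue(3, 10, 6, 20) == 1.0
        assert position_symbol_pvalue(0, 10, 0, 20) == 1.0

    def test_degenerate_zero_variance_hits_floor(self):
        assert position_symbol_pvalue(10, 10, 0, 10) == pytest.approx(1e-6)

    def test_matches_welch_on_explicit_vectors(self):
        # oracle: scipy Welch t-test on the expanded binary indicator vectors
        a = np.array([1] * 8 + [0] * 2, dtype=float)
        b = np.array([1] * 2 + [0] * 8, dtype=float)
        expected = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert position_symbol_pvalue(8, 10, 2, 10) == pytest.approx(expected, rel=1e-12)

    @given(
        st.integers(0, 15),
        st.integers(0, 12),
        st.integers(2, 15),
        st.integers(2, 12),
    )
    def test_always_matches_welch_oracle(self, c1, c2, n1, n2):
        c1, c2 = min(c1, n1), min(c2, n2)
        a = np.array([1] * c1 + [0] * (n1 - c1), dtype=float)
        b = np.array([1] * c2 + [0] * (n2 - c2), dtype=float)
        got = position_symbol_pvalue(c1, n1, c2, n2)
        if c1 * n2 == c2 * n1:
            assert got == 1.0
        elif a.var() == 0 and b.var() == 0:
            assert got == pytest.approx(1e-6)
        else:
            expected = stats.ttest_ind(a, b, equal_var=False).pvalue
            assert got == pytest.approx(max(1e-6, expected), rel=1e-9)

    def test_too_small_classes_rejected(self):
        with pytest.raises(ValueError):
            position_symbol_pvalue(1, 1, 0, 10)


def _ds_from(peptides, labels):
    from nitrosite.io import LabeledDataset, SiteWindow

    L = len(peptides[0])
    windows = [
        SiteWindow("p", i + 1, peptides[0][L // 2], pep,
                   "positive" if lab else "negative")
        for i, (pep, lab) in enumerate(zip(peptides, labels))
    ]
    return LabeledDataset(windows, "Y-nitration", L)


class TestBuildPssm:
    def test_identical_class_distributions_give_zero_E(self):
        peps = ["KAYAC", "CAYAK"]
        ds = _ds_from(peps + peps, [1, 1, 0, 0])
        model = build_pssm(ds)
        np.testing.assert_array_equal(model.E, 0.0)

    def test_sign_follows_class_preference(self):
        pos = ["KYA"] * 4
        neg = ["AYA"] * 4
        model = build_pssm(_ds_from(pos + neg, [1] * 4 + [0] * 4))
        col = 0  # position immediately left of center
        assert model.E[ALPHABET.index("K"), col] > 0
        assert model.E[ALPHABET.index("A"), col] < 0

    def test_center_column_dropped(self):
        model = build_pssm(
            _ds_from(["KYA", "RYC", "AYA", "CYC"], [1, 1, 0, 0])
        )
        assert model.E.shape == (21, 2)
        assert model.center_index == 2

    def test_41_window_has_40_columns(self, small_planted):
        ds, _ = small_planted
        model = build_pssm(ds)
        assert model.E.shape == (21, ds.window_length - 1)

    def test_frequency_columns_sum_to_one(self, small_planted):
        ds, _ = small_planted
        model = build_pssm(ds)
        np.testing.assert_allclose(model.F_pos.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(model.F_neg.sum(axis=0), 1.0, atol=1e-12)

    def test_sign_of_E_matches_frequency_difference(self, small_planted):
        ds, _ = small_planted
        model = build_pssm(ds)
        np.testing.assert_array_equal(
            np.sign(model.E), np.sign(model.F_pos - model.F_neg)
        )

    def test_swap_antisymmetry(self, small_planted):
        ds, _ = small_planted
        m1 = build_pssm(ds.peptides, ds.labels)
        m2 = build_pssm(ds.peptides, [1 - l for l in ds.labels])
        np.testing.assert_allclose(m1.E, -m2.E, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            build_pssm(["KYA", "AYA", "CYA"], [1, 1, 1])

    def test_p_values_in_unit_interval(self, small_planted):
        ds, _ = small_planted
        model = build_pssm(ds)
        assert model.P.min() >= 1e-6
        assert model.P.max() <= 1.0


class TestEncodePssm:
    def test_length_and_center_irrelevance(self):
        model = build_pssm(_ds_from(["KYA", "RYC", "AYA", "CYC"], [1, 1, 0, 0]))
        v1 = encode_pssm("KYC", model).values
        assert len(v1) == 2
        # same flanks, any center: identical encodings
        v2 = model.encode("KWC")
        np.testing.assert_array_equal(v1, v2)

    def test_zero_under_identical_training_classes(self):
        peps = ["KAYAC", "CAYAK"]
        model = build_pssm(_ds_from(peps + peps, [1, 1, 0, 0]))
        np.testing.assert_array_equal(encode_pssm("RAYAR", model).values, 0.0)

    def test_length_mismatch_rejected(self):
        model = build_pssm(_ds_from(["KYA", "RYC", "AYA", "CYC"], [1, 1, 0, 0]))
        with pytest.raises(ValueError, match="length"):
            model.encode("KAYAC")


class TestPssmSerialization:
    def test_round_trip(self, tmp_path, small_planted):
        ds, _ = small_planted
        model = build_pssm(ds)
        path = tmp_path / "model.pssm.tsv"
        model.save(path)
        loaded = PssmModel.load(path)
        np.testing.assert_array_equal(model.E, loaded.E)
        np.testing.assert_array_equal(model.P, loaded.P)
        assert (loaded.L, loaded.n_pos, loaded.n_neg) == (
            model.L,
            model.n_pos,
            model.n_neg,
        )

    def test_garbage_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("not a model\n")
        with pytest.raises(ValueError, match="not a recognized"):
            PssmModel.load(path)


class TestCombined:
    def test_all_four_schemes_give_3311(self):
        model = build_pssm(_ds_from41())
        fv = encode_combined(
            window41_obj(), ("onehot", "pfr", "kspace", "pssm"), pssm_model=model
        )
        assert len(fv.values) == 3311
        assert [t for t, _ in fv.scheme_tags] == ["onehot", "pfr", "kspace", "pssm"]
        assert [n for _, n in fv.scheme_tags] == [861, 410, 2000, 40]

    def test_kspace_plus_pssm_gives_2040(self):
        model = build_pssm(_ds_from41())
        fv = encode_combined(window41_obj(), ("kspace", "pssm"), pssm_model=model)
        assert len(fv.values) == 2040

    def test_pssm_alone_gives_40(self):
        model = build_pssm(_ds_from41())
        fv = encode_combined(window41_obj(), ("pssm",), pssm_model=model)
        assert len(fv.values) == 40

    def test_missing_pssm_context_rejected(self):
        with pytest.raises(ValueError, match="pssm"):
            encode_combined(window41_obj(), ("kspace", "pssm"))

    def test_featurizer_requires_labels_for_pssm(self):
        with pytest.raises(ValueError, match="labels"):
            WindowFeaturizer(schemes=("pssm",)).fit([window41()])


def window41_obj():
    return SiteWindow("p", 21, "Y", window41(), "unknown")


def _ds_from41():
    rng = np.random.default_rng(0)
    peps = []
    for _ in range(8):
        chars = rng.choice(list(AA20), size=41)
        chars[20] = "Y"
        peps.append("".join(chars))
    return _ds_from(peps, [1, 1, 1, 1, 0, 0, 0, 0])
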