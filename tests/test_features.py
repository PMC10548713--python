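import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import equations_oracle as oracle
import rmethyl as rm
from rmethyl import features as ft
from rmethyl import constants

AA = sorted("ACDEFGHIKLMNPQRSTVWY")
window_text = st.text(alphabet=AA, min_size=11, max_size=11).map(
    lambda s: s[:5] + "R" + s[6:]
)


class TestComposition:
    def test_aac_glycine_window(self):
        v = rm.aac("GGGGGRGGGGG")
        names = rm.feature_names(("AAC",))
        assert v[names.index("AAC_G")] == pytest.approx(10 / 11)
        assert v[names.index("AAC_R")] == pytest.approx(1 / 11)
        assert np.count_nonzero(v) == 2

    def test_aac_padded_window_keeps_full_denominator(self):
        v = rm.aac("XXXXXRGGGGX")
        names = rm.feature_names(("AAC",))
        assert v[names.index("AAC_R")] == pytest.approx(1 / 11)
        assert v[names.index("AAC_G")] == pytest.approx(4 / 11)
        assert v.sum() == pytest.approx(5 / 11)

    @given(window_text)
    @settings(max_examples=50, deadline=None)
    def test_padfree_aac_sums_to_one(self, w):
        assert rm.aac(w).sum() == pytest.approx(1.0)

    def test_dpc_counts_adjacent_pairs(self):
        v = rm.dpc("GGGGGRGGGGG")
        names = rm.feature_names(("DPC",))
        assert v[names.index("DPC_GG")] == pytest.approx(8 / 11)
        assert v[names.index("DPC_GR")] == pytest.approx(1 / 11)
        assert v[names.index("DPC_RG")] == pytest.approx(1 / 11)
        assert v.sum() == pytest.approx(10 / 11)

    def test_dpc_skips_pad_pairs(self):
        v = rm.dpc("XXXXXRGGGGX")
        names = rm.feature_names(("DPC",))
        assert v[names.index("DPC_RG")] == pytest.approx(1 / 11)
        assert v[names.index("DPC_GG")] == pytest.approx(3 / 11)
        assert v.sum() == pytest.approx(4 / 11)

    def test_dpc_alternative_denominator(self):
        v = rm.dpc("GGGGGRGGGGG", denominator="l-1")
        assert v.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            rm.dpc("GGGGGRGGGGG", denominator="n")

    def test_dpc_is_order_sensitive(self):
        # composition-identical windows with different adjacency
        a, b = "GAGAGRGAGAG", "AAGGGRGGGAA"
        assert sorted(a) == sorted(b)
        assert not np.allclose(rm.dpc(a), rm.dpc(b))


class TestEntropies:
    def test_homopolymer_entropies_are_zero(self):
        v = rm.itb_features("AAAAAAAAAAA")
        assert np.allclose(v, 0.0)

    def test_uniform_profile_analytics(self):
        prof = rm.CompositionProfile(np.full(20, 1 / 20), 20)
        block = rm.entropy_block(prof)
        assert block["SE"] == pytest.approx(math.log2(20))
        assert block["relative_SE"] == pytest.approx(0.0, abs=1e-12)
        assert block["information_gain"] == pytest.approx(math.log2(20))
        assert block["RE"] == pytest.approx(math.log2(20))
        # alpha = 2 closed forms
        assert block["HE"] == pytest.approx(1.9)
        assert block["AE"] == pytest.approx(19.0)

    def test_two_state_profile_shannon(self):
        prof = rm.composition_profile("GGGGGRGGGGG")
        block = rm.entropy_block(prof)
        expected = -(10 / 11) * math.log2(10 / 11) - (1 / 11) * math.log2(1 / 11)
        assert block["SE"] == pytest.approx(expected, abs=1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            rm.EntropyParams(alpha=1.0)
        with pytest.raises(ValueError):
            rm.EntropyParams(alpha=-0.5)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_generalized_entropies_converge_to_shannon(self, raw):
        # proper distribution (sums to 1): RE/HE/AE at alpha near 1 -> SE
        p = np.zeros(20)
        p[: len(raw)] = np.array(raw) / np.sum(raw)
        prof = rm.CompositionProfile(p, 20)
        se = rm.entropy_block(prof, rm.EntropyParams(alpha=2.0))["SE"]
        for alpha in (1 + 1e-4, 1 - 1e-4):
            block = rm.entropy_block(prof, rm.EntropyParams(alpha=alpha))
            assert block["RE"] == pytest.approx(se, abs=1e-3)
            assert block["HE"] == pytest.approx(se, abs=1e-3)
            assert block["AE"] == pytest.approx(se, abs=1e-3)

    @given(window_text, st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_itb_block_is_permutation_invariant(self, w, seed):
        perm = "".join(np.random.default_rng(seed).permutation(list(w)))
        assert np.allclose(rm.itb_features(w), rm.itb_features(perm))
        assert rm.itb_features(w).shape == (4,)


class TestPhysicochemical:
    def test_extinction_coefficient_cases(self):
        assert ft.extinction_coefficient("GGGGGRGGGGG") == 0
        assert ft.extinction_coefficient("GGGGGRGGGGG", oxidized=True) == 0
        # 1 Trp + 1 Tyr + 2 Cys, oxidized: 5500 + 1490 + 125
        assert ft.extinction_coefficient("WYCCGRGGGGG", oxidized=True) == 7115
        assert ft.extinction_coefficient("WYCCGRGGGGG", oxidized=False) == 6990

    @given(window_text)
    @settings(max_examples=50, deadline=None)
    def test_reduced_never_exceeds_oxidized(self, w):
        assert ft.extinction_coefficient(w) <= ft.extinction_coefficient(w, oxidized=True)

    def test_instability_index_with_stubbed_table(self, monkeypatch):
        monkeypatch.setattr(constants, "diwv", lambda: {a + b: 3.0 for a in AA for b in AA})
        assert ft.instability_index("GGGGGRGGGGG") == pytest.approx(10 / 11 * 10 * 3.0)

    def test_instability_index_matches_lookup_oracle(self):
        w = "AAAAARAAAAA"
        assert ft.instability_index(w) == pytest.approx(oracle.instability_index(w), abs=1e-9)

    def test_instability_threshold_rule(self):
        assert not ft.is_unstable(40.0)
        assert ft.is_unstable(40.0001)

    def test_instability_requires_two_residues(self):
        with pytest.raises(ValueError):
            ft.instability_index("XXXXXRXXXXX")

    def test_gravy_known_values(self):
        assert ft.gravy("AAAAAAAAAAA") == pytest.approx(1.8)
        assert ft.gravy("GGGGGRGGGGG") == pytest.approx((10 * -0.4 - 4.5) / 11)

    def test_gravy_mean_property(self):
        base = ft.gravy("GGGGGRGGGGG")
        # appending a residue whose hydropathy equals the current mean is a no-op
        # (no residue has that exact value, so check the identity numerically)
        kd = constants.hydropathy()
        seq = "GGGGGRGGGGG"
        total = sum(kd[r] for r in seq)
        assert (total + base) / 12 == pytest.approx(base)

    def test_molecular_weight_glycine_window(self):
        masses = constants.residue_masses()
        expected = (
            10 * (masses["G"] - constants.WATER_MASS)
            + (masses["R"] - constants.WATER_MASS)
            + constants.WATER_MASS
        )
        assert ft.molecular_weight("GGGGGRGGGGG") == pytest.approx(expected)

    def test_aromaticity_cases(self):
        assert ft.aromaticity("GGGGGRGGGGG") == 0.0
        assert ft.aromaticity("FGGGGRGGGGG") == pytest.approx(1 / 11)

    def test_pp_block_shape_and_layout(self):
        v = ft.pp_features("WYCCGRGGGGG")
        assert v.shape == (10,)
        names = rm.feature_names(("PP",))
        assert v[names.index("PP_EX_RED")] == 6990
        assert v[names.index("PP_EX_OX")] == 7115

    @pytest.mark.parametrize("seed", range(5))
    def test_pp_matches_biopython_protparam(self, seed):
        """Independent cross-check against Bio.SeqUtils.ProtParam."""
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = np.random.default_rng(seed)
        for _ in range(40):
            w = "".join(rng.choice(AA, 11))
            w = w[:5] + "R" + w[6:]
            pa = ProteinAnalysis(w)
            assert ft.gravy(w) == pytest.approx(pa.gravy(), abs=1e-9)
            assert ft.aromaticity(w) == pytest.approx(pa.aromaticity(), abs=1e-9)
            assert ft.instability_index(w) == pytest.approx(pa.instability_index(), abs=1e-9)
            assert ft.molecular_weight(w) == pytest.approx(pa.molecular_weight(), abs=1e-6)
            red, ox = pa.molar_extinction_coefficient()
            assert ft.extinction_coefficient(w) == red
            assert ft.extinction_coefficient(w, oxidized=True) == ox
            # biopython's pI search is clamped to [4.05, 12]; compare inside it
            bp_pi = pa.isoelectric_point()
            if 4.1 < bp_pi < 11.9:
                assert ft.isoelectric_point(w) == pytest.approx(bp_pi, abs=0.02)


class TestEncodeWindow:
    def test_vector_length_and_block_boundaries(self):
        v = rm.encode_window("GGGGGRGGGGG")
        names = rm.feature_names()
        assert v.shape == (434,)
        assert len(names) == 434 and len(set(names)) == 434
        assert names[0] == "AAC_A"
        assert names[20] == "DPC_AA"
        assert names[420] == "ITB_SE"
        assert names[424] == "PP_pI"
        assert rm.BLOCKS == {"AAC": (0, 20), "DPC": (20, 420), "ITB": (420, 424), "PP": (424, 434)}

    def test_identical_windows_encode_identically(self):
        a = rm.encode_window("MARAGRKLRAA"[:11])
        b = rm.encode_window("MARAGRKLRAA"[:11])
        assert np.array_equal(a, b)

    @given(window_text, st.integers(0, 3), st.integers(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_encoding_is_finite_even_when_padded(self, w, pad_l, pad_r):
        padded = "X" * pad_l + w[pad_l:11 - pad_r] + "X" * pad_r
        assert len(padded) == 11 and padded[5] == "R"
        v = rm.encode_window(padded)
        assert np.all(np.isfinite(v))

    def test_block_subsets_have_expected_widths(self):
        assert rm.encode_window("GGGGGRGGGGG", blocks=("AAC",)).shape == (20,)
        assert rm.encode_window("GGGGGRGGGGG", blocks=("AAC", "DPC")).shape == (420,)
        assert rm.encode_window("GGGGGRGGGGG", blocks=("ITB",)).shape == (4,)

    def test_encode_dataset_layout(self, planted_dataset):
        df = rm.encode_dataset(rm.LabeledDataset(windows=planted_dataset.windows[:8]))
        assert df.shape == (8, 435)
        assert df.columns[0] == "label"
        assert list(df.columns[1:]) == rm.feature_names()
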