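"""Window extraction, mutation application and one-hot encoding."""

import numpy as np
import pytest

from varcons.curation import AA1_TO_3, ProteinVariant, VariantClass, parse_hgvs_p
from varcons.featurize import (FeaturizerConfig, ReferenceMismatchError,
                               apply_mutation, build_example, center_residue,
                               decode_window, encode_window, extract_window,
                               slice_profile, SNVBOX_DIM)
from varcons.simulate import reachable_missense

L5 = FeaturizerConfig(window_length=5)


def mk_missense(pos, ref, alt, tx="T1"):
    return ProteinVariant(tx, f"p.{AA1_TO_3[ref]}{pos}{AA1_TO_3[alt]}",
                          VariantClass.MISSENSE, pos, ref, alt)


class TestCenterResidue:
    def test_class_conventions(self):
        assert center_residue(parse_hgvs_p("p.Gly54Glu")) == 54
        assert center_residue(parse_hgvs_p("p.Gly2_Met46del")) == 46
        assert center_residue(parse_hgvs_p("p.Tyr5Ter")) == 5
        assert center_residue(parse_hgvs_p("p.Thr7fs")) == 7
        assert center_residue(parse_hgvs_p("p.Gly10_Lys12del")) == 10


class TestExtractWindow:
    def test_interior_window(self):
        assert extract_window("MKTAYIAKQR", 5, L5) == "TAYIA"

    def test_left_overhang_padded(self):
        assert extract_window("MKTAYIAKQR", 2, L5) == "-MKTA"

    def test_right_overhang_padded(self):
        assert extract_window("MKTAYIAKQR", 10, L5) == "KQR--"

    def test_window_of_one(self):
        assert extract_window("MKTAYIAKQR", 5,
                              FeaturizerConfig(window_length=1)) == "Y"

    def test_center_out_of_range(self):
        with pytest.raises(IndexError):
            extract_window("MKTA", 5, L5)


class TestApplyMutation:
    def test_missense_substitutes_center(self):
        v = mk_missense(5, "Y", "F")
        assert apply_mutation("TAYIA", v, L5) == "TAFIA"

    def test_missense_reference_mismatch(self):
        v = mk_missense(5, "W", "F")
        with pytest.raises(ReferenceMismatchError):
            apply_mutation("TAYIA", v, L5)

    def test_stop_gain_pads_center_and_beyond(self):
        v = parse_hgvs_p("p.Tyr5Ter")
        assert apply_mutation("TAYIA", v, L5) == "TA---"

    def test_stop_site_retention_is_configurable(self):
        cfg = FeaturizerConfig(window_length=5, pad_stop_site=False)
        v = parse_hgvs_p("p.Tyr5Ter")
        assert apply_mutation("TAYIA", v, cfg) == "TAY--"

    def test_frameshift_same_as_stop_gain(self):
        v = parse_hgvs_p("p.Tyr5fs")
        assert apply_mutation("TAYIA", v, L5) == "TA---"

    def test_start_lost_pads_before_center(self):
        v = parse_hgvs_p("p.Gly2_Tyr5del")  # start-lost anchored at 5
        assert v.variant_class is VariantClass.START_LOST
        assert apply_mutation("TAYIA", v, L5) == "--YIA"

    def test_deletion_pads_span_in_place(self):
        v = parse_hgvs_p("p.Tyr5_Ile6del")  # centred at 5, span 5..6
        assert apply_mutation("TAYIA", v, L5) == "TA--A"


class TestEncoding:
    def test_one_hot_and_pad_rows(self):
        cfg = FeaturizerConfig(window_length=1)
        m = encode_window("A", cfg)
        assert m.shape == (1, 20) and m.sum() == 1.0 and m[0, 0] == 1.0
        assert encode_window("-", cfg).sum() == 0.0
        assert encode_window("X", cfg).sum() == 0.0

    def test_row_sums_binary(self):
        m = encode_window("TA-IA", L5)
        assert set(m.sum(axis=1).tolist()) <= {0.0, 1.0}

    def test_round_trip(self):
        for w in ("TAYIA", "--YIA", "TA---", "A-C-D"):
            assert decode_window(encode_window(w, L5), L5) == w


class TestSliceProfile:
    def test_overhang_rows_zero(self, small_world):
        tx, _, _, profile = small_world[0]
        mat = slice_profile(profile, 2, L5)
        assert mat.shape == (5, 20)
        assert mat[0].sum() == 0.0  # position -1 outside transcript
        # interior reliable rows sum to ~1
        if profile.reliable[2]:
            assert mat[3].sum() == pytest.approx(1.0, abs=1e-6)

    def test_unreliable_rows_zero(self):
        from varcons.msa import Alignment, build_profile
        prof = build_profile(Alignment("ACDEF", ("ACDEF",) * 5))  # depth 5
        mat = slice_profile(prof, 3, L5)
        assert mat.sum() == 0.0


class TestBuildExample:
    def test_snvbox_zero_filled_when_missing(self, small_world):
        tx, _, _, profile = small_world[0]
        v = mk_missense(10, tx.protein[9],
                        sorted(reachable_missense(tx.codon(10)))[0],
                        tx.transcript_id)
        ex = build_example(v, tx.protein, profile, snvbox_lookup={}, cfg=L5)
        assert ex.snvbox.shape == (SNVBOX_DIM,)
        assert ex.snvbox.sum() == 0.0

    def test_missense_differs_only_at_center(self, small_world):
        tx, _, _, profile = small_world[0]
        v = mk_missense(10, tx.protein[9],
                        sorted(reachable_missense(tx.codon(10)))[0],
                        tx.transcript_id)
        ex = build_example(v, tx.protein, profile, cfg=L5)
        diff = np.flatnonzero((ex.wt_mat != ex.mut_mat).any(axis=1))
        assert diff.tolist() == [2]


@pytest.fixture(scope="module")
def random_variants(small_world):
    """>=1000 random variants covering all five classes."""
    rng = np.random.default_rng(123)
    out = []
    classes = ["missense", "stop_gain", "frameshift", "start_lost", "deletion"]
    while len(out) < 1100:
        tx, _, _, profile = small_world[int(rng.integers(0, len(small_world)))]
        n = len(tx.protein)
        cls = classes[int(rng.integers(0, len(classes)))]
        pos = int(rng.integers(1, n + 1))
        ref = tx.protein[pos - 1]
        r3 = AA1_TO_3[ref]
        if cls == "missense":
            alts = sorted(reachable_missense(tx.codon(pos)))
            if not alts:
                continue
            alt = alts[int(rng.integers(0, len(alts)))]
            term = f"p.{r3}{pos}{AA1_TO_3[alt]}"
        elif cls == "stop_gain":
            term = f"p.{r3}{pos}Ter"
        elif cls == "frameshift":
            term = f"p.{r3}{pos}fs"
        elif cls == "start_lost":
            if n < 3:
                continue
            pos = int(rng.integers(3, n + 1))
            term = f"p.{AA1_TO_3[tx.protein[1]]}2_{AA1_TO_3[tx.protein[pos-1]]}{pos}del"
        else:  # deletion
            if pos < 3:
                continue
            end = min(n, pos + int(rng.integers(0, 5)))
            term = (f"p.{r3}{pos}del" if end == pos else
                    f"p.{r3}{pos}_{AA1_TO_3[tx.protein[end-1]]}{end}del")
        out.append((parse_hgvs_p(term, tx.transcript_id), tx, profile))
    return out


class TestInvariantsAcrossClasses:
    def test_shapes_row_sums_and_padding_conventions(self, random_variants):
        cfg = FeaturizerConfig(window_length=21)
        h = cfg.half
        seen = set()
        for v, tx, profile in random_variants:
            ex = build_example(v, tx.protein, profile, cfg=cfg)
            seen.add(v.variant_class)
            for mat in (ex.wt_mat, ex.mut_mat):
                assert mat.shape == (21, 20)
                assert set(np.round(mat.sum(axis=1), 6).tolist()) <= {0.0, 1.0}
            msa_sums = ex.msa_mat.sum(axis=1)
            assert np.all((np.abs(msa_sums - 1) < 1e-5) | (np.abs(msa_sums) < 1e-9))
            wt = decode_window(ex.wt_mat, cfg)
            mut = decode_window(ex.mut_mat, cfg)
            cls = v.variant_class
            if cls is VariantClass.MISSENSE:
                assert sum(a != b for a, b in zip(wt, mut)) == 1
                assert wt[h] != mut[h]
            elif cls in (VariantClass.STOP_GAIN, VariantClass.FRAMESHIFT):
                assert mut[h:] == "-" * (21 - h)
                assert mut[:h] == wt[:h]
            elif cls is VariantClass.START_LOST:
                assert mut[:h] == "-" * h
                assert mut[h:] == wt[h:]
            else:  # deletion: contiguous pad block at the deleted span
                assert mut[h] == "-"
                diff = [i for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
                assert diff == list(range(diff[0], diff[-1] + 1))
        assert len(seen) == 5
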