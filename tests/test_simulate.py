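"""Simulated-variant generation under single-nucleotide codon constraints."""

import itertools

import numpy as np
import pytest

from varcons.curation import VariantClass
from varcons.msa import AA_INDEX, Alignment, MsaFilterConfig, build_profile
from varcons.simulate import (CODON_TO_AA, STOP_CODONS, CodingTranscript,
                              SimConfig, SimLabel, SimulatedVariant,
                              classify_candidate, enumerate_candidates,
                              reachable_missense, sample_simulated,
                              simulate_transcript)


def brute_force_reachable(codon: str) -> set[str]:
    """Independent enumeration through the standard codon table."""
    ref = CODON_TO_AA[codon]
    out = set()
    for i, nt in itertools.product(range(3), "ACGT"):
        alt = codon[:i] + nt + codon[i + 1:]
        if alt != codon and alt not in STOP_CODONS and CODON_TO_AA[alt] != ref:
            out.add(CODON_TO_AA[alt])
    return out


class TestReachableMissense:
    def test_worked_examples(self):
        assert reachable_missense("GGA") == {"R", "E", "A", "V"}
        assert reachable_missense("ATG") == {"L", "V", "K", "T", "R", "I"}

    def test_all_61_codons_match_brute_force(self):
        for codon in sorted(set(CODON_TO_AA) - STOP_CODONS):
            got = reachable_missense(codon)
            assert got == brute_force_reachable(codon), codon
            assert CODON_TO_AA[codon] not in got

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reachable_missense("GGN")
        with pytest.raises(ValueError):
            reachable_missense("TAA")  # stop codon


class TestEnumerateCandidates:
    def test_single_codon_transcript(self):
        tx = CodingTranscript("T1", "G", "GGA")
        cands = enumerate_candidates(tx)
        assert {v.alt_aa for v in cands} == {"R", "E", "A", "V"}
        assert all(v.variant_class is VariantClass.MISSENSE for v in cands)

    def test_empty_transcript(self):
        assert enumerate_candidates(CodingTranscript("T0", "", "")) == []

    def test_deterministic_order_and_per_residue_bound(self):
        tx = CodingTranscript("T2", "MG", "ATGGGA")
        cands = enumerate_candidates(tx)
        assert cands == enumerate_candidates(tx)
        key = [(v.position, v.alt_aa) for v in cands]
        assert key == sorted(key)
        for pos in (1, 2):
            assert sum(1 for v in cands if v.position == pos) <= 9

    def test_translation_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CodingTranscript("T3", "MA", "ATGGGA")  # GGA is Gly, not Ala


def _profile_from_rows(query: str, rows: list[str], min_depth=10):
    return build_profile(Alignment(query, tuple(rows)),
                         MsaFilterConfig(min_depth=min_depth))


class TestClassifyCandidate:
    def setup_method(self):
        from varcons.curation import AA1_TO_3, ProteinVariant
        self.mk = lambda pos, ref, alt: ProteinVariant(
            "T1", f"p.{AA1_TO_3[ref]}{pos}{AA1_TO_3[alt]}",
            VariantClass.MISSENSE, pos, ref, alt)

    def test_conserved_residue_gives_pathogenic_like(self):
        # freq {A: 0.6, S: 0.4}; A->W hits a conserved residue
        prof = _profile_from_rows("A", ["A"] * 8 + ["S"] * 6, min_depth=10)
        assert prof.freq[0, AA_INDEX["A"]] == pytest.approx(0.6)
        assert classify_candidate(self.mk(1, "A", "W"), prof) is SimLabel.PATHOGENIC_LIKE

    def test_tolerated_alt_is_benign_first_by_default(self):
        prof = _profile_from_rows("A", ["A"] * 8 + ["S"] * 6)
        assert classify_candidate(self.mk(1, "A", "S"), prof) is SimLabel.BENIGN_LIKE
        cfg = SimConfig(precedence="pathogenic_first")
        assert classify_candidate(self.mk(1, "A", "S"), prof, cfg) is SimLabel.PATHOGENIC_LIKE

    def test_neither_rule_gives_unlabeled(self):
        # freq approximately {A: 0.4, S: 0.35, T: 0.25}: no residue above 50%,
        # and a G substitution is unseen
        rows = ["A"] * 7 + ["S"] * 7 + ["T"] * 5
        prof = _profile_from_rows("A", rows)
        assert prof.freq[0].max() < 0.5
        assert classify_candidate(self.mk(1, "A", "G"), prof) is SimLabel.UNLABELED

    def test_unreliable_residue_gives_unlabeled(self):
        prof = _profile_from_rows("A", ["A"] * 5)  # depth 5 <= 10
        assert classify_candidate(self.mk(1, "A", "W"), prof) is SimLabel.UNLABELED

    def test_out_of_range_position(self):
        prof = _profile_from_rows("A", ["A"] * 12)
        with pytest.raises(IndexError):
            classify_candidate(self.mk(2, "A", "W"), prof)


class TestSampleSimulated:
    def _labeled(self, n):
        from varcons.curation import AA1_TO_3, ProteinVariant
        out = []
        for i in range(n):
            v = ProteinVariant("T1", f"p.Ala{i+1}Val", VariantClass.MISSENSE,
                               i + 1, "A", "V")
            out.append(SimulatedVariant(v, SimLabel.PATHOGENIC_LIKE))
        return out

    def test_exact_count_and_order_preserved(self):
        labeled = self._labeled(100)
        out = sample_simulated(labeled, SimConfig(sample_fraction=0.10, seed=0))
        assert len(out) == 10
        positions = [sv.variant.position for sv in out]
        assert positions == sorted(positions)

    def test_fraction_one_is_identity(self):
        labeled = self._labeled(7)
        assert sample_simulated(labeled, SimConfig(sample_fraction=1.0, seed=0)) == labeled

    def test_same_seed_reproduces(self):
        labeled = self._labeled(50)
        cfg = SimConfig(sample_fraction=0.3, seed=42)
        assert sample_simulated(labeled, cfg) == sample_simulated(labeled, cfg)

    def test_sampling_is_unbiased(self):
        labeled = self._labeled(20)
        hits = np.zeros(20)
        for seed in range(1000):
            out = sample_simulated(labeled, SimConfig(sample_fraction=0.5, seed=seed))
            for sv in out:
                hits[sv.variant.position - 1] += 1
        freq = hits / 1000
        assert np.all(np.abs(freq - 0.5) < 0.05)


class TestToyTranscriptEndToEnd:
    """Hand-built MSA on a short transcript vs brute-force enumeration."""

    def brute_force(self, tx, prof, cfg):
        expected = {}
        for pos in range(1, len(tx.protein) + 1):
            if not prof.reliable[pos - 1]:
                continue
            row = prof.freq[pos - 1]
            for alt in brute_force_reachable(tx.codon(pos)):
                benign = row[AA_INDEX[alt]] > cfg.benign_freq_threshold
                path = row.max() > cfg.conserved_threshold
                if benign:
                    expected[(pos, alt)] = SimLabel.BENIGN_LIKE
                elif path:
                    expected[(pos, alt)] = SimLabel.PATHOGENIC_LIKE
        return expected

    def test_labeled_sets_match_brute_force(self):
        # protein MGKW: conserved G (col 2), polymorphic K/R (col 3, R at 40%),
        # shallow col 4
        tx = CodingTranscript("TOY", "MGKW", "ATGGGAAAATGG")
        rows = []
        for i in range(15):
            k_or_r = "R" if i < 6 else "K"   # 6/15 = 40% arginine
            w = "W" if i < 8 else "-"        # depth 8 at column 4: unreliable
            rows.append("M" + "G" + k_or_r + w)
        prof = build_profile(Alignment(tx.protein, tuple(rows)))
        cfg = SimConfig(sample_fraction=1.0, seed=0)
        got = {(sv.variant.position, sv.variant.alt_aa): sv.sim_label
               for sv in simulate_transcript(tx, prof, cfg)}
        expected = self.brute_force(tx, prof, cfg)
        assert got == expected
        assert len(expected) > 0
        # every emitted variant is reachable by one nucleotide substitution
        for (pos, alt) in got:
            assert alt in brute_force_reachable(tx.codon(pos))
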