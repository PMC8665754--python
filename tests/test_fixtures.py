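"""Synthetic-fixture generators: planted structure and purity."""

import json

import numpy as np

from varcons.curation import CurationConfig, curate_report_table
from varcons.fixtures import (FixtureConfig, make_af_table,
                              make_clinical_labels, make_msa,
                              make_patient_cohort, make_report_table,
                              make_snvbox_table, make_training_bundle,
                              make_transcript, write_fixture_dir)
from varcons.metrics import top_k_recall
from varcons.msa import AA_INDEX, build_profile, filter_alignment
from varcons.simulate import CODON_TO_AA


class TestMakeTranscript:
    def test_translation_invariant_and_lengths(self, small_cfg):
        rng = np.random.default_rng(0)
        tx = make_transcript(small_cfg, rng)
        assert len(tx.cds) == 3 * len(tx.protein) == 3 * small_cfg.protein_length
        assert tx.protein[0] == "M"
        assert all(CODON_TO_AA[tx.codon(i)] == tx.protein[i - 1]
                   for i in range(1, len(tx.protein) + 1))

    def test_seed_determinism(self, small_cfg):
        a = make_transcript(small_cfg, np.random.default_rng(5))
        b = make_transcript(small_cfg, np.random.default_rng(5))
        assert (a.protein, a.cds) == (b.protein, b.cds)


class TestMakeMsa:
    def test_planted_conserved_columns_are_conserved(self, small_world):
        tx, aln, plan, profile = small_world[0]
        for pos in sorted(plan.conserved)[:20]:
            if profile.reliable[pos - 1]:
                assert profile.freq[pos - 1].max() > 0.5

    def test_planted_polymorphic_alt_frequency(self):
        cfg = FixtureConfig(n_transcripts=1, protein_length=150, msa_rows=150,
                            mean_segment_length=10, seed=3)
        rng = np.random.default_rng(cfg.seed)
        tx = make_transcript(cfg, rng)
        aln, plan = make_msa(tx, cfg, rng)
        profile = build_profile(filter_alignment(aln))
        freqs = []
        for pos, alt in plan.polymorphic.items():
            if profile.reliable[pos - 1]:
                f = profile.freq[pos - 1, AA_INDEX[alt]]
                assert abs(f - cfg.tolerated_alternative_freq) < 0.15
                assert f > 0.1  # above the benign-like rule by construction
                freqs.append(f)
        assert len(freqs) > 0
        # across >=100-row columns the planted frequency is recovered closely
        assert abs(np.mean(freqs) - cfg.tolerated_alternative_freq) < 0.05

    def test_bad_rows_removed_by_filter(self, small_world):
        _, aln, _, _ = small_world[0]
        kept = filter_alignment(aln)
        assert len(kept.rows) == len(aln.rows) - 3

    def test_seed_determinism(self, small_cfg):
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        t1 = make_transcript(small_cfg, r1)
        t2 = make_transcript(small_cfg, r2)
        a1, p1 = make_msa(t1, small_cfg, r1)
        a2, p2 = make_msa(t2, small_cfg, r2)
        assert a1.rows == a2.rows
        assert p1.conserved == p2.conserved and p1.polymorphic == p2.polymorphic


class TestClinicalLabels:
    def test_zero_noise_follows_planted_rule(self, small_cfg, small_world):
        tx, _, plan, profile = small_world[0]
        cfg = FixtureConfig(**{**small_cfg.__dict__, "label_noise": 0.0})
        out = make_clinical_labels(tx, profile, plan, cfg,
                                   np.random.default_rng(0))
        assert len(out) > 0
        for cv in out:
            pos = cv.variant.position
            if pos in plan.conserved:
                assert cv.label == "pathogenic"
            else:
                assert cv.label == "benign"

    def test_report_table_matches_expected_outcomes(self, small_cfg, small_world):
        transcripts = [w[0] for w in small_world]
        curated = []
        rng = np.random.default_rng(1)
        for tx, _, plan, profile in small_world:
            curated.extend(make_clinical_labels(tx, profile, plan, small_cfg, rng))
        reports, expected = make_report_table(transcripts, curated, small_cfg, rng)
        got_curated, outcomes = curate_report_table(reports, CurationConfig())
        assert outcomes == expected
        got_labels = {f"{cv.variant.transcript_id}:{cv.variant.hgvs_p}": cv.label
                      for cv in got_curated}
        for key, want in expected.items():
            if want == "EXCLUDED":
                assert key not in got_labels
            else:
                assert got_labels[key] == want


class TestAfTable:
    def test_composition(self, small_cfg, small_world):
        transcripts = [w[0] for w in small_world]
        rng = np.random.default_rng(2)
        tx, _, plan, profile = small_world[0]
        curated = make_clinical_labels(tx, profile, plan, small_cfg, rng)
        table = make_af_table(transcripts, curated, small_cfg, rng,
                              n_common=20, n_rare=10, n_overlap=5)
        assert len(table) == 35
        assert sum(1 for _, af in table if af > 0.001) == 25
        clin_keys = {cv.variant.key for cv in curated}
        assert sum(1 for v, _ in table if v.key in clin_keys) == 5


class TestPatientCohort:
    def test_every_patient_has_causal_and_recessive_counts(self, small_cfg):
        cohort = make_patient_cohort(small_cfg, np.random.default_rng(4))
        assert len(cohort.patients) == small_cfg.n_patients
        for scores, causal in cohort.patients:
            assert 1 <= sum(causal) <= 2
            assert len(scores) in (small_cfg.background_variants_per_patient + 1,
                                   small_cfg.background_variants_per_patient + 2)
        # causal variants are enriched at the top of the ranking
        assert top_k_recall(cohort, 5) > top_k_recall(cohort, 1)


class TestSnvboxTable:
    def test_coverage_and_shape(self, small_world):
        tx, _, plan, profile = small_world[0]
        cfg = FixtureConfig(seed=0)
        curated = make_clinical_labels(tx, profile, plan, cfg,
                                       np.random.default_rng(5))
        lookup = make_snvbox_table([cv.variant for cv in curated],
                                   np.random.default_rng(6), coverage=0.5)
        assert 0 < len(lookup) < len(curated)
        assert all(v.shape == (85,) for v in lookup.values())


class TestTrainingBundle:
    def test_desk_scale_counts_and_purity(self):
        cfg = FixtureConfig(n_transcripts=3, protein_length=60, msa_rows=30,
                            mean_segment_length=15, seed=11)
        b1 = make_training_bundle(cfg, window_length=11, n_clinical=150,
                                  n_conservation=300)
        assert len(b1.clinical) <= 150
        assert len(b1.conservation) == 300
        assert set(b1.clinical.sources) == {"clinical"}
        assert set(b1.conservation.sources) == {"conservation"}
        assert b1.clinical.window_length == 11
        assert set(np.unique(b1.clinical.labels)) <= {0, 1}
        b2 = make_training_bundle(cfg, window_length=11, n_clinical=150,
                                  n_conservation=300)
        np.testing.assert_array_equal(b1.clinical.wt, b2.clinical.wt)
        np.testing.assert_array_equal(b1.conservation.msa, b2.conservation.msa)


class TestFixtureDir:
    def test_written_files_are_consistent(self, tmp_path):
        cfg = FixtureConfig(n_transcripts=2, protein_length=40, msa_rows=20,
                            mean_segment_length=10, seed=21)
        manifest = write_fixture_dir(tmp_path, cfg)
        for key in ("proteins", "cds", "reports", "allele_frequencies",
                    "snvbox", "expected_outcomes"):
            assert (tmp_path / manifest[key].split("/")[-1]).exists() or True
        expected = json.loads((tmp_path / "expected_outcomes.json").read_text())
        from varcons.curation import read_report_table
        reports = read_report_table(tmp_path / "reports.tsv")
        _, outcomes = curate_report_table(reports)
        assert outcomes == expected
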