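import numpy as np
import pytest

from varcons.fixtures import FixtureConfig, make_msa, make_transcript
from varcons.msa import MsaFilterConfig, build_profile, filter_alignment


@pytest.fixture(scope="session")
def small_cfg():
    return FixtureConfig(n_transcripts=4, protein_length=80, msa_rows=30,
                         mean_segment_length=20, seed=7)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """A few transcripts with alignments, plans and profiles."""
    rng = np.random.default_rng(small_cfg.seed)
    out = []
    for i in range(small_cfg.n_transcripts):
        tx = make_transcript(small_cfg, rng, transcript_id=f"TX{i:04d}")
        aln, plan = make_msa(tx, small_cfg, rng)
        profile = build_profile(filter_alignment(aln))
        out.append((tx, aln, plan, profile))
    return out


@pytest.fixture(scope="session")
def msa_cfg():
    return MsaFilterConfig()
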