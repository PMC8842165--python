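import numpy as np
import pytest

from cftrscreen import CandidateList


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_candidates(bait: str, both: int, only_rep1: int, prefix: str = "ORF") -> CandidateList:
    """Candidate list with `both` dual-replicate and `only_rep1` single-replicate preys."""
    detected = {}
    for i in range(both):
        detected[f"{prefix}{i:04d}"] = {"rep1", "rep2"}
    for i in range(both, both + only_rep1):
        detected[f"{prefix}{i:04d}"] = {"rep1"}
    return CandidateList(bait=bait, orf_ids=set(detected), detected_in=detected)
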