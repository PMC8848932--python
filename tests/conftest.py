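from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from mirtail.reference import HairpinRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_hairpin() -> HairpinRecord:
    """60-nt hairpin with 21-nt arms, a loop, and a 10-nt 3' flank.

    Bases adjacent to both arm 3' ends are C/G so enumerated tails behave
    predictably, but the sequence is otherwise irregular.
    """
    #         5p arm [2,23)            loop                 3p arm [37,58)
    seq = (
        "AT"
        + "TGAGGTAGTAGGTTGTATACG"  # 5p mature (ends CG)
        + "CGTTGATATGTTGG"          # loop
        + "ACTGCCTTAGCTTAGGATCCG"  # 3p mature (ends CG)
        + "GC"
    )
    assert len(seq) == 60
    return HairpinRecord(
        id="toy-mir",
        sequence=seq,
        mature5p=(2, 23),
        mature3p=(37, 58),
        flank3p="CGATTACGGT",
        family="toy",
    )
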