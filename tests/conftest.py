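from __future__ import annotations

import pytest

from riconf.evidence_catalog import default_catalog
from riconf.riset_io import (
    Effect,
    GenomicInterval,
    RIType,
    RegulatoryInteraction,
    Strand,
)

# default-catalog code shorthands used throughout the suite
BPP = "EXP-IDA-BINDING-OF-PURIFIED-PROTEINS"  # group 1
MUT = "EXP-SITE-MUTATION"  # group 2
EXTRACT = "EXP-IDA-BINDING-OF-CELLULAR-EXTRACTS"  # group 3
CHIP_CHIP = "HT-EXP-IDA-CHIP-CHIP"  # group 4
CHIP_SEQ = "HT-EXP-IDA-CHIP-SEQ"  # group 4
CHIP_EXO = "HT-EXP-IDA-CHIP-EXO"  # group 4
GSELEX = "HT-EXP-IDA-GSELEX"  # group 5
DAP_SEQ = "HT-EXP-IDA-DAP-SEQ"  # group 6
COMP = "COMP-ANALYSIS"  # group 7
EXPRESSION = "EXP-GENE-EXPRESSION-ANALYSIS"  # function aspect
HT_EXPRESSION = "HT-EXP-GENE-EXPRESSION-ANALYSIS"  # function aspect
AUTHOR = "AS-AUTHOR-STATEMENT"  # no group


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_ri(
    binding=(),
    function=(),
    ri_id="RI00001",
    tf="TestTF",
    ri_type=RIType.TF_PROMOTER,
    target="target-1",
    effect=Effect.ACTIVATION,
    site=None,
):
    if isinstance(site, tuple):
        site = GenomicInterval(
            left=site[0],
            right=site[1],
            strand=Strand.FORWARD,
            genome_version="U00096.3",
        )
    return RegulatoryInteraction(
        ri_id=ri_id,
        tf_name=tf,
        ri_type=ri_type,
        target_id=target,
        effect=effect,
        site=site,
        binding_evidence=frozenset(binding),
        function_evidence=frozenset(function),
    )
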