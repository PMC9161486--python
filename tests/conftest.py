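import pytest

from seedshift.isomir import MatureArm, PremirnaReference

# Canonical mature miR-183-5p embedded in a synthetic hairpin context.
# The flanks are synthetic (not the genomic pre-miR-183 sequence); they only
# provide templated bases for 5'/3' offsets during classification.
MIR183_MATURE = "UAUGGCACUGGUAGAAUUCACU"
HAIRPIN_5P_FLANK = "CCGCAGAG"
HAIRPIN_3P_FLANK = "GUGCCUUACCGAAGGG"


@pytest.fixture(scope="session")
def mir183_mature() -> str:
    return MIR183_MATURE


@pytest.fixture(scope="session")
def mir183_ref() -> PremirnaReference:
    hairpin = HAIRPIN_5P_FLANK + MIR183_MATURE + HAIRPIN_3P_FLANK
    start = len(HAIRPIN_5P_FLANK)
    return PremirnaReference(
        "synthetic-mir183",
        hairpin,
        (MatureArm("miR-183-5p", start, start + len(MIR183_MATURE)),),
    )
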