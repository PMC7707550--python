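import numpy as np
import pytest

from strainwss import DepthTrack, ReferenceGenome, SampleProfile, VariantCall

# state k maps to alt base 'C','G','T' against ref base 'A' in handcrafted
# profiles; keeps alt != ref for any state >= 1
STATE_BASE = {1: "C", 2: "G", 3: "T"}


def build_reference(length=1000, species_id="sp1", sequence_id="ref1", cutoff=None):
    return ReferenceGenome(
        species_id=species_id, sequence_id=sequence_id, length=length, cutoff=cutoff
    )


def build_profile(
    reference,
    states=None,
    depth=20,
    sample_id="S1",
    individual_id=None,
    timepoint="t0",
):
    """Handcrafted profile: ``states`` maps 1-based position -> genotype
    state; ``depth`` is a constant or a full-length array."""
    if isinstance(depth, (int, float)):
        depth_arr = np.full(reference.length, int(depth), dtype=np.int64)
    else:
        depth_arr = np.asarray(depth, dtype=np.int64)
    calls = {
        pos: VariantCall(
            position=pos,
            ref_allele="A",
            alt_allele=STATE_BASE[state],
            genotype_state=state,
            depth_at_site=int(depth_arr[pos - 1]),
        )
        for pos, state in (states or {}).items()
    }
    return SampleProfile(
        sample_id=sample_id,
        individual_id=individual_id or sample_id,
        timepoint_label=timepoint,
        reference=reference,
        calls=calls,
        depth=DepthTrack(reference=reference, depth=depth_arr),
    )


@pytest.fixture
def reference():
    return build_reference()


@pytest.fixture
def make_reference():
    return build_reference


@pytest.fixture
def make_profile():
    return build_profile
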