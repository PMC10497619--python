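import logging

import pytest
from hypothesis import settings

from barrierscreen import library_design as ld
from barrierscreen import synthetic_screen as ss

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

logging.getLogger("barrierscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def candidate_resources():
    """Synthetic candidate pools and LAD coordinates for library design."""
    return ss.generate_candidate_resources(seed=11)


@pytest.fixture(scope="session")
def designed_library(candidate_resources):
    """The fully assembled 1000-element screening library."""
    return ld.assemble_library(
        candidate_resources["ctcf"],
        candidate_resources["mir"],
        candidate_resources["lads"],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_library():
    """A 30-element library with 80 bp cores and shared 10 bp flanks,
    sized for alignment-heavy tests."""
    cands = ld.generate_random_elements(30, 80, seed=42, id_prefix="EL")
    left, right = "GTACGTACGT", "CATGCATGCA"
    return [
        ld.LibraryElement(
            id=c.id,
            category_label="RANDOM",
            core_sequence=c.sequence,
            oligo_sequence=left + c.sequence + right,
        )
        for c in cands
    ]
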