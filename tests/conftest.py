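import numpy as np
import pytest

from mirexport import (
    Hairpin,
    HairpinReference,
    MatureArm,
    SimulationConfig,
    simulate_reference,
)
from mirexport.simulate import SpikeConfig


def brute_force_align(read: str, ref: HairpinReference, max_mm: int = 2):
    """Exhaustive pure-Python Hamming scan at every offset of every hairpin.

    Independent oracle for the vectorized aligner: returns minimal-mismatch
    placements as (hairpin_id, 1-based start, mismatches).
    """
    seq = read.upper().replace("U", "T")
    hits = []
    for hp in ref:
        for s0 in range(len(hp.sequence) - len(seq) + 1):
            window = hp.sequence[s0 : s0 + len(seq)]
            mm = sum(a != b for a, b in zip(seq, window))
            if mm <= max_mm:
                hits.append((hp.hairpin_id, s0 + 1, mm))
    if not hits:
        return []
    best = min(h[2] for h in hits)
    return sorted(h for h in hits if h[2] == best)


@pytest.fixture(scope="session")
def toy_ref() -> HairpinReference:
    """Two handcrafted hairpins, one mature arm each (well separated)."""
    hp1 = "GCGTACGT" + "TGAGGTAGTAGGTTGTATAGTT" + "CTATCGATCGTTACGGAACTGCTAGCTAGG"
    hp2 = "ATCCGGTA" + "ACCCGTAGAACCGACCTTGCGG" + "GGATCGATAAGCTTACCCGGGTTTAAACCC"
    return HairpinReference(
        (
            Hairpin("hp-a", hp1, (MatureArm("mir-a", 9, 30),)),
            Hairpin("hp-b", hp2, (MatureArm("mir-b", 9, 30),)),
        )
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """Small but complete study: 40 miRNAs, 20k reads/library, spike on."""
    return SimulationConfig(
        n_mirnas=40, reads_per_library=20_000, spike=SpikeConfig(), seed=11
    )


@pytest.fixture(scope="session")
def sim_ref(sim_config) -> HairpinReference:
    return simulate_reference(sim_config)
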