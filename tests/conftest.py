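"""Shared fixtures: simulated datasets reused across the suite.

The simulations are the package's own synthetic_data generators; session
scope keeps the ~100k-tag datasets from being regenerated per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from occupeak import (
    ChromTable,
    SimulationSpec,
    call_peaks,
    default_spec,
    simulate_background,
    simulate_chipseq,
)

#: Reconstructed fragment length for the generators' read geometry:
#: the median forward/reverse midpoint distance equals L - r = 200 - 36.
RECONSTRUCTED_FRAGLEN = 164

NULL_SEED = 11
SPIKED_SEED = 7
FRAGSIM_SEED = 5


@pytest.fixture(scope="session")
def chroms_10mb() -> ChromTable:
    return ChromTable({"chrS": 10_000_000})


@pytest.fixture(scope="session")
def null_spec(chroms_10mb) -> SimulationSpec:
    """Pure uniform background: 1e5 tags on 10 Mb."""
    return SimulationSpec(chroms=chroms_10mb, n_background=100_000, seed=NULL_SEED)


@pytest.fixture(scope="session")
def null_tags(null_spec):
    return simulate_background(null_spec)


@pytest.fixture(scope="session")
def spiked():
    """The standard spiked dataset: background plus 100 loci x 50 fragments."""
    spec = default_spec(seed=SPIKED_SEED)
    tags, truth = simulate_chipseq(spec)
    return spec, tags, truth


@pytest.fixture(scope="session")
def spiked_called(spiked):
    """Peaks called on the spiked dataset at the default threshold."""
    spec, tags, _ = spiked
    return call_peaks(tags, spec.chroms, fraglen_override=RECONSTRUCTED_FRAGLEN)


@pytest.fixture(scope="session")
def fragment_sim(chroms_10mb):
    """300 enriched loci sequenced from both fragment ends, light background.

    The geometry behind fragment-length estimation: forward reads pile at
    fragment 5' ends, reverse reads at 3' ends.
    """
    centers = np.linspace(30_000, 9_970_000, 300).astype(int)
    spec = SimulationSpec(
        chroms=chroms_10mb,
        n_background=20_000,
        seed=FRAGSIM_SEED,
        read_mode="both",
        peaks=tuple(("chrS", int(c), 50) for c in centers),
    )
    tags, truth = simulate_chipseq(spec)
    return spec, tags, truth
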