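import numpy as np
import pytest

from mitopop.alignment import WINDOW_START, AlignedSequenceSet, SequenceRecord


def make_alignment(seqs, ids=None, regions=None, countries=None,
                   populations=None, start=WINDOW_START):
    """Build an AlignedSequenceSet in window coordinates from raw strings."""
    n = len(seqs)
    ids = ids or [f"s{i + 1}" for i in range(n)]
    regions = regions or ["AFE"] * n
    countries = countries or [""] * n
    populations = populations or [r for r in regions]
    width = len(seqs[0])
    records = tuple(
        SequenceRecord(i, s, c, r, p)
        for i, s, c, r, p in zip(ids, seqs, countries, regions, populations)
    )
    return AlignedSequenceSet(records, start, start + width - 1,
                              tuple(range(start, start + width)))


@pytest.fixture
def make_aln():
    return make_alignment


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset():
    """A small simulated two-haplogroup dataset with its truth bundle."""
    from mitopop.simulate import SimConfig, simulate_two_haplogroup_dataset

    cfg = SimConfig(
        n_per_region={"AFE": 24, "AFW": 20, "EUI": 16},
        haplogroup_fractions={"AFE": 60, "AFW": 90, "EUI": 25},
        seed=7,
    )
    return simulate_two_haplogroup_dataset(cfg)
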