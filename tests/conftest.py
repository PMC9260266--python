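import itertools

import pandas as pd
import pytest

from msapkit.io import BandMatrix, SampleMeta


def make_band_matrix(profiles, samples=None, loci=None):
    """Build a BandMatrix from {sample_id: [(h, m), ...]} (NA cells allowed
    as None)."""
    sample_ids = list(profiles)
    n_loci = len(next(iter(profiles.values())))
    if loci is None:
        loci = [f"L{i + 1}" for i in range(n_loci)]
    if samples is None:
        samples = [
            SampleMeta(sid, "root", "M", 0.0, i + 1)
            for i, sid in enumerate(sample_ids)
        ]
    idx = pd.Index(loci, name="locus_id")
    h = pd.DataFrame(
        {
            sid: [pd.NA if p[0] is None else p[0] for p in profiles[sid]]
            for sid in sample_ids
        },
        index=idx,
        dtype="Int64",
    )
    m = pd.DataFrame(
        {
            sid: [pd.NA if p[1] is None else p[1] for p in profiles[sid]]
            for sid in sample_ids
        },
        index=idx,
        dtype="Int64",
    )
    return BandMatrix(samples=samples, h=h, m=m)


@pytest.fixture
def toy_matrix():
    """3 loci x 2 samples, all four flag combinations represented."""
    return make_band_matrix(
        {"s1": [(1, 1), (1, 0), (0, 1)], "s2": [(0, 0), (1, 1), (0, 1)]}
    )


ALL_PATTERN_PAIRS = list(itertools.product("I II III IV".split(), repeat=2))
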