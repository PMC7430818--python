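import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from panelpipe.dataset import GenotypeDataset

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def _random_tags(n, length, seed):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return ["".join(rng.choice(bases, size=length)) for _ in range(n)]


@pytest.fixture
def make_dataset():
    """Factory for small hand-crafted datasets.

    ``calls`` is a (markers x samples) array with -1 missing and alt
    dosage otherwise; everything else is filled with sensible defaults.
    """

    def _make(
        calls,
        ref_counts=None,
        alt_counts=None,
        tags=None,
        clone_ids=None,
        snp_positions=None,
        samples=None,
        populations=None,
        trios=(),
        replicate_groups=None,
        rep_avg=None,
        tag_length=30,
    ):
        calls = np.asarray(calls, dtype=np.int8)
        m, s = calls.shape
        if samples is None:
            samples = [f"S{i + 1}" for i in range(s)]
        if tags is None:
            tags = _random_tags(m, tag_length, seed=99)
        if clone_ids is None:
            clone_ids = [f"C{i + 1}" for i in range(m)]
        if snp_positions is None:
            snp_positions = [0] * m
        markers = pd.DataFrame(
            {
                "clone_id": clone_ids,
                "snp_position": snp_positions,
                "ref_allele": ["A"] * m,
                "alt_allele": ["G"] * m,
                "tag_sequence": tags,
                "rep_avg": rep_avg if rep_avg is not None else [np.nan] * m,
            }
        )
        if populations is not None:
            populations = pd.Series(populations, dtype=object)
        if replicate_groups is not None:
            replicate_groups = pd.Series(replicate_groups, dtype=object)
        return GenotypeDataset(
            markers=markers,
            samples=samples,
            calls=calls,
            ref_counts=None if ref_counts is None else np.asarray(ref_counts),
            alt_counts=None if alt_counts is None else np.asarray(alt_counts),
            populations=populations,
            trios=list(trios),
            replicate_groups=replicate_groups,
        )

    return _make
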