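import numpy as np
import pandas as pd
import pytest

from altpath import ActivityProfile, SampleGroups


@pytest.fixture
def small_groups() -> SampleGroups:
    labels = {f"a{i}": "primary" for i in range(6)}
    labels.update({f"b{i}": "metastatic" for i in range(6)})
    return SampleGroups(labels, "primary", "metastatic")


@pytest.fixture
def small_profile(small_groups) -> ActivityProfile:
    rng = np.random.default_rng(11)
    samples = small_groups.group1_samples + small_groups.group2_samples
    genes = [f"g{i}" for i in range(12)]
    mat = rng.integers(0, 2, size=(len(genes), len(samples)), dtype=np.int8)
    return ActivityProfile(pd.DataFrame(mat, index=genes, columns=samples))


def random_dataset(seed: int, n_genes: int = 30, per_group: int = 12):
    """A random activity dataset for symmetry/property tests."""
    rng = np.random.default_rng(seed)
    labels = {f"a{i}": "g1" for i in range(per_group)}
    labels.update({f"b{i}": "g2" for i in range(per_group)})
    groups = SampleGroups(labels, "g1", "g2")
    genes = [f"g{i:03d}" for i in range(n_genes)]
    probs = rng.uniform(0.1, 0.9, size=(n_genes, 2))
    samples = groups.group1_samples + groups.group2_samples
    mat = np.concatenate([
        (rng.random((n_genes, per_group)) < probs[:, :1]).astype(np.int8),
        (rng.random((n_genes, per_group)) < probs[:, 1:]).astype(np.int8),
    ], axis=1)
    return ActivityProfile(pd.DataFrame(mat, index=genes, columns=samples)), groups
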