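import numpy as np
import pytest

from lcmsprep.core import AbundanceMatrix, ProteinMap, StudyDesign


@pytest.fixture
def two_group_design():
    """Six samples, two balanced groups."""
    return StudyDesign([f"S{i}" for i in range(1, 7)],
                       ["A", "A", "A", "B", "B", "B"])


@pytest.fixture
def small_matrix():
    """3 peptides x 6 samples, one missing cell at (0, 2)."""
    rng = np.random.default_rng(42)
    vals = rng.normal(20.0, 1.0, size=(3, 6))
    vals[0, 2] = np.nan
    return AbundanceMatrix(vals, ["PEP1", "PEP2", "PEP3"],
                           [f"S{i}" for i in range(1, 7)])


@pytest.fixture
def small_pmap():
    return ProteinMap({"PEP1": "PROT1", "PEP2": "PROT1", "PEP3": "PROT2"})


def make_matrix(values, log_base=2.0, prefix="P"):
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        values,
        [f"{prefix}{i + 1}" for i in range(values.shape[0])],
        [f"S{j + 1}" for j in range(values.shape[1])],
        log_base=log_base,
    )


def balanced_design(n_per_group, n_groups=2):
    n = n_per_group * n_groups
    return StudyDesign([f"S{j + 1}" for j in range(n)],
                       [f"G{g + 1}" for g in range(n_groups)
                        for _ in range(n_per_group)])
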