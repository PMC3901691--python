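import warnings

import numpy as np
import pytest

from dnabindpred import enumerate_feature_space, make_toy_worked_example
from dnabindpred.io import AA_ALPHABET, ProteinRecord, PSSMatrix, StructuralProfile


@pytest.fixture(scope="session")
def space():
    return enumerate_feature_space()


@pytest.fixture(scope="session")
def toy():
    return make_toy_worked_example()


def random_triple(rng: np.random.Generator, length: int | None = None, pid: str = "p"):
    """A random valid (record, raw PSSM, structural profile) triple."""
    L = int(length if length is not None else rng.integers(11, 61))
    seq = "".join(rng.choice(list(AA_ALPHABET), size=L))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short test chains are intended
        record = ProteinRecord(id=pid, sequence=seq)
    pssm = PSSMatrix(
        protein_id=pid,
        scores=np.clip(np.rint(rng.normal(0, 3, size=(L, 20))), -10, 10),
    )
    profile = StructuralProfile(
        protein_id=pid,
        ss="".join(rng.choice(list("CHE"), size=L)),
        rsa=rng.beta(2, 2, size=L),
    )
    return record, pssm, profile


def gaussian_classification_data(
    rng: np.random.Generator,
    n_per_class: int = 100,
    n_features: int = 20,
    informative: dict[int, float] | None = None,
):
    """Class-labelled Gaussian features; ``informative`` maps a column index
    to its positive-class mean shift (in sd units).  Everything else is
    standard-normal noise in both classes."""
    informative = informative or {}
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.repeat([0, 1], n_per_class)
    for col, shift in informative.items():
        X[y == 1, col] += shift
    return X, y
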