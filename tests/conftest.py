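import numpy as np
import pytest
from hypothesis import settings

from divallele import AlleleSet, GenotypeFitnessMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def _pat(bits: str) -> np.ndarray:
    return np.array([c == "1" for c in bits], dtype=bool)


@pytest.fixture
def fig1_alleles() -> AlleleSet:
    """Two-allele example: A recognizes 5 of 10 sites, B 4 of 10, only
    positions 5 and 8 (1-indexed) are covered by neither, one shared site."""
    a = _pat("1111010000")
    b = _pat("0000011011")
    return AlleleSet(merits=[0.5, 0.4], patterns=np.array([a, b]))


@pytest.fixture
def stable_layout() -> AlleleSet:
    """Three-allele recognition layout whose DAA system keeps all alleles."""
    return AlleleSet(
        merits=[0.8, 0.7, 0.1],
        patterns=np.array([_pat("0111111110"), _pat("1111111000"), _pat("0000000001")]),
    )


@pytest.fixture
def unstable_layout() -> AlleleSet:
    """Three-allele layout with the same merits whose DAA system collapses
    to a single allele."""
    return AlleleSet(
        merits=[0.8, 0.7, 0.1],
        patterns=np.array([_pat("0111111110"), _pat("0111111010"), _pat("0001000000")]),
    )


@pytest.fixture
def stable_daa_matrix() -> GenotypeFitnessMatrix:
    """DAA genotype fitness matrix of the stable three-allele layout."""
    return GenotypeFitnessMatrix(
        [[0.8, 0.9, 0.9], [0.9, 0.7, 0.8], [0.9, 0.8, 0.1]], model_tag="daa"
    )


@pytest.fixture
def unstable_daa_matrix() -> GenotypeFitnessMatrix:
    """DAA matrix of the collapsing layout: only the best allele survives."""
    return GenotypeFitnessMatrix(
        [[0.8, 0.8, 0.8], [0.8, 0.7, 0.7], [0.8, 0.7, 0.1]], model_tag="daa"
    )


def random_stable_system(rng: np.random.Generator, k: int):
    """A random symmetric overdominant-ish fitness matrix on k alleles."""
    w = rng.uniform(0.05, 0.95, k)
    off = np.maximum.outer(w, w) + rng.uniform(0.0, 1.0, (k, k)) * (
        1.0 - np.maximum.outer(w, w)
    )
    values = (off + off.T) / 2.0
    np.fill_diagonal(values, w)
    return GenotypeFitnessMatrix(np.clip(values, 0.0, 1.0))
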