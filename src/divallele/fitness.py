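"""Genotype fitness matrices for the three overdominance models.

All models share the same viability framework: a symmetric matrix
``F = (f_ij)`` of genotype fitnesses in [0, 1] whose diagonal holds the
intrinsic merits (``f_ii = w_i``). The models differ only in how heterozygote
fitness is built from the two alleles:

* symmetric overdominance — every heterozygote is fully protected,
  ``f_ij = 1`` for ``i != j``;
* asymmetric overdominance (AO) — merits combine with a mean-field overlap
  discount, ``f_ij = w_i + w_j - w_i * w_j``;
* divergent allele advantage (DAA) — the heterozygote recognizes the union
  of the two alleles' epitope sets, ``f_ij = |union| / lS``, so the discount
  is the *actual* overlap of the two recognition patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hmean

from .alleles import AlleleSet

__all__ = [
    "GenotypeFitnessMatrix",
    "StabilityReport",
    "build_symmetric_f",
    "build_ao_f",
    "build_daa_f",
    "ao_threshold",
    "read_fitness_csv",
    "write_fitness_csv",
]

_SYMMETRY_ATOL = 1e-12


@dataclass(frozen=True)
class GenotypeFitnessMatrix:
    """Symmetric k x k matrix of genotype fitnesses ``f_ij`` in [0, 1]."""

    values: np.ndarray
    model_tag: str = "custom"
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("genotype fitness matrix must be square")
        if values.size == 0:
            raise ValueError("genotype fitness matrix must be non-empty")
        if not np.allclose(values, values.T, atol=_SYMMETRY_ATOL, rtol=0.0):
            raise ValueError("genotype fitness matrix must be symmetric")
        if np.any(values < -_SYMMETRY_ATOL) or np.any(values > 1.0 + _SYMMETRY_ATOL):
            raise ValueError("genotype fitnesses must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))
        if self.ids is not None:
            ids = tuple(str(i) for i in self.ids)
            if len(ids) != values.shape[0]:
                raise ValueError("ids must match matrix size")
            object.__setattr__(self, "ids", ids)

    @property
    def k(self) -> int:
        return int(self.values.shape[0])

    @property
    def merits(self) -> np.ndarray:
        """Intrinsic merits, i.e. the diagonal ``f_ii = w_i``."""
        return np.diag(self.values)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.ids is not None:
            return self.ids
        return tuple(f"A{i + 1}" for i in range(self.k))

    def submatrix(self, indices) -> np.ndarray:
        indices = np.asarray(indices, dtype=int)
        return self.values[np.ix_(indices, indices)]


@dataclass(frozen=True)
class StabilityReport:
    """Persistence diagnosis of a k-allele system under the AO model.

    All ``k`` alleles persist at equilibrium if and only if every intrinsic
    merit exceeds the threshold ``t = ((k - 1) / k) * harmonic_mean(w)``.
    """

    threshold: float
    harmonic_mean: float
    stable: bool
    k: int


def _as_allele_set(alleles) -> AlleleSet:
    if isinstance(alleles, AlleleSet):
        return alleles
    return AlleleSet(merits=np.asarray(alleles, dtype=float))


def build_symmetric_f(alleles: AlleleSet | np.ndarray) -> GenotypeFitnessMatrix:
    """Symmetric overdominance: all heterozygotes fully fit (``f_ij = 1``).

    Kept for completeness and for invariant checks; with any merits below 1
    it retains every allele indefinitely, which is why it fails to explain
    the observed loss of poor alleles.
    """
    alleles = _as_allele_set(alleles)
    if np.any(alleles.merits >= 1.0):
        warnings.warn(
            "merit of 1 present: heterozygotes are not strictly fitter, "
            "the model is not overdominant for that allele",
            stacklevel=2,
        )
    values = np.ones((alleles.k, alleles.k))
    np.fill_diagonal(values, alleles.merits)
    return GenotypeFitnessMatrix(values, model_tag="symmetric", ids=alleles.ids)


def build_ao_f(alleles: AlleleSet | np.ndarray) -> GenotypeFitnessMatrix:
    """Asymmetric overdominance: ``f_ij = w_i + w_j - w_i * w_j``.

    The product term discounts the *average* overlap of the two alleles'
    pathogen coverage, so heterozygote fitnesses are strictly ordered by the
    underlying merits: ``max(w_i, w_j) < f_ij < 1`` whenever both merits are
    in (0, 1).
    """
    alleles = _as_allele_set(alleles)
    w = alleles.merits
    values = w[:, None] + w[None, :] - np.outer(w, w)
    np.fill_diagonal(values, w)
    return GenotypeFitnessMatrix(values, model_tag="ao", ids=alleles.ids)


def build_daa_f(alleles: AlleleSet) -> GenotypeFitnessMatrix:
    """Divergent allele advantage: ``f_ij`` = fraction of sites in the union.

    MHC alleles are codominantly expressed, so a heterozygote presents an
    epitope set if *either* allele recognizes it; its fitness is the union
    coverage ``|P_i | P_j| / lS``. Complementary (divergent) alleles of low
    merit can therefore form highly fit heterozygotes, which the mean-field
    AO discount cannot produce.
    """
    if not isinstance(alleles, AlleleSet) or alleles.patterns is None:
        raise ValueError("the DAA model requires recognition patterns")
    values = pattern_union_matrix(alleles.patterns)
    return GenotypeFitnessMatrix(values, model_tag="daa", ids=alleles.ids)


def pattern_intersection_counts(patterns: np.ndarray) -> np.ndarray:
    """Pairwise counts ``r_ij`` of sites recognized by both alleles.

    Computed as a single-precision matrix product; exact for any realistic
    ``lS`` (counts are integers below 2**24).
    """
    dense = np.asarray(patterns, dtype=np.float32)
    counts = dense @ dense.T
    return np.rint(counts).astype(np.int64)

def pattern_union_matrix(patterns: np.ndarray) -> np.ndarray:
    """Pairwise union coverage ``(m_i + m_j - r_ij) / lS``; diagonal ``m_i / lS``."""
    patterns = np.asarray(patterns, dtype=bool)
    ls = patterns.shape[1]
    m = patterns.sum(axis=1).astype(np.int64)
    r = pattern_intersection_counts(patterns)
    union = m[:, None] + m[None, :] - r
    return union / ls


def ao_threshold(alleles: AlleleSet | np.ndarray) -> StabilityReport:
    """Stability threshold of the AO model.

    ``t = ((k - 1) / k) * harmonic_mean(w)``; the full k-allele polymorphism
    persists iff every merit exceeds ``t``. A zero merit makes the harmonic
    mean (hence the threshold) undefined.
    """
    alleles = _as_allele_set(alleles)
    w = alleles.merits
    if np.any(w <= 0.0):
        raise ValueError(
            "AO stability threshold undefined: the harmonic mean requires "
            "strictly positive merits"
        )
    k = alleles.k
    w_hat = float(hmean(w))
    t = (k - 1) / k * w_hat
    return StabilityReport(
        threshold=t, harmonic_mean=w_hat, stable=bool(w.min() > t), k=k
    )


def write_fitness_csv(matrix: GenotypeFitnessMatrix, path) -> None:
    """Write a genotype fitness matrix as CSV with allele labels."""
    labels = list(matrix.labels)
    frame = pd.DataFrame(
        matrix.values, index=pd.Index(labels, name="allele"), columns=labels
    )
    frame.to_csv(path)


def read_fitness_csv(path, model_tag: str = "custom") -> GenotypeFitnessMatrix:
    """Read a square, symmetric genotype fitness CSV with header + row labels."""
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: matrix is {values.shape[0]} x {values.shape[1]}, not square"
        )
    return GenotypeFitnessMatrix(
        values, model_tag=model_tag, ids=tuple(str(i) for i in frame.index)
    )
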