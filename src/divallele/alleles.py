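"""Allele sets: intrinsic merits and epitope-recognition patterns.

An allele is characterized by its *intrinsic merit* ``w`` — the viability of
the homozygote carrying two copies of it — and, for the mechanistic divergent
allele advantage (DAA) model, by a binary *recognition pattern* over ``lS``
abstract epitope sets: entry ``s`` is True when the allele's MHC molecule
presents epitope set ``s`` to the immune system. The merit of an allele with
a pattern is the recognized fraction ``m / lS``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RecognitionPattern",
    "AlleleSet",
    "read_patterns_csv",
    "write_patterns_csv",
]


@dataclass(frozen=True)
class RecognitionPattern:
    """Binary epitope-recognition profile of a single allele.

    Parameters
    ----------
    sites
        Boolean vector of length ``lS``; True at positions the allele
        recognizes.
    """

    sites: np.ndarray

    def __post_init__(self) -> None:
        sites = np.asarray(self.sites, dtype=bool)
        if sites.ndim != 1 or sites.size == 0:
            raise ValueError("a recognition pattern must be a non-empty 1-D vector")
        object.__setattr__(self, "sites", sites)

    @property
    def length(self) -> int:
        """Total number of epitope sets ``lS``."""
        return int(self.sites.size)

    @property
    def n_recognized(self) -> int:
        """Number of recognized sites ``m``."""
        return int(self.sites.sum())

    @property
    def merit(self) -> float:
        """Recognized fraction ``m / lS``, the allele's intrinsic merit."""
        return self.n_recognized / self.length


@dataclass(frozen=True)
class AlleleSet:
    """A set of ``k`` alleles with merits and optional recognition patterns.

    When ``patterns`` is provided, the merits are defined by the patterns
    (``w_i = m_i / lS``); merits passed alongside inconsistent patterns are
    recomputed from the patterns with a warning, since the mechanistic model
    derives fitness from recognition, not the other way round.
    """

    merits: np.ndarray
    patterns: np.ndarray | None = None
    ids: tuple[str, ...] | None = None
    _merit_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        merits = np.atleast_1d(np.asarray(self.merits, dtype=float))
        if merits.ndim != 1 or merits.size == 0:
            raise ValueError("an allele set needs at least one allele")
        if np.any(merits < 0.0) or np.any(merits > 1.0):
            raise ValueError("intrinsic merits must lie in [0, 1]")
        patterns = self.patterns
        if patterns is not None:
            patterns = np.asarray(patterns, dtype=bool)
            if patterns.ndim != 2 or patterns.shape[0] != merits.size:
                raise ValueError(
                    "patterns must be a (k, lS) boolean matrix matching the merits"
                )
            counts = patterns.sum(axis=1)
            derived = counts / patterns.shape[1]
            if not np.array_equal(derived, merits):
                if not np.allclose(derived, merits, atol=1e-12):
                    warnings.warn(
                        "supplied merits disagree with recognition patterns; "
                        "recomputing merits as recognized fractions",
                        stacklevel=2,
                    )
                merits = derived
            object.__setattr__(self, "_merit_counts", counts)
        object.__setattr__(self, "merits", merits)
        object.__setattr__(self, "patterns", patterns)
        if self.ids is not None:
            ids = tuple(str(i) for i in self.ids)
            if len(ids) != merits.size:
                raise ValueError("ids must match the number of alleles")
            object.__setattr__(self, "ids", ids)

    @property
    def k(self) -> int:
        """Number of alleles."""
        return int(self.merits.size)

    @property
    def sequence_length(self) -> int | None:
        """Pattern length ``lS``, or None when no patterns are attached."""
        return None if self.patterns is None else int(self.patterns.shape[1])

    @property
    def labels(self) -> tuple[str, ...]:
        if self.ids is not None:
            return self.ids
        return tuple(f"A{i + 1}" for i in range(self.k))

    def pattern(self, i: int) -> RecognitionPattern:
        """Recognition pattern of allele ``i``."""
        if self.patterns is None:
            raise ValueError("this allele set carries no recognition patterns")
        return RecognitionPattern(self.patterns[i])

    def ordered_by_merit(self) -> "AlleleSet":
        """Return a copy with alleles sorted by nonincreasing merit.

        Sorting is never done implicitly; the stable order of the input is
        otherwise preserved everywhere.
        """
        order = np.argsort(-self.merits, kind="stable")
        return self.take(order)

    def take(self, indices) -> "AlleleSet":
        """Subset/reorder the allele set by integer indices."""
        indices = np.asarray(indices, dtype=int)
        return AlleleSet(
            merits=self.merits[indices],
            patterns=None if self.patterns is None else self.patterns[indices],
            ids=None if self.ids is None else tuple(self.labels[i] for i in indices),
        )


def write_patterns_csv(alleles: AlleleSet, path) -> None:
    """Write recognition patterns as a 0/1 CSV (rows = alleles, cols = sites)."""
    if alleles.patterns is None:
        raise ValueError("allele set has no patterns to write")
    ls = alleles.patterns.shape[1]
    frame = pd.DataFrame(
        alleles.patterns.astype(int),
        index=pd.Index(alleles.labels, name="allele"),
        columns=[f"site_{j + 1}" for j in range(ls)],
    )
    frame.to_csv(path)


def read_patterns_csv(path) -> AlleleSet:
    """Read a 0/1 pattern CSV written by :func:`write_patterns_csv`."""
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy()
    if values.size == 0:
        raise ValueError(f"{path}: empty pattern file")
    if not np.isin(values, (0, 1)).all():
        bad = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise ValueError(
            f"{path}: non-binary cell at row {bad[0] + 2}, column {bad[1] + 2}"
        )
    patterns = values.astype(bool)
    return AlleleSet(
        merits=patterns.mean(axis=1),
        patterns=patterns,
        ids=tuple(str(i) for i in frame.index),
    )
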