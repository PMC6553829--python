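"""Equilibrium summary statistics: diversity, overdominance, and overlap.

For a surviving allele set at equilibrium the comparison between models uses

* ``n_equil`` — number of persisting alleles;
* ``r_equil`` — range (max - min) of intrinsic merits among them;
* ``h_bar`` / ``h_i`` — average / per-allele overdominance, the relative
  fitness excess of heterozygotes over homozygotes at equilibrium;
* ``g_ij`` / ``g_i`` / ``g_bar`` — pairwise, per-allele-average and
  population-weighted epitope-recognition overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alleles import AlleleSet
from .equilibrium import EquilibriumResult
from .fitness import GenotypeFitnessMatrix, pattern_intersection_counts

__all__ = [
    "MetricsRecord",
    "overdominance",
    "overlap",
    "merit_range",
    "allele_count",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricsRecord:
    """Per-equilibrium metrics for one model run."""

    n_equil: int
    r_equil: float
    h_bar: float
    h_i: np.ndarray
    w_bar: float
    g_i: np.ndarray | None = None
    g_bar: float = float("nan")


def allele_count(equilibrium: EquilibriumResult) -> int:
    """Number of alleles persisting at equilibrium."""
    return int(equilibrium.surviving.size)


def merit_range(alleles: AlleleSet | np.ndarray, equilibrium: EquilibriumResult) -> float:
    """Max minus min intrinsic merit over the surviving alleles.

    With quantized merits (multiples of ``1/lS``) ranges from paired model
    runs are exactly comparable, so ties are decided by exact equality.
    """
    merits = alleles.merits if isinstance(alleles, AlleleSet) else np.asarray(alleles)
    surv = merits[equilibrium.surviving]
    if surv.size == 0:
        return float("nan")
    return float(surv.max() - surv.min())


def overdominance(
    F: GenotypeFitnessMatrix | np.ndarray,
    equilibrium: EquilibriumResult,
    *,
    weighted: bool = True,
) -> tuple[float, np.ndarray]:
    """Average and per-allele overdominance at equilibrium.

    ``h_bar = (whet_bar - whom_bar) / whom_bar`` where, under the default
    genotype-frequency weighting, heterozygote and homozygote mean fitnesses
    are Hardy-Weinberg weighted within their class:

        whet_bar = sum_{i != j} p_i p_j f_ij / sum_{i != j} p_i p_j
        whom_bar = sum_i p_i^2 f_ii / sum_i p_i^2

    With ``weighted=False`` plain (unweighted) class means are used instead.
    Per allele, ``h_i = (whet_i - f_ii) / f_ii`` with
    ``whet_i = sum_{j != i} p_j f_ij / (1 - p_i)``, the mean fitness of the
    heterozygotes carrying allele ``i``. A single-survivor equilibrium has no
    heterozygotes; NaN is returned.
    """
    values = F.values if isinstance(F, GenotypeFitnessMatrix) else np.asarray(F)
    idx = equilibrium.surviving
    p = equilibrium.proportions
    sub = values[np.ix_(idx, idx)]
    n = idx.size
    if n == 0:
        raise ValueError("no surviving alleles")
    diag = np.diag(sub)
    if np.any(diag == 0.0):
        raise ValueError("homozygote fitness of zero: overdominance undefined")
    if n == 1:
        return float("nan"), np.array([float("nan")])
    off_mask = ~np.eye(n, dtype=bool)
    if weighted:
        pw = np.outer(p, p)
        whet_bar = float((pw * sub)[off_mask].sum() / pw[off_mask].sum())
        whom_bar = float(np.sum(p**2 * diag) / np.sum(p**2))
    else:
        whet_bar = float(sub[off_mask].mean())
        whom_bar = float(diag.mean())
    h_bar = (whet_bar - whom_bar) / whom_bar
    # per-allele: heterozygote mean for allele i over partners j != i
    denom = 1.0 - p
    whet_i = ((sub * p[None, :]).sum(axis=1) - diag * p) / denom
    h_i = (whet_i - diag) / diag
    return float(h_bar), h_i


def overlap(
    alleles: AlleleSet,
    equilibrium: EquilibriumResult,
    *,
    intersections: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Average recognition overlap per surviving allele, and its weighted mean.

    ``g_ij = r_ij / lS`` is the fraction of sites recognized by *both*
    alleles of a pair; ``g_i = sum_{j != i} p_j g_ij / (1 - p_i)`` averages
    an allele's overlap with the rest of the gene pool using the partner
    proportions as weights (the ``1 - p_i`` factor renormalizes them), and
    ``g_bar = sum_i p_i g_i``. Pass precomputed pairwise ``intersections``
    (full k x k ``r_ij`` counts) to avoid recomputing the pattern product.
    """
    if alleles.patterns is None:
        raise ValueError("overlap metrics require recognition patterns")
    ls = alleles.patterns.shape[1]
    idx = equilibrium.surviving
    p = equilibrium.proportions
    if intersections is None:
        r = pattern_intersection_counts(alleles.patterns[idx])
    else:
        r = np.asarray(intersections)[np.ix_(idx, idx)]
    g = r / ls
    n = idx.size
    if n == 1:
        return np.array([float("nan")]), float("nan")
    diag = np.diag(g)
    denom = 1.0 - p
    g_i = np.where(
        denom > 0.0,
        ((g * p[None, :]).sum(axis=1) - diag * p) / np.where(denom > 0, denom, 1.0),
        np.nan,
    )
    g_bar = float(np.nansum(p * g_i))
    return g_i, g_bar


def compute_metrics(
    alleles: AlleleSet,
    F: GenotypeFitnessMatrix,
    equilibrium: EquilibriumResult,
    *,
    weighted: bool = True,
    with_overlap: bool = True,
    intersections: np.ndarray | None = None,
) -> MetricsRecord:
    """All equilibrium metrics for one model run."""
    h_bar, h_i = overdominance(F, equilibrium, weighted=weighted)
    g_i, g_bar = (None, float("nan"))
    if with_overlap and alleles.patterns is not None:
        g_i, g_bar = overlap(alleles, equilibrium, intersections=intersections)
    return MetricsRecord(
        n_equil=allele_count(equilibrium),
        r_equil=merit_range(alleles, equilibrium),
        h_bar=h_bar,
        h_i=h_i,
        w_bar=equilibrium.population_fitness,
        g_i=g_i,
        g_bar=g_bar,
    )
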