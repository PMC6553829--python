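"""Equilibria of the single-locus multi-allele viability model.

With random mating and discrete non-overlapping generations the allele
proportions evolve as

    p_i(t+1) = p_i(t) * w_i^m(p(t)) / wbar(p(t)),

where ``w_i^m = (F p)_i`` is the marginal fitness of allele ``i`` and
``wbar = p . F p`` the population fitness. At an interior equilibrium all
marginal fitnesses are equal, so the surviving proportions solve the linear
system ``F x = 1`` up to normalization. The solver below applies that linear
solve, eliminating alleles whose solution entry is nonpositive and repeating
until all entries are positive; a solution whose final principal submatrix is
(numerically) singular is reported as such, because only the nonsingular case
guarantees a globally stable, unique equilibrium. A discrete-time iterator of
the dynamics above is provided as an independent check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import get_lapack_funcs

from .fitness import GenotypeFitnessMatrix

__all__ = [
    "PopulationState",
    "EquilibriumResult",
    "marginal_fitness",
    "population_fitness",
    "make_state",
    "step_dynamics",
    "solve_equilibrium",
    "iterate_to_convergence",
    "result_to_json",
]

#: treat the final submatrix as singular when its reciprocal condition number
#: falls below sqrt(machine epsilon)
RCOND_SINGULAR = math.sqrt(np.finfo(float).eps)

#: default convergence tolerance on the marginal-fitness spread (the linear
#: solver and the time-stepping dynamics agree to ~11 decimals at this level)
DEFAULT_TOL = 1e-11

#: proportions below this are treated as extinct during time stepping
DEFAULT_PRUNE = 1e-12


def _values(F) -> np.ndarray:
    if isinstance(F, GenotypeFitnessMatrix):
        return F.values
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[0] != F.shape[1]:
        raise ValueError("fitness matrix must be square")
    if not np.allclose(F, F.T, atol=1e-12, rtol=0.0):
        raise ValueError("fitness matrix must be symmetric")
    return F


def marginal_fitness(F, p) -> np.ndarray:
    """Marginal fitnesses ``w_i^m = (F p)_i``."""
    values = _values(F)
    p = np.asarray(p, dtype=float)
    if p.shape != (values.shape[0],):
        raise ValueError("proportion vector does not match matrix size")
    return values @ p


def population_fitness(F, p) -> float:
    """Population mean fitness ``wbar = p . F p``."""
    return float(np.dot(p, marginal_fitness(F, p)))


@dataclass(frozen=True)
class PopulationState:
    """Allele proportions with their marginal and population fitness."""

    proportions: np.ndarray
    marginal_fitness: np.ndarray
    population_fitness: float


def make_state(F, p) -> PopulationState:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    wm = marginal_fitness(F, p)
    return PopulationState(p, wm, float(np.dot(p, wm)))


def step_dynamics(F, state: PopulationState) -> PopulationState:
    """One generation of the viability dynamics.

    Population fitness is nondecreasing along these trajectories for any
    symmetric fitness matrix, which makes the iteration a reliable oracle for
    the linear solver.
    """
    if state.population_fitness <= 0.0:
        raise ZeroDivisionError("population fitness is zero: dynamics undefined")
    p_next = state.proportions * state.marginal_fitness / state.population_fitness
    p_next = p_next / p_next.sum()
    return make_state(F, p_next)


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of an equilibrium computation.

    Attributes
    ----------
    surviving
        Indices (into the original matrix) of alleles with positive
        equilibrium proportion.
    proportions
        Equilibrium proportions of the surviving alleles (sum to 1).
    population_fitness
        ``wbar`` at the equilibrium.
    eliminations
        Alleles removed per elimination round, in order.
    status
        ``"stable"`` for a positive solution with nonsingular submatrix;
        ``"singular"`` when the final submatrix is numerically singular (the
        equilibrium is then not guaranteed unique or globally stable);
        ``"degenerate"`` when the elimination loop cycles or empties, or the
        iteration hit its step limit.
    """

    surviving: np.ndarray
    proportions: np.ndarray
    population_fitness: float
    eliminations: tuple[np.ndarray, ...] = field(default_factory=tuple)
    status: str = "stable"
    k: int = 0

    def full_proportions(self) -> np.ndarray:
        """Proportions over all original alleles (zeros for eliminated ones)."""
        p = np.zeros(self.k)
        p[self.surviving] = self.proportions
        return p


def _solve_with_rcond(a: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Solve ``a x = 1`` by LU, returning (x, reciprocal condition number)."""
    if a.shape == (1, 1):
        v = a[0, 0]
        if v == 0.0:
            return None, 0.0
        return np.array([1.0 / v]), 1.0
    getrf, getrs, gecon = get_lapack_funcs(("getrf", "getrs", "gecon"), (a,))
    anorm = np.linalg.norm(a, 1)
    lu, piv, info = getrf(a)
    if info > 0:  # exact zero pivot
        return None, 0.0
    rcond, _ = gecon(lu, anorm, norm="1")
    x, info = getrs(lu, piv, np.ones(a.shape[0]))
    if info != 0 or not np.all(np.isfinite(x)):
        return None, float(rcond)
    return x, float(rcond)


def solve_equilibrium(
    F,
    *,
    one_at_a_time: bool = False,
    rcond_threshold: float = RCOND_SINGULAR,
) -> EquilibriumResult:
    """Equilibrium proportions by linear solve with elimination.

    Solves ``F x = 1`` on the current allele set, removes every allele with
    ``x_i <= 0`` (or only the most negative one when ``one_at_a_time``), and
    repeats until all entries are positive; the surviving proportions are the
    normalized solution. If the final principal submatrix is numerically
    singular the equilibrium is flagged ``status="singular"`` — callers that
    need guaranteed stability should discard it.
    """
    values = _values(F)
    k = values.shape[0]
    idx = np.arange(k)
    eliminations: list[np.ndarray] = []
    seen: set[frozenset] = set()
    x = None
    rcond = 0.0
    while idx.size > 0:
        key = frozenset(idx.tolist())
        if key in seen:
            return EquilibriumResult(
                surviving=np.array([], dtype=int),
                proportions=np.array([]),
                population_fitness=float("nan"),
                eliminations=tuple(eliminations),
                status="degenerate",
                k=k,
            )
        seen.add(key)
        sub = values[np.ix_(idx, idx)]
        x, rcond = _solve_with_rcond(sub)
        if x is None:
            # exactly singular before reaching an all-positive solution
            return EquilibriumResult(
                surviving=idx,
                proportions=np.full(idx.size, np.nan),
                population_fitness=float("nan"),
                eliminations=tuple(eliminations),
                status="singular",
                k=k,
            )
        nonpos = x <= 0.0
        if not nonpos.any():
            break
        if one_at_a_time:
            drop = np.zeros(idx.size, dtype=bool)
            drop[np.argmin(x)] = True
            nonpos = drop
        eliminations.append(idx[nonpos])
        idx = idx[~nonpos]
    if idx.size == 0:
        return EquilibriumResult(
            surviving=idx,
            proportions=np.array([]),
            population_fitness=float("nan"),
            eliminations=tuple(eliminations),
            status="degenerate",
            k=k,
        )
    p = x / x.sum()
    sub = values[np.ix_(idx, idx)]
    wbar = float(p @ sub @ p)
    status = "singular" if rcond < rcond_threshold else "stable"
    return EquilibriumResult(
        surviving=idx,
        proportions=p,
        population_fitness=wbar,
        eliminations=tuple(eliminations),
        status=status,
        k=k,
    )


def iterate_to_convergence(
    F,
    p0=None,
    *,
    tol: float = DEFAULT_TOL,
    max_steps: int = 2_000_000,
    prune: float = DEFAULT_PRUNE,
) -> EquilibriumResult:
    """Iterate the discrete-time dynamics until the marginals equalize.

    Convergence is declared when the spread ``max |w_i^m - wbar|`` over
    alleles above the prune threshold drops below ``tol``. Alleles whose
    proportion falls below ``prune`` are reported as eliminated. Reaching
    ``max_steps`` yields ``status="degenerate"``.
    """
    values = _values(F)
    k = values.shape[0]
    if p0 is None:
        p = np.full(k, 1.0 / k)
    else:
        p = np.asarray(p0, dtype=float)
        if p.shape != (k,) or np.any(p < 0.0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("p0 must be a point on the k-simplex")
    status = "degenerate"
    for _ in range(max_steps):
        wm = values @ p
        wbar = float(p @ wm)
        if wbar <= 0.0:
            raise ZeroDivisionError("population fitness is zero: dynamics undefined")
        alive = p > prune
        if np.max(np.abs(wm[alive] - wbar)) < tol:
            status = "stable"
            break
        p = p * wm / wbar
        p = p / p.sum()
    alive = p > prune
    surviving = np.flatnonzero(alive)
    eliminated = np.flatnonzero(~alive)
    props = p[alive] / p[alive].sum()
    sub = values[np.ix_(surviving, surviving)]
    return EquilibriumResult(
        surviving=surviving,
        proportions=props,
        population_fitness=float(props @ sub @ props),
        eliminations=(eliminated,) if eliminated.size else (),
        status=status,
        k=k,
    )


def result_to_json(result: EquilibriumResult, labels=None) -> str:
    """Serialize an equilibrium result to JSON."""
    if labels is None:
        labels = [f"A{i + 1}" for i in range(result.k)]
    payload = {
        "status": result.status,
        "survivors": [labels[i] for i in result.surviving],
        "proportions": [float(v) for v in result.proportions],
        "population_fitness": result.population_fitness,
        "eliminations": [
            [labels[i] for i in round_] for round_ in result.eliminations
        ],
    }
    return json.dumps(payload, indent=2, allow_nan=True)
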