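"""Scenario definitions and allele-set generation for the model comparison.

The AO-vs-DAA comparison sweeps 80 scenarios that cross eight intrinsic-merit
ranges ``(wmin, wmax)`` with five initial allele counts ``n_ini`` in
{50, 100, 250, 500, 1000} and two merit-resolution factors ``f`` in {2, 10}.
The recognition-sequence length ``lS`` is chosen so the range contains at
least ``f * n_ini`` distinct representable merits (multiples of ``1/lS``),
which keeps accidental merit ties rare. Merits are kept away from the exact
0 and 1 endpoints by the margin ``eps = (wmax - wmin) / (2 * n_ini)``, so no
"perfect" or "useless" allele can occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alleles import AlleleSet

__all__ = [
    "ScenarioSpec",
    "MERIT_RANGES",
    "NINI_VALUES",
    "scenario_table",
    "get_scenario",
    "sequence_length",
    "draw_random_merits",
    "fixed_merits",
    "sample_patterns",
]

#: the eight (wmin, wmax) merit ranges, in scenario-table order
MERIT_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 0.1),
    (0.45, 0.55),
    (0.2, 0.6),
    (0.3, 0.7),
    (0.4, 0.8),
    (0.1, 0.9),
    (0.0, 1.0),
    (0.9, 1.0),
)

NINI_VALUES: tuple[int, ...] = (50, 100, 250, 500, 1000)
F_VALUES: tuple[int, ...] = (2, 10)


@dataclass(frozen=True)
class ScenarioSpec:
    """One point of the scenario grid: merit bounds, allele count, resolution."""

    wmin: float
    wmax: float
    nini: int
    f: int
    scenario_id: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.wmin < self.wmax <= 1.0:
            raise ValueError("need 0 <= wmin < wmax <= 1")
        if self.nini < 1:
            raise ValueError("nini must be positive")
        if self.f < 1:
            raise ValueError("f must be positive")

    @property
    def epsilon(self) -> float:
        """Edge margin keeping merits strictly inside (wmin, wmax)."""
        return (self.wmax - self.wmin) / (2 * self.nini)

    @property
    def sequence_length(self) -> int:
        return sequence_length(self)


def sequence_length(spec: ScenarioSpec) -> int:
    """Smallest ``lS`` giving at least ``f * n_ini`` representable merits.

    Merits are multiples of ``1/lS``; the half-open count of such multiples
    in ``[wmin, wmax]`` is at least ``(wmax - wmin) * lS + 1``, so the
    ceiling of ``f * n_ini / (wmax - wmin)`` is the minimal length meeting
    the requirement.
    """
    width = spec.wmax - spec.wmin
    if width <= 0.0:
        raise ValueError("wmax must exceed wmin")
    # tolerance absorbs float noise in width (e.g. 0.1 is not exact binary)
    ls = math.ceil(spec.f * spec.nini / width - 1e-9)
    assert width * ls + 1 >= spec.f * spec.nini - 1e-6
    return ls


def scenario_table() -> list[ScenarioSpec]:
    """The 80 scenarios: for each merit range, the f=2 block of five allele
    counts, then the f=10 block."""
    specs = []
    sid = 1
    for wmin, wmax in MERIT_RANGES:
        for f in F_VALUES:
            for nini in NINI_VALUES:
                specs.append(ScenarioSpec(wmin, wmax, nini, f, scenario_id=sid))
                sid += 1
    return specs


def get_scenario(scenario_id: int) -> ScenarioSpec:
    if not 1 <= scenario_id <= 80:
        raise ValueError(f"scenario_id must be in 1..80, got {scenario_id}")
    return scenario_table()[scenario_id - 1]


def draw_random_merits(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_ini`` merits i.i.d. uniform on ``[wmin + eps, wmax - eps]``."""
    return rng.uniform(spec.wmin + spec.epsilon, spec.wmax - spec.epsilon, spec.nini)


def fixed_merits(spec: ScenarioSpec) -> np.ndarray:
    """``n_ini`` evenly spaced merits from ``wmin + eps`` to ``wmax - eps``."""
    if spec.nini == 1:
        return np.array([(spec.wmin + spec.wmax) / 2.0])
    return np.linspace(spec.wmin + spec.epsilon, spec.wmax - spec.epsilon, spec.nini)


def _site_counts(merits: np.ndarray, ls: int, rounding: str) -> np.ndarray:
    scaled = np.asarray(merits, dtype=float) * ls
    if rounding == "half-even":
        counts = np.rint(scaled)
    elif rounding == "floor":
        counts = np.floor(scaled)
    elif rounding == "ceil":
        counts = np.ceil(scaled)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return counts.astype(np.int64)


def sample_patterns(
    merits,
    ls: int,
    rng: np.random.Generator,
    *,
    rounding: str = "half-even",
) -> AlleleSet:
    """Random recognition patterns realizing the given merits.

    Allele ``i`` recognizes ``m_i = round(lS * w_i)`` sites chosen uniformly
    at random among the ``lS`` positions. The returned allele set carries the
    *quantized* merits ``m_i / lS`` (off by at most ``1/(2 lS)`` from the
    input), so the AO and DAA models built from it see identical merits.
    """
    merits = np.atleast_1d(np.asarray(merits, dtype=float))
    if ls < 1:
        raise ValueError("sequence length must be >= 1")
    counts = _site_counts(merits, ls, rounding)
    k = merits.size
    patterns = np.zeros((k, ls), dtype=bool)
    for i in range(k):
        m = counts[i]
        if m == 0:
            continue
        if m == ls:
            patterns[i] = True
            continue
        # uniform m-subset: the m smallest of lS i.i.d. uniform keys
        keys = rng.random(ls)
        patterns[i, np.argpartition(keys, m)[:m]] = True
    return AlleleSet(merits=counts / ls, patterns=patterns)
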