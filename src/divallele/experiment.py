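"""Paired AO/DAA scenario sweeps and their aggregation.

Each repeat of a scenario generates one allele set — merits drawn uniformly
(Random experiment) or held at an evenly spaced grid (Fixed experiment), plus
fresh random recognition patterns in both — builds the AO and the DAA
genotype fitness matrices *from the same allele set*, solves both equilibria
and records the summary metrics. Sharing the allele set makes the comparison
paired: per repeat, the models differ only in how heterozygote fitness is
formed. Repeats whose final submatrix is singular are redrawn (whole allele
set for Random, patterns only for Fixed) and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alleles import AlleleSet
from .equilibrium import solve_equilibrium
from .fitness import GenotypeFitnessMatrix, build_ao_f, pattern_intersection_counts
from .metrics import MetricsRecord, compute_metrics
from .scenarios import ScenarioSpec, draw_random_merits, fixed_merits, sample_patterns, scenario_table

__all__ = [
    "REPEATS_MAIN",
    "REPEATS_OVERLAP",
    "IterationRecord",
    "RedrawLimitError",
    "repeat_schedule",
    "run_repeat",
    "run_scenario",
    "run_experiment",
    "records_to_frame",
    "aggregate",
]

#: full repeat schedule by initial allele count
REPEATS_MAIN = {50: 10_000, 100: 10_000, 250: 2_000, 500: 500, 1000: 100}
#: reduced schedule used for the overlap statistics
REPEATS_OVERLAP = {50: 500, 100: 200, 250: 50, 500: 20, 1000: 5}

#: desk-scale defaults: 1% of the full schedule, but never fewer than three
#: repeats per scenario so every per-scenario comparison fraction is averaged
#: over at least a few pattern draws
DESK_SCALE = 0.01
DESK_MIN_REPEATS = 3

_EXPERIMENTS = ("random", "fixed")
_OVERLAP_PERCENTILES = (1, 2, 5, 10)


class RedrawLimitError(RuntimeError):
    """Raised when consecutive singular draws exhaust the redraw budget."""


def repeat_schedule(
    nini: int,
    schedule: str = "main",
    *,
    scale: float = 1.0,
    min_repeats: int = 1,
) -> int:
    """Number of repeats for a scenario, scalable for desk-size runs."""
    table = {"main": REPEATS_MAIN, "overlap": REPEATS_OVERLAP}.get(schedule)
    if table is None:
        raise ValueError(f"unknown schedule {schedule!r}")
    if nini not in table:
        raise ValueError(f"no repeat count defined for nini={nini}")
    return max(min_repeats, int(round(table[nini] * scale)))


@dataclass(frozen=True)
class IterationRecord:
    """One model's outcome for one repeat of one scenario."""

    scenario_id: int
    experiment: str
    repeat_index: int
    model: str
    seed: int
    metrics: MetricsRecord
    status: str
    redraws: int


def _repeat_rng(
    base_seed: int, spec: ScenarioSpec, experiment: str, repeat_index: int, attempt: int
) -> tuple[np.random.Generator, int]:
    sid = 0 if spec.scenario_id is None else spec.scenario_id
    ss = np.random.SeedSequence(
        [int(base_seed), sid, _EXPERIMENTS.index(experiment), repeat_index, attempt]
    )
    return np.random.default_rng(ss), int(ss.generate_state(1)[0] % (2**31))


def run_repeat(
    spec: ScenarioSpec,
    experiment: str,
    repeat_index: int,
    base_seed: int,
    *,
    max_redraws: int = 50,
    with_overlap: bool = True,
    weighted_h: bool = True,
) -> tuple[IterationRecord, IterationRecord]:
    """One paired AO/DAA repeat; returns the (AO, DAA) records.

    On a singular equilibrium the draw is repeated: the Random experiment
    redraws merits and patterns, the Fixed experiment only the patterns
    (its merits are deterministic). Both models are recomputed from the
    redrawn set so the pairing is preserved.
    """
    if experiment not in _EXPERIMENTS:
        raise ValueError(f"experiment must be one of {_EXPERIMENTS}")
    ls = spec.sequence_length
    for attempt in range(max_redraws + 1):
        rng, seed = _repeat_rng(base_seed, spec, experiment, repeat_index, attempt)
        merits = (
            draw_random_merits(spec, rng) if experiment == "random" else fixed_merits(spec)
        )
        alleles = sample_patterns(merits, ls, rng)
        # one pattern product serves the DAA matrix and both overlap metrics
        r = pattern_intersection_counts(alleles.patterns)
        m = alleles.patterns.sum(axis=1).astype(np.int64)
        F_daa = GenotypeFitnessMatrix(
            (m[:, None] + m[None, :] - r) / ls, model_tag="daa"
        )
        F_ao = build_ao_f(alleles)
        eq_ao = solve_equilibrium(F_ao)
        eq_daa = solve_equilibrium(F_daa)
        if eq_ao.status == "stable" and eq_daa.status == "stable":
            records = []
            for model, F, eq in (("ao", F_ao, eq_ao), ("daa", F_daa, eq_daa)):
                metrics = compute_metrics(
                    alleles,
                    F,
                    eq,
                    weighted=weighted_h,
                    with_overlap=with_overlap,
                    intersections=r,
                )
                records.append(
                    IterationRecord(
                        scenario_id=spec.scenario_id or 0,
                        experiment=experiment,
                        repeat_index=repeat_index,
                        model=model,
                        seed=seed,
                        metrics=metrics,
                        status="stable",
                        redraws=attempt,
                    )
                )
            return records[0], records[1]
    raise RedrawLimitError(
        f"scenario {spec.scenario_id}, {experiment} repeat {repeat_index}: "
        f"{max_redraws} consecutive singular/degenerate draws"
    )


def run_scenario(
    spec: ScenarioSpec,
    experiment: str,
    n_repeats: int,
    base_seed: int,
    **kwargs,
) -> list[IterationRecord]:
    """All repeats of one scenario, as a flat record list."""
    records: list[IterationRecord] = []
    for rep in range(n_repeats):
        records.extend(run_repeat(spec, experiment, rep, base_seed, **kwargs))
    return records


def records_to_frame(records: list[IterationRecord]) -> pd.DataFrame:
    """Flatten records to one row per model per repeat."""
    rows = []
    for rec in records:
        met = rec.metrics
        g_i = met.g_i
        row = {
            "scenario_id": rec.scenario_id,
            "experiment": rec.experiment,
            "repeat_index": rec.repeat_index,
            "model": rec.model,
            "seed": rec.seed,
            "status": rec.status,
            "redraws": rec.redraws,
            "n_equil": met.n_equil,
            "r_equil": met.r_equil,
            "h_bar": met.h_bar,
            "w_bar": met.w_bar,
            "g_bar": met.g_bar,
        }
        if g_i is not None and np.isfinite(g_i).any():
            finite = g_i[np.isfinite(g_i)]
            row["g_min"] = float(finite.min())
            for q in _OVERLAP_PERCENTILES:
                row[f"g_p{q}"] = float(np.percentile(finite, q))
        else:
            row["g_min"] = float("nan")
            for q in _OVERLAP_PERCENTILES:
                row[f"g_p{q}"] = float("nan")
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["scenario_id", "experiment", "repeat_index", "model"]
    ).reset_index(drop=True)


def run_experiment(
    experiment: str,
    *,
    scenarios=None,
    schedule: str = "main",
    scale: float = 1.0,
    min_repeats: int = 1,
    n_repeats: int | None = None,
    base_seed: int = 0,
    out_dir: str | Path | None = None,
    with_overlap: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Run (a selection of) the 80-scenario sweep for one experiment.

    With ``out_dir`` set, per-scenario CSV shards are written and existing
    shards are reused, so an interrupted sweep resumes where it stopped.
    Records are deterministic given ``base_seed`` and independent across
    repeats, so execution order never affects the result.
    """
    if scenarios is None:
        scenarios = scenario_table()
    shard_dir = None
    if out_dir is not None:
        shard_dir = Path(out_dir)
        shard_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for spec in scenarios:
        n_rep = (
            n_repeats
            if n_repeats is not None
            else repeat_schedule(spec.nini, schedule, scale=scale, min_repeats=min_repeats)
        )
        shard = None
        if shard_dir is not None:
            shard = shard_dir / f"records_{experiment}_s{spec.scenario_id:02d}.csv"
            if shard.exists():
                frames.append(pd.read_csv(shard))
                continue
        if progress:
            print(
                f"scenario {spec.scenario_id:2d} ({experiment}): "
                f"nini={spec.nini}, lS={spec.sequence_length}, repeats={n_rep}",
                flush=True,
            )
        records = run_scenario(
            spec, experiment, n_rep, base_seed, with_overlap=with_overlap
        )
        frame = records_to_frame(records)
        if shard is not None:
            frame.to_csv(shard, index=False)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _paired_fractions(frame: pd.DataFrame, column: str) -> pd.DataFrame:
    """Per-scenario fractions of repeats where DAA >, <, = AO on a metric."""
    wide = frame.pivot_table(
        index=["scenario_id", "repeat_index"], columns="model", values=column
    )
    daa, ao = wide["daa"], wide["ao"]
    comp = pd.DataFrame(
        {
            "daa_gt": (daa > ao).astype(float),
            "ao_gt": (ao > daa).astype(float),
            "equal": (daa == ao).astype(float),
        },
        index=wide.index,
    )
    return comp.groupby(level="scenario_id").mean()


def aggregate(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-scenario aggregates and pooled summary for one experiment's frame.

    The pooled comparison fractions are reported both ways the per-repeat
    results can be combined: ``scenario_mean`` (unweighted mean of the
    per-scenario fractions — the primary reading, since repeat counts differ
    across scenarios) and ``iteration_pooled`` (all repeats lumped together).
    """
    if frame.empty:
        raise ValueError("no records to aggregate")
    unpaired = frame.groupby(["scenario_id", "repeat_index"])["model"].nunique()
    if (unpaired != 2).any():
        raise ValueError("records are not fully AO/DAA paired")
    per_model = frame.groupby(["scenario_id", "model"]).agg(
        n_mean=("n_equil", "mean"),
        n_max=("n_equil", "max"),
        r_mean=("r_equil", "mean"),
        r_max=("r_equil", "max"),
        h_bar_mean=("h_bar", "mean"),
        w_bar_mean=("w_bar", "mean"),
        g_bar_mean=("g_bar", "mean"),
        g_min_mean=("g_min", "mean"),
        g_p1_mean=("g_p1", "mean"),
        g_p2_mean=("g_p2", "mean"),
        g_p5_mean=("g_p5", "mean"),
        g_p10_mean=("g_p10", "mean"),
        redraws=("redraws", "sum"),
    )
    wide = per_model.unstack("model")
    wide.columns = [f"{metric}_{model}" for metric, model in wide.columns]
    range_comp = _paired_fractions(frame, "r_equil").add_prefix("range_")
    count_comp = _paired_fractions(frame, "n_equil").add_prefix("count_")
    per_scenario = wide.join(range_comp).join(count_comp)

    def _pooled(comp: pd.DataFrame, prefix: str, column: str) -> dict:
        pooled_wide = frame.pivot_table(
            index=["scenario_id", "repeat_index"], columns="model", values=column
        )
        daa, ao = pooled_wide["daa"], pooled_wide["ao"]
        return {
            f"{prefix}_daa_wider_scenario_mean": float(comp[f"{prefix}_daa_gt"].mean()),
            f"{prefix}_ao_wider_scenario_mean": float(comp[f"{prefix}_ao_gt"].mean()),
            f"{prefix}_equal_scenario_mean": float(comp[f"{prefix}_equal"].mean()),
            f"{prefix}_daa_wider_iteration_pooled": float((daa > ao).mean()),
            f"{prefix}_ao_wider_iteration_pooled": float((ao > daa).mean()),
            f"{prefix}_equal_iteration_pooled": float((daa == ao).mean()),
        }

    pooled = {}
    pooled.update(_pooled(per_scenario, "range", "r_equil"))
    pooled.update(_pooled(per_scenario, "count", "n_equil"))
    if "g_bar_mean_ao" in per_scenario:
        g_ok = per_scenario[["g_bar_mean_ao", "g_bar_mean_daa"]].dropna()
        gmin_ok = per_scenario[["g_min_mean_ao", "g_min_mean_daa"]].dropna()
        if len(g_ok):
            pooled["overlap_ao_higher_scenario_fraction"] = float(
                (g_ok["g_bar_mean_ao"] > g_ok["g_bar_mean_daa"]).mean()
            )
        if len(gmin_ok):
            pooled["overlap_min_ao_higher_scenario_fraction"] = float(
                (gmin_ok["g_min_mean_ao"] > gmin_ok["g_min_mean_daa"]).mean()
            )
    pooled["n_scenarios"] = int(frame["scenario_id"].nunique())
    pooled["n_repeats_total"] = int(len(frame) // 2)
    return per_scenario, pooled


def write_outputs(frame: pd.DataFrame, out_dir: str | Path) -> None:
    """Write records.csv, aggregates.csv and summary.json for a run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out / "records.csv", index=False)
    per_scenario, pooled = aggregate(frame)
    per_scenario.to_csv(out / "aggregates.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(pooled, fh, indent=2)
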