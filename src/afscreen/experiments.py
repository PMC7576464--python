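"""Experimental grids: the baseline 9 scores x 4 arms comparison and the
one-way sensitivity analyses over device sensitivity and false-positive rate.

Seeding: every cohort gets its own ``numpy.random.SeedSequence`` derived from
the plan's base seed and a spawn key encoding (score, arm, grid variant), so
cohorts are mutually independent — as in the published simulations — and every
output is bit-reproducible for a fixed configuration and base seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import NO_DEVICE, Arm, device_arm
from .engine import simulate_cohort
from .outcomes import ArmComparison, CohortSummary, compare, summarize
from .params import (
    CostParameters,
    InvalidParameterError,
    ParameterSet,
    default_config,
    validate,
)

__all__ = [
    "ExperimentPlan",
    "plan_from_config",
    "cohort_seed",
    "run_baseline_grid",
    "run_sensitivity_grid",
    "BaselineResult",
    "SensitivityResult",
    "write_baseline_tables",
    "write_sensitivity_tables",
    "write_run_metadata",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentPlan:
    """Which cohorts to simulate and how to seed them."""

    scores: tuple[int, ...] = tuple(range(1, 10))
    confirmations: tuple[float, ...] = (1.0, 0.75, 0.5)
    n: int = 30_000
    base_seed: int = 20201006
    sensitivity_grid: tuple[float, ...] = (0.86, 0.93, 1.0)
    false_positive_grid: tuple[float, ...] = (0.002, 0.01, 0.05)
    sensitivity_confirmation: float = 0.75

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(int(s) for s in self.scores))
        object.__setattr__(self, "confirmations", tuple(float(c) for c in self.confirmations))
        object.__setattr__(self, "sensitivity_grid", tuple(float(v) for v in self.sensitivity_grid))
        object.__setattr__(
            self, "false_positive_grid", tuple(float(v) for v in self.false_positive_grid)
        )
        if not self.scores or any(not 1 <= s <= 9 for s in self.scores):
            raise InvalidParameterError(f"scores must be a non-empty subset of 1..9, got {self.scores}")
        if self.n < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")
        for name in ("confirmations", "sensitivity_grid", "false_positive_grid"):
            grid = getattr(self, name)
            if not grid or any(not 0.0 <= v <= 1.0 for v in grid):
                raise InvalidParameterError(
                    f"{name} must be a non-empty grid of values in [0, 1], got {grid}"
                )
        if not 0.0 <= self.sensitivity_confirmation <= 1.0:
            raise InvalidParameterError(
                f"sensitivity_confirmation must lie in [0, 1], got {self.sensitivity_confirmation}"
            )


def plan_from_config(section: dict) -> ExperimentPlan:
    known = {
        "scores",
        "confirmations",
        "n",
        "base_seed",
        "sensitivity_grid",
        "false_positive_grid",
        "sensitivity_confirmation",
    }
    unknown = set(section) - known
    if unknown:
        raise InvalidParameterError(f"unknown experiment keys: {sorted(unknown)}")
    return ExperimentPlan(**section)


def cohort_seed(base_seed: int, score: int, arm: Arm, variant: int = 0) -> np.random.SeedSequence:
    """Independent, stable seed stream for one (score, arm, variant) cohort."""
    arm_code = 1 if arm.has_device else 0
    conf_code = int(round(arm.ecg_confirmation * 1000)) if arm.has_device else 0
    return np.random.SeedSequence(
        entropy=base_seed, spawn_key=(score, arm_code, conf_code, variant)
    )


def _run_one(
    score: int,
    arm: Arm,
    params: ParameterSet,
    costs: CostParameters,
    plan: ExperimentPlan,
    variant: int = 0,
) -> CohortSummary:
    seed = cohort_seed(plan.base_seed, score, arm, variant)
    t0 = time.perf_counter()
    result = simulate_cohort(score, arm, params, costs, plan.n, seed)
    summary = summarize(result)
    log.info(
        "score=%d arm=%s conf=%.2f variant=%d n=%d runtime=%.2fs "
        "avg_cost=%.2f strokes=%d fatal=%d",
        score, arm.label, arm.ecg_confirmation, variant, plan.n,
        time.perf_counter() - t0, summary.average_cost,
        summary.total_strokes, summary.fatal_strokes,
    )
    return summary


@dataclass
class BaselineResult:
    summaries: dict[tuple[int, str, float], CohortSummary]
    comparisons: list[ArmComparison]
    summaries_frame: pd.DataFrame = field(repr=False, default=None)
    comparisons_frame: pd.DataFrame = field(repr=False, default=None)


def run_baseline_grid(
    plan: ExperimentPlan, params: ParameterSet, costs: CostParameters
) -> BaselineResult:
    """Simulate every score in the no-device arm and each device arm
    (one per ECG confirmation rate), and compare each device arm against the
    matched no-device cohort."""
    validate(params, costs)
    summaries: dict[tuple[int, str, float], CohortSummary] = {}
    comparisons: list[ArmComparison] = []

    for score in plan.scores:
        reference = _run_one(score, NO_DEVICE, params, costs, plan)
        summaries[(score, "no_device", 0.0)] = reference
        for conf in plan.confirmations:
            arm = device_arm(conf)
            summary = _run_one(score, arm, params, costs, plan)
            summaries[(score, "device", conf)] = summary
            comparisons.append(compare(reference, summary))

    summaries_frame = pd.DataFrame(
        {
            "score": s.score,
            "arm": s.arm_label,
            "ecg_confirmation": s.ecg_confirmation,
            "n": s.n,
            "average_cost_eur": s.average_cost,
            "total_strokes": s.total_strokes,
            "nonfatal_strokes": s.nonfatal_strokes,
            "fatal_strokes": s.fatal_strokes,
        }
        for s in summaries.values()
    )
    comparisons_frame = pd.DataFrame(
        {
            "score": c.score,
            "ecg_confirmation": c.ecg_confirmation,
            "cost_difference_eur": c.cost_difference,
            "prevented_strokes": c.prevented_strokes,
            "cost_per_prevented_stroke_eur": c.cost_per_prevented_stroke,
            "prevented_fatal_strokes": c.prevented_fatal_strokes,
            "cost_per_prevented_fatal_stroke_eur": c.cost_per_prevented_fatal_stroke,
        }
        for c in comparisons
    )
    return BaselineResult(summaries, comparisons, summaries_frame, comparisons_frame)


@dataclass
class SensitivityResult:
    by_sensitivity: dict[tuple[int, float], CohortSummary]  # (score, sensitivity)
    by_false_positive: dict[tuple[int, float], CohortSummary]  # (score, fp rate)


def run_sensitivity_grid(
    plan: ExperimentPlan, params: ParameterSet, costs: CostParameters
) -> SensitivityResult:
    """One-way grids over device sensitivity and false-positive rate.

    Device arm only, ECG confirmation fixed at
    ``plan.sensitivity_confirmation`` (0.75 in the published analysis).
    """
    validate(params, costs)
    arm = device_arm(plan.sensitivity_confirmation)
    by_sens: dict[tuple[int, float], CohortSummary] = {}
    by_fp: dict[tuple[int, float], CohortSummary] = {}
    for score in plan.scores:
        for value in plan.sensitivity_grid:
            varied = params.replace(device_sensitivity=value)
            variant = int(round(value * 100_000))
            by_sens[(score, value)] = _run_one(score, arm, varied, costs, plan, variant)
        for value in plan.false_positive_grid:
            if (
                value == params.device_false_positive
                and (score, params.device_sensitivity) in by_sens
            ):
                # the (base sensitivity, base false-positive) cell is shared
                # between the two grids; reuse the sensitivity-grid run
                by_fp[(score, value)] = by_sens[(score, params.device_sensitivity)]
                continue
            varied = params.replace(device_false_positive=value)
            variant = 1_000_000 + int(round(value * 100_000))
            by_fp[(score, value)] = _run_one(score, arm, varied, costs, plan, variant)
    return SensitivityResult(by_sens, by_fp)


# ---------------------------------------------------------------------------
# report files
# ---------------------------------------------------------------------------


def _arm_columns(s: CohortSummary, prefix: str) -> dict:
    return {
        f"{prefix}_avg_cost_eur": s.average_cost,
        f"{prefix}_total_strokes": s.total_strokes,
        f"{prefix}_nonfatal_strokes": s.nonfatal_strokes,
        f"{prefix}_fatal_strokes": s.fatal_strokes,
    }


def _paired_table(result: BaselineResult, pairs: list[tuple[str, tuple[str, float]]]) -> pd.DataFrame:
    scores = sorted({k[0] for k in result.summaries})
    rows = []
    for score in scores:
        row: dict = {"score": score}
        for prefix, (label, conf) in pairs:
            row.update(_arm_columns(result.summaries[(score, label, conf)], prefix))
        rows.append(row)
    frame = pd.DataFrame(rows)
    mean_row = frame.drop(columns="score").mean()
    mean_row["score"] = "mean"
    frame = pd.concat([frame, mean_row.to_frame().T], ignore_index=True)
    return frame


def _round_costs(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col == "score":
            continue
        out[col] = out[col].astype(float).round(0).astype("Int64")
    return out


def write_baseline_tables(result: BaselineResult, out_dir) -> list[Path]:
    """Write table3/4/5 report CSVs (whole-euro, published layout) plus
    full-precision machine-readable companions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table3 = _paired_table(
        result, [("no_device", ("no_device", 0.0)), ("device_conf50", ("device", 0.5))]
    )
    table4 = _paired_table(
        result, [("device_conf75", ("device", 0.75)), ("device_conf100", ("device", 1.0))]
    )
    for name, frame in (("table3.csv", table3), ("table4.csv", table4)):
        path = out_dir / name
        _round_costs(frame).to_csv(path, index=False)
        written.append(path)

    rows = []
    for conf in sorted({c.ecg_confirmation for c in result.comparisons}, reverse=True):
        for c in sorted(result.comparisons, key=lambda c: c.score):
            if c.ecg_confirmation != conf:
                continue
            rows.append(
                {
                    "ecg_confirmation": conf,
                    "score": c.score,
                    "cost_difference_eur": round(c.cost_difference),
                    "prevented_strokes": c.prevented_strokes,
                    "cost_per_prevented_stroke_eur": (
                        "undefined"
                        if c.cost_per_prevented_stroke is None
                        else round(c.cost_per_prevented_stroke)
                    ),
                    "prevented_fatal_strokes": c.prevented_fatal_strokes,
                    "cost_per_prevented_fatal_stroke_eur": (
                        "undefined"
                        if c.cost_per_prevented_fatal_stroke is None
                        else round(c.cost_per_prevented_fatal_stroke)
                    ),
                }
            )
    path = out_dir / "table5.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    for name, frame in (
        ("summaries_full.csv", result.summaries_frame),
        ("comparisons_full.csv", result.comparisons_frame),
    ):
        path = out_dir / name
        frame.to_csv(path, index=False)
        written.append(path)
    return written


def _sensitivity_table(
    cells: dict[tuple[int, float], CohortSummary], grid: tuple[float, ...]
) -> pd.DataFrame:
    scores = sorted({k[0] for k in cells})
    rows = []
    for score in scores:
        row: dict = {"score": score}
        for value in grid:
            s = cells[(score, value)]
            prefix = f"value_{value:g}"
            row[f"{prefix}_avg_cost_eur"] = round(s.average_cost)
            row[f"{prefix}_total_strokes"] = s.total_strokes
            row[f"{prefix}_fatal_strokes"] = s.fatal_strokes
        rows.append(row)
    return pd.DataFrame(rows)


def write_sensitivity_tables(
    result: SensitivityResult, plan: ExperimentPlan, out_dir
) -> list[Path]:
    """Write table6 (device sensitivity) and table7 (false-positive rate)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, cells, grid in (
        ("table6.csv", result.by_sensitivity, plan.sensitivity_grid),
        ("table7.csv", result.by_false_positive, plan.false_positive_grid),
    ):
        path = out_dir / name
        _sensitivity_table(cells, grid).to_csv(path, index=False)
        written.append(path)
    return written


def write_run_metadata(
    out_dir, plan: ExperimentPlan, config: dict | None = None
) -> Path:
    """Deterministic run metadata (config echo, seed, version) — no
    timestamps, so identical runs produce byte-identical files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "afscreen",
        "version": __version__,
        "base_seed": plan.base_seed,
        "n": plan.n,
        "scores": list(plan.scores),
        "confirmations": list(plan.confirmations),
        "sensitivity_grid": list(plan.sensitivity_grid),
        "false_positive_grid": list(plan.false_positive_grid),
        "config": config if config is not None else default_config(),
    }
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
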