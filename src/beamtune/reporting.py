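"""Aggregate per-plan gamma pass rates into verification statistics.

Each verification plan carries the local-criterion (1%/1 mm) gamma pass rate
of its measured film dose against every beam model under comparison. The
statistics mirror how such commissioning studies are summarized: per-model
mean GPR by delivery technique (DCAT vs VMAT), and per-plan GPR ratios of an
optimized model to the clinical baseline, expressed as a percentage
improvement and averaged per technique.

A packaged fixture of 15 lung SBRT verification plans (11 DCAT, 4 VMAT;
models: clinical AAA, SRT-optimized AAA, SRT-optimized Acuros XB) is
included so the aggregation can be exercised and demonstrated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BeamtuneError

TECHNIQUES = ("DCAT", "VMAT")

#: model keys used by the packaged fixture
MODELS = ("clin_aaa", "opt_aaa", "opt_acuros")


@dataclass(frozen=True)
class PlanVerificationRecord:
    """One verification plan with per-model gamma pass rates [%]."""

    plan_id: int
    target_volume: float     # [cm^3]
    technique: str           # DCAT | VMAT
    n_arcs: int
    mu: int                  # monitor units
    gpr_by_model: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise BeamtuneError(f"unknown technique {self.technique!r}")
        for model, g in self.gpr_by_model.items():
            if not 0.0 <= g <= 100.0:
                raise BeamtuneError(f"GPR {g!r} for {model!r} outside [0, 100]")


def records_from_frame(df: pd.DataFrame) -> list[PlanVerificationRecord]:
    """Build records from a table with plan metadata plus one GPR column per model."""
    meta = {"plan_id", "target_volume_cm3", "technique", "n_arcs", "mu"}
    missing = meta - set(df.columns)
    if missing:
        raise BeamtuneError(f"records table missing columns {sorted(missing)}")
    models = [c for c in df.columns if c not in meta]
    return [
        PlanVerificationRecord(
            plan_id=int(row.plan_id),
            target_volume=float(row.target_volume_cm3),
            technique=str(row.technique),
            n_arcs=int(row.n_arcs),
            mu=int(row.mu),
            gpr_by_model={m: float(getattr(row, m)) for m in models},
        )
        for row in df.itertuples(index=False)
    ]


def load_records(path: str | Path) -> list[PlanVerificationRecord]:
    """Read verification records from a CSV file."""
    return records_from_frame(pd.read_csv(path))


def table1_fixture() -> list[PlanVerificationRecord]:
    """The packaged 15-plan lung-SBRT verification fixture."""
    with resources.files("beamtune.data").joinpath("verification_plans.csv").open() as fh:
        return records_from_frame(pd.read_csv(fh))


def _select(
    records: Sequence[PlanVerificationRecord], technique: str | None
) -> list[PlanVerificationRecord]:
    if technique is None:
        return list(records)
    sel = [r for r in records if r.technique == technique]
    if not sel:
        raise BeamtuneError(f"no records with technique {technique!r}")
    return sel


def mean_gpr(
    records: Sequence[PlanVerificationRecord],
    model: str,
    technique: str | None = None,
) -> float:
    """Mean GPR [%] of a model over matching plans, reported to 0.1."""
    sel = _select(records, technique)
    try:
        vals = [r.gpr_by_model[model] for r in sel]
    except KeyError:
        raise BeamtuneError(f"model {model!r} missing from records") from None
    return round(float(np.mean(vals)), 1)


@dataclass(frozen=True)
class ImprovementStats:
    """Per-plan GPR ratio improvements of a model over a baseline."""

    per_plan: Mapping[int, float]    # plan_id -> 100*(GPR_model/GPR_base - 1)
    mean: float                      # unrounded mean of per-plan ratios

    @property
    def mean_rounded(self) -> float:
        return round(self.mean, 1)


def improvement_stats(
    records: Sequence[PlanVerificationRecord],
    model: str,
    baseline: str,
    technique: str | None = None,
) -> ImprovementStats:
    """Mean per-plan ratio improvement of ``model`` over ``baseline`` [%].

    Improvements are means of per-plan ratios (not ratios of means), the
    convention matching per-plan normalized GPR bars.
    """
    sel = _select(records, technique)
    per_plan = {}
    for r in sel:
        base = r.gpr_by_model[baseline]
        if base <= 0:
            raise BeamtuneError(f"plan {r.plan_id}: baseline GPR must be positive")
        per_plan[r.plan_id] = 100.0 * (r.gpr_by_model[model] / base - 1.0)
    return ImprovementStats(per_plan=per_plan, mean=float(np.mean(list(per_plan.values()))))


def summary_table(records: Sequence[PlanVerificationRecord],
                  baseline: str = "clin_aaa") -> pd.DataFrame:
    """Mean GPR and mean ratio improvement per (technique, model)."""
    models = sorted({m for r in records for m in r.gpr_by_model})
    rows = []
    for tech in TECHNIQUES:
        if not any(r.technique == tech for r in records):
            continue
        for m in models:
            row = {
                "technique": tech,
                "model": m,
                "mean_gpr": mean_gpr(records, m, tech),
            }
            if m != baseline and baseline in records[0].gpr_by_model:
                row["mean_improvement_pct"] = improvement_stats(
                    records, m, baseline, tech
                ).mean_rounded
            rows.append(row)
    return pd.DataFrame(rows)
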