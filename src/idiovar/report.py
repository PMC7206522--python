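"""Cohort-level aggregation and the end-to-end per-patient pipeline.

One patient's analysis runs diary logs → aligned series → inclusion filter →
imputation/stationarity filter → VAR with AIC lag selection → Granger tests
in both directions → cumulative IRF and FEVD over a 10-day horizon, once per
sleep model (model "tst": total sleep time + depression; model "tib": time in
bed + depression).  The cohort report then counts significant associations by
model, direction and sign, and averages IRF/FEVD magnitudes across patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ingest import InclusionDecision, PatientSeries, align_series, inclusion_filter
from .preprocess import prepare_pair
from .var_model import GrangerResult, PatientVAR, VARResults

__all__ = [
    "ModelGranger",
    "PatientAnalysis",
    "AssociationSummary",
    "analyze_patient",
    "analyze_cohort",
    "classify_associations",
    "aggregate_abs_mean",
    "table_mean_row",
    "cohort_descriptives",
]

SLEEP_MODELS = {"tst": "tst_min", "tib": "tib_min"}


@dataclass
class ModelGranger:
    """Both directed Granger tests of one patient under one sleep model."""

    patient_id: str
    model: str  # 'tst' | 'tib'
    sleep_to_dep: GrangerResult
    dep_to_sleep: GrangerResult


@dataclass
class PatientAnalysis:
    """Everything the pipeline derived for one patient and one sleep model."""

    patient_id: str
    model: str
    inclusion: InclusionDecision
    lag_order: int | None = None
    var_results: VARResults | None = None
    granger: ModelGranger | None = None
    cum_irf: dict = field(default_factory=dict)     # direction -> np.ndarray (H+1,)
    fevd_cross: dict = field(default_factory=dict)  # direction -> np.ndarray (H,)
    preprocess_info: dict = field(default_factory=dict)


def analyze_patient(
    series: PatientSeries,
    model: str = "tib",
    maxlag: int = 7,
    alpha: float = 0.05,
    horizon: int = 10,
    min_days: int = 130,
    max_missing_frac: float = 0.30,
    order_grid=None,
    bonferroni: bool = False,
) -> PatientAnalysis:
    """Run the full idiographic analysis for one patient and one sleep model.

    ``bonferroni=True`` halves ``alpha`` to correct for testing the two
    causal directions within the model; the default (off) matches the
    uncorrected per-test 5% convention of idiographic reporting.
    """
    if model not in SLEEP_MODELS:
        raise ValueError(f"model must be one of {sorted(SLEEP_MODELS)}")
    decision = inclusion_filter(series, min_days=min_days, max_missing_frac=max_missing_frac)
    out = PatientAnalysis(patient_id=series.patient_id, model=model, inclusion=decision)
    if not decision.include:
        return out

    if bonferroni:
        alpha = alpha / 2.0
    sleep = getattr(series, SLEEP_MODELS[model])
    dep = series.dep_score
    kwargs = {} if order_grid is None else {"order_grid": order_grid}
    fs, fd, info = prepare_pair(sleep, dep, names=(model, "dep"), **kwargs)
    out.preprocess_info = info

    var_model = PatientVAR(np.column_stack([fs, fd]), names=(model, "dep"))
    res = var_model.fit(maxlag=maxlag)
    out.var_results = res
    out.lag_order = res.p
    out.granger = ModelGranger(
        patient_id=series.patient_id,
        model=model,
        sleep_to_dep=res.granger(model, "dep", alpha=alpha),
        dep_to_sleep=res.granger("dep", model, alpha=alpha),
    )
    for impulse, response, key in (
        (model, "dep", "sleep_to_dep"),
        ("dep", model, "dep_to_sleep"),
    ):
        irf = res.irf(impulse, response, horizon=horizon)
        out.cum_irf[key] = irf.cumulative
    for fv in res.fevd(horizon=horizon):
        if fv.target == "dep":
            out.fevd_cross["sleep_to_dep"] = fv.share_from(model)
        else:
            out.fevd_cross["dep_to_sleep"] = fv.share_from("dep")
    return out


def analyze_cohort(
    logs_by_patient: dict,
    models: tuple[str, ...] = ("tst", "tib"),
    **kwargs,
) -> list[PatientAnalysis]:
    """Align and analyze every patient under every sleep model."""
    analyses = []
    for pid in sorted(logs_by_patient):
        series = align_series(logs_by_patient[pid])
        for model in models:
            analyses.append(analyze_patient(series, model=model, **kwargs))
    return analyses


@dataclass
class AssociationSummary:
    """Counts of significant associations: model × direction × sign."""

    table: pd.DataFrame

    def count(self, model: str, direction: str, sign: str | None = None) -> int:
        row = self.table[
            (self.table["model"] == model) & (self.table["direction"] == direction)
        ]
        if row.empty:
            return 0
        if sign is None:
            return int(row["total"].iloc[0])
        return int(row[sign].iloc[0])


def classify_associations(results: list[ModelGranger]) -> AssociationSummary:
    """Tabulate significant Granger results by model, direction and sign.

    A patient-model with both directions significant is counted once under
    ``mutual`` (and not under either single direction), the convention of the
    published summary table.
    """
    rows = {}
    for model in ("tib", "tst"):
        for direction in ("sleep_causes_dep", "dep_causes_sleep", "mutual"):
            rows[(model, direction)] = {"positive": 0, "negative": 0}
    for rec in results:
        s2d, d2s = rec.sleep_to_dep, rec.dep_to_sleep
        if s2d.significant and d2s.significant:
            rows[(rec.model, "mutual")][s2d.association_sign] += 1
        elif s2d.significant:
            rows[(rec.model, "sleep_causes_dep")][s2d.association_sign] += 1
        elif d2s.significant:
            rows[(rec.model, "dep_causes_sleep")][d2s.association_sign] += 1
    table = pd.DataFrame(
        [
            {
                "model": model,
                "direction": direction,
                "positive": counts["positive"],
                "negative": counts["negative"],
                "total": counts["positive"] + counts["negative"],
            }
            for (model, direction), counts in rows.items()
        ]
    )
    return AssociationSummary(table)


def _round_half_up(x: float, digits: int = 2) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_abs_mean(values, digits: int = 2) -> float:
    """Mean of absolute values, half-up rounded — the cohort-table convention.

    Printed cohort mean rows average response *magnitudes* so that positive
    and negative patient effects do not cancel.  Exact decimal arithmetic is
    used so that printed two-decimal inputs round the way they do on paper.
    """
    vals = list(values)
    if not vals:
        raise ValueError("no values to aggregate")
    total = sum(abs(Decimal(repr(float(v)))) for v in vals)
    mean = total / len(vals)
    q = Decimal(1).scaleb(-digits)
    return float(mean.quantize(q, rounding=ROUND_HALF_UP))


def table_mean_row(frame: pd.DataFrame, value_cols: list[str], signed: bool = False) -> pd.Series:
    """Column-wise mean row for a per-patient table.

    ``signed=False`` (default) reproduces the published convention — mean of
    magnitudes; ``signed=True`` gives the plain arithmetic mean, emitted
    alongside for comparison.
    """
    if signed:
        return frame[value_cols].mean().round(2)
    return pd.Series(
        {c: aggregate_abs_mean(frame[c].to_numpy()) for c in value_cols}
    )


def cohort_descriptives(table: pd.DataFrame) -> dict:
    """Cohort summary: mean/min/max diary days, median age, sex counts."""
    days = table["days"].to_numpy(dtype=float)
    mean_days = int(
        Decimal(repr(float(np.mean(days)))).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    )
    out = {
        "n_patients": int(len(table)),
        "mean_days": mean_days,
        "min_days": int(days.min()),
        "max_days": int(days.max()),
        "median_age": float(np.median(table["age"].to_numpy(dtype=float))),
        "sex_counts": table["sex"].value_counts().to_dict(),
    }
    return out
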