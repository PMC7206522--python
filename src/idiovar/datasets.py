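"""Bundled reference tables from the motivating feasibility cohort.

Three small per-patient tables published with the study that motivated this
pipeline (the raw diaries themselves are not public):

* ``cohort_demographics`` — patient id, diary span in days, sex, age;
* ``cumulative_irf_reference`` — cumulative impulse responses over a 10-day
  horizon for each patient with a significant Granger result, grouped by
  direction (``tib_to_dep``, ``dep_to_tib``, ``tst_to_dep``, ``dep_to_tst``);
  units are minutes when sleep responds, score units when depression responds;
* ``fevd_reference`` — forecast-error variance shares for the same patients
  (the published table prints horizons 1–6 and 8–10; lag 7 was not printed).

These serve as worked-example inputs for the aggregation conventions in
:mod:`idiovar.report`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_cohort_demographics",
    "load_cumulative_irf_reference",
    "load_fevd_reference",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("idiovar.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_cohort_demographics() -> pd.DataFrame:
    """Per-patient diary span (days), sex and age, one row per patient."""
    return _load("cohort_demographics.csv")


def load_cumulative_irf_reference() -> pd.DataFrame:
    """Published per-patient cumulative IRFs, horizons 0–10, by direction."""
    return _load("cumulative_irf_reference.csv")


def load_fevd_reference() -> pd.DataFrame:
    """Published per-patient FEVD shares at the printed horizons, by direction."""
    return _load("fevd_reference.csv")
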