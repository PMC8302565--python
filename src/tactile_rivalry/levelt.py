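"""Levelt-proposition-II surfaces: condition curves and equidominance.

Levelt's proposition II states that increasing the difference between
percept strengths mainly increases the mean dominance duration of the
stronger percept.  For the tactile stimulus the control parameter is the
intensity difference delta-I (dB): as it grows the SIM percept weakens and
the AM percept strengthens, so the SIM mean-duration curve should fall, the
AM curve rise, and the alternation rate peak at equidominance (equal
dominance proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phases import AM, SIM


@dataclass
class ConditionCurve:
    """Across-subject mean and SEM of the per-condition summaries."""

    table: pd.DataFrame  # delta_i_db, percept, mean_duration, sem_duration,
    #                      mean_proportion, sem_proportion
    rates: pd.DataFrame  # delta_i_db, mean_rate, sem_rate

    def proportion_curve(self, percept: str = SIM) -> pd.DataFrame:
        sel = self.table[self.table["percept"] == percept]
        return sel[["delta_i_db", "mean_proportion"]].reset_index(drop=True)


def _mean_sem(x: pd.Series) -> tuple[float, float]:
    v = x.dropna().to_numpy(dtype=float)
    if v.size == 0:
        return np.nan, np.nan
    sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return float(v.mean()), float(sem)


def condition_curves(subject_table: pd.DataFrame) -> ConditionCurve:
    """Per-condition curves (mean +/- SEM across subjects).

    ``subject_table`` is the tidy output of
    :func:`tactile_rivalry.phases.subject_condition_means` — one row per
    (subject, delta_i_db, percept).  Conditions with fewer than two
    contributing subjects raise; missing subject cells are dropped with a
    warning.
    """
    rows = []
    for (di, percept), grp in subject_table.groupby(["delta_i_db", "percept"]):
        n_missing = grp["mean_duration_s"].isna().sum()
        if n_missing:
            warnings.warn(f"dropping {n_missing} missing subject cells at "
                          f"delta_i={di}, percept={percept}")
        n_eff = grp["mean_duration_s"].notna().sum()
        if n_eff < 2:
            raise ValueError(f"fewer than 2 subjects with data at "
                             f"delta_i={di}, percept={percept}")
        mdur, sdur = _mean_sem(grp["mean_duration_s"])
        mprop, sprop = _mean_sem(grp["proportion"])
        rows.append((di, percept, mdur, sdur, mprop, sprop, int(n_eff)))
    table = pd.DataFrame(rows, columns=[
        "delta_i_db", "percept", "mean_duration", "sem_duration",
        "mean_proportion", "sem_proportion", "n_subjects"]).sort_values(
        ["delta_i_db", "percept"]).reset_index(drop=True)

    rates = alternation_rate_curve(subject_table)
    return ConditionCurve(table=table, rates=rates)


def alternation_rate_curve(subject_table: pd.DataFrame) -> pd.DataFrame:
    """Mean alternation rate (switches/min) per condition across subjects."""
    sub = subject_table.drop_duplicates(["subject", "delta_i_db"])
    rows = []
    for di, grp in sub.groupby("delta_i_db"):
        if grp["alternation_rate"].notna().sum() < 2:
            raise ValueError(f"fewer than 2 subjects with data at delta_i={di}")
        m, s = _mean_sem(grp["alternation_rate"])
        rows.append((di, m, s))
    return pd.DataFrame(rows, columns=["delta_i_db", "mean_rate", "sem_rate"]
                        ).sort_values("delta_i_db").reset_index(drop=True)


@dataclass
class EquidominanceEstimate:
    delta_i_db: float | None
    bracket: tuple[float, float] | None
    at_boundary: bool


def estimate_equidominance(curves: ConditionCurve) -> EquidominanceEstimate:
    """Delta-I at which the SIM dominance proportion crosses one half.

    Linear interpolation in dB between the two tested levels bracketing the
    .5 crossing of the SIM proportion curve; an exact attainment is returned
    as-is.  With several crossings the one nearest the alternation-rate
    maximum is taken (the rate should peak at equidominance).  A curve that
    never reaches .5 yields a boundary flag — no extrapolation.
    """
    prop = curves.proportion_curve(SIM).sort_values("delta_i_db")
    x = prop["delta_i_db"].to_numpy(dtype=float)
    y = prop["mean_proportion"].to_numpy(dtype=float)

    hits: list[tuple[float, tuple[float, float]]] = []
    for i in range(len(x)):
        if np.isclose(y[i], 0.5):
            hits.append((x[i], (x[i], x[i])))
    for i in range(len(x) - 1):
        y0, y1 = y[i] - 0.5, y[i + 1] - 0.5
        if y0 * y1 < 0:
            xc = x[i] + (x[i + 1] - x[i]) * (-y0) / (y1 - y0)
            hits.append((float(xc), (float(x[i]), float(x[i + 1]))))
    if not hits:
        return EquidominanceEstimate(delta_i_db=None, bracket=None,
                                     at_boundary=True)
    if len(hits) > 1:
        rates = curves.rates
        peak = float(rates.loc[rates["mean_rate"].idxmax(), "delta_i_db"])
        hits.sort(key=lambda h: abs(h[0] - peak))
    xc, bracket = hits[0]
    return EquidominanceEstimate(delta_i_db=xc, bracket=bracket,
                                 at_boundary=False)
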