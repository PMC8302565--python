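"""Lag-1 and lag-2 correlations between successive dominance durations.

Two estimators of serial dependence in the percept stream:

* **pooled** — durations are normalized to the mean of each percept type
  within each trial (removing inter-subject and inter-trial scale
  differences that would otherwise induce spurious correlation), lagged
  pairs are pooled across all trials and subjects, and a single Pearson
  coefficient is computed with its two-sided t-based p-value;
* **single-trial** — the raw (un-normalized) Pearson coefficient is
  computed within every trial with enough pairs, and the distribution of
  per-trial coefficients is tested against zero with a one-sample t-test.

Because phases strictly alternate, lag-1 pairs always relate different
percepts (SIM->AM or AM->SIM) and lag-2 pairs the same percept
(SIM->SIM or AM->AM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phases import AM, SIM, PerceptPhase, Trial

TRANSITIONS = {
    ("SIM", "AM"): 1, ("AM", "SIM"): 1,
    ("SIM", "SIM"): 2, ("AM", "AM"): 2,
}


@dataclass(frozen=True)
class LagSpec:
    """Which lagged pairing to analyse: source percept and target percept.

    The lag is implied: different percepts -> lag 1 (adjacent phases), same
    percept -> lag 2 (next-but-one phase).
    """

    source: str
    target: str

    def __post_init__(self):
        if (self.source, self.target) not in TRANSITIONS:
            raise ValueError(f"unknown transition {self.source}->{self.target}")

    @property
    def lag(self) -> int:
        return TRANSITIONS[(self.source, self.target)]

    def __str__(self) -> str:
        return f"lag{self.lag}:{self.source}->{self.target}"


ALL_SPECS = (LagSpec(SIM, AM), LagSpec(AM, SIM), LagSpec(SIM, SIM),
             LagSpec(AM, AM))


@dataclass
class CorrelationResult:
    method: str           # "pooled" or "single_trial"
    spec: LagSpec
    corr: float           # Pearson r (pooled) or mean m of per-trial r's
    p: float
    N: int                # pair count (pooled) or eligible-trial count
    std: float | None = None   # SD of per-trial coefficients
    t: float | None = None     # one-sample t statistic (single-trial method)

    def summary(self) -> str:
        if self.method == "pooled":
            return (f"{self.spec}  pooled corr={self.corr:+.3f} "
                    f"p={self.p:.2g} N={self.N}")
        return (f"{self.spec}  single-trial m={self.corr:+.3f} "
                f"std={self.std:.3f} t={self.t:.2f} p={self.p:.2g} N={self.N}")


class MalformedSequenceError(ValueError):
    pass


def lagged_pairs(phases: list[PerceptPhase], spec: LagSpec,
                 values: np.ndarray | None = None) -> np.ndarray:
    """(n_pairs, 2) array of lagged duration pairs for one phase sequence.

    Lag 1 with transition X->Y pairs every phase labelled X with its
    successor; lag 2 with X->X pairs it with the phase after that.  Censored
    phases never enter a pair (their duration is unknown).  ``values``
    optionally substitutes per-phase values (e.g. normalized durations) for
    the raw ones.
    """
    labels = [p.percept for p in phases]
    for a, b in zip(labels, labels[1:]):
        if a == b:
            raise MalformedSequenceError(
                "phase sequence is not strictly alternating")
    if values is None:
        values = np.array([p.duration for p in phases], dtype=float)
    ok = np.array([not p.censored for p in phases])
    lag = spec.lag
    pairs = [
        (values[i], values[i + lag])
        for i in range(len(phases) - lag)
        if labels[i] == spec.source and labels[i + lag] == spec.target
        and ok[i] and ok[i + lag]
    ]
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


def _normalized_values(trial: Trial) -> np.ndarray:
    """Durations normalized by the trial's per-percept-type means."""
    vals = np.array([p.duration for p in trial.phases], dtype=float)
    out = np.empty_like(vals)
    for percept in (SIM, AM):
        mask = np.array([p.percept == percept and not p.censored
                         for p in trial.phases])
        lab = np.array([p.percept == percept for p in trial.phases])
        mean = vals[mask].mean() if mask.any() else np.nan
        out[lab] = vals[lab] / mean
    return out


def pooled_corr(trials: list[Trial], spec: LagSpec,
                method: str = "t", n_perm: int = 10000,
                rng: np.random.Generator | int | None = None
                ) -> CorrelationResult:
    """Pooled-scatter Pearson correlation across all trials and subjects.

    Durations are normalized per trial x percept type before pooling.  The
    p-value is the two-sided t-based one by default; ``method="permutation"``
    instead permutes the second pair member within the pooled scatter.
    """
    chunks = [lagged_pairs(t.phases, spec, values=_normalized_values(t))
              for t in trials if not t.excluded]
    pairs = np.vstack([c for c in chunks if c.size]) if chunks else \
        np.empty((0, 2))
    pairs = pairs[np.isfinite(pairs).all(axis=1)]
    if pairs.shape[0] < 3:
        raise ValueError("fewer than 3 pooled pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise ValueError("undefined correlation: zero-variance pooled margin")
    r, p = stats.pearsonr(x, y)
    if method == "permutation":
        rng = np.random.default_rng(rng)
        null = np.empty(n_perm)
        for k in range(n_perm):
            null[k] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (n_perm + 1))
    return CorrelationResult(method="pooled", spec=spec, corr=float(r),
                             p=float(p), N=int(pairs.shape[0]))


def single_trial_corr(trials: list[Trial], spec: LagSpec,
                      min_pairs: int = 3) -> CorrelationResult:
    """Distribution of within-trial correlations tested against zero.

    Each trial with at least ``min_pairs`` lagged pairs contributes one raw
    Pearson coefficient; the mean m of the distribution is tested with a
    two-sided one-sample t-test.  Trials with degenerate (zero-variance)
    margins are skipped like under-filled ones.
    """
    coefs = []
    for t in trials:
        if t.excluded:
            continue
        pairs = lagged_pairs(t.phases, spec)
        if pairs.shape[0] < min_pairs:
            continue
        x, y = pairs[:, 0], pairs[:, 1]
        if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
            continue
        coefs.append(float(stats.pearsonr(x, y)[0]))
    if len(coefs) < 2:
        raise ValueError("fewer than 2 trials with computable correlations")
    coefs = np.asarray(coefs)
    m = float(coefs.mean())
    sd = float(coefs.std(ddof=1))
    if sd == 0.0:
        return CorrelationResult(method="single_trial", spec=spec, corr=m,
                                 p=np.nan, N=coefs.size, std=0.0, t=np.nan)
    tt = stats.ttest_1samp(coefs, 0.0)
    return CorrelationResult(method="single_trial", spec=spec, corr=m,
                             p=float(tt.pvalue), N=coefs.size, std=sd,
                             t=float(tt.statistic))


def correlation_table(trials: list[Trial], min_pairs: int = 3
                      ) -> pd.DataFrame:
    """All four transitions by both methods, one row per (method, spec)."""
    rows = []
    for spec in ALL_SPECS:
        for res in (pooled_corr(trials, spec),
                    single_trial_corr(trials, spec, min_pairs=min_pairs)):
            rows.append({
                "method": res.method, "lag": spec.lag,
                "transition": f"{spec.source}->{spec.target}",
                "corr": res.corr, "p": res.p, "N": res.N,
                "std": res.std, "t": res.t,
            })
    return pd.DataFrame(rows)
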