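"""Duration-distribution analysis: normalization, gamma/log-normal fits,
KS goodness-of-fit, central moments and the scaling property.

Dominance durations in bistable perception vary widely across observers and
conditions, but their distribution keeps a characteristic shape.  A scaling
property holds when central moments are proportional to powers of the mean,

    mu_2 propto mu_1^2,  mu_3 propto mu_1^3
        <=>  c_v = const,  gamma_1 = const,

with c_v = sqrt(mu_2)/mu_1 (coefficient of variation) and
gamma_1 = mu_3 / mu_2^(3/2) (skewness).  Normalizing durations by their
group mean removes the scale, so pooled normalized samples from different
conditions are comparable and can be tested against gamma and log-normal
families.

Closed forms used as oracles elsewhere: for a gamma distribution
gamma_1 / c_v = 2 identically; for a log-normal, gamma_1 = c_v^3 + 3 c_v.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phases import Trial

FAMILIES = ("gamma", "lognormal")


@dataclass
class MomentSummary:
    """Sample moments: mean, central moments, cv, skewness and their ratio.

    Central moments use the biased (1/n) definitions.  For a degenerate
    (zero-variance) sample cv = 0 and gamma1 is undefined (NaN).
    """

    mu1: float
    mu2: float
    mu3: float
    cv: float
    gamma1: float
    gamma1_over_cv: float
    n: int


@dataclass
class FitResult:
    family: str
    params: dict[str, float]
    loglik: float
    ks_d: float | None = None
    ks_p: float | None = None

    def frozen(self):
        """Frozen scipy distribution with the fitted parameters."""
        if self.family == "gamma":
            return stats.gamma(self.params["shape"], scale=self.params["scale"])
        return stats.lognorm(self.params["sigma"],
                             scale=np.exp(self.params["mu_log"]))

    def summary(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        ks = (f", KS D={self.ks_d:.4f} p={self.ks_p:.4f}"
              if self.ks_d is not None else "")
        return f"{self.family}({pars}), loglik={self.loglik:.2f}{ks}"


def moment_summary(samples: np.ndarray) -> MomentSummary:
    """Mean, second/third central moments, cv, skewness and gamma1/cv."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for third moments")
    mu1 = float(x.mean())
    d = x - mu1
    mu2 = float(np.mean(d**2))
    mu3 = float(np.mean(d**3))
    if mu2 == 0.0:
        return MomentSummary(mu1, 0.0, 0.0, cv=0.0, gamma1=np.nan,
                             gamma1_over_cv=np.nan, n=x.size)
    cv = np.sqrt(mu2) / mu1
    gamma1 = mu3 / mu2**1.5
    return MomentSummary(mu1, mu2, mu3, cv=float(cv), gamma1=float(gamma1),
                         gamma1_over_cv=float(gamma1 / cv), n=x.size)


# ---------------------------------------------------------------------------
# normalization


def normalize_durations(trials: list[Trial],
                        scheme: str = "per_subject_condition_percept",
                        drop_first: bool = False,
                        drop_censored: bool = True) -> pd.DataFrame:
    """Durations divided by their group mean under the chosen scheme.

    Schemes: ``per_trial_percept`` groups by (subject, condition, repetition,
    percept); ``per_subject_condition_percept`` pools repetitions first.
    Within every group the normalized mean is exactly one, so samples from
    different subjects and conditions can be pooled.  ``drop_first`` removes
    each trial's first phase before normalization.
    """
    if scheme not in ("per_trial_percept", "per_subject_condition_percept"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    rows = []
    for t in trials:
        phases = t.phases[1:] if drop_first else t.phases
        for p in phases:
            if drop_censored and p.censored:
                continue
            rows.append((t.subject, t.delta_i, t.repetition, p.percept,
                         p.duration))
    table = pd.DataFrame(rows, columns=["subject", "delta_i_db", "repetition",
                                        "percept", "duration_s"])
    if table.empty:
        raise ValueError("no durations to normalize")
    keys = (["subject", "delta_i_db", "repetition", "percept"]
            if scheme == "per_trial_percept"
            else ["subject", "delta_i_db", "percept"])
    gmean = table.groupby(keys)["duration_s"].transform("mean")
    if (gmean <= 0).any():
        raise ValueError("degenerate group with non-positive mean")
    table["normalized"] = table["duration_s"] / gmean
    return table


# ---------------------------------------------------------------------------
# fitting and goodness of fit


class DurationDistribution:
    """Maximum-likelihood model of positive duration samples.

    Two-parameter families only (no location shift): gamma (shape, scale)
    fitted by scipy's MLE with the location pinned at zero, and log-normal
    via the exact closed-form MLE of the log-durations (mu_log, sigma).
    """

    def __init__(self, samples: np.ndarray, family: str = "gamma"):
        x = np.asarray(samples, dtype=float)
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if x.size < 5:
            raise ValueError("need at least 5 samples")
        if (x <= 0).any():
            raise ValueError("durations must be strictly positive")
        if np.allclose(x, x[0]):
            raise ValueError("degenerate constant sample: MLE diverges")
        self.samples = x
        self.family = family

    def fit(self) -> FitResult:
        x = self.samples
        if self.family == "gamma":
            shape, _, scale = stats.gamma.fit(x, floc=0.0)
            params = {"shape": float(shape), "scale": float(scale)}
            loglik = float(stats.gamma.logpdf(x, shape, scale=scale).sum())
        else:
            logs = np.log(x)
            mu_log = float(logs.mean())
            sigma = float(logs.std(ddof=0))
            params = {"mu_log": mu_log, "sigma": sigma}
            loglik = float(stats.lognorm.logpdf(x, sigma,
                                                scale=np.exp(mu_log)).sum())
        result = FitResult(family=self.family, params=params, loglik=loglik)
        result.ks_d, result.ks_p = ks_gof(x, result)
        return result


def fit_duration_dist(samples: np.ndarray, family: str) -> FitResult:
    """Functional wrapper around :class:`DurationDistribution`."""
    return DurationDistribution(samples, family).fit()


def ks_gof(samples: np.ndarray, fitted: FitResult) -> tuple[float, float]:
    """One-sample KS statistic and asymptotic p against the fitted CDF.

    The p-value treats the fitted parameters as known; since they were
    estimated from the same sample the test is conservative (the Lilliefors
    bias) — rejection still indicates incompatibility with the family.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples for a KS test")
    res = stats.kstest(x, fitted.frozen().cdf)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# scaling property


@dataclass
class ScalingAssessment:
    per_condition: pd.DataFrame  # delta_i_db, n, cv, cv_lo, cv_hi,
    #                              gamma1_over_cv and its CI
    max_cv_diff: float
    max_cv_diff_ci: tuple[float, float]
    dropped: list[float]

    def summary(self) -> str:
        lines = ["Scaling-property assessment (bootstrap 95% CIs)"]
        for r in self.per_condition.itertuples():
            lines.append(
                f"  dI={r.delta_i_db:g} dB  n={r.n}  cv={r.cv:.3f} "
                f"[{r.cv_lo:.3f}, {r.cv_hi:.3f}]  g1/cv={r.gamma1_over_cv:.3f} "
                f"[{r.g1cv_lo:.3f}, {r.g1cv_hi:.3f}]")
        lo, hi = self.max_cv_diff_ci
        lines.append(f"  max pairwise cv difference: {self.max_cv_diff:.3f} "
                     f"[{lo:.3f}, {hi:.3f}]")
        return "\n".join(lines)


def scaling_assessment(trials: list[Trial],
                       conditions: list[float] | None = None,
                       n_boot: int = 1000,
                       min_phases: int = 20,
                       scheme: str = "per_subject_condition_percept",
                       rng: np.random.Generator | int | None = None
                       ) -> ScalingAssessment:
    """Constancy of cv and gamma1/cv across conditions (scaling property).

    Durations are normalized under ``scheme`` and pooled per condition;
    conditions with fewer than ``min_phases`` phases are dropped with a
    warning (extreme conditions have few alternations, making second and
    third moments unreliable).  Percentile bootstrap intervals are attached
    to each condition's cv and gamma1/cv and to the constancy summary (the
    maximum pairwise cv difference) — a scaling violation shows as that
    interval excluding zero.
    """
    rng = np.random.default_rng(rng)
    table = normalize_durations(trials, scheme=scheme)
    if conditions is None:
        conditions = sorted(table["delta_i_db"].unique().tolist())
    pooled: dict[float, np.ndarray] = {}
    dropped: list[float] = []
    for di in conditions:
        x = table.loc[table["delta_i_db"] == di, "normalized"].to_numpy()
        if x.size < min_phases:
            warnings.warn(f"condition delta_i={di} dropped: only {x.size} "
                          f"phases (< {min_phases})")
            dropped.append(di)
        else:
            pooled[di] = x
    if len(pooled) < 2:
        raise ValueError("need >= 2 conditions with enough phases")

    rows = []
    boot_cv = {}
    for di, x in pooled.items():
        ms = moment_summary(x)
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        bs = x[idx]
        mu1 = bs.mean(axis=1)
        d = bs - mu1[:, None]
        mu2 = np.mean(d**2, axis=1)
        mu3 = np.mean(d**3, axis=1)
        cv_b = np.sqrt(mu2) / mu1
        g1cv_b = (mu3 / mu2**1.5) / cv_b
        boot_cv[di] = cv_b
        rows.append((di, x.size, ms.cv,
                     float(np.percentile(cv_b, 2.5)),
                     float(np.percentile(cv_b, 97.5)),
                     ms.gamma1_over_cv,
                     float(np.percentile(g1cv_b, 2.5)),
                     float(np.percentile(g1cv_b, 97.5))))
    per_condition = pd.DataFrame(rows, columns=[
        "delta_i_db", "n", "cv", "cv_lo", "cv_hi",
        "gamma1_over_cv", "g1cv_lo", "g1cv_hi"])

    dis = list(pooled)
    point = max(abs(per_condition.set_index("delta_i_db").loc[a, "cv"]
                    - per_condition.set_index("delta_i_db").loc[b, "cv"])
                for i, a in enumerate(dis) for b in dis[i + 1:])
    boot_max = np.max(
        [[abs(boot_cv[a][k] - boot_cv[b][k])
          for i, a in enumerate(dis) for b in dis[i + 1:]]
         for k in range(n_boot)], axis=1)
    ci = (float(np.percentile(boot_max, 2.5)),
          float(np.percentile(boot_max, 97.5)))
    return ScalingAssessment(per_condition=per_condition,
                             max_cv_diff=float(point), max_cv_diff_ci=ci,
                             dropped=dropped)


def histogram_with_fits(samples: np.ndarray, n_bins: int = 20
                        ) -> pd.DataFrame:
    """Histogram bin data plus fitted gamma/log-normal densities for replotting."""
    x = np.asarray(samples, dtype=float)
    counts, edges = np.histogram(x, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                        "density": counts})
    for family in FAMILIES:
        fit = fit_duration_dist(x, family)
        out[f"{family}_density"] = fit.frozen().pdf(centers)
    return out
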