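"""Within-subject (repeated-measures) ANOVA, sphericity machinery, effect
sizes, Bonferroni pairwise tests and noncentral-F power analysis.

The univariate mixed-model decomposition is used throughout: each
within-subject effect is tested against its own subject-by-effect
interaction error term.  Mauchly's sphericity test and the
Greenhouse-Geisser (GG) epsilon are computed for every effect with at least
three levels; the GG-corrected p-value is always stored, and the reporting
convention (quote the corrected p when Mauchly reaches significance) is
applied at the summary layer, never by discarding the uncorrected value.

The entry point is the model class::

    res = RepeatedMeasuresAnova(df, dv="mean_duration_s",
                                within=["delta_i_db", "percept"],
                                subject="subject").fit()
    print(res.summary())

Designs must be complete and balanced (every subject observed once in every
cell); missing cells raise rather than being imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    """One effect row of a within-subject ANOVA table."""

    effect: str
    df_num: float
    df_den: float
    F: float
    p: float
    ges: float
    eta_p2: float
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    p_gg: float
    ss_effect: float
    ss_error: float


class MissingCellError(ValueError):
    pass


def _orthonormal_contrast(m: int) -> np.ndarray:
    """(m-1) x m orthonormal contrast matrix (orthonormalised Helmert)."""
    c = np.zeros((m - 1, m))
    for i in range(m - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def mauchly_epsilon(cov: np.ndarray, n_subjects: int
                    ) -> tuple[float, float, float]:
    """Mauchly's W (with chi-square p) and Greenhouse-Geisser epsilon.

    ``cov`` is the m x m sample covariance of a subject's m within-condition
    scores.  W is computed from the covariance of the orthonormally
    contrasted scores S = C cov C'; its null distribution is approximated by
    the standard chi-square with m(m-1)/2 - 1 degrees of freedom.  Epsilon is
    the eigenvalue form (sum lambda)^2 / ((m-1) sum lambda^2) of S, which
    ranges from 1/(m-1) (maximal non-sphericity) to 1 (sphericity).

    With m = 2 sphericity holds trivially: W = 1, p = 1, epsilon = 1.
    """
    cov = np.asarray(cov, dtype=float)
    m = cov.shape[0]
    if cov.shape != (m, m):
        raise ValueError("covariance must be square")
    if m < 2:
        raise ValueError("need at least 2 within levels")
    C = _orthonormal_contrast(m)
    S = C @ cov @ C.T
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    if eig.max() <= 0:
        raise ValueError("degenerate within-subject covariance")
    eps = float(eig.sum() ** 2 / ((m - 1) * (eig**2).sum()))
    if m == 2:
        return 1.0, 1.0, 1.0
    if eig.min() <= 0 or n_subjects <= m - 1:
        raise ValueError("rank-deficient covariance: more within levels than "
                         "subjects support")
    d = m - 1
    W = float(np.prod(eig) / (eig.sum() / d) ** d)
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n_subjects - 1))
    chi2 = -(n_subjects - 1) * f * math.log(max(W, 1e-300))
    dof = m * (m - 1) / 2.0 - 1.0
    p = float(stats.chi2.sf(chi2, dof))
    return W, p, eps


class RepeatedMeasuresAnova:
    """Within-subject ANOVA model for one or two within factors.

    Parameters
    ----------
    data : tidy long DataFrame with one row per subject x cell observation.
    dv : name of the dependent-variable column.
    within : list of one or two within-subject factor column names.
    subject : name of the subject-identifier column.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within: list[str],
                 subject: str = "subject"):
        if not 1 <= len(within) <= 2:
            raise ValueError("within must name 1 or 2 factors")
        self.data = data
        self.dv = dv
        self.within = list(within)
        self.subject = subject
        self._validate()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, dv: str, within: list[str],
                       subject: str = "subject") -> "RepeatedMeasuresAnova":
        return cls(data, dv, within, subject)

    def _validate(self) -> None:
        d = self.data
        for col in [self.dv, self.subject, *self.within]:
            if col not in d.columns:
                raise ValueError(f"column {col!r} not in data")
        counts = d.groupby([self.subject, *self.within], sort=True).size()
        self.subjects_ = sorted(d[self.subject].unique().tolist())
        self.levels_ = [sorted(d[f].unique().tolist()) for f in self.within]
        n_cells = int(np.prod([len(lv) for lv in self.levels_]))
        if len(self.subjects_) < 3:
            raise ValueError("need at least 3 subjects")
        if len(counts) != len(self.subjects_) * n_cells or (counts != 1).any():
            raise MissingCellError(
                "design is not complete/balanced: every subject must be "
                "observed exactly once in every cell (no imputation is done)")
        if d[self.dv].isna().any():
            raise MissingCellError("missing dependent-variable values")

    def _cell_matrix(self) -> np.ndarray:
        """subjects x cells matrix, cells in lexicographic level order."""
        d = self.data.set_index([self.subject, *self.within])[self.dv]
        shape = [len(self.subjects_)] + [len(lv) for lv in self.levels_]
        idx = pd.MultiIndex.from_product([self.subjects_, *self.levels_])
        return d.reindex(idx).to_numpy(dtype=float).reshape(shape)

    def fit(self) -> "RMAnovaResults":
        Y = self._cell_matrix()  # (n, a) or (n, a, b)
        n = Y.shape[0]
        grand = Y.mean()
        # SS below this are floating-point residue of exact cancellation
        self._ss_tol = 1e-12 * float(np.sum(Y * Y) + 1e-30)
        ss_subject = float(np.sum((Y.mean(axis=tuple(range(1, Y.ndim)))
                                   - grand) ** 2)) * int(np.prod(Y.shape[1:]))
        effects: list[AnovaResult] = []

        if Y.ndim == 2:
            a = Y.shape[1]
            mj = Y.mean(axis=0)
            mi = Y.mean(axis=1)
            ss_a = float(n * np.sum((mj - grand) ** 2))
            resid = Y - mi[:, None] - mj[None, :] + grand
            ss_axs = float(np.sum(resid**2))
            effects.append(self._effect_row(
                self.within[0], ss_a, a - 1, ss_axs, (a - 1) * (n - 1),
                scores=Y @ _orthonormal_contrast(a).T))
        else:
            a, b = Y.shape[1], Y.shape[2]
            mi = Y.mean(axis=(1, 2))
            mj = Y.mean(axis=(0, 2))
            mk = Y.mean(axis=(0, 1))
            mjk = Y.mean(axis=0)
            mij = Y.mean(axis=2)
            mik = Y.mean(axis=1)
            ss_a = float(n * b * np.sum((mj - grand) ** 2))
            ss_b = float(n * a * np.sum((mk - grand) ** 2))
            ss_ab = float(n * np.sum((mjk - mj[:, None] - mk[None, :] + grand) ** 2))
            ss_axs = float(b * np.sum(
                (mij - mi[:, None] - mj[None, :] + grand) ** 2))
            ss_bxs = float(a * np.sum(
                (mik - mi[:, None] - mk[None, :] + grand) ** 2))
            ss_total = float(np.sum((Y - grand) ** 2))
            ss_abxs = ss_total - (ss_subject + ss_a + ss_b + ss_ab
                                  + ss_axs + ss_bxs)
            ss_abxs = max(ss_abxs, 0.0)
            Ca = _orthonormal_contrast(a)
            Cb = _orthonormal_contrast(b)
            flat = Y.reshape(n, a * b)
            mean_b = np.kron(np.eye(a), np.ones(b) / b)   # collapse over B
            mean_a = np.kron(np.ones(a) / a, np.eye(b)).reshape(b, a * b)
            effects.append(self._effect_row(
                self.within[0], ss_a, a - 1, ss_axs, (a - 1) * (n - 1),
                scores=flat @ mean_b.T @ Ca.T))
            effects.append(self._effect_row(
                self.within[1], ss_b, b - 1, ss_bxs, (b - 1) * (n - 1),
                scores=flat @ mean_a.T @ Cb.T))
            effects.append(self._effect_row(
                f"{self.within[0]}:{self.within[1]}", ss_ab,
                (a - 1) * (b - 1), ss_abxs, (a - 1) * (b - 1) * (n - 1),
                scores=flat @ np.kron(Ca, Cb).T))

        ss_all_error = ss_subject + sum(e.ss_error for e in effects)
        for e in effects:
            denom = e.ss_effect + ss_all_error
            e.ges = e.ss_effect / denom if denom > 0 else 0.0
        return RMAnovaResults(effects=effects, n_subjects=n,
                              ss_subject=ss_subject, model=self)

    def _effect_row(self, name: str, ss_eff: float, df_num: int,
                    ss_err: float, df_den: int,
                    scores: np.ndarray) -> AnovaResult:
        n = scores.shape[0]
        tol = getattr(self, "_ss_tol", 0.0)
        if ss_eff < tol:
            ss_eff = 0.0
        if ss_err < tol:
            ss_err = 0.0
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        denom = ss_eff + ss_err
        eta_p2 = ss_eff / denom if denom > 0 else 0.0

        # sphericity from the contrasted-score covariance (m-1 columns)
        if scores.shape[1] >= 2:
            cov_scores = np.cov(scores, rowvar=False)
            eig = np.clip(np.linalg.eigvalsh(cov_scores), 0.0, None)
            d = scores.shape[1]
            if eig.sum() > 0:
                eps = float(eig.sum() ** 2 / (d * (eig**2).sum()))
            else:
                eps = 1.0
            if eig.min() > 0 and n > d:
                W = float(np.prod(eig) / (eig.sum() / d) ** d)
                fmul = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1))
                chi2 = -(n - 1) * fmul * math.log(max(W, 1e-300))
                dof = (d + 1) * d / 2.0 - 1.0
                mauchly_p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
            else:
                W, mauchly_p = np.nan, np.nan
        else:
            W, mauchly_p, eps = 1.0, 1.0, 1.0

        if np.isfinite(F) and F > 0:
            p_gg = float(stats.f.sf(F, df_num * eps, df_den * eps))
        else:
            p_gg = 1.0 if F == 0 else 0.0
        return AnovaResult(effect=name, df_num=df_num, df_den=df_den,
                           F=float(F), p=p, ges=np.nan, eta_p2=float(eta_p2),
                           mauchly_W=W, mauchly_p=mauchly_p, gg_epsilon=eps,
                           p_gg=p_gg, ss_effect=ss_eff, ss_error=ss_err)


class RMAnovaResults:
    """Fitted within-subject ANOVA: table, effect sizes and summary."""

    def __init__(self, effects: list[AnovaResult], n_subjects: int,
                 ss_subject: float, model: RepeatedMeasuresAnova):
        self.effects = effects
        self.n_subjects = n_subjects
        self.ss_subject = ss_subject
        self.model = model

    @property
    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "effect": e.effect, "df_num": e.df_num, "df_den": e.df_den,
            "F": e.F, "p": e.p, "ges": e.ges, "eta_p2": e.eta_p2,
            "mauchly_W": e.mauchly_W, "mauchly_p": e.mauchly_p,
            "gg_epsilon": e.gg_epsilon, "p_gg": e.p_gg,
        } for e in self.effects])

    def reported_p(self, effect: str, alpha: float = 0.05) -> float:
        """p-value under the reporting rule: GG-corrected when Mauchly's
        test reaches significance, uncorrected otherwise."""
        e = next(x for x in self.effects if x.effect == effect)
        if np.isfinite(e.mauchly_p) and e.mauchly_p < alpha:
            return e.p_gg
        return e.p

    def summary(self) -> str:
        lines = [
            "Within-subject ANOVA "
            f"(n={self.n_subjects} subjects, dv={self.model.dv!r})",
            f"{'effect':<24}{'df_num':>7}{'df_den':>8}{'F':>9}{'p':>9}"
            f"{'ges':>7}{'eps_GG':>8}{'p[GG]':>9}",
        ]
        for e in self.effects:
            lines.append(
                f"{e.effect:<24}{e.df_num:>7.0f}{e.df_den:>8.0f}{e.F:>9.2f}"
                f"{e.p:>9.4f}{e.ges:>7.3f}{e.gg_epsilon:>8.3f}{e.p_gg:>9.4f}")
        return "\n".join(lines)


def rm_anova(data: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject") -> list[AnovaResult]:
    """Functional wrapper: fit and return the effect rows."""
    return RepeatedMeasuresAnova(data, dv, within, subject).fit().effects


def effect_sizes(result: AnovaResult) -> tuple[float, float]:
    """(generalized eta-squared, partial eta-squared) of a fitted effect."""
    return result.ges, result.eta_p2


# ---------------------------------------------------------------------------
# pairwise comparisons


def pairwise_bonferroni(subject_table: pd.DataFrame, dv: str, factor: str,
                        subject: str = "subject") -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests over all level pairs of a factor.

    Returns a lower-triangular DataFrame (rows level j, columns level i < j)
    of corrected p-values: the two-sided paired-t p multiplied by the number
    of pairs, capped at 1.  Pairs with zero within-pair variance get p = 1
    when the means tie exactly and NaN (degenerate) otherwise.
    """
    wide = subject_table.pivot_table(index=subject, columns=factor, values=dv)
    if wide.isna().any().any():
        raise MissingCellError("missing subject cells in pairwise table")
    levels = sorted(wide.columns.tolist())
    pairs = list(combinations(levels, 2))
    n_pairs = len(pairs)
    out = pd.DataFrame(np.nan, index=levels[1:], columns=levels[:-1])
    for la, lb in pairs:
        diff = (wide[la] - wide[lb]).to_numpy(dtype=float)
        if diff.size < 3:
            raise ValueError("need >= 3 subjects per pair")
        if np.allclose(diff.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(diff.mean(), 0.0) else np.nan
        else:
            p = float(stats.ttest_rel(wide[la], wide[lb]).pvalue)
        if np.isfinite(p):
            p = min(p * n_pairs, 1.0)
        out.loc[lb, la] = p
    return out


# ---------------------------------------------------------------------------
# effect-size conversion and power


def eta2_to_f(eta_p2: float) -> float:
    """Cohen's f from partial eta-squared: f = sqrt(eta / (1 - eta))."""
    if not 0 <= eta_p2 < 1:
        raise ValueError("eta_p2 must lie in [0, 1)")
    return math.sqrt(eta_p2 / (1.0 - eta_p2))


@dataclass
class PowerSpec:
    """Inputs of a within-factor noncentral-F power computation.

    ``rho`` is the correlation among repeated measures entering the
    noncentrality denominator as (1 - rho); its sign convention is left to
    the caller (a negative printed correlation entered as a magnitude gives
    the computation most power calculators perform).  ``epsilon`` is the
    nonsphericity correction applied to both degrees of freedom and the
    noncentrality parameter.
    """

    f: float | None = None
    eta_p2: float | None = None
    m: int = 2
    alpha: float = 0.05
    power: float = 0.8
    rho: float = 0.0
    epsilon: float = 1.0

    def __post_init__(self):
        if self.f is None:
            if self.eta_p2 is None:
                raise ValueError("provide f or eta_p2")
            self.f = eta2_to_f(self.eta_p2)
        if self.f < 0:
            raise ValueError("f must be non-negative")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.m < 2:
            raise ValueError("need m >= 2 within levels")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not 1.0 / (self.m - 1) - 1e-12 <= self.epsilon <= 1.0 + 1e-12:
            raise ValueError("epsilon must lie in [1/(m-1), 1]")


def rm_power(n_subjects: int, spec: PowerSpec) -> float:
    """Power of the within-factor F test at the given sample size.

    Degrees of freedom (m-1)*epsilon and (N-1)(m-1)*epsilon; noncentrality
    lambda = f^2 * N * m * epsilon / (1 - rho).
    """
    if n_subjects < 2:
        return 0.0
    m, eps = spec.m, spec.epsilon
    df1 = (m - 1) * eps
    df2 = (n_subjects - 1) * (m - 1) * eps
    lam = spec.f**2 * n_subjects * m * eps / (1.0 - spec.rho)
    crit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest N (subjects, >= 3) whose power reaches the target.

    Integer bisection over [3, n_max]; power is monotone non-decreasing in N
    for a fixed spec.  Raises when the target is unreachable (f = 0 or the
    ceiling is hit).
    """
    if spec.f == 0:
        raise ValueError("power target unreachable with zero effect size")
    lo, hi = 3, n_max
    if rm_power(hi, spec) < spec.power:
        raise ValueError(f"power target unreachable below N={n_max}")
    if rm_power(lo, spec) >= spec.power:
        return lo
    while hi - lo > 1:  # invariant: power(lo) < target <= power(hi)
        mid = (lo + hi) // 2
        if rm_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
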