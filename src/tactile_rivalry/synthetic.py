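"""Synthetic tactile-rivalry experiments: phase sequences and keypress traces.

Emulates the report stream of a vibrotactile rivalry session: subjects hold
one of two keys to report the currently dominant percept (SIM or AM) during
3-min trials, at five intensity-difference (delta-I, in dB) conditions with
three repetitions each, ordered by a 5x5 Latin-square design.

Dominance durations strictly alternate between percepts.  Marginals are
gamma or log-normal with percept- and condition-specific means and a common
coefficient of variation; serial dependence (positive at lag 1, negative at
lag 2) is induced by a Gaussian copula over a latent stationary AR(2)
process.  A single root seed expands into per-subject and per-trial
substreams so any subset of the dataset is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .phases import AM, SIM, PerceptPhase, Trial, trials_to_phase_table

DEFAULT_DELTA_I = (0.5, 1.0, 2.0, 4.0, 6.0)


def default_mean_sim(delta_i_db: float) -> float:
    """Mean SIM dominance duration (s): log-linear in dB, decreasing.

    Calibrated so the SIM and AM curves cross near 2.5 dB at ~15 s, placing
    equidominance between the 2 and 4 dB conditions and grand means in the
    15-20 s range typical of tactile rivalry.
    """
    return 15.0 * math.exp(-0.25 * (delta_i_db - 2.5))


def default_mean_am(delta_i_db: float) -> float:
    """Mean AM dominance duration (s): log-linear in dB, increasing."""
    return 15.0 * math.exp(0.25 * (delta_i_db - 2.5))


@dataclass
class GeneratorParams:
    """Study-design and distributional parameters of the synthetic experiment.

    Defaults reproduce the reference design: 15 subjects x 5 delta-I levels
    (.5, 1, 2, 4, 6 dB) x 3 repetitions of 180 s trials, cv 0.6, weak
    positive lag-1 and negative lag-2 duration correlations.
    """

    n_subjects: int = 15
    delta_i_levels: tuple[float, ...] = DEFAULT_DELTA_I
    n_repetitions: int = 3
    trial_length: float = 180.0
    marginal_family: str = "gamma"  # or "lognormal"
    mean_sim_fn: Callable[[float], float] = field(default=default_mean_sim)
    mean_am_fn: Callable[[float], float] = field(default=default_mean_am)
    cv_target: float = 0.6
    lag1_corr_target: float = 0.15
    lag2_corr_target: float = -0.15
    subject_sd: float = 0.3    # log-scale SD of multiplicative subject effect
    jitter_sd: float = 0.1     # keypress reaction-time jitter, seconds
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trial_length <= 0:
            raise ValueError("trial_length must be positive")
        if self.cv_target <= 0:
            raise ValueError("cv_target must be positive")
        if self.marginal_family not in ("gamma", "lognormal"):
            raise ValueError(f"unknown marginal family {self.marginal_family!r}")
        if not (abs(self.lag1_corr_target) < 1 and abs(self.lag2_corr_target) < 1):
            raise ValueError("lag correlation targets must lie in (-1, 1)")
        for di in self.delta_i_levels:
            if self.mean_sim_fn(di) <= 0 or self.mean_am_fn(di) <= 0:
                raise ValueError("mean functions must be strictly positive "
                                 "over the delta-I range")
        ar2_coefficients(self.lag1_corr_target, self.lag2_corr_target)


def ar2_coefficients(rho1: float, rho2: float) -> tuple[float, float, float]:
    """Yule-Walker AR(2) coefficients for target lag-1/lag-2 autocorrelations.

    Returns ``(phi1, phi2, innovation_sd)`` with the innovation variance set
    so the stationary marginal variance is one.  Raises on an inadmissible
    (non-stationary) autocorrelation pair.
    """
    denom = 1.0 - rho1 * rho1
    if denom <= 0:
        raise ValueError(f"lag-1 autocorrelation {rho1} is inadmissible")
    phi1 = rho1 * (1.0 - rho2) / denom
    phi2 = (rho2 - rho1 * rho1) / denom
    stationary = (abs(phi2) < 1.0 and phi1 + phi2 < 1.0 and phi2 - phi1 < 1.0)
    innov_var = 1.0 - phi1 * rho1 - phi2 * rho2
    if not stationary or innov_var <= 0:
        raise ValueError(
            f"autocorrelation pair (rho1={rho1}, rho2={rho2}) violates AR(2) "
            f"stationarity: phi1={phi1:.3f}, phi2={phi2:.3f}")
    return phi1, phi2, math.sqrt(innov_var)


@dataclass
class KeypressTrace:
    """Rendered binary report channels at a fixed sample rate."""

    sample_rate: float
    left_key: np.ndarray   # SIM report channel
    right_key: np.ndarray  # AM report channel
    subject: int = 0
    delta_i: float = 0.0
    repetition: int = 0

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.left_key.size) / self.sample_rate
        return pd.DataFrame({"time_s": t, "left_key": self.left_key,
                             "right_key": self.right_key})


# ---------------------------------------------------------------------------
# design


def _random_latin_square(k: int, rng: np.random.Generator) -> np.ndarray:
    """A random k x k Latin square via row/column/symbol shuffles of the
    cyclic square (not uniform over all squares, which is unnecessary here)."""
    base = (np.arange(k)[:, None] + np.arange(k)[None, :]) % k
    base = base[rng.permutation(k)][:, rng.permutation(k)]
    relabel = rng.permutation(k)
    return relabel[base]


def build_design(n_subjects: int, seed: int,
                 delta_i_levels: tuple[float, ...] = DEFAULT_DELTA_I,
                 n_repetitions: int = 3) -> dict[int, list[tuple[float, int]]]:
    """Per-subject ordered trial slots under a Latin-square design.

    Each subject receives ``n_repetitions`` blocks of ``len(delta_i_levels)``
    trials; within a block every delta-I level appears exactly once, and each
    block is a row of a (randomly relabelled) Latin square so condition order
    is counterbalanced across subjects and repetitions.  Deterministic given
    ``seed``.  Returns ``{subject: [(delta_i, repetition), ...]}``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    k = len(delta_i_levels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD51]))
    levels = np.asarray(delta_i_levels, dtype=float)
    design: dict[int, list[tuple[float, int]]] = {}
    square = _random_latin_square(k, rng)
    row = 0
    for subj in range(n_subjects):
        slots: list[tuple[float, int]] = []
        for rep in range(n_repetitions):
            if row == k:
                square = _random_latin_square(k, rng)
                row = 0
            slots.extend((float(di), rep) for di in levels[square[row]])
            row += 1
        design[subj] = slots
    return design


# ---------------------------------------------------------------------------
# phase sequences


def _marginal(family: str, mean: float, cv: float):
    """Frozen scipy distribution with the requested mean and cv."""
    cv = max(cv, 1e-9)  # variance floor: degenerate limit stays finite
    if family == "gamma":
        shape = 1.0 / cv**2
        return stats.gamma(shape, scale=mean / shape)
    sigma2 = math.log1p(cv**2)
    mu_log = math.log(mean) - sigma2 / 2.0
    return stats.lognorm(math.sqrt(sigma2), scale=math.exp(mu_log))


def sample_phase_sequence(params: GeneratorParams, delta_i: float,
                          subject_effect: float, trial_length: float,
                          rng: np.random.Generator) -> list[PerceptPhase]:
    """One trial's strictly alternating phase sequence.

    Durations are marginal draws (gamma or log-normal) with percept- and
    condition-specific means scaled by the subject effect and the common cv;
    serial dependence comes from mapping a latent unit-variance AR(2) series
    through the Gaussian CDF and each percept's quantile function (a Gaussian
    copula — the latent autocorrelations are the lag targets, so realised
    duration correlations approximate them after the monotone transform).
    The final phase is truncated at ``trial_length`` and flagged censored.
    """
    phi1, phi2, innov_sd = ar2_coefficients(params.lag1_corr_target,
                                            params.lag2_corr_target)
    means = {SIM: params.mean_sim_fn(delta_i) * subject_effect,
             AM: params.mean_am_fn(delta_i) * subject_effect}
    dists = {p: _marginal(params.marginal_family, means[p], params.cv_target)
             for p in (SIM, AM)}

    first = SIM if rng.random() < 0.5 else AM
    labels = (SIM, AM) if first == SIM else (AM, SIM)

    burn = 100
    z_prev, z_prev2 = 0.0, 0.0
    for _ in range(burn):
        z_prev, z_prev2 = (phi1 * z_prev + phi2 * z_prev2
                           + innov_sd * rng.standard_normal()), z_prev

    phases: list[PerceptPhase] = []
    t = 0.0
    i = 0
    while t < trial_length:
        z = phi1 * z_prev + phi2 * z_prev2 + innov_sd * rng.standard_normal()
        z_prev, z_prev2 = z, z_prev
        u = stats.norm.cdf(z)
        percept = labels[i % 2]
        dur = float(dists[percept].ppf(u))
        dur = max(dur, 1e-6)
        if t + dur >= trial_length:
            phases.append(PerceptPhase(percept, onset=t,
                                       duration=trial_length - t,
                                       censored=True))
            t = trial_length
        else:
            phases.append(PerceptPhase(percept, onset=t, duration=dur))
            t += dur
        i += 1
    return phases


def generate_dataset(params: GeneratorParams) -> list[Trial]:
    """Full synthetic experiment: one Trial per design slot.

    Subject effects are drawn once per subject as exp(N(0, subject_sd^2));
    every trial gets its own substream spawned from the root seed, so
    regenerating any subject or trial alone reproduces it exactly.
    """
    design = build_design(params.n_subjects, params.seed,
                          params.delta_i_levels, params.n_repetitions)
    root = np.random.SeedSequence(params.seed)
    subject_streams = root.spawn(params.n_subjects)
    trials: list[Trial] = []
    for subj, slots in design.items():
        subj_ss = subject_streams[subj]
        effect_rng = np.random.default_rng(subj_ss)
        subject_effect = float(np.exp(params.subject_sd *
                                      effect_rng.standard_normal()))
        trial_streams = subj_ss.spawn(len(slots))
        for (di, rep), tss in zip(slots, trial_streams):
            rng = np.random.default_rng(tss)
            phases = sample_phase_sequence(params, di, subject_effect,
                                           params.trial_length, rng)
            trials.append(Trial(subject=subj, delta_i=di, repetition=rep,
                                phases=phases,
                                trial_length=params.trial_length))
    return trials


# ---------------------------------------------------------------------------
# trace rendering


def render_trace(phases: list[PerceptPhase], sample_rate: float = 100.0,
                 jitter_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 trial_length: float | None = None) -> KeypressTrace:
    """Render a phase sequence as two binary keypress channels.

    Each phase becomes a held-key segment (SIM -> left key, AM -> right key).
    At every switch the outgoing key is released and the incoming key pressed
    after independent non-negative reaction-time delays (|N(0, jitter_sd)|,
    truncated so boundaries never reorder), which leaves short no-key gaps at
    switches.  With ``jitter_sd=0`` the rendering is exact to the sample grid.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if trial_length is None:
        trial_length = phases[-1].onset + phases[-1].duration if phases else 0.0
    n = int(round(trial_length * sample_rate))
    left = np.zeros(n, dtype=np.int8)
    right = np.zeros(n, dtype=np.int8)

    for k, ph in enumerate(phases):
        start, end = ph.onset, ph.onset + ph.duration
        if jitter_sd > 0:
            if k > 0:  # delayed press after the switch, bounded within phase
                start = start + min(abs(rng.normal(0.0, jitter_sd)),
                                    ph.duration * 0.45)
            if k < len(phases) - 1:  # delayed release, bounded before next press
                end = end + min(abs(rng.normal(0.0, jitter_sd)),
                                phases[k + 1].duration * 0.40)
        i0 = int(round(start * sample_rate))
        i1 = min(int(round(end * sample_rate)), n)
        channel = left if ph.percept == SIM else right
        channel[i0:i1] = 1

    # enforce exclusivity: overlapping presses (possible under jitter) are
    # resolved by blanking, matching how both-key samples parse as unreported
    both = (left == 1) & (right == 1)
    left[both] = 0
    right[both] = 0
    return KeypressTrace(sample_rate=sample_rate, left_key=left, right_key=right)


# ---------------------------------------------------------------------------
# I/O


def write_phase_table(trials: list[Trial], path) -> None:
    trials_to_phase_table(trials).to_csv(path, index=False)


def write_trace(trace: KeypressTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)
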