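"""Keypress-trace parsing, trial exclusion, rebalancing and subject-level aggregation.

A perceptual *phase* is one uninterrupted dominance interval of a percept
(``SIM`` — one simultaneous vibration on both hands — or ``AM`` — pulses
apparently jumping between hands).  Subjects report the current percept by
holding one of two keys; this module turns those binary traces into phase
tables and aggregates them to the per-trial and per-subject summaries the
downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SIM = "SIM"
AM = "AM"
PERCEPTS = (SIM, AM)

#: CSV header of the long phase-table dialect shared with the generator.
PHASE_TABLE_COLUMNS = [
    "subject", "delta_i_db", "repetition", "percept",
    "onset_s", "duration_s", "censored",
]

#: Default trial-exclusion bounds on mean percept duration, in seconds.
#: The 4 s floor equals the span of the shortest reportable stimulus
#: alternation H-L-H-L-H- (five 400 ms pulses, each followed by a 400 ms
#: silent interval); the 150 s ceiling flags trials where perception
#: effectively did not alternate within the 3-min trial.
MIN_MEAN_S = 4.0
MAX_MEAN_S = 150.0

#: Gaps of unreported time shorter than this (seconds) inside a run of the
#: same percept are treated as keypress re-grips, not genuine switches.
MERGE_TOLERANCE_S = 0.5


def exclusion_floor_from_stimulus(n_pulses: int = 5, pulse_s: float = 0.4,
                                  gap_s: float = 0.4) -> float:
    """Span of the shortest reportable alternation of the stimulus.

    Each vibrotactile pulse lasts ``pulse_s`` and is followed by a silent
    interval of ``gap_s``; ``n_pulses`` pulses (H-L-H-L-H-) therefore span
    ``n_pulses * (pulse_s + gap_s)`` seconds.  With the experiment's 400 ms
    pulses and gaps this is 4 s, the floor used by :func:`apply_exclusion`.
    """
    return n_pulses * (pulse_s + gap_s)


@dataclass(frozen=True)
class PerceptPhase:
    """One dominance interval: percept label, onset and duration in seconds."""

    percept: str
    onset: float
    duration: float
    censored: bool = False

    def __post_init__(self):
        if self.percept not in PERCEPTS:
            raise ValueError(f"unknown percept label {self.percept!r}")
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.onset < 0:
            raise ValueError("phase onset must be non-negative")


@dataclass
class Trial:
    """Ordered phases for one subject x delta-I x repetition slot."""

    subject: int
    delta_i: float
    repetition: int
    phases: list[PerceptPhase] = field(default_factory=list)
    trial_length: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None

    def durations(self, percept: str | None = None,
                  drop_censored: bool = True) -> np.ndarray:
        sel = [
            p.duration for p in self.phases
            if (percept is None or p.percept == percept)
            and not (drop_censored and p.censored)
        ]
        return np.asarray(sel, dtype=float)


@dataclass
class ExclusionReport:
    n_total: int
    n_excluded: int
    per_condition: dict[float, int]
    min_mean: float
    max_mean: float
    mode: str

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "per_condition_excluded": {str(k): v for k, v in
                                       sorted(self.per_condition.items())},
            "min_mean_s": self.min_mean,
            "max_mean_s": self.max_mean,
            "mode": self.mode,
        }


@dataclass
class TrialSummary:
    """Per-trial dominance summary (means, proportions, alternation rate)."""

    mean_dur_sim: float
    mean_dur_am: float
    prop_sim: float
    prop_am: float
    alternation_rate: float  # switches per minute of reported time
    n_phases: int


class MalformedTraceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# trace -> phases


def extract_phases(left_key: np.ndarray, right_key: np.ndarray,
                   sample_rate: float,
                   merge_tolerance: float = MERGE_TOLERANCE_S) -> list[PerceptPhase]:
    """Parse two binary key channels into an ordered phase list.

    A phase is a maximal run of samples during which exactly one key is held
    (left = SIM, right = AM).  Samples with no key or both keys held are
    unreported time and belong to no phase.  Runs of the same percept
    separated only by unreported gaps shorter than ``merge_tolerance`` are
    merged (keypress re-grips should not split a phase).  A phase still held
    at the end of the trace is flagged censored.
    """
    left = np.asarray(left_key)
    right = np.asarray(right_key)
    if left.shape != right.shape or left.ndim != 1:
        raise MalformedTraceError("key channels must be 1-D and equal length")
    if not (np.isin(left, (0, 1)).all() and np.isin(right, (0, 1)).all()):
        raise MalformedTraceError("key channels must be binary")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")

    # per-sample state: 0 unreported, 1 SIM, 2 AM
    state = np.where((left == 1) & (right == 0), 1,
                     np.where((right == 1) & (left == 0), 2, 0))
    n = state.size
    raw: list[tuple[str, int, int]] = []  # (label, start, stop) sample runs
    boundaries = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, stops):
        if state[s] != 0:
            raw.append((SIM if state[s] == 1 else AM, int(s), int(e)))

    # merge same-label runs across short unreported gaps
    merged: list[tuple[str, int, int]] = []
    max_gap = merge_tolerance * sample_rate
    for label, s, e in raw:
        if merged and merged[-1][0] == label and s - merged[-1][2] <= max_gap:
            merged[-1] = (label, merged[-1][1], e)
        else:
            merged.append((label, s, e))

    phases = [
        PerceptPhase(label, onset=s / sample_rate, duration=(e - s) / sample_rate,
                     censored=(e == n))
        for label, s, e in merged
    ]
    return phases


# ---------------------------------------------------------------------------
# exclusion


def apply_exclusion(trials: list[Trial], min_mean: float = MIN_MEAN_S,
                    max_mean: float = MAX_MEAN_S,
                    mode: str = "per_percept") -> tuple[list[Trial], ExclusionReport]:
    """Apply the trial-exclusion rule and return (kept trials, report).

    ``mode="per_percept"`` (default) excludes a trial when *either* percept
    type's mean duration falls outside ``[min_mean, max_mean]`` or when a
    percept type has no phases at all (perception did not alternate).
    ``mode="across_percept"`` applies the bounds to the mean over all phases
    regardless of type; non-alternating trials are still excluded.  Kept
    trials are returned unchanged; input trials are not mutated.
    """
    if min_mean >= max_mean:
        raise ValueError("min_mean must be below max_mean")
    if mode not in ("per_percept", "across_percept"):
        raise ValueError(f"unknown exclusion mode {mode!r}")

    kept: list[Trial] = []
    excluded: list[Trial] = []
    per_condition: dict[float, int] = {}
    for trial in trials:
        reason = _exclusion_reason(trial, min_mean, max_mean, mode)
        if reason is None:
            kept.append(trial)
        else:
            excluded.append(replace_trial(trial, excluded=True,
                                          exclusion_reason=reason))
            per_condition[trial.delta_i] = per_condition.get(trial.delta_i, 0) + 1
    report = ExclusionReport(
        n_total=len(trials), n_excluded=len(excluded),
        per_condition=per_condition, min_mean=min_mean, max_mean=max_mean,
        mode=mode,
    )
    return kept, report


def replace_trial(trial: Trial, **kw) -> Trial:
    out = Trial(subject=trial.subject, delta_i=trial.delta_i,
                repetition=trial.repetition, phases=list(trial.phases),
                trial_length=trial.trial_length,
                excluded=trial.excluded, exclusion_reason=trial.exclusion_reason)
    for k, v in kw.items():
        setattr(out, k, v)
    return out


def _exclusion_reason(trial: Trial, min_mean: float, max_mean: float,
                      mode: str) -> str | None:
    if not trial.phases:
        return "no_phases"
    per_type = {p: trial.durations(p, drop_censored=False) for p in PERCEPTS}
    for p in PERCEPTS:
        if per_type[p].size == 0:
            return f"no_{p}_phases"
    if mode == "per_percept":
        for p in PERCEPTS:
            m = per_type[p].mean()
            if m > max_mean:
                return f"mean_{p}_above_{max_mean:g}s"
            if m < min_mean:
                return f"mean_{p}_below_{min_mean:g}s"
    else:
        m = trial.durations(drop_censored=False).mean()
        if m > max_mean:
            return f"mean_above_{max_mean:g}s"
        if m < min_mean:
            return f"mean_below_{min_mean:g}s"
    return None


# ---------------------------------------------------------------------------
# summaries and tables


def trial_summary(trial: Trial, drop_censored: bool = True) -> TrialSummary:
    """Per-trial dominance summary.

    Means are over (optionally censoring-filtered) durations per percept;
    proportions are shares of *reported* time (so they sum to one exactly);
    the alternation rate is (n_phases - 1) per minute of reported time.
    Censored phases always count toward reported time and proportions even
    when dropped from duration means — their span was reported, only their
    full duration is unknown.
    """
    if trial.excluded:
        raise ValueError("summary of an excluded trial is undefined")
    if not trial.phases:
        raise ValueError("summary of a trial with zero phases is undefined")
    dur_sim = trial.durations(SIM, drop_censored=drop_censored)
    dur_am = trial.durations(AM, drop_censored=drop_censored)
    rep_sim = trial.durations(SIM, drop_censored=False).sum()
    rep_am = trial.durations(AM, drop_censored=False).sum()
    reported = rep_sim + rep_am
    n = len(trial.phases)
    rate = 60.0 * (n - 1) / reported if reported > 0 else 0.0
    return TrialSummary(
        mean_dur_sim=float(dur_sim.mean()) if dur_sim.size else np.nan,
        mean_dur_am=float(dur_am.mean()) if dur_am.size else np.nan,
        prop_sim=float(rep_sim / reported),
        prop_am=float(rep_am / reported),
        alternation_rate=float(rate),
        n_phases=n,
    )


def trials_to_phase_table(trials: list[Trial]) -> pd.DataFrame:
    """Long phase table with the shared CSV dialect's columns."""
    rows = [
        (t.subject, t.delta_i, t.repetition, p.percept, p.onset, p.duration,
         p.censored)
        for t in trials for p in t.phases
    ]
    return pd.DataFrame(rows, columns=PHASE_TABLE_COLUMNS)


def phase_table_to_trials(table: pd.DataFrame,
                          trial_length: float | None = None) -> list[Trial]:
    """Inverse of :func:`trials_to_phase_table`."""
    trials = []
    for (subj, di, rep), grp in table.groupby(
            ["subject", "delta_i_db", "repetition"], sort=True):
        grp = grp.sort_values("onset_s")
        phases = [PerceptPhase(r.percept, float(r.onset_s), float(r.duration_s),
                               bool(r.censored))
                  for r in grp.itertuples()]
        trials.append(Trial(subject=int(subj), delta_i=float(di),
                            repetition=int(rep), phases=phases,
                            trial_length=trial_length))
    return trials


def load_phase_table(path) -> pd.DataFrame:
    """Load a phase-table CSV, validating the dialect.

    This is also the hook for replication inputs: any externally deposited
    dataset converted to the documented long-CSV dialect loads through here.
    Unrecognised columns raise rather than being guessed at silently.
    """
    table = pd.read_csv(path)
    missing = set(PHASE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(
            f"phase table at {path} lacks required columns {sorted(missing)}; "
            f"expected dialect {PHASE_TABLE_COLUMNS}")
    return table[PHASE_TABLE_COLUMNS]


def trial_mean_table(trials: list[Trial],
                     drop_censored: bool = True) -> pd.DataFrame:
    """Per-trial per-percept mean durations, one row per (trial, percept)."""
    rows = []
    for t in trials:
        for percept in PERCEPTS:
            d = t.durations(percept, drop_censored=drop_censored)
            if d.size:
                rows.append((t.subject, t.delta_i, t.repetition, percept,
                             float(d.mean()), int(d.size)))
    return pd.DataFrame(rows, columns=["subject", "delta_i_db", "repetition",
                                       "percept", "mean_duration_s", "n_phases"])


def rebalance(trial_means: pd.DataFrame, target_n: int = 45,
              rng: np.random.Generator | int | None = None,
              expected_cells: list[tuple[float, str]] | None = None
              ) -> pd.DataFrame:
    """Rebalance (delta-I, percept) cells of per-trial means to ``target_n`` rows.

    Cells below ``target_n`` observations are topped up by drawing
    mean-duration values with replacement from the cell's retained values,
    substituting for excluded trials so every experimental condition carries
    the same number of observations.  Original rows are flagged
    ``observed``; added rows ``resampled``.  Deterministic given the rng.
    ``expected_cells`` optionally names the full (delta_i, percept) grid so
    a condition whose every trial was excluded raises instead of silently
    vanishing from the output.
    """
    rng = np.random.default_rng(rng)
    if expected_cells is not None:
        present = set(map(tuple, trial_means[["delta_i_db", "percept"]]
                          .itertuples(index=False)))
        for cell in expected_cells:
            if tuple(cell) not in present:
                raise ValueError(f"unrecoverable cell: no retained trials at "
                                 f"delta_i={cell[0]}, percept={cell[1]}")
    out = trial_means.copy()
    out["source"] = "observed"
    extra = []
    for (di, percept), grp in trial_means.groupby(["delta_i_db", "percept"]):
        n = len(grp)
        if n == 0:
            raise ValueError(f"unrecoverable cell: no retained trials at "
                             f"delta_i={di}, percept={percept}")
        if n < target_n:
            picks = grp.sample(n=target_n - n, replace=True,
                               random_state=rng)
            picks = picks.assign(source="resampled")
            extra.append(picks)
    if extra:
        out = pd.concat([out] + extra, ignore_index=True)
    return out.reset_index(drop=True)


def subject_condition_means(trials: list[Trial],
                            drop_censored: bool = True) -> pd.DataFrame:
    """Subject-level table keyed (subject, delta_i_db, percept).

    For each subject and condition the mean duration pools *all* durations
    across the three repetitions (it is not a mean of per-trial means), and
    the dominance proportion and alternation rate are computed from pooled
    reported time the same way.  Subjects with no retained durations in a
    cell yield a missing-value row.
    """
    rows = []
    subjects = sorted({t.subject for t in trials})
    conditions = sorted({t.delta_i for t in trials})
    for subj in subjects:
        for di in conditions:
            cell = [t for t in trials
                    if t.subject == subj and t.delta_i == di and not t.excluded]
            rep_time = {p: sum(t.durations(p, drop_censored=False).sum()
                               for t in cell) for p in PERCEPTS}
            total_rep = rep_time[SIM] + rep_time[AM]
            n_phases = sum(len(t.phases) for t in cell)
            n_switches = sum(max(len(t.phases) - 1, 0) for t in cell)
            rate = 60.0 * n_switches / total_rep if total_rep > 0 else np.nan
            for percept in PERCEPTS:
                pooled = np.concatenate(
                    [t.durations(percept, drop_censored=drop_censored)
                     for t in cell]) if cell else np.array([])
                if pooled.size == 0:
                    import warnings
                    warnings.warn(
                        f"subject {subj} has no retained {percept} durations "
                        f"at delta_i={di}; emitting missing value")
                rows.append((
                    subj, di, percept,
                    float(pooled.mean()) if pooled.size else np.nan,
                    float(rep_time[percept] / total_rep) if total_rep > 0 else np.nan,
                    float(rate),
                    int(pooled.size),
                ))
    return pd.DataFrame(rows, columns=[
        "subject", "delta_i_db", "percept", "mean_duration_s",
        "proportion", "alternation_rate", "n_durations"])
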