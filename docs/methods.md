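# Methods

## The observation model

A rivalry trial produces an ordered sequence of *dominance phases*: maximal
intervals during which one percept (SIM or AM) is continuously reported.
Phases strictly alternate; durations are positive, right-skewed, and — a
robust regularity of bistable perception — approximately gamma or
log-normal with a coefficient of variation near 0.6 that is stable across
conditions even as the means change severalfold (the *scaling property*:
central moments proportional to powers of the mean, equivalently constant
c_v and constant skewness γ₁).  Successive durations are not independent:
adjacent phases (different percepts) correlate weakly positively, phases two
apart (same percept) negatively.

All downstream statistics in this package are built on exactly these
features, and the synthetic generator reproduces them by construction so the
pipeline can be validated end to end.

## The synthetic generator

**Design.**  `n_subjects` subjects each complete `n_repetitions` blocks of
`len(delta_i_levels)` trials of `trial_length` seconds.  Within a block every
ΔI level appears exactly once; blocks are rows of randomly relabelled
Latin squares, so condition order is counterbalanced within and across
subjects.  A single root seed is expanded with `numpy.random.SeedSequence`
into per-subject and per-trial substreams: any subject or trial regenerates
identically in isolation.

**Durations.**  Phase *i* of a trial has percept label fixed by parity after
a fair coin flip for the first percept (strict alternation is structural,
not emergent).  Its duration is

    d_i = F⁻¹_percept(Φ(z_i)),

where `z_i` is a latent stationary unit-variance Gaussian AR(2) process and
`F_percept` is the gamma (default) or log-normal CDF with mean
μ_percept(ΔI)·s (subject effect `s = exp(N(0, subject_sd²))`) and
coefficient of variation `cv_target`.  The AR(2) coefficients are the
Yule–Walker solution for the requested lag-1/lag-2 autocorrelations, with an
explicit stationarity check; the innovation variance is set for unit
marginal variance, and 100 burn-in steps wash out the zero initial state.
Because the quantile transform is monotone but nonlinear, realised duration
correlations only *approximate* the latent targets (they attenuate slightly
at lag 1 and, after per-trial normalization and censoring, overshoot at
lag 2); the targets are treated as approximate throughout and the tests
assert signs and significance, not magnitudes.  The final phase is truncated
at `trial_length` and flagged censored.

**Defaults and why.**

| parameter | default | meaning |
|---|---|---|
| `n_subjects` / `delta_i_levels` / `n_repetitions` | 15 / (.5, 1, 2, 4, 6) dB / 3 | the reference design: 225 trials |
| `trial_length` | 180 s | 3-min trials |
| `mean_sim_fn`, `mean_am_fn` | 15·exp(∓0.25·(ΔI−2.5)) s | log-linear in dB, crossing at 2.5 dB so equidominance falls between the 2 and 4 dB conditions; 6–28 s over the tested range, the scale typical of tactile rivalry |
| `cv_target` | 0.6 | the observed, condition-stable coefficient of variation |
| `lag1_corr_target`, `lag2_corr_target` | +0.15, −0.15 | weak positive lag-1 / negative lag-2 serial dependence |
| `subject_sd` | 0.3 | log-scale SD of the multiplicative subject effect (≈ ±35 % between-subject spread of mean durations) |
| `jitter_sd` | 0.1 s | keypress reaction-time jitter; no empirical gap statistics exist for this paradigm, so this is a free choice of plausible motor latency |
| `sample_rate` | 100 Hz | keypress sampling rate |

The mean-function calibration is a generator default chosen once, not an
empirical claim; only its *structure* (SIM decreasing, AM increasing,
crossing between 2 and 4 dB) carries over to assertions.

**Rendering.**  Each phase becomes a held-key segment (SIM → left key,
AM → right key).  At switches the outgoing release and incoming press are
delayed by independent |N(0, jitter_sd)| reaction times, truncated to at
most 45 % / 40 % of the neighbouring phase so boundaries never reorder;
this leaves short no-key gaps at switches.  Overlaps that survive truncation
are blanked, because both-key samples parse as unreported time.  With zero
jitter, rendering followed by extraction recovers every duration to within
one sample period (asserted as a round-trip oracle).

**What the generator does not emulate.**  No vibrotactile waveform, no
mixed or third percepts, no attention or adaptation dynamics, no
first-phase lengthening, no drop-out or response errors beyond Gaussian
jitter.  Passing tests therefore certify the *analysis machinery* under the
stated statistical structure, not the behaviour of human observers.

## Phase pipeline conventions

* **Extraction.**  A phase is a maximal run of samples with exactly one key
  held; no-key and both-key samples are unreported time.  Same-percept runs
  separated by unreported gaps ≤ 0.5 s are merged (a re-grip is shorter
  than any stimulus cycle and should not split a phase).  A phase still held
  at trace end is censored.
* **Exclusion.**  A trial is excluded when a percept type never occurs
  (perception did not alternate) or when a mean duration leaves
  [4 s, 150 s].  The floor equals the span of the shortest reportable
  stimulus alternation (five 400 ms pulses each followed by 400 ms silence);
  the ceiling flags effectively non-alternating 3-min trials.  The bound can
  be read per percept type or across both; *per-percept* is the default
  (the trial-level figure-of-merit plots per-type means, and the 4 s floor
  is motivated by a single percept's minimal span), and both modes are
  implemented and reported.
* **Censored phases** are dropped from duration means by default (their
  duration is unknown) but always count toward reported time, proportions
  and switch counts.
* **Proportions** use reported time as the denominator, so
  prop_SIM + prop_AM = 1 exactly; **alternation rate** is
  (n_phases − 1) per minute of reported time.
* **Rebalancing** substitutes for excluded trials by resampling *per-trial
  mean durations* (not raw phases) with replacement within each
  (ΔI, percept) cell up to 45 observations — the full-design cell size —
  flagging added rows `resampled`.
* **Subject aggregation** pools all durations across the three repetitions
  (not a mean of per-trial means), per subject × condition × percept.

## Repeated-measures ANOVA

The univariate within-subject decomposition: each effect is tested against
its subject-by-effect interaction (MS_effect / MS_effect×subject).  Designs
must be complete and balanced; missing cells raise (no imputation).  For
every effect with ≥ 3 levels, Mauchly's W is computed from the covariance
of orthonormally contrasted scores with the standard chi-square
approximation, and the Greenhouse–Geisser ε from the eigenvalue form
(Σλ)²/((m−1)Σλ²), bounded in [1/(m−1), 1].  The GG-corrected p (df scaled by
ε) is *always* stored; `reported_p` applies the convention of quoting it
only when Mauchly reaches significance.  Effect sizes: partial
η²_p = SS_e/(SS_e+SS_err(e)) and generalized
η²_G = SS_e/(SS_e + ΣSS_all_error including between-subject).  Pairwise
comparisons are plain paired t-tests with the p-value multiplied by the
number of pairs (capped at 1); no sphericity correction enters the pairwise
tests.  The Huynh–Feldt correction is not implemented (GG only).

Power for a within factor uses the noncentral F with
df₁ = (m−1)ε, df₂ = (N−1)(m−1)ε and λ = f²·N·m·ε/(1−ρ), where ρ is the
correlation among repeated measures.  The sign convention for ρ is
deliberately exposed: a printed negative repeated-measures correlation
entered as a magnitude (the conventional choice) yields a much smaller
required N than the literal negative value, and published sample-size
statements rarely say which was used — `required_sample_size` therefore
reports under whichever ρ the caller supplies, and the acceptance script
reports both.

## Duration distributions

Sample central moments use the biased (1/n) definitions, matching the
population-style formulas that define the scaling property.  Fits are
two-parameter maximum likelihood with no location shift: gamma via scipy's
constrained MLE (`floc=0`), log-normal via the exact closed form on
log-durations.  Goodness of fit is the one-sample KS test against the
fitted CDF with the asymptotic p-value; because parameters are estimated
from the same sample this p is conservative (Lilliefors bias) and no
parametric-bootstrap correction is applied — documented, since rejection
then remains meaningful.  The scaling assessment normalizes durations per
subject × condition × percept (a per-trial scheme is available), pools per
condition, drops conditions with < 20 phases (extreme ΔI yields too few
alternations for stable third moments), and attaches percentile-bootstrap
95 % CIs to each condition's c_v and γ₁/c_v and to the constancy summary —
the maximum pairwise c_v difference; a visual judgement in the original
analyses, quantified here as an explicit interval.

## Lag correlations

Pooled method: durations normalized to the mean of each percept type within
each trial (to avoid spurious correlation from inter-subject and inter-trial
scale differences), pairs pooled over trials and subjects, Pearson r with
the two-sided t-based p (a permutation option exists).  Single-trial method:
raw, un-normalized Pearson r within each trial having ≥ `min_pairs` pairs
(default 3, the smallest N with a defined t-based p), then a one-sample
t-test of the coefficient distribution against zero.  First phases are
included in pairs (no first-duration effect is modelled); censored phases
never enter a pair.

## Numerical choices

* Sums of squares below 10⁻¹² × ΣY² are snapped to zero so an exactly
  constant dv yields F = 0 rather than 0/0 noise.
* `cv_target` has a 10⁻⁹ variance floor so the degenerate cv→0 limit returns
  durations pinned at the mean instead of overflowing the gamma shape.
* AR(2) admissibility is checked eagerly (at parameter construction), not
  at sampling time.
* Equidominance interpolation is linear in dB (the natural axis of the
  design); multiple crossings resolve to the one nearest the
  alternation-rate maximum; no extrapolation outside the tested range.
* Bootstrap and resampling routines take an explicit `rng` (seed or
  Generator) and are deterministic given it.

## Problem sizes

The test suite and acceptance script run the full reference design
(225 trials) for pipeline checks, 500 single-condition trials for
correlation calibration, 10⁵ draws for moment closed-form checks, 1000
simulated null designs for the ANOVA type-I calibration, and 300–500
bootstrap/seed replicates elsewhere — sizes at which Monte-Carlo error is
comfortably inside the asserted tolerances while the whole suite stays in
the tens of seconds.

## Known limitations

* The copula construction cannot hit arbitrary (lag-1, lag-2) pairs exactly;
  targets are approximate and only admissible (stationary) pairs are
  accepted.
* The KS p-values ignore parameter estimation (conservative).
* The ANOVA layer handles within-subject factors only — no between-subject
  factors, mixed models, or unbalanced Type-II/III machinery.
* Rebalanced-table ANOVA treats the within-cell observation index as the
  repeated-measures unit; after resampling, rows of a unit are not a real
  subject's measurements, so that ANOVA describes the balanced design the
  substitution procedure constructs, exactly as in the original analysis
  style, not a literal subject-level model.
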