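"""Staircase psychophysics of shape discrimination under adaptation.

Simulates the delayed match-to-sample experiment: on each trial a morph
stimulus drawn from the 40 levels nearest a prototype must be discriminated
from that prototype.  Difficulty is controlled by a 1-up/3-down adaptive
staircase, which converges on the 79.4% (= 0.5^(1/3)) correct point of the
observer's psychometric function.  Adaptation to a shape class lowers the
discrimination threshold for that class; the synthetic observer implements
this as a threshold shift (``adaptation_gain`` morph units).

Staircases terminate after eight reversals; the threshold estimate is the
mean of the last five reversal levels.  A session produces a balanced
subject x run x prototype x condition threshold table analysed with a
three-way repeated-measures ANOVA and per-prototype paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr

__all__ = [
    "P_CONVERGENCE",
    "ObserverModel",
    "StaircaseConfig",
    "StaircaseState",
    "observer_prob_correct",
    "staircase_step",
    "estimate_threshold",
    "run_staircase",
    "staircase_convergence",
    "run_session",
    "default_cohort",
    "analyze_thresholds",
    "rm_anova",
    "paired_t",
]

#: fixed point of the 1-up/3-down rule: p such that p^3 = 1/2
P_CONVERGENCE = 0.5 ** (1.0 / 3.0)  # ~0.7937


@dataclass(frozen=True)
class ObserverModel:
    """Cumulative-Gaussian observer for the match-to-sample task.

    The psychometric function is a renormalised cumulative Gaussian with
    chance floor 0.5 at morph level 0 and ceiling 1 - lapse:

        p(x) = 0.5 + (0.5 - lapse) * (Phi((x - mu)/s) - Phi(-mu/s)) / (1 - Phi(-mu/s))

    with slope ``s`` a free parameter (morph units) and the location ``mu``
    solved from the calibration equation p(threshold) = 0.5^(1/3), so that
    ``base_threshold`` is exactly the level the 1-up/3-down staircase
    converges to.  Under adaptation of the matching shape class the
    effective threshold drops by ``adaptation_gain`` morph units.
    """

    base_threshold: float
    lapse_rate: float = 0.01
    adaptation_gain: float = 0.0
    slope: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.base_threshold <= 0:
            raise ValueError("base_threshold must be positive")
        if self.adaptation_gain < 0:
            raise ValueError("adaptation_gain must be non-negative")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def effective_threshold(self, condition: str) -> float:
        t = self.base_threshold
        if condition == "adapted":
            t = t - self.adaptation_gain
        return max(t, 1e-6)

    def location(self, condition: str) -> float:
        return _solve_location(self.effective_threshold(condition), self.slope, self.lapse_rate)


def _renorm_cdf(level: float, mu: float, s: float) -> float:
    """(Phi((x-mu)/s) - Phi(-mu/s)) / (1 - Phi(-mu/s)), computed stably as
    1 - exp(log Phi((mu-x)/s) - log Phi(mu/s))."""
    return 1.0 - float(np.exp(log_ndtr((mu - level) / s) - log_ndtr(mu / s)))


@lru_cache(maxsize=256)
def _solve_location(threshold: float, slope: float, lapse: float) -> float:
    """Location mu such that the renormalised curve passes 0.5^(1/3) at threshold."""
    from scipy.optimize import brentq

    q = (P_CONVERGENCE - 0.5) / (0.5 - lapse)
    lo, hi = threshold - 50 * slope, threshold + 50 * slope
    return float(brentq(lambda mu: _renorm_cdf(threshold, mu, slope) - q, lo, hi, xtol=1e-12))


def observer_prob_correct(obs: ObserverModel, level: float, condition: str = "unadapted") -> float:
    """P(correct) at a morph level: chance 0.5 at level 0, ceiling 1 - lapse."""
    if level < 0:
        raise ValueError("level must be non-negative")
    frac = _renorm_cdf(level, obs.location(condition), obs.slope)
    return float(0.5 + (0.5 - obs.lapse_rate) * frac)


@dataclass(frozen=True)
class StaircaseConfig:
    n_up: int = 1
    n_down: int = 3
    step_size: float = 1.0
    start_level: float = 30.0
    min_level: float = 1.0
    max_level: float = 40.0  # the 40 morph steps closest to the prototype
    stop_reversals: int = 8
    threshold_reversals: int = 5

    def __post_init__(self):
        if self.stop_reversals <= self.threshold_reversals:
            raise ValueError("stop_reversals must exceed threshold_reversals")


@dataclass
class StaircaseState:
    current_level: float
    consecutive_correct: int = 0
    trial_log: list = field(default_factory=list)
    reversal_levels: list = field(default_factory=list)
    last_direction: str = "none"  # {up, down, none}
    finished: bool = False


def staircase_step(state: StaircaseState, correct: bool, cfg: StaircaseConfig) -> StaircaseState:
    """Apply one trial outcome under the 1-up/3-down rule (in place).

    One error raises the morph level (easier); three consecutive correct
    responses lower it (harder).  A reversal is logged at the turning level
    whenever the direction of movement flips; the staircase finishes once
    ``stop_reversals`` reversals have accumulated.
    """
    if state.finished:
        raise RuntimeError("cannot step a finished staircase")
    state.trial_log.append((state.current_level, bool(correct)))
    move = None
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= cfg.n_down:
            move = "down"
            state.consecutive_correct = 0
    else:
        move = "up"
        state.consecutive_correct = 0
    if move is not None:
        if state.last_direction != "none" and move != state.last_direction:
            state.reversal_levels.append(state.current_level)
            if len(state.reversal_levels) >= cfg.stop_reversals:
                state.finished = True
        state.last_direction = move
        delta = -cfg.step_size if move == "down" else cfg.step_size
        state.current_level = float(np.clip(state.current_level + delta, cfg.min_level, cfg.max_level))
    return state


def estimate_threshold(state: StaircaseState, cfg: StaircaseConfig) -> float:
    """Mean of the last ``threshold_reversals`` reversal levels."""
    if not state.finished:
        raise RuntimeError("staircase has not finished")
    tail = state.reversal_levels[-cfg.threshold_reversals:]
    return float(np.mean(tail))


def run_staircase(
    obs: ObserverModel,
    cfg: StaircaseConfig,
    condition: str,
    rng: np.random.Generator,
    max_trials: int = 10_000,
) -> StaircaseState:
    """Simulate one staircase to completion against the observer."""
    state = StaircaseState(current_level=cfg.start_level)
    for _ in range(max_trials):
        if state.finished:
            break
        p = observer_prob_correct(obs, state.current_level, condition)
        staircase_step(state, rng.random() < p, cfg)
    return state


def staircase_convergence(
    obs: ObserverModel,
    cfg: StaircaseConfig | None = None,
    n_trials: int = 10_000,
    seed: int = 0,
    burn_in: int = 500,
    condition: str = "unadapted",
) -> dict:
    """Measure the percent-correct level at which the staircase converges.

    Runs a non-terminating staircase for ``n_trials`` trials and reports the
    empirical steady-state accuracy (fraction correct after ``burn_in``),
    the mean converged morph level (from post-burn-in reversals) with the
    observer's P(correct) there, and the analytic fixed point of the
    1-up/3-down rule, p* = 0.5^(1/3).
    """
    cfg = cfg or StaircaseConfig()
    cfg = replace(cfg, stop_reversals=n_trials + 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 71]))
    state = StaircaseState(current_level=cfg.start_level)
    for _ in range(n_trials):
        p = observer_prob_correct(obs, state.current_level, condition)
        staircase_step(state, rng.random() < p, cfg)
    tail = state.trial_log[burn_in:]
    accuracy = float(np.mean([c for _, c in tail]))
    # skip reversals from the initial descent toward the convergence region
    revs = np.asarray(state.reversal_levels[5:], dtype=float)
    mean_level = float(revs.mean()) if len(revs) else float(np.mean([l for l, _ in tail]))
    return {
        "accuracy": accuracy,
        "percent_correct": 100.0 * accuracy,
        "mean_level": mean_level,
        "p_at_mean_level": observer_prob_correct(obs, mean_level, condition),
        "analytic_fixed_point": P_CONVERGENCE,
        "n_trials": n_trials,
    }


# ---------------------------------------------------------------------------
# session-level simulation


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the behavioral arm (20 subjects, 2 repetitions)."""

    n_subjects: int = 20
    n_repetitions: int = 2
    mean_threshold_a: float = 14.0  # class A is easier to discriminate
    mean_threshold_b: float = 19.0
    threshold_sd: float = 3.0
    adaptation_gain_a: float = 4.6  # mean threshold decrease, morph units
    adaptation_gain_b: float = 6.4
    gain_sd: float = 1.5
    lapse_rate: float = 0.01


def default_cohort() -> CohortConfig:
    return CohortConfig()


def _subject_observers(cohort: CohortConfig, subject: int, master_seed: int) -> dict[str, ObserverModel]:
    ss = np.random.SeedSequence([master_seed & 0x7FFFFFFF, 101, subject])
    rng = np.random.default_rng(ss)
    obs = {}
    for proto, mean_t, gain in (
        ("A", cohort.mean_threshold_a, cohort.adaptation_gain_a),
        ("B", cohort.mean_threshold_b, cohort.adaptation_gain_b),
    ):
        t = float(np.clip(rng.normal(mean_t, cohort.threshold_sd), 6.0, 32.0))
        g = float(np.clip(rng.normal(gain, cohort.gain_sd), 0.0, t - 2.0))
        obs[proto] = ObserverModel(
            base_threshold=t, lapse_rate=cohort.lapse_rate, adaptation_gain=g, seed=subject
        )
    return obs


def run_session(
    cohort: CohortConfig | None = None,
    cfg: StaircaseConfig | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Simulate the full behavioral session for a cohort.

    Every subject completes each adaptation run (adapt-A, adapt-B) twice in
    ABAB or BABA order (counterbalanced by subject parity).  Within a run,
    two interleaved staircases — one per prototype — are simulated to
    completion; the staircase whose prototype matches the run's adaptor class
    runs in the "adapted" condition.

    Returns a tidy, balanced threshold table with columns
    (subject, run, prototype, condition, threshold).
    """
    cohort = cohort or CohortConfig()
    cfg = cfg or StaircaseConfig()
    rows = []
    for subject in range(cohort.n_subjects):
        observers = _subject_observers(cohort, subject, master_seed)
        order = ["A", "B"] if subject % 2 == 0 else ["B", "A"]
        for rep in range(1, cohort.n_repetitions + 1):
            for adaptor in order:
                run_seed = np.random.SeedSequence(
                    [master_seed & 0x7FFFFFFF, 202, subject, rep, 0 if adaptor == "A" else 1]
                )
                rngs = [np.random.default_rng(s) for s in run_seed.spawn(2)]
                for proto, rng in zip(("A", "B"), rngs):
                    condition = "adapted" if proto == adaptor else "unadapted"
                    state = run_staircase(observers[proto], cfg, condition, rng)
                    rows.append(
                        {
                            "subject": subject,
                            "run": rep,
                            "prototype": proto,
                            "condition": condition,
                            "threshold": estimate_threshold(state, cfg),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analysis


def paired_t(x: Iterable[float], y: Iterable[float]) -> dict:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    degenerate = sd == 0
    if degenerate:
        t = np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
        p = 0.0 if d.mean() != 0 else 1.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), df=n - 1)
    return {
        "t": float(t),
        "df": n - 1,
        "p": float(p),
        "mean_diff": float(d.mean()),
        "degenerate": bool(degenerate),
    }


def rm_anova(table: pd.DataFrame, dv: str, subject: str, within: list[str]) -> dict:
    """Repeated-measures ANOVA main effects via explicit cell-mean sums of squares.

    For each within-subject factor F, SS_F is computed from the factor's
    marginal means and tested against the F x subject interaction mean square
    (the canonical within-subject error term).  Factors with zero effect SS
    report F = 0 even when the error SS is also zero.
    """
    subjects = np.sort(table[subject].unique())
    n_s = len(subjects)
    grand = table[dv].mean()
    out = {}
    n_total = len(table)
    for factor in within:
        levels = np.sort(table[factor].unique())
        m_f = table.groupby(factor)[dv].mean()
        ss_f = (n_total / len(levels)) * float(((m_f - grand) ** 2).sum())
        m_s = table.groupby(subject)[dv].mean()
        m_fs = table.groupby([factor, subject])[dv].mean()
        reps = n_total / (len(levels) * n_s)  # observations per factor x subject cell
        ss_err = 0.0
        for lv in levels:
            for s in subjects:
                ss_err += reps * (m_fs.loc[(lv, s)] - m_f.loc[lv] - m_s.loc[s] + grand) ** 2
        df1 = len(levels) - 1
        df2 = df1 * (n_s - 1)
        ms_f = ss_f / df1
        ms_err = ss_err / df2
        if ss_f == 0:
            f_stat, p = 0.0, 1.0
        elif ms_err == 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ms_f / ms_err
            p = float(stats.f.sf(f_stat, df1, df2))
        out[factor] = {"F": float(f_stat), "df1": df1, "df2": df2, "p": float(p)}
    return out


def analyze_thresholds(table: pd.DataFrame) -> dict:
    """Threshold analysis: 3-way RM ANOVA + per-prototype paired tests.

    Requires a balanced table (every subject has all 8 condition x prototype
    x run cells).  Paired tests compare adapted vs unadapted thresholds per
    prototype (averaged over runs within subject) and report the mean
    threshold decrease.
    """
    cells = table.groupby(["subject"]).size()
    if cells.nunique() != 1 or cells.iloc[0] != 8:
        raise ValueError("unbalanced table: every subject needs all 8 cells")
    anova = rm_anova(table, dv="threshold", subject="subject", within=["condition", "prototype", "run"])
    paired = {}
    for proto in ("A", "B"):
        sub = table[table.prototype == proto]
        wide = sub.groupby(["subject", "condition"])["threshold"].mean().unstack("condition")
        diff = wide["unadapted"] - wide["adapted"]
        if len(wide) >= 3:
            res = paired_t(wide["unadapted"], wide["adapted"])
            res["mean_decrease"] = res.pop("mean_diff")
        else:  # too few subjects for inference; report the effect only
            res = {
                "t": float("nan"),
                "df": len(wide) - 1,
                "p": float("nan"),
                "degenerate": False,
                "insufficient_n": True,
                "mean_decrease": float(diff.mean()),
            }
        paired[proto] = res
    return {"anova": anova, "paired_tests": paired}
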