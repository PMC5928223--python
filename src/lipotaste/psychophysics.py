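"""Ascending 3-AFC psychophysics: concentration series, sessions, thresholds.

Detection thresholds for linoleic acid (LA) are measured with a
three-alternative forced-choice (3-AFC) staircase on an ascending geometric
concentration series.  Per set the subject must pick the odd sample among
three, so chance performance is 1/3.  The procedure stops when the subject
identifies the LA sample correctly three times consecutively; that
concentration is the detection threshold.  Subjects who never meet the
criterion are censored at the series maximum and classified non-tasters.

The stop rule implemented here presents one 3-AFC set per trial: after a
correct identification the *same* concentration is presented again, after an
incorrect one the series advances one step.  Three consecutive correct sets
therefore always occur at a single concentration, which is the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConcentrationSeries",
    "AFCSession",
    "build_concentration_series",
    "simulate_3afc_session",
    "detect_threshold",
    "classify_taster",
    "geometric_mean_threshold",
    "DEFAULT_CUTOFF",
]

#: taster / non-taster cutoff, % wt/wt LA
DEFAULT_CUTOFF = 0.5


@dataclass(frozen=True)
class ConcentrationSeries:
    """An ascending geometric series of stimulus concentrations (% wt/wt)."""

    concentrations: tuple
    c_min: float
    step_log10: float
    n_steps: int

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if len(c) != self.n_steps:
            raise ValueError("length of concentrations must equal n_steps")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(c) > 1:
            ratios = c[1:] / c[:-1]
            if not np.allclose(ratios, 10.0 ** self.step_log10, rtol=1e-9):
                raise ValueError("consecutive ratio must equal 10**step_log10")
        if not math.isclose(c[0], self.c_min, rel_tol=1e-12):
            raise ValueError("first concentration must equal c_min")

    def __len__(self):
        return self.n_steps

    def __getitem__(self, k):
        return self.concentrations[k]

    @property
    def maximum(self) -> float:
        return self.concentrations[-1]


@dataclass
class AFCSession:
    """One subject's 3-AFC record: trials and the resulting threshold.

    ``trials`` is an ordered list of ``(concentration, correct)`` pairs with
    non-decreasing concentrations.  ``censored`` is True when the stop
    criterion was never met; the threshold is then the series maximum.
    """

    subject_id: str
    trials: list = field(default_factory=list)
    threshold: float = float("nan")
    censored: bool = False


def build_concentration_series(
    c_min: float = 0.00028, step_log10: float = 0.25, n_steps: int = 18
) -> ConcentrationSeries:
    """Build the ascending geometric series ``c_min * 10**(step_log10*k)``.

    Defaults give the 18-solution LA ladder from 0.00028% to ~5% wt/wt in
    0.25 log10 steps.
    """
    if c_min <= 0:
        raise ValueError("c_min must be positive")
    if step_log10 <= 0:
        raise ValueError("step_log10 must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    conc = tuple(c_min * 10.0 ** (step_log10 * k) for k in range(n_steps))
    return ConcentrationSeries(conc, c_min, step_log10, n_steps)


def simulate_3afc_session(
    series: ConcentrationSeries,
    true_threshold: float,
    guess_rate: float = 1.0 / 3.0,
    lapse_rate: float = 0.0,
    seed: int | None = None,
    subject_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> AFCSession:
    """Simulate a subject running the ascending 3-AFC staircase.

    The subject answers correctly with probability ``guess_rate`` below
    ``true_threshold`` and ``1 - lapse_rate`` at or above it (a step-function
    psychometric observer).  Stop rule: a correct answer repeats the same
    concentration, an incorrect one advances the series; three consecutive
    correct answers end the session with that concentration as threshold.
    An incorrect answer at the top concentration censors the session.
    """
    if not (0.0 <= guess_rate <= 1.0 and 0.0 <= lapse_rate <= 1.0):
        raise ValueError("guess_rate and lapse_rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    trials: list = []
    idx, streak = 0, 0
    while True:
        c = series[idx]
        p_correct = guess_rate if c < true_threshold else 1.0 - lapse_rate
        correct = bool(rng.random() < p_correct)
        trials.append((c, correct))
        if correct:
            streak += 1
            if streak == 3:
                return AFCSession(subject_id, trials, threshold=c, censored=False)
        else:
            streak = 0
            idx += 1
            if idx >= len(series):
                return AFCSession(
                    subject_id, trials, threshold=series.maximum, censored=True
                )


def detect_threshold(
    trials: Sequence, series_max: float | None = None
) -> tuple[float, bool]:
    """Score a trial record: first concentration with 3 consecutive corrects.

    Returns ``(threshold, censored)``.  The streak must occur at a single
    concentration (the repeat-on-correct rule); it resets on an incorrect
    answer or a concentration change.  If no streak occurs the session is
    censored at the largest presented concentration (or ``series_max``).
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    concs = [c for c, _ in trials]
    if any(b < a for a, b in zip(concs, concs[1:])):
        raise ValueError("trial concentrations must be non-decreasing")
    streak, streak_conc = 0, None
    for c, correct in trials:
        if correct:
            if streak_conc is not None and c != streak_conc:
                streak = 0
            streak_conc = c
            streak += 1
            if streak == 3:
                return float(c), False
        else:
            streak, streak_conc = 0, None
    top = series_max if series_max is not None else max(concs)
    return float(top), True


def classify_taster(
    threshold: float, cutoff: float = DEFAULT_CUTOFF, censored: bool = False
) -> str:
    """Classify a subject as taster ``"T"`` or non-taster ``"NT"``.

    Non-tasters are subjects whose detection threshold is at or above the
    cutoff (default 0.5% wt/wt LA) or whose session was censored.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return "NT" if (censored or threshold >= cutoff) else "T"


def geometric_mean_threshold(thresholds: Sequence[float]) -> float:
    """Geometric mean exp(mean(log x)) of a set of positive thresholds."""
    t = np.asarray(thresholds, dtype=float)
    if t.size == 0:
        raise ValueError("thresholds must be non-empty")
    if np.any(t <= 0):
        raise ValueError("thresholds must be positive")
    return float(np.exp(np.mean(np.log(t))))
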