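"""Behavioral preference scoring for filial imprinting.

After an hour of exposure to a training stimulus, each chick is tested by
presenting the training stimulus and a novel alternative stimulus in a
running wheel. Approach to each stimulus (metres of wheel travel) yields a
preference score on [0, 100]:

    score = 100 * approach_to_training / (approach_to_training + approach_to_alt)

A score of 50 means no preference (no learning); 100 means exclusive
approach to the training stimulus (strong learning). The group-level check
is a one-sample t-test of the mean score against the no-preference value 50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, UndefinedScoreError

#: Metres travelled per running-wheel revolution.
METRES_PER_REVOLUTION = 0.94

#: Score signalling indifference between the two test stimuli.
NO_PREFERENCE = 50.0


@dataclass(frozen=True)
class BehaviorSummary:
    """Group-level summary of imprinting strength.

    ``t_vs_50`` / ``p_vs_50`` come from a one-sample t-test of the mean
    preference score against the no-preference value of 50 (two-tailed by
    default, n - 1 degrees of freedom). Approach means are in metres and
    may be ``None`` when approach data were not supplied.
    """

    n: int
    mean_preference: float
    sem_preference: float
    t_vs_50: float
    p_vs_50: float
    mean_approach_training: float | None = None
    mean_approach_testing: float | None = None


def revolutions_to_metres(revolutions: float) -> float:
    """Convert running-wheel revolutions to metres (1 revolution = 0.94 m)."""
    return revolutions * METRES_PER_REVOLUTION


def preference_score(approach_train_stim: float, approach_alt_stim: float) -> float:
    """Preference score: percent of total test approach toward the training stimulus.

    Parameters
    ----------
    approach_train_stim, approach_alt_stim
        Approach (metres, nonnegative) to the training and alternative
        stimulus during the preference test.

    Returns
    -------
    float
        ``100 * a_train / (a_train + a_alt)`` on [0, 100].

    Raises
    ------
    UndefinedScoreError
        If both approaches are zero (score undefined; the chick is flagged
        and excluded upstream).
    ValueError
        If either approach is negative.
    """
    if approach_train_stim < 0 or approach_alt_stim < 0:
        raise ValueError("approach distances must be nonnegative")
    total = approach_train_stim + approach_alt_stim
    if total == 0:
        raise UndefinedScoreError("total approach during test is zero; score undefined")
    return 100.0 * approach_train_stim / total


def group_preference_test(
    scores,
    *,
    null_value: float = NO_PREFERENCE,
    tail: str = "two",
    mean_approach_training: float | None = None,
    mean_approach_testing: float | None = None,
) -> BehaviorSummary:
    """One-sample t-test of mean preference score against the no-preference value.

    ``tail`` is ``"two"`` (default) or ``"greater"`` for the one-sided
    alternative that the group learned (mean > 50).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 scores, got {n}")
    mean = float(scores.mean())
    sem = float(scores.std(ddof=1) / np.sqrt(n))
    alternative = {"two": "two-sided", "greater": "greater"}[tail]
    if sem == 0.0:
        # all scores identical: the test degenerates to exact comparison
        t = 0.0 if mean == null_value else float(np.sign(mean - null_value)) * np.inf
        p = 1.0 if mean == null_value else 0.0
    else:
        t, p = stats.ttest_1samp(scores, null_value, alternative=alternative)
    return BehaviorSummary(
        n=n,
        mean_preference=mean,
        sem_preference=sem,
        t_vs_50=float(t),
        p_vs_50=float(p),
        mean_approach_training=mean_approach_training,
        mean_approach_testing=mean_approach_testing,
    )


def summarize_behavior(chicks, *, tail: str = "two") -> BehaviorSummary:
    """Behavior summary for the trained chicks of an experiment.

    ``chicks`` is an iterable of :class:`~imprintstat.datamodel.ChickRecord`;
    untrained chicks are ignored. Mean approach during training and during
    testing (both stimuli summed) are reported alongside the score test.
    """
    trained = [c for c in chicks if c.trained]
    scores = [c.preference_score for c in trained if c.preference_score is not None]
    appr_train = [c.approach_training for c in trained if c.approach_training is not None]
    appr_test = [
        c.approach_test_training_stim + c.approach_test_alternative_stim
        for c in trained
        if c.approach_test_training_stim is not None
        and c.approach_test_alternative_stim is not None
    ]
    return group_preference_test(
        scores,
        tail=tail,
        mean_approach_training=float(np.mean(appr_train)) if appr_train else None,
        mean_approach_testing=float(np.mean(appr_test)) if appr_test else None,
    )
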