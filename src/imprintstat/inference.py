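"""Decision criteria: learning-dependent change, predisposition, side-effect.

A significant amount-vs-score correlation in trained chicks can arise two
ways: the protein changed *because* of learning, or the protein level
pre-dated training and set the chick's readiness to learn (a
predisposition). The criteria separating them:

* **Learning-dependent change** — significant correlation, the level
  extrapolated to the maximum attained preference score differs from the
  untrained mean (Welch two-sample t with Satterthwaite df), and *no*
  significant reduction of residual variance below the untrained variance.

* **Predisposition** — significant correlation, trained total variance
  homogeneous with untrained (two-tailed F), and residual variance about
  the regression significantly *below* the untrained variance (one-tailed
  F): if levels merely index readiness to learn, the score "explains away"
  part of the baseline variability.

* **Training side-effect** — the level at preference score 50 (training
  without learning) differs from the untrained mean: an effect of the
  training procedure itself (locomotion, arousal) rather than of learning.

All tests are two-tailed at alpha = 0.05 except the residual-variance
reduction, which is directional by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .exceptions import ImprintstatError
from .model import GroupSummary, Prediction

#: Significance level used throughout unless overridden.
DEFAULT_ALPHA = 0.05

#: p-value below which a non-significant result is still worth a note.
MARGINAL_P = 0.1


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-sample comparison of two estimates with separate SEs/dfs."""

    estimate_diff: float
    t: float
    df: float  # Satterthwaite df; fractional
    p: float
    tail: str = "two"


@dataclass(frozen=True)
class VarianceTestResult:
    """F test of a variance ratio (trained residual or total / untrained)."""

    ratio: float
    df_num: int
    df_den: int
    p: float
    tail: str


@dataclass(frozen=True)
class CorrelationTriple:
    """(r, df, p) for the amount-vs-preference-score association."""

    r: float
    df: int
    p: float


@dataclass(frozen=True)
class ClassificationResult:
    """Verdict for one measure with all supporting statistics."""

    measure_key: str
    correlation_significant: bool
    learning_dependent: bool
    predisposition: bool
    training_side_effect: bool
    verdict_notes: str
    correlation: CorrelationTriple
    cmp_max_score: ComparisonResult
    cmp_score_50: ComparisonResult
    residual_variance: VarianceTestResult
    total_variance: VarianceTestResult
    alpha: float = DEFAULT_ALPHA
    n_tests: int = field(default=5)


def welch_compare(
    est_a: float,
    se_a: float,
    df_a: float,
    est_b: float,
    se_b: float,
    df_b: float,
    *,
    tail: str = "two",
) -> ComparisonResult:
    """Welch two-sample t with Satterthwaite degrees of freedom.

    ``t = (est_a - est_b) / sqrt(se_a^2 + se_b^2)`` and
    ``df = (se_a^2 + se_b^2)^2 / (se_a^4/df_a + se_b^4/df_b)``, which lies
    between min(df_a, df_b) and df_a + df_b. Used to compare a regression
    intercept (df = slope df) with the untrained group mean (df = n - 1).
    """
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be nonnegative")
    if se_a == 0 and se_b == 0:
        raise ImprintstatError("both standard errors are zero; comparison degenerate")
    var = se_a**2 + se_b**2
    t = (est_a - est_b) / var**0.5
    df = var**2 / (se_a**4 / df_a + se_b**4 / df_b)
    if tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    elif tail == "one":
        p = float(stats.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return ComparisonResult(estimate_diff=float(est_a - est_b), t=float(t),
                            df=float(df), p=min(p, 1.0), tail=tail)


def compare_prediction_to_group(pred: Prediction, group: GroupSummary,
                                *, tail: str = "two") -> ComparisonResult:
    """Welch comparison of a predicted level against a group summary."""
    return welch_compare(pred.estimate, pred.se, pred.df,
                         group.mean, group.sem, group.df, tail=tail)


def residual_variance_test(
    residual_variance: float,
    df_residual: float,
    untrained_variance: float,
    df_untrained: float,
    *,
    tail: str = "one_less",
) -> VarianceTestResult:
    """Is the residual variance about the regression *below* the untrained variance?

    One-tailed by default: p is the probability, under equal variances, of
    an F variate with (df_untrained, df_residual) dfs at least as large as
    untrained/residual — i.e. of a reduction at least this extreme. A small
    p means the preference score explains away baseline variability, the
    predisposition signature. ``tail="two"`` doubles the smaller tail.
    """
    if residual_variance <= 0 or untrained_variance <= 0:
        raise ImprintstatError("variances must be positive for the F test")
    ratio = residual_variance / untrained_variance
    sf_less = float(stats.f.sf(1.0 / ratio, df_untrained, df_residual))
    if tail == "one_less":
        p = sf_less
    elif tail == "two":
        p = min(1.0, 2 * min(sf_less, 1.0 - sf_less))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return VarianceTestResult(ratio=float(ratio), df_num=df_untrained,
                              df_den=df_residual, p=p, tail=tail)


def total_variance_test(
    trained_total_variance: float,
    df_trained: float,
    untrained_variance: float,
    df_untrained: float,
) -> VarianceTestResult:
    """Two-tailed F test of trained total variance vs untrained variance.

    Homogeneity here is *required* by the predisposition account: if the
    protein is untouched by training, trained and untrained chicks share
    the same total spread.
    """
    if trained_total_variance <= 0 or untrained_variance <= 0:
        raise ImprintstatError("variances must be positive for the F test")
    ratio = trained_total_variance / untrained_variance
    sf = float(stats.f.sf(ratio, df_trained, df_untrained))
    p = min(1.0, 2 * min(sf, 1.0 - sf))
    return VarianceTestResult(ratio=float(ratio), df_num=df_trained,
                              df_den=df_untrained, p=p, tail="two")


def classify_measure(
    correlation: CorrelationTriple,
    cmp_max_score: ComparisonResult,
    cmp_score_50: ComparisonResult,
    residual_var: VarianceTestResult,
    total_var: VarianceTestResult,
    *,
    alpha: float = DEFAULT_ALPHA,
    measure_key: str = "",
) -> ClassificationResult:
    """Apply the decision criteria to one measure.

    A significant correlation is the gateway. Given it:

    * residual variance significantly reduced *and* total variance
      homogeneous -> ``predisposition``;
    * residual variance not reduced *and* level at the maximum score
      different from the untrained mean -> ``learning_dependent``;
    * level at score 50 different from the untrained mean ->
      ``training_side_effect`` (assessable alongside learning);
    * none of the above -> no flag, with a note (insufficient evidence).

    Marginal results (p < 0.1) are mentioned in the notes but never flagged.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    notes: list[str] = []
    corr_sig = correlation.p < alpha
    learning = predisposition = side_effect = False
    if corr_sig:
        reduced = residual_var.p < alpha
        homogeneous = total_var.p >= alpha
        predisposition = reduced and homogeneous
        learning = (not reduced) and cmp_max_score.p < alpha
        side_effect = cmp_score_50.p < alpha
        if predisposition:
            notes.append(
                "significant correlation with reduced residual variance and "
                "homogeneous total variance: predisposition to learn"
            )
        if learning:
            notes.append(
                "significant correlation, level at maximum score differs from "
                "untrained mean, residual variance not reduced: learning-dependent"
            )
        if side_effect:
            notes.append(
                "level at score 50 differs from untrained mean: training "
                "side-effect unrelated to learning"
            )
        if reduced and not homogeneous:
            notes.append(
                "residual variance reduced but trained total variance differs "
                "from untrained: predisposition criteria not met"
            )
        if not (learning or predisposition):
            if not notes:
                notes.append(
                    "significant correlation but insufficient evidence to "
                    "attribute it to learning or to a predisposition"
                )
            if not learning and not reduced and alpha <= cmp_max_score.p < MARGINAL_P:
                notes.append(
                    f"level at maximum score vs untrained mean marginal "
                    f"(p = {cmp_max_score.p:.3g})"
                )
    else:
        notes.append("no significant correlation with preference score: no evidence")
        if alpha <= correlation.p < MARGINAL_P:
            notes.append(f"correlation marginal (p = {correlation.p:.3g})")
    return ClassificationResult(
        measure_key=measure_key,
        correlation_significant=bool(corr_sig),
        learning_dependent=bool(learning),
        predisposition=bool(predisposition),
        training_side_effect=bool(side_effect),
        verdict_notes="; ".join(notes),
        correlation=correlation,
        cmp_max_score=cmp_max_score,
        cmp_score_50=cmp_score_50,
        residual_variance=residual_var,
        total_variance=total_var,
        alpha=alpha,
    )
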