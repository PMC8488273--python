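"""End-to-end orchestration: per-measure analysis and simulation studies.

``run_analysis`` takes a validated experiment and, independently for every
(region, hemisphere, measure) cell — the IMM and the PPN control region and
the two hemispheres are never pooled — derives ratio measures, removes the
batch effect, summarizes the untrained group, fits the preference-score
regression on trained chicks, compares the extrapolated levels at score 50
and at the maximum attained score against the untrained mean, runs both
variance tests, and applies the classification criteria. A failure in one
measure is recorded and the remaining measures still run.

``run_simulation_study`` repeats generate -> analyze -> classify over many
synthetic replicates and aggregates flag rates with Monte-Carlo standard
errors — the operating characteristics of the whole decision procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import inference
from .datamodel import ExperimentData, derive_ratio_measures
from .exceptions import ImprintstatError, InsufficientDataError
from .inference import (
    ClassificationResult,
    CorrelationTriple,
    classify_measure,
    compare_prediction_to_group,
    residual_variance_test,
    total_variance_test,
)
from .model import (
    BatchStandardizer,
    GroupSummary,
    ModelFit,
    Prediction,
    PreferenceRegression,
    correlation_from_fit,
    predict_at_score,
    untrained_summary,
)
from .synthetic import ScenarioConfig, generate_experiment, scenario_presets

log = logging.getLogger(__name__)

#: Number of inferential tests reported per measure (correlation, two
#: intercept comparisons, two variance tests) — no multiplicity correction
#: is applied across measures, so this count lets users apply their own.
TESTS_PER_MEASURE = 5


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings, echoed into the results for provenance."""

    alpha: float = inference.DEFAULT_ALPHA
    max_score: float | str = "observed"  # "observed" or a fixed score
    batch_mean_scope: str = "all"  # "all" or "trained_only"
    reml: bool = True
    variance_test_tail: str = "one_less"
    with_covariates: bool = False
    relaxed_validation: bool = False

    def resolved(self) -> dict:
        return asdict(self)


@dataclass
class MeasureResult:
    """Everything computed for one region/hemisphere/measure cell."""

    measure_key: str
    untrained: GroupSummary | None = None
    fit: ModelFit | None = None
    correlation: CorrelationTriple | None = None
    max_score: float | None = None
    pred_at_max: Prediction | None = None
    pred_at_50: Prediction | None = None
    cmp_max: inference.ComparisonResult | None = None
    cmp_50: inference.ComparisonResult | None = None
    residual_var_test: inference.VarianceTestResult | None = None
    total_var_test: inference.VarianceTestResult | None = None
    classification: ClassificationResult | None = None
    covariates: object | None = None
    dropped_chicks: tuple[str, ...] = ()
    error: str | None = None


# Numeric rows of the block report layout, in output order.
_BLOCK_ROWS = (
    "untrained_mean", "untrained_sem", "untrained_df",
    "correlation_r", "correlation_df", "correlation_p",
    "intercept_at_max", "se_intercept_at_max", "max_score",
    "cmp_max_t", "cmp_max_df", "cmp_max_p",
    "intercept_at_50", "se_intercept_at_50",
    "cmp_50_t", "cmp_50_df", "cmp_50_p",
    "residual_over_untrained_variance", "residual_variance_p",
    "trained_over_untrained_total_variance", "total_variance_p",
    "slope", "se_slope", "n_trained", "n_untrained",
    "learning_dependent", "predisposition", "training_side_effect",
    "correlation_significant", "n_tests",
)


@dataclass
class ResultsTable:
    """Per-measure results plus the resolved configuration and run errors."""

    results: dict[str, MeasureResult]
    config: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Block report layout: one column per measure, one row per statistic."""
        cols = {}
        for key, r in self.results.items():
            c: dict[str, float] = dict.fromkeys(_BLOCK_ROWS, np.nan)
            if r.untrained is not None:
                c["untrained_mean"] = r.untrained.mean
                c["untrained_sem"] = r.untrained.sem
                c["untrained_df"] = r.untrained.df
                c["n_untrained"] = r.untrained.n
            if r.correlation is not None:
                c["correlation_r"] = r.correlation.r
                c["correlation_df"] = r.correlation.df
                c["correlation_p"] = r.correlation.p
            if r.fit is not None:
                c["slope"] = r.fit.slope
                c["se_slope"] = r.fit.se_slope
                c["n_trained"] = r.fit.n_obs
            if r.pred_at_max is not None:
                c["intercept_at_max"] = r.pred_at_max.estimate
                c["se_intercept_at_max"] = r.pred_at_max.se
                c["max_score"] = r.max_score
            if r.cmp_max is not None:
                c["cmp_max_t"] = r.cmp_max.t
                c["cmp_max_df"] = r.cmp_max.df
                c["cmp_max_p"] = r.cmp_max.p
            if r.pred_at_50 is not None:
                c["intercept_at_50"] = r.pred_at_50.estimate
                c["se_intercept_at_50"] = r.pred_at_50.se
            if r.cmp_50 is not None:
                c["cmp_50_t"] = r.cmp_50.t
                c["cmp_50_df"] = r.cmp_50.df
                c["cmp_50_p"] = r.cmp_50.p
            if r.residual_var_test is not None:
                c["residual_over_untrained_variance"] = r.residual_var_test.ratio
                c["residual_variance_p"] = r.residual_var_test.p
            if r.total_var_test is not None:
                c["trained_over_untrained_total_variance"] = r.total_var_test.ratio
                c["total_variance_p"] = r.total_var_test.p
            if r.classification is not None:
                c["learning_dependent"] = float(r.classification.learning_dependent)
                c["predisposition"] = float(r.classification.predisposition)
                c["training_side_effect"] = float(r.classification.training_side_effect)
                c["correlation_significant"] = float(r.classification.correlation_significant)
                c["n_tests"] = TESTS_PER_MEASURE
            cols[key] = c
        return pd.DataFrame(cols).reindex(list(_BLOCK_ROWS))

    def notes(self) -> dict[str, str]:
        out = {}
        for key, r in self.results.items():
            if r.error:
                out[key] = f"ERROR: {r.error}"
            elif r.classification is not None:
                out[key] = r.classification.verdict_notes
        return out


def write_results_table(results: ResultsTable | pd.DataFrame, path) -> None:
    """Write the block-layout results CSV (full float precision, re-loadable)."""
    frame = results.to_frame() if isinstance(results, ResultsTable) else results
    frame.to_csv(path, index=True, index_label="statistic", float_format="%.17g")


def load_results_table(path) -> pd.DataFrame:
    """Read a results CSV back into the block-layout frame."""
    return pd.read_csv(path, index_col="statistic", float_precision="round_trip")


def _compare_allowing_exact(pred, group) -> inference.ComparisonResult:
    """Welch comparison, degenerating gracefully on exactly noiseless input.

    With both SEs exactly zero (noiseless synthetic data) the comparison is
    exact: unequal estimates differ certainly (p = 0), equal ones do not
    (p = 1). Real data never hit this branch.
    """
    if pred.se == 0 and group.sem == 0:
        diff = pred.estimate - group.mean
        equal = np.isclose(diff, 0.0, atol=1e-12)
        return inference.ComparisonResult(
            estimate_diff=float(diff),
            t=0.0 if equal else float(np.sign(diff)) * np.inf,
            df=float(min(pred.df, group.df)),
            p=1.0 if equal else 0.0,
        )
    return compare_prediction_to_group(pred, group)


def _variance_test_allowing_zero(res_var, df_res, un_var, df_un, *, tail):
    """Residual-variance reduction test tolerating exactly-zero variances.

    Zero residual against positive untrained variance is a certain
    reduction (p = 0); a zero untrained variance makes a reduction
    impossible to support (p = 1).
    """
    if res_var > 0 and un_var > 0:
        return residual_variance_test(res_var, df_res, un_var, df_un, tail=tail)
    if res_var == 0 and un_var > 0:
        return inference.VarianceTestResult(ratio=0.0, df_num=df_un, df_den=df_res,
                                            p=0.0, tail=tail)
    return inference.VarianceTestResult(ratio=float("nan"), df_num=df_un, df_den=df_res,
                                        p=1.0, tail=tail)


def _total_variance_allowing_zero(tr_var, df_tr, un_var, df_un):
    """Two-tailed total-variance F test tolerating exactly-zero variances."""
    if tr_var > 0 and un_var > 0:
        return total_variance_test(tr_var, df_tr, un_var, df_un)
    equal = tr_var == un_var
    return inference.VarianceTestResult(
        ratio=float("nan") if un_var == 0 else 0.0,
        df_num=df_tr, df_den=df_un, p=1.0 if equal else 0.0, tail="two",
    )


def _analyze_one(
    sub: pd.DataFrame, cfg: AnalysisConfig, measure_key: str
) -> MeasureResult:
    res = MeasureResult(measure_key=measure_key)
    # Replicate rows (same chick, several filters) are averaged per chick.
    if sub["chick_id"].duplicated().any():
        log.info("%s: averaging replicate rows per chick", measure_key)
        keys = ["chick_id", "batch_id", "trained", "preference_score"]
        sub = sub.groupby(keys, dropna=False, as_index=False)["relative_amount"].mean()
    values = sub["relative_amount"].to_numpy(dtype=float)
    batches = sub["batch_id"].to_numpy()
    trained_mask = sub["trained"].to_numpy(dtype=bool)

    # Standardized amounts feed the group summaries and variance tests; the
    # regression itself is fitted to raw amounts with the batch random
    # intercept (standardizing first would soak up part of the score effect
    # through the batch means and attenuate the slope).
    std = BatchStandardizer()
    if cfg.batch_mean_scope == "trained_only":
        if not trained_mask.any():
            raise InsufficientDataError("no trained chicks to scope batch means on")
        std.fit(values[trained_mask], batches[trained_mask])
    else:
        std.fit(values, batches)
    z = std.transform(values, batches)

    if (~trained_mask).sum() >= 2:
        res.untrained = untrained_summary(z[~trained_mask])

    tr = sub[trained_mask].copy()
    tr["z"] = z[trained_mask]
    usable = tr["preference_score"].notna()
    res.dropped_chicks = tuple(tr.loc[~usable, "chick_id"])
    for cid in res.dropped_chicks:
        log.warning("%s: dropping trained chick %s (no preference score)", measure_key, cid)
    tr = tr[usable]
    if len(tr) == 0:
        raise InsufficientDataError("no trained chicks with this measure")
    est = PreferenceRegression(reml=cfg.reml).fit(
        tr["preference_score"].to_numpy(dtype=float),
        tr["relative_amount"].to_numpy(dtype=float),
        groups=tr["batch_id"].to_numpy(),
    )
    res.fit = est.result_
    r, df, p = correlation_from_fit(est.result_)
    res.correlation = CorrelationTriple(r=r, df=df, p=p)
    max_score = (
        float(tr["preference_score"].max()) if cfg.max_score == "observed"
        else float(cfg.max_score)
    )
    res.max_score = max_score
    res.pred_at_max = predict_at_score(est.result_, max_score)
    res.pred_at_50 = predict_at_score(est.result_, 50.0)

    if res.untrained is not None:
        res.cmp_max = _compare_allowing_exact(res.pred_at_max, res.untrained)
        res.cmp_50 = _compare_allowing_exact(res.pred_at_50, res.untrained)
        res.residual_var_test = _variance_test_allowing_zero(
            est.result_.residual_variance, est.result_.df_residual,
            res.untrained.variance, res.untrained.df,
            tail=cfg.variance_test_tail,
        )
        zt = tr["z"].to_numpy(dtype=float)
        res.total_var_test = _total_variance_allowing_zero(
            float(np.var(zt, ddof=1)), len(zt) - 1,
            res.untrained.variance, res.untrained.df,
        )
        res.classification = classify_measure(
            res.correlation, res.cmp_max, res.cmp_50,
            res.residual_var_test, res.total_var_test,
            alpha=cfg.alpha, measure_key=measure_key,
        )
    else:
        raise InsufficientDataError("fewer than 2 untrained chicks with this measure")

    if cfg.with_covariates:
        from .model import fit_with_approach_covariates

        have = tr[["approach_training_m", "approach_test_train_m",
                   "approach_test_alt_m"]].notna().all(axis=1)
        if have.all():
            res.covariates = fit_with_approach_covariates(
                tr["relative_amount"].to_numpy(dtype=float),
                tr["preference_score"].to_numpy(dtype=float),
                tr["approach_training_m"].to_numpy(dtype=float),
                (tr["approach_test_train_m"] + tr["approach_test_alt_m"]).to_numpy(dtype=float),
                tr["batch_id"].to_numpy(),
            )
        else:
            log.warning("%s: approach covariates missing; covariate model skipped", measure_key)
    return res


def run_analysis(data: ExperimentData, cfg: AnalysisConfig = AnalysisConfig()) -> ResultsTable:
    """Full pipeline on one experiment: ratios, standardization, fits, verdicts."""
    data.validate(relaxed=cfg.relaxed_validation)
    data = derive_ratio_measures(data)
    mdf = data.measurement_frame().merge(data.behavior_frame(), on="chick_id", how="left")
    results: dict[str, MeasureResult] = {}
    for (region, hemi, measure), sub in mdf.groupby(
        ["region", "hemisphere", "measure"], sort=True
    ):
        key = f"{region}/{hemi}/{measure}/{data.timepoint}"
        try:
            results[key] = _analyze_one(sub, cfg, key)
        except ImprintstatError as e:
            log.warning("%s: %s", key, e)
            res = MeasureResult(measure_key=key, error=str(e))
            # untrained summary is still worth emitting when computable
            untrained_mask = ~sub["trained"].to_numpy(dtype=bool)
            if untrained_mask.sum() >= 2:
                z = BatchStandardizer().fit_transform(
                    sub["relative_amount"].to_numpy(dtype=float),
                    sub["batch_id"].to_numpy(),
                )
                res.untrained = untrained_summary(z[untrained_mask])
            results[key] = res
    return ResultsTable(
        results=results,
        config=cfg.resolved(),
        metadata=dict(data.metadata, timepoint=data.timepoint),
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Flag rates of the decision procedure over synthetic replicates."""

    scenario: str
    replicates: int
    rates: dict[str, float]
    mc_se: dict[str, float]
    seeds: tuple[int, ...]
    n_failures: int
    slopes: np.ndarray
    slope_ses: np.ndarray
    slope_dfs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rate": self.rates, "mc_se": self.mc_se}
        ).rename_axis("criterion")


_FLAGS = ("correlation_significant", "learning_dependent", "predisposition",
          "training_side_effect")


def run_simulation_study(
    scenario: str | ScenarioConfig,
    replicates: int,
    *,
    seed: int = 0,
    preset: str = "paper-like-1h",
    analysis: AnalysisConfig = AnalysisConfig(),
    **scenario_overrides,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the full pipeline.

    Each replicate generates a fresh experiment (child seed drawn from the
    master ``seed``), runs :func:`run_analysis`, and records the
    classification flags together with the fitted slope, its SE and df.
    Replicates whose analysis fails are counted, not fatal.
    """
    if replicates < 1:
        raise ImprintstatError("replicates must be >= 1")
    if isinstance(scenario, ScenarioConfig):
        base_cfg, scen_name = scenario, scenario.scenario
    else:
        base_cfg = scenario_presets(preset, scenario, **scenario_overrides)
        scen_name = scenario
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=replicates)
    flags = {f: [] for f in _FLAGS}
    slopes, ses, dfs = [], [], []
    failures = 0
    from dataclasses import replace as _replace

    for s in seeds:
        cfg = _replace(base_cfg, seed=int(s))
        try:
            data = generate_experiment(cfg)
            table = run_analysis(data, analysis)
            (res,) = table.results.values()
            if res.error or res.classification is None:
                raise ImprintstatError(res.error or "no classification")
        except ImprintstatError as e:
            failures += 1
            log.warning("replicate seed %d failed: %s", s, e)
            continue
        cl = res.classification
        for f in _FLAGS:
            flags[f].append(getattr(cl, f))
        slopes.append(res.fit.slope)
        ses.append(res.fit.se_slope)
        dfs.append(res.fit.df_slope)
    n_ok = replicates - failures
    rates = {f: (float(np.mean(v)) if v else float("nan")) for f, v in flags.items()}
    mc_se = {
        f: (float(np.sqrt(r * (1 - r) / n_ok)) if n_ok and np.isfinite(r) else float("nan"))
        for f, r in rates.items()
    }
    return OperatingCharacteristics(
        scenario=scen_name,
        replicates=replicates,
        rates=rates,
        mc_se=mc_se,
        seeds=tuple(int(s) for s in seeds),
        n_failures=failures,
        slopes=np.asarray(slopes, dtype=float),
        slope_ses=np.asarray(ses, dtype=float),
        slope_dfs=np.asarray(dfs, dtype=float),
    )
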