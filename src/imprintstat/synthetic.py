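"""Synthetic imprinting experiments with the study's statistical structure.

The generator reproduces the design of the source study — hatch batches of
up to three trained chicks plus one untrained control, preference scores
centred near 72 on [0, 100], protein amounts around 1 relative unit with
batch random effects — under four generative scenarios:

``null``
    Protein level unrelated to anything: y = mu0 + u_batch + e.
``learning``
    Training changes the protein in proportion to how much was learned:
    trained y = mu0 + u_batch + beta * (score - 50) + e. At score 50 (no
    learning) the expected level equals the untrained mean — no side-effect.
``side_effect``
    Training shifts the protein by delta regardless of learning:
    trained y = mu0 + u_batch + delta + e.
``predisposition``
    A latent per-chick aptitude d ~ N(0, sigma_d^2) raises both the
    protein level (y = mu0 + u_batch + d + e, trained and untrained alike)
    and the score (score = mu_ps + kappa * d + eta, clamped to [0, 100]).
    Training never touches the protein; the correlation in trained chicks
    exists because the score reads out the aptitude.

Scenario-specific parameters are forced to zero outside their scenario
unless ``combine=True``. Output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import preference_score
from .datamodel import ChickRecord, ExperimentData, Measurement
from .densitometry import REFERENCE_MICROGRAMS, STANDARD_MICROGRAMS
from .exceptions import ImprintstatError

#: Floor applied to generated relative amounts (they must stay positive;
#: at the default noise scales this clips ~1e-5 of draws).
_AMOUNT_FLOOR = 1e-6

#: Trained-chick counts per batch for the two study-sized designs.
DESIGN_PRESETS = {
    "paper-like-1h": (3, 2, 2, 2, 2, 2, 2, 2, 2, 2),  # 21 trained / 10 batches
    "paper-like-24h": (3, 2, 2, 2, 2, 2, 2, 2, 2),  # 19 trained / 9 batches
}

SCENARIOS = ("null", "learning", "side_effect", "predisposition")


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters for one synthetic experiment.

    Scale conventions: amounts in relative units (baseline ``mu0`` = 1),
    scores in preference-score units on [0, 100]. ``learning_slope`` is
    amount per score unit; ``aptitude_score_gain`` is score units per
    aptitude unit (aptitude shares the amount scale).
    """

    scenario: str = "null"
    n_batches: int = 10
    trained_per_batch: tuple[int, ...] = DESIGN_PRESETS["paper-like-1h"]
    mu0: float = 1.0
    batch_sd: float = 0.10
    residual_sd: float = 0.10
    learning_slope: float = 0.005
    side_effect_shift: float = 0.30
    aptitude_sd: float = 0.20
    aptitude_score_gain: float = 110.0
    score_noise_sd: float = 22.0
    score_mean: float = 72.0
    seed: int = 0
    combine: bool = False
    region: str = "IMM"
    hemisphere: str = "left"
    measure: str = "Total"
    timepoint: str = "h1"

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ImprintstatError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.n_batches < 1 or len(self.trained_per_batch) != self.n_batches:
            raise ImprintstatError(
                "trained_per_batch must list one count per batch "
                f"(got {len(self.trained_per_batch)} for {self.n_batches} batches)"
            )
        if any(not 1 <= k <= 3 for k in self.trained_per_batch):
            raise ImprintstatError("trained chicks per batch must be between 1 and 3")
        for name in ("batch_sd", "residual_sd", "aptitude_sd", "score_noise_sd"):
            if getattr(self, name) < 0:
                raise ImprintstatError(f"{name} must be >= 0")

    def effective(self) -> "ScenarioConfig":
        """Config with out-of-scenario effect parameters forced to zero."""
        if self.combine:
            return self
        over = {}
        if self.scenario != "learning":
            over["learning_slope"] = 0.0
        if self.scenario != "side_effect":
            over["side_effect_shift"] = 0.0
        if self.scenario != "predisposition":
            over["aptitude_sd"] = 0.0
            over["aptitude_score_gain"] = 0.0
        return replace(self, **over)


#: Scenario-dependent overrides applied on top of the common defaults.
#: The predisposition scenario uses an aptitude-to-residual sd ratio of 2
#: and small score noise so that the score is a clean readout of aptitude.
SCENARIO_DEFAULTS: dict[str, dict] = {
    "null": {},
    "learning": {},
    "side_effect": {},
    "predisposition": {"score_noise_sd": 5.0},
}


@dataclass(frozen=True)
class DensitometryConfig:
    """Gel-level emulation: per-gel gain, multiplicative OD noise, standards."""

    gain_range: tuple[float, float] = (0.5, 2.0)
    od_noise_sd: float = 0.02  # sd of noise as a fraction of the true OD
    standards: tuple[float, ...] = STANDARD_MICROGRAMS

    def validate(self) -> None:
        lo, hi = self.gain_range
        if not (0 < lo <= hi):
            raise ImprintstatError("gain range must be positive with lo <= hi")
        if self.od_noise_sd < 0:
            raise ImprintstatError("od_noise_sd must be >= 0")


def scenario_presets(name: str, scenario: str = "null", *, seed: int = 0,
                     **overrides) -> ScenarioConfig:
    """Study-sized design presets.

    ``"paper-like-1h"``: 10 batches, 21 trained + 10 untrained chicks;
    ``"paper-like-24h"``: 9 batches, 19 trained + 9 untrained chicks.
    Scenario defaults (see :data:`SCENARIO_DEFAULTS`) are applied, then any
    explicit overrides.
    """
    if name not in DESIGN_PRESETS:
        raise ImprintstatError(
            f"unknown preset {name!r}; available presets: {sorted(DESIGN_PRESETS)}"
        )
    pattern = DESIGN_PRESETS[name]
    if scenario not in SCENARIOS:
        raise ImprintstatError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    kwargs = {
        "scenario": scenario,
        "n_batches": len(pattern),
        "trained_per_batch": pattern,
        "seed": seed,
        "timepoint": "h1" if name.endswith("1h") else "h24",
    }
    kwargs.update(SCENARIO_DEFAULTS[scenario])
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def _approaches_for_score(rng: np.random.Generator, score: float) -> tuple[float, float, float]:
    """Training approach and the two test approaches consistent with a score.

    Total test approach and training approach are lognormal, centred near
    the study's reported group means (~13 m testing, ~64 m training); the
    test total is split between the stimuli exactly in the score's ratio.
    """
    total_test = float(rng.lognormal(mean=np.log(11.0), sigma=0.6))
    a_train_stim = score / 100.0 * total_test
    a_alt_stim = total_test - a_train_stim
    approach_training = float(rng.lognormal(mean=np.log(45.0), sigma=0.8))
    return approach_training, a_train_stim, a_alt_stim


def generate_experiment(cfg: ScenarioConfig) -> ExperimentData:
    """Draw one complete synthetic experiment under the configured scenario."""
    cfg.validate()
    eff = cfg.effective()
    rng = np.random.default_rng(eff.seed)
    # Aptitude feeds the protein level whenever it is drawn at all; its sd
    # is already forced to 0 outside the predisposition scenario.
    gamma = 1.0 if eff.aptitude_sd > 0 else 0.0
    chicks: list[ChickRecord] = []
    measurements: list[Measurement] = []
    for b in range(eff.n_batches):
        batch_id = f"B{b + 1:02d}"
        u_b = rng.normal(0.0, eff.batch_sd)
        for j in range(eff.trained_per_batch[b]):
            chick_id = f"{batch_id}T{j + 1}"
            d = rng.normal(0.0, eff.aptitude_sd)
            eta = rng.normal(0.0, eff.score_noise_sd)
            score = float(np.clip(eff.score_mean + eff.aptitude_score_gain * d + eta, 0.0, 100.0))
            eps = rng.normal(0.0, eff.residual_sd)
            amount = (
                eff.mu0 + u_b + eff.side_effect_shift
                + eff.learning_slope * (score - 50.0) + gamma * d + eps
            )
            a_training, a_train_stim, a_alt_stim = _approaches_for_score(rng, score)
            chicks.append(
                ChickRecord(
                    chick_id=chick_id,
                    batch_id=batch_id,
                    trained=True,
                    approach_training=a_training,
                    approach_test_training_stim=a_train_stim,
                    approach_test_alternative_stim=a_alt_stim,
                    # recomputed from the approaches so the stored score is
                    # exactly consistent with them; clipped against fp overshoot
                    preference_score=float(
                        np.clip(preference_score(a_train_stim, a_alt_stim), 0.0, 100.0)
                    ),
                )
            )
            measurements.append(
                Measurement(chick_id=chick_id, region=eff.region, hemisphere=eff.hemisphere,
                            measure=eff.measure,
                            relative_amount=float(max(amount, _AMOUNT_FLOOR)))
            )
        # one untrained control per batch; aptitude drawn but unobservable
        chick_id = f"{batch_id}U"
        d = rng.normal(0.0, eff.aptitude_sd)
        eps = rng.normal(0.0, eff.residual_sd)
        amount = eff.mu0 + u_b + gamma * d + eps
        chicks.append(ChickRecord(chick_id=chick_id, batch_id=batch_id, trained=False))
        measurements.append(
            Measurement(chick_id=chick_id, region=eff.region, hemisphere=eff.hemisphere,
                        measure=eff.measure,
                        relative_amount=float(max(amount, _AMOUNT_FLOOR)))
        )
    data = ExperimentData(
        chicks=chicks,
        measurements=measurements,
        timepoint=eff.timepoint,
        metadata={"scenario": eff.scenario, "seed": eff.seed, "generator": "imprintstat"},
    )
    data.validate()
    return data


def generate_densitometry(
    data: ExperimentData, dcfg: DensitometryConfig = DensitometryConfig(), *, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate gel readout: per-gel standards and raw sample band ODs.

    One gel per (batch, measure). Each gel gets a gain g drawn from
    ``gain_range``; a band whose true relative amount is a reads OD
    ``g * a * (1 + noise)`` and the standard at m micrograms reads
    ``g * m / 30 * (1 + noise)``. Calibrating each gel and normalizing
    recovers the relative amounts up to the noise (exactly, at zero noise,
    for any gain).

    Returns ``(standards, samples)`` tables ready for
    :func:`imprintstat.densitometry.relative_amounts_from_od`.
    """
    dcfg.validate()
    rng = np.random.default_rng(seed)
    batch_of = {c.chick_id: c.batch_id for c in data.chicks}
    gels = sorted({(batch_of[m.chick_id], m.measure) for m in data.measurements})
    lo, hi = dcfg.gain_range
    std_rows, sample_rows = [], []
    gains = {}
    for batch_id, measure in gels:
        gel_id = f"{batch_id}-{measure}"
        g = float(rng.uniform(lo, hi))
        gains[(batch_id, measure)] = (gel_id, g)
        for m_ug in dcfg.standards:
            true_od = g * m_ug / REFERENCE_MICROGRAMS
            od = true_od * (1.0 + rng.normal(0.0, dcfg.od_noise_sd))
            std_rows.append({"gel_id": gel_id, "micrograms": m_ug, "od": od})
    for m in data.measurements:
        gel_id, g = gains[(batch_of[m.chick_id], m.measure)]
        true_od = g * m.relative_amount
        od = true_od * (1.0 + rng.normal(0.0, dcfg.od_noise_sd))
        sample_rows.append(
            {"chick_id": m.chick_id, "region": m.region, "hemisphere": m.hemisphere,
             "measure": m.measure, "gel_id": gel_id, "od": od}
        )
    return pd.DataFrame(std_rows), pd.DataFrame(sample_rows)
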