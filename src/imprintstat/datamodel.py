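"""Domain types and long-format CSV I/O for imprinting experiments.

The experimental unit is the *batch*: a hatch cohort contributing up to
three trained chicks and one untrained control. From each chick four brain
samples are taken (left/right IMM, left/right PPN) and each sample yields
relative amounts of Total-Src, 416P-Src and 527P-Src, from which three
ratio measures are derived. Data travel as two tidy tables joined on
``chick_id``: a behavior table (one row per chick) and a measurement table
(one row per chick x region x hemisphere x measure).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .behavior import preference_score
from .exceptions import (
    DuplicateMeasurementError,
    ParseError,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

REGIONS = ("IMM", "PPN")
HEMISPHERES = ("left", "right")
BASE_MEASURES = ("Total", "P416", "P527")
RATIO_MEASURES = ("P416_over_Total", "P527_over_Total", "P527_over_P416")
MEASURES = BASE_MEASURES + RATIO_MEASURES
TIMEPOINTS = ("h1", "h24")

#: (numerator, denominator) defining each derived ratio measure.
RATIO_DEFINITIONS: dict[str, tuple[str, str]] = {
    "P416_over_Total": ("P416", "Total"),
    "P527_over_Total": ("P527", "Total"),
    "P527_over_P416": ("P527", "P416"),
}

#: Maximum allowed discrepancy (score units) between a stated preference
#: score and the score recomputed from the two test approaches.
SCORE_CONSISTENCY_TOL = 0.5

BEHAVIOR_COLUMNS = (
    "chick_id",
    "batch_id",
    "trained",
    "approach_training_m",
    "approach_test_train_m",
    "approach_test_alt_m",
)
MEASUREMENT_COLUMNS = ("chick_id", "region", "hemisphere", "measure", "relative_amount")


@dataclass(frozen=True)
class ChickRecord:
    """One chick: identity, training status, approaches and preference score.

    Approach fields are in metres and, like the preference score, exist
    only for trained chicks. The preference score must be consistent (to
    0.5 units) with the two test approaches when all are present.
    """

    chick_id: str
    batch_id: str
    trained: bool
    approach_training: float | None = None
    approach_test_training_stim: float | None = None
    approach_test_alternative_stim: float | None = None
    preference_score: float | None = None

    def validate(self) -> None:
        if not self.trained:
            if any(
                v is not None
                for v in (
                    self.approach_training,
                    self.approach_test_training_stim,
                    self.approach_test_alternative_stim,
                    self.preference_score,
                )
            ):
                raise ValidationError(
                    f"untrained chick {self.chick_id!r} must not carry approach "
                    "fields or a preference score"
                )
            return
        for name in ("approach_training", "approach_test_training_stim",
                     "approach_test_alternative_stim"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"chick {self.chick_id!r}: {name} is negative ({v})")
        if self.preference_score is not None:
            if not 0.0 <= self.preference_score <= 100.0:
                raise ValidationError(
                    f"chick {self.chick_id!r}: preference score "
                    f"{self.preference_score} outside [0, 100]"
                )
            a, b = self.approach_test_training_stim, self.approach_test_alternative_stim
            if a is not None and b is not None and a + b > 0:
                expected = preference_score(a, b)
                if abs(expected - self.preference_score) > SCORE_CONSISTENCY_TOL:
                    raise ValidationError(
                        f"chick {self.chick_id!r}: stated preference score "
                        f"{self.preference_score:.2f} disagrees with score "
                        f"{expected:.2f} recomputed from test approaches"
                    )


@dataclass(frozen=True)
class Measurement:
    """One relative amount for a chick x region x hemisphere x measure cell."""

    chick_id: str
    region: str
    hemisphere: str
    measure: str
    relative_amount: float
    replicate_id: str | None = None

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r} (expected one of {REGIONS})")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}")
        if not (self.relative_amount > 0 and math.isfinite(self.relative_amount)):
            raise ValidationError(
                f"chick {self.chick_id!r} {self.region}/{self.hemisphere}/{self.measure}: "
                f"relative amount must be a positive finite number, got {self.relative_amount}"
            )

    @property
    def key(self) -> tuple:
        return (self.chick_id, self.region, self.hemisphere, self.measure, self.replicate_id)


@dataclass
class ExperimentData:
    """A complete experiment: chicks, their measurements, and metadata."""

    chicks: list[ChickRecord]
    measurements: list[Measurement]
    timepoint: str = "h1"
    metadata: dict = field(default_factory=dict)

    def chick(self, chick_id: str) -> ChickRecord:
        for c in self.chicks:
            if c.chick_id == chick_id:
                return c
        raise KeyError(chick_id)

    def validate(self, *, relaxed: bool = False) -> None:
        """Check all record and cross-record invariants.

        ``relaxed`` waives the design requirement that every batch holds
        at least one trained and exactly one untrained chick.
        """
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        ids = set()
        for c in self.chicks:
            if c.chick_id in ids:
                raise ValidationError(f"duplicate chick id {c.chick_id!r}")
            ids.add(c.chick_id)
            c.validate()
        seen = set()
        for m in self.measurements:
            m.validate()
            if m.chick_id not in ids:
                raise ValidationError(f"measurement references unknown chick {m.chick_id!r}")
            if m.key in seen:
                raise DuplicateMeasurementError(
                    f"duplicate measurement for chick {m.chick_id!r} "
                    f"{m.region}/{m.hemisphere}/{m.measure}"
                )
            seen.add(m.key)
        if not relaxed:
            by_batch: dict[str, list[ChickRecord]] = {}
            for c in self.chicks:
                by_batch.setdefault(c.batch_id, []).append(c)
            for batch_id, members in by_batch.items():
                n_tr = sum(c.trained for c in members)
                n_un = len(members) - n_tr
                if n_tr < 1 or n_un != 1:
                    raise ValidationError(
                        f"batch {batch_id!r} has {n_tr} trained and {n_un} untrained "
                        "chicks; expected >=1 trained and exactly 1 untrained "
                        "(pass relaxed=True to waive)"
                    )

    def behavior_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chick_id": [c.chick_id for c in self.chicks],
                "batch_id": [c.batch_id for c in self.chicks],
                "trained": [c.trained for c in self.chicks],
                "approach_training_m": [c.approach_training for c in self.chicks],
                "approach_test_train_m": [c.approach_test_training_stim for c in self.chicks],
                "approach_test_alt_m": [c.approach_test_alternative_stim for c in self.chicks],
                "preference_score": [c.preference_score for c in self.chicks],
            }
        )

    def measurement_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chick_id": [m.chick_id for m in self.measurements],
                "region": [m.region for m in self.measurements],
                "hemisphere": [m.hemisphere for m in self.measurements],
                "measure": [m.measure for m in self.measurements],
                "relative_amount": [m.relative_amount for m in self.measurements],
                "replicate_id": [m.replicate_id for m in self.measurements],
            }
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _read_table(path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter if delimiter is not None else None  # None => sniff
    return pd.read_csv(path, sep=sep, engine="python", encoding="utf-8")


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def _parse_float(value, *, row: int, column: str, allow_missing: bool = True) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if allow_missing:
            return None
        raise ParseError(f"row {row}: missing value in column {column!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row}: could not parse {value!r} in column {column!r} as a number"
        ) from None


_TRUE = {"1", "true", "yes", "t", "trained"}
_FALSE = {"0", "false", "no", "f", "untrained"}


def _parse_bool(value, *, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"row {row}: could not parse {value!r} in column {column!r} as a flag")


def load_experiment(
    behavior_path,
    measurements_path,
    *,
    timepoint: str = "h1",
    delimiter: str | None = None,
    relaxed: bool = False,
    metadata: dict | None = None,
) -> ExperimentData:
    """Load and validate an experiment from its behavior and measurement CSVs.

    Ratio measures must not appear in the file — they are derived by
    :func:`derive_ratio_measures`. A stated preference score is checked
    against the score recomputed from the two test approaches (0.5-unit
    tolerance); if absent it is derived from the approaches.
    """
    bdf = _read_table(behavior_path, delimiter)
    _require_columns(bdf, BEHAVIOR_COLUMNS[:3], "behavior")
    chicks = []
    for i, row in enumerate(bdf.to_dict("records"), start=2):  # header is line 1
        trained = _parse_bool(row["trained"], row=i, column="trained")
        get = lambda col: _parse_float(row.get(col), row=i, column=col)
        score = get("preference_score") if "preference_score" in bdf.columns else None
        a_tr = get("approach_test_train_m") if "approach_test_train_m" in bdf.columns else None
        a_alt = get("approach_test_alt_m") if "approach_test_alt_m" in bdf.columns else None
        if trained and score is None and a_tr is not None and a_alt is not None and a_tr + a_alt > 0:
            score = preference_score(a_tr, a_alt)
        chicks.append(
            ChickRecord(
                chick_id=str(row["chick_id"]),
                batch_id=str(row["batch_id"]),
                trained=trained,
                approach_training=(
                    get("approach_training_m") if "approach_training_m" in bdf.columns else None
                ),
                approach_test_training_stim=a_tr,
                approach_test_alternative_stim=a_alt,
                preference_score=score,
            )
        )
    mdf = _read_table(measurements_path, delimiter)
    _require_columns(mdf, MEASUREMENT_COLUMNS, "measurement")
    measurements = []
    for i, row in enumerate(mdf.to_dict("records"), start=2):
        measure = str(row["measure"])
        if measure in RATIO_MEASURES:
            raise ValidationError(
                f"row {i}: ratio measure {measure!r} must be derived, not read from file"
            )
        amount = _parse_float(
            row["relative_amount"], row=i, column="relative_amount", allow_missing=False
        )
        rep = row.get("replicate_id")
        measurements.append(
            Measurement(
                chick_id=str(row["chick_id"]),
                region=str(row["region"]),
                hemisphere=str(row["hemisphere"]),
                measure=measure,
                relative_amount=amount,
                replicate_id=None if rep is None or pd.isna(rep) else str(rep),
            )
        )
    data = ExperimentData(
        chicks=chicks,
        measurements=measurements,
        timepoint=timepoint,
        metadata=metadata or {},
    )
    data.validate(relaxed=relaxed)
    return data


def write_experiment(data: ExperimentData, behavior_path, measurements_path) -> None:
    """Write an experiment back to its two CSV tables (full float precision)."""
    data.behavior_frame().to_csv(behavior_path, index=False, float_format="%.17g")
    mf = data.measurement_frame()
    # Ratio rows are derived on load; never persist them.
    mf = mf[~mf["measure"].isin(RATIO_MEASURES)]
    mf.to_csv(measurements_path, index=False, float_format="%.17g")


def derive_ratio_measures(data: ExperimentData) -> ExperimentData:
    """Append the three ratio measures where all components are present.

    For each chick x region x hemisphere cell holding Total, P416 and
    P527, adds 416P/Total, 527P/Total and 527P/416P rows. Cells missing a
    component (or with a zero denominator) get no ratio row and are
    logged. Idempotent: existing ratio rows are never duplicated.
    """
    by_cell: dict[tuple, dict[str, float]] = {}
    existing = set()
    for m in data.measurements:
        cell = (m.chick_id, m.region, m.hemisphere)
        if m.measure in BASE_MEASURES and m.replicate_id is None:
            by_cell.setdefault(cell, {})[m.measure] = m.relative_amount
        if m.measure in RATIO_MEASURES:
            existing.add(cell + (m.measure,))
    new_rows = []
    for cell, comps in sorted(by_cell.items()):
        # all three components must be present before any ratio is derived
        if set(comps) < set(BASE_MEASURES):
            missing = sorted(set(BASE_MEASURES) - set(comps))
            log.info("cell %s: missing %s; no ratio rows derived", cell, missing)
            continue
        for ratio, (num, den) in RATIO_DEFINITIONS.items():
            if cell + (ratio,) in existing:
                continue
            if comps[den] == 0:
                log.warning("cell %s: zero denominator for %s; ratio skipped", cell, ratio)
                continue
            new_rows.append(
                Measurement(
                    chick_id=cell[0],
                    region=cell[1],
                    hemisphere=cell[2],
                    measure=ratio,
                    relative_amount=comps[num] / comps[den],
                )
            )
    return replace(data, measurements=list(data.measurements) + new_rows)
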