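"""Standard-curve calibration of immunoblot densitometry.

Each autoradiograph carries four calibration standards (15, 30, 45 and
60 µg of total protein). Band optical density (OD) is linear in loaded
protein over this range, so an ordinary least-squares line of OD on µg is
fitted per gel. The OD that the fitted line assigns to 30 µg defines one
unit: a sample band's *relative amount of protein* is its OD divided by
the line's value at 30 µg. This cancels the overall gain of the gel /
film / scanner chain, making relative amounts comparable across gels —
multiplying every OD on a gel by any positive constant leaves them
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError, SchemaError

log = logging.getLogger(__name__)

#: Loaded protein (µg) defining one relative-amount unit.
REFERENCE_MICROGRAMS = 30.0

#: The four standard loads applied to every gel.
STANDARD_MICROGRAMS = (15.0, 30.0, 45.0, 60.0)

#: Default QC gate on the standard-curve fit.
DEFAULT_LINEARITY_THRESHOLD = 0.95


class StandardPoint(NamedTuple):
    """One calibration standard: protein load (µg) and its band OD."""

    protein_amount: float
    optical_density: float


@dataclass(frozen=True)
class GelCalibration:
    """Fitted standard line for one autoradiograph.

    ``od_at_30`` is the line evaluated at 30 µg (not the raw 30 µg band)
    and defines one relative-amount unit for every sample on the gel.
    """

    gel_id: str
    points: tuple[StandardPoint, ...]
    slope: float
    intercept: float
    od_at_30: float
    r_squared: float


def fit_calibration(
    points: Sequence[StandardPoint],
    gel_id: str = "",
    *,
    through_origin: bool = False,
) -> GelCalibration:
    """Least-squares line of optical density on µg protein for one gel.

    Parameters
    ----------
    points
        At least two standards with distinct protein amounts.
    through_origin
        Force a zero intercept. Off by default: only linearity, not
        proportionality, is assumed of the film response.

    Raises
    ------
    CalibrationError
        Fewer than two distinct amounts, or a fitted value at 30 µg that
        is not positive (the unit would be degenerate).
    """
    pts = tuple(StandardPoint(float(a), float(o)) for a, o in points)
    amounts = np.array([p.protein_amount for p in pts])
    ods = np.array([p.optical_density for p in pts])
    if len(pts) < 2 or np.unique(amounts).size < 2:
        raise CalibrationError(
            f"gel {gel_id!r}: need >=2 standards with distinct amounts, got {len(pts)}"
        )
    if through_origin:
        slope = float(amounts @ ods / (amounts @ amounts))
        intercept = 0.0
        fitted = slope * amounts
    else:
        # Constant OD across standards: slope 0, r^2 defined as 0.
        if np.ptp(ods) == 0:
            slope, intercept = 0.0, float(ods[0])
            fitted = np.full_like(ods, intercept)
        else:
            res = stats.linregress(amounts, ods)
            slope, intercept = float(res.slope), float(res.intercept)
            fitted = intercept + slope * amounts
    ss_tot = float(np.sum((ods - ods.mean()) ** 2))
    ss_res = float(np.sum((ods - fitted) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    od_at_30 = intercept + slope * REFERENCE_MICROGRAMS
    if od_at_30 <= 0:
        raise CalibrationError(
            f"gel {gel_id!r}: fitted OD at {REFERENCE_MICROGRAMS:g} ug is "
            f"{od_at_30:.4g} <= 0; calibration degenerate"
        )
    return GelCalibration(
        gel_id=gel_id,
        points=pts,
        slope=slope,
        intercept=intercept,
        od_at_30=float(od_at_30),
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
    )


def relative_amount(od: float, cal: GelCalibration) -> float:
    """Convert a band OD to a relative amount of protein: ``od / od_at_30``."""
    if od < 0:
        raise ValueError(f"optical density must be nonnegative, got {od}")
    return float(od) / cal.od_at_30


def calibration_linearity(
    cal: GelCalibration, threshold: float = DEFAULT_LINEARITY_THRESHOLD
) -> tuple[bool, float]:
    """QC gate: does the standard curve fit a straight line well enough?

    Returns ``(passed, r_squared)``; failing gels should be excluded from
    analysis (the pipeline logs and drops them).
    """
    passed = cal.r_squared >= threshold
    if not passed:
        log.warning(
            "gel %r fails linearity QC: r^2 = %.4f < %.3f", cal.gel_id, cal.r_squared, threshold
        )
    return passed, cal.r_squared


def calibrations_from_table(
    standards: pd.DataFrame, *, through_origin: bool = False
) -> dict[str, GelCalibration]:
    """Fit one calibration per gel from a standards table.

    ``standards`` needs columns ``gel_id``, ``micrograms``, ``od``.
    """
    for col in ("gel_id", "micrograms", "od"):
        if col not in standards.columns:
            raise SchemaError(f"standards table missing column {col!r}")
    out = {}
    for gel_id, grp in standards.groupby("gel_id", sort=False):
        pts = [StandardPoint(a, o) for a, o in zip(grp["micrograms"], grp["od"])]
        out[str(gel_id)] = fit_calibration(pts, str(gel_id), through_origin=through_origin)
    return out


def relative_amounts_from_od(
    samples: pd.DataFrame,
    standards: pd.DataFrame,
    *,
    through_origin: bool = False,
    linearity_threshold: float | None = DEFAULT_LINEARITY_THRESHOLD,
) -> pd.DataFrame:
    """Normalize sample band ODs into relative amounts, gel by gel.

    ``samples`` needs columns ``gel_id`` and ``od``; all other columns are
    carried through. Gels failing the linearity QC (when a threshold is
    given) are dropped with a log message. Returns a copy of ``samples``
    with a ``relative_amount`` column, restricted to passing gels.
    """
    cals = calibrations_from_table(standards, through_origin=through_origin)
    if "gel_id" not in samples.columns or "od" not in samples.columns:
        raise SchemaError("samples table must have columns 'gel_id' and 'od'")
    keep = []
    for gel_id, cal in cals.items():
        if linearity_threshold is not None:
            passed, _ = calibration_linearity(cal, linearity_threshold)
            if not passed:
                log.warning("dropping all samples from gel %r (failed linearity QC)", gel_id)
                continue
        keep.append(gel_id)
    out = samples[samples["gel_id"].astype(str).isin(keep)].copy()
    od_at_30 = out["gel_id"].astype(str).map({g: cals[g].od_at_30 for g in keep})
    out["relative_amount"] = out["od"].astype(float) / od_at_30
    return out
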