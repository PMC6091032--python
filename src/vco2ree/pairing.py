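"""Pair indirect-calorimetry measurements with ventilator VCO2 block means.

Each IC measurement at time ``t`` is matched to the arithmetic mean of the
ventilator VCO2 records in the half-open window ``[t - window, t)`` — the
six hours *preceding* the assessment, with the assessment instant itself
excluded so a record stamped at ``t`` is never double-used.  A window is
only accepted when its record coverage (records present / records expected
at the trace's nominal step) reaches ``min_coverage``; under-covered
measurements are excluded and counted, never silently filled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weir import DEFAULT_COEFFICIENTS, RQGrid, WeirCoefficients, ree_from_vco2, ree_weir

__all__ = [
    "DEFAULT_WINDOW_MINUTES",
    "DEFAULT_MIN_COVERAGE",
    "PairedDataset",
    "block_mean_vco2",
    "build_paired_dataset",
    "rq_column",
    "read_paired_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MINUTES = 360.0
DEFAULT_MIN_COVERAGE = 0.8

#: Column schema of the paired analysis table / paired.csv.
BASE_COLUMNS = ["patient_id", "time_min", "ree_ic", "block_vco2", "coverage"]


def rq_column(rq: float) -> str:
    """Column name holding the VCO2-only estimate at a grid RQ."""
    return f"ree_vco2_rq{rq:.2f}"


@dataclass
class PairedDataset:
    """Matched (reference REE, ventilator block VCO2, estimates) rows.

    ``frame`` holds one row per retained IC measurement, sorted by
    patient_id then time, with columns ``patient_id, time_min, ree_ic,
    block_vco2, coverage`` plus one ``ree_vco2_rq*`` column per grid RQ.
    """

    frame: pd.DataFrame
    rq_grid: RQGrid = field(default_factory=RQGrid)
    window_minutes: float = DEFAULT_WINDOW_MINUTES
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.window_minutes <= 0:
            raise ValueError("window_minutes must be positive")
        missing = [c for c in BASE_COLUMNS if c not in self.frame.columns]
        missing += [c for rq in self.rq_grid if (c := rq_column(rq)) not in self.frame.columns]
        if missing:
            raise ValueError(f"paired frame is missing columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def ree_vco2(self, rq: float) -> np.ndarray:
        """Estimate column (kcal/day) for one grid RQ."""
        return self.frame[rq_column(rq)].to_numpy()

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _infer_step(times: np.ndarray) -> float:
    if times.size < 2:
        raise ValueError("cannot infer trace step from fewer than 2 records")
    return float(np.median(np.diff(times)))


def block_mean_vco2(
    times,
    vco2,
    t: float,
    window: float = DEFAULT_WINDOW_MINUTES,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    step: float | None = None,
) -> tuple[float, float]:
    """Mean ventilator VCO2 over the half-open window ``[t - window, t)``.

    Parameters
    ----------
    times, vco2 : array-like
        One patient's trace: timestamps (minutes, strictly increasing) and
        VCO2 records (mL/min).
    t : float
        IC measurement time (minutes).
    step : float, optional
        Nominal record spacing in minutes; inferred from the median
        timestamp difference when omitted.

    Returns
    -------
    (mean, coverage)
        ``mean`` is NaN when coverage < ``min_coverage`` (including an empty
        window); ``coverage`` = records present / records expected
        (= window/step), capped at 1.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 <= min_coverage <= 1:
        raise ValueError("min_coverage must lie in [0, 1]")
    times = np.asarray(times, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if times.shape != vco2.shape:
        raise ValueError("times and vco2 must have equal length")
    if step is None:
        step = _infer_step(times)
    lo = np.searchsorted(times, t - window, side="left")
    hi = np.searchsorted(times, t, side="left")
    n_present = hi - lo
    n_expected = window / step
    coverage = min(1.0, n_present / n_expected)
    if n_present == 0 or coverage < min_coverage:
        return float("nan"), coverage
    return float(vco2[lo:hi].mean()), coverage


def build_paired_dataset(
    ic: pd.DataFrame,
    traces: pd.DataFrame,
    rq_grid: RQGrid = RQGrid(),
    window: float = DEFAULT_WINDOW_MINUTES,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    coeffs: WeirCoefficients = DEFAULT_COEFFICIENTS,
) -> PairedDataset:
    """Build the analysis dataset from IC measurements and ventilator traces.

    Parameters
    ----------
    ic : DataFrame
        Columns ``patient_id, time_min, vo2_ml_min, vco2_ml_min`` (the
        ic_measurements.csv schema).
    traces : DataFrame
        Columns ``patient_id, time_min, vco2_ml_min`` (the vent_trace.csv
        schema); per-patient timestamps strictly increasing (ties keep the
        first occurrence).

    Notes
    -----
    The reference REE is computed by the Weir equation on the IC gases; the
    estimates apply the fixed-RQ estimator to the block-mean VCO2 for every
    grid RQ.  Measurements without a trace, or whose window coverage is
    below ``min_coverage``, are excluded with a logged count.
    """
    for col in ("patient_id", "time_min", "vo2_ml_min", "vco2_ml_min"):
        if col not in ic.columns:
            raise ValueError(f"ic table is missing column {col!r}")
    for col in ("patient_id", "time_min", "vco2_ml_min"):
        if col not in traces.columns:
            raise ValueError(f"trace table is missing column {col!r}")

    trace_groups: dict = {}
    for pid, g in traces.groupby("patient_id", sort=False):
        g = g.drop_duplicates(subset="time_min", keep="first").sort_values("time_min")
        trace_groups[pid] = (
            g["time_min"].to_numpy(dtype=float),
            g["vco2_ml_min"].to_numpy(dtype=float),
        )

    ic = ic.sort_values(["patient_id", "time_min"], kind="mergesort")
    rows = []
    n_no_trace = 0
    n_low_coverage = 0
    for rec in ic.itertuples(index=False):
        pair = trace_groups.get(rec.patient_id)
        if pair is None:
            n_no_trace += 1
            continue
        mean, coverage = block_mean_vco2(
            pair[0], pair[1], rec.time_min, window=window, min_coverage=min_coverage
        )
        if math.isnan(mean):
            n_low_coverage += 1
            continue
        row = {
            "patient_id": rec.patient_id,
            "time_min": rec.time_min,
            "ree_ic": ree_weir(rec.vo2_ml_min, rec.vco2_ml_min, coeffs),
            "block_vco2": mean,
            "coverage": coverage,
        }
        for rq in rq_grid:
            row[rq_column(rq)] = ree_from_vco2(mean, rq, coeffs)
        rows.append(row)

    if n_no_trace:
        logger.warning("excluded %d IC measurements with no ventilator trace", n_no_trace)
    if n_low_coverage:
        logger.warning(
            "excluded %d IC measurements with window coverage < %.2f",
            n_low_coverage,
            min_coverage,
        )
    if not rows:
        raise ValueError("no IC measurement survived pairing; nothing to analyse")
    frame = pd.DataFrame(rows).reset_index(drop=True)
    return PairedDataset(
        frame=frame,
        rq_grid=rq_grid,
        window_minutes=window,
        n_excluded=n_no_trace + n_low_coverage,
    )


def read_paired_csv(path, rq_grid: RQGrid = RQGrid(), window: float = DEFAULT_WINDOW_MINUTES) -> PairedDataset:
    """Load a paired.csv written by :meth:`PairedDataset.write_csv`."""
    return PairedDataset(frame=pd.read_csv(path), rq_grid=rq_grid, window_minutes=window)
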