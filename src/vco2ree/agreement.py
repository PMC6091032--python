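"""Method-comparison statistics for paired REE estimates.

Implements the full agreement battery used to compare a VCO2-only REE
estimate against the indirect-calorimetry reference: bias and SD of paired
differences, percentage error/difference, Pearson correlation with Fisher-z
CI, Lin's concordance correlation coefficient with bootstrap or asymptotic
CI, ratio-band agreement rates (85–115% and the tight 95–105% band), and
Bland–Altman limits of agreement.

Percentage "error" and "difference" lack a universal definition in the
method-comparison literature, so both are exposed as explicit modes (see
:class:`PctMode`); defaults are mean absolute deviation relative to the
reference and relative to the pair mean, respectively.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PctMode",
    "AgreementSummary",
    "BlandAltmanResult",
    "bias_and_sd",
    "ratio_band_agreement",
    "lin_ccc",
    "pearson_with_ci",
    "percentage_metrics",
    "bland_altman",
    "summarize_agreement",
    "performance_table",
    "performance_frame",
]

DEFAULT_BANDS: tuple[tuple[float, float], tuple[float, float]] = (
    (0.85, 1.15),
    (0.95, 1.05),
)


class PctMode(str, enum.Enum):
    """Definitions selectable for the percentage metrics.

    - ``rel_ref``: mean(|est - ref| / ref)
    - ``rel_pair_mean``: mean(|est - ref| / ((est + ref)/2))
    - ``critchley``: 1.96 * SD(est - ref) / mean(ref)  (Critchley & Critchley
      percentage-error criterion for cardiac-output comparisons)
    """

    REL_REF = "rel_ref"
    REL_PAIR_MEAN = "rel_pair_mean"
    CRITCHLEY = "critchley"


@dataclass(frozen=True)
class AgreementSummary:
    """One row of the performance table: the eight agreement metrics for a
    single fixed-RQ (or formula-based) estimator against the reference.

    ``pct_error``, ``pct_difference``, ``agreement`` and ``tight_agreement``
    are fractions (0.24 means 24%); differences are kcal/day,
    estimate minus reference.
    """

    rq: float | None
    n: int
    mean_difference: float
    sd_difference: float
    pct_error: float
    pct_difference: float
    pearson_r: float
    pearson_ci: tuple[float, float]
    ccc: float
    ccc_ci: tuple[float, float]
    agreement: float
    tight_agreement: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement with the per-pair points."""

    bias: float
    loa_low: float
    loa_high: float
    points: np.ndarray = field(repr=False)  # shape (n, 2): (pair mean, difference)


def _paired_arrays(est, ref, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(est, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if est.shape != ref.shape:
        raise ValueError(
            f"est and ref must have equal length, got {est.size} and {ref.size}"
        )
    if est.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {est.size}")
    return est, ref


def bias_and_sd(est, ref) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of the paired differences
    est - ref."""
    est, ref = _paired_arrays(est, ref)
    diff = est - ref
    return float(diff.mean()), float(diff.std(ddof=1))


def ratio_band_agreement(est, ref, low: float, high: float) -> float:
    """Fraction of pairs with est/ref inside the closed interval
    [low, high]."""
    if not low < high:
        raise ValueError(f"band must satisfy low < high, got ({low}, {high})")
    est, ref = _paired_arrays(est, ref, min_n=1)
    if np.any(ref <= 0):
        raise ValueError("reference values must all be positive for ratio bands")
    ratio = est / ref
    return float(np.mean((ratio >= low) & (ratio <= high)))


def _is_constant(x: np.ndarray) -> bool:
    return bool(np.all(x == x[0]))


def _ccc_point(est: np.ndarray, ref: np.ndarray) -> float:
    # population (n-denominator) moments, per Lin's original definition
    sx = est.var()
    sy = ref.var()
    sxy = ((est - est.mean()) * (ref - ref.mean())).mean()
    return float(2.0 * sxy / (sx + sy + (est.mean() - ref.mean()) ** 2))


def lin_ccc(
    est,
    ref,
    ci_method: str | None = "bootstrap",
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with 95% CI.

    CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), the Pearson
    correlation damped by the distance of the best-fit line from the
    identity line.

    ``ci_method`` is ``"bootstrap"`` (nonparametric percentile, ``n_boot``
    resamples), ``"fisher"`` (Lin's 1989 asymptotic variance on the z scale)
    or ``None`` (point estimate only; CI returned as NaN).
    """
    est, ref = _paired_arrays(est, ref, min_n=3)
    if _is_constant(est):
        raise ValueError("est has zero variance; CCC undefined")
    if _is_constant(ref):
        raise ValueError("ref has zero variance; CCC undefined")
    ccc = _ccc_point(est, ref)
    if ci_method is None:
        return ccc, float("nan"), float("nan")
    n = est.size
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        be, br = est[idx], ref[idx]
        me, mr = be.mean(axis=1), br.mean(axis=1)
        sx = be.var(axis=1)
        sy = br.var(axis=1)
        sxy = ((be - me[:, None]) * (br - mr[:, None])).mean(axis=1)
        denom = sx + sy + (me - mr) ** 2
        ok = denom > 0
        reps = 2.0 * sxy[ok] / denom[ok]
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return ccc, float(lo), float(hi)
    if ci_method == "fisher":
        if abs(ccc) == 1.0:
            return ccc, ccc, ccc
        r = float(np.corrcoef(est, ref)[0, 1])
        u = (est.mean() - ref.mean()) / np.sqrt(est.std() * ref.std())
        z = np.arctanh(ccc)
        var_z = (
            (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
            + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
            - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)
        ) / (n - 2)
        half = 1.959963984540054 * np.sqrt(var_z)
        return ccc, float(np.tanh(z - half)), float(np.tanh(z + half))
    raise ValueError(f"unknown ci_method {ci_method!r}")


def pearson_with_ci(est, ref) -> tuple[float, float, float]:
    """Pearson correlation with 95% Fisher-z confidence interval."""
    est, ref = _paired_arrays(est, ref, min_n=4)
    if _is_constant(est) or _is_constant(ref):
        raise ValueError("zero variance input; correlation undefined")
    r = float(stats.pearsonr(est, ref).statistic)
    if abs(r) == 1.0:  # Fisher z degenerates; the CI collapses to {r}
        return r, r, r
    z = np.arctanh(r)
    half = 1.959963984540054 / np.sqrt(est.size - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def percentage_metrics(
    est,
    ref,
    error_mode: PctMode | str = PctMode.REL_REF,
    difference_mode: PctMode | str = PctMode.REL_PAIR_MEAN,
) -> tuple[float, float]:
    """Percentage error and percentage difference as fractions."""
    est, ref = _paired_arrays(est, ref, min_n=1)
    if np.any(ref <= 0):
        raise ValueError("reference values must all be positive")

    def one(mode: PctMode | str) -> float:
        mode = PctMode(mode)
        if mode is PctMode.REL_REF:
            return float(np.mean(np.abs(est - ref) / ref))
        if mode is PctMode.REL_PAIR_MEAN:
            return float(np.mean(np.abs(est - ref) / ((est + ref) / 2.0)))
        # Critchley: half-width of the limits of agreement over the mean
        # reference, needs n >= 2 for the SD
        if est.size < 2:
            raise ValueError("critchley mode needs at least 2 pairs")
        return float(1.96 * (est - ref).std(ddof=1) / ref.mean())

    return one(error_mode), one(difference_mode)


def bland_altman(est, ref) -> BlandAltmanResult:
    """Bland–Altman analysis: per-pair (mean, difference) points, bias and
    1.96-SD limits of agreement."""
    est, ref = _paired_arrays(est, ref)
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    points = np.column_stack(((est + ref) / 2.0, diff))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, points=points
    )


def summarize_agreement(
    est,
    ref,
    rq: float | None = None,
    bands=DEFAULT_BANDS,
    error_mode: PctMode | str = PctMode.REL_REF,
    difference_mode: PctMode | str = PctMode.REL_PAIR_MEAN,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> AgreementSummary:
    """Run the full battery for one estimator column against the reference."""
    est, ref = _paired_arrays(est, ref)
    (band, tight_band) = bands
    md, sd = bias_and_sd(est, ref)
    pe, pdiff = percentage_metrics(est, ref, error_mode, difference_mode)
    if _is_constant(est) or _is_constant(ref):
        # a constant estimate (e.g. a degenerate formula) still has a
        # well-defined bias and band agreement; correlations do not exist
        nan = float("nan")
        r = r_lo = r_hi = ccc = c_lo = c_hi = nan
    else:
        r, r_lo, r_hi = pearson_with_ci(est, ref)
        ccc, c_lo, c_hi = lin_ccc(est, ref, ci_method=ci_method, n_boot=n_boot, seed=seed)
    return AgreementSummary(
        rq=rq,
        n=int(est.size),
        mean_difference=md,
        sd_difference=sd,
        pct_error=pe,
        pct_difference=pdiff,
        pearson_r=r,
        pearson_ci=(r_lo, r_hi),
        ccc=ccc,
        ccc_ci=(c_lo, c_hi),
        agreement=ratio_band_agreement(est, ref, *band),
        tight_agreement=ratio_band_agreement(est, ref, *tight_band),
    )


def performance_table(
    ds,
    bands=DEFAULT_BANDS,
    error_mode: PctMode | str = PctMode.REL_REF,
    difference_mode: PctMode | str = PctMode.REL_PAIR_MEAN,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> list[AgreementSummary]:
    """One :class:`AgreementSummary` per RQ in the paired dataset's grid,
    ordered as the grid (ascending RQ).

    Each CCC bootstrap uses an independent child stream of ``seed`` so that
    adding an RQ column never perturbs the others.
    """
    if len(ds.frame) == 0:
        raise ValueError("paired dataset is empty")
    ref = ds.frame["ree_ic"].to_numpy()
    out = []
    children = np.random.SeedSequence(seed).spawn(len(ds.rq_grid))
    for rq, child in zip(ds.rq_grid, children):
        est = ds.ree_vco2(rq)
        out.append(
            summarize_agreement(
                est,
                ref,
                rq=rq,
                bands=bands,
                error_mode=error_mode,
                difference_mode=difference_mode,
                ci_method=ci_method,
                n_boot=n_boot,
                seed=np.random.default_rng(child),
            )
        )
    return out


def performance_frame(summaries: list[AgreementSummary]) -> pd.DataFrame:
    """Flatten summaries into the writable performance-table DataFrame."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "rq": s.rq,
                "n": s.n,
                "mean_difference": s.mean_difference,
                "sd_difference": s.sd_difference,
                "pct_error": s.pct_error,
                "pct_difference": s.pct_difference,
                "pearson_r": s.pearson_r,
                "pearson_ci_low": s.pearson_ci[0],
                "pearson_ci_high": s.pearson_ci[1],
                "ccc": s.ccc,
                "ccc_ci_low": s.ccc_ci[0],
                "ccc_ci_high": s.ccc_ci[1],
                "agreement": s.agreement,
                "tight_agreement": s.tight_agreement,
            }
        )
    return pd.DataFrame(rows)
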