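"""Report assembly: performance table, Bland–Altman summaries, calibration.

Renders a markdown report whose every number is re-derivable from the CSV
artifacts written alongside it.  The performance table is printed with RQ
rows in descending order (0.89 first), kcal quantities to 2 decimals and
fractions to 2 decimals.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import AgreementSummary, BlandAltmanResult, bland_altman, performance_frame
from .calibration import CalibrationResult

__all__ = [
    "bland_altman_by_rq",
    "bland_altman_frame",
    "write_performance_csv",
    "calibration_to_dict",
    "write_calibration_json",
    "render_report",
    "plot_bland_altman",
    "plot_scatter",
]


def bland_altman_by_rq(ds) -> dict[float, BlandAltmanResult]:
    """Bland–Altman analysis of each grid-RQ estimator against the
    reference."""
    ref = ds.frame["ree_ic"].to_numpy()
    return {rq: bland_altman(ds.ree_vco2(rq), ref) for rq in ds.rq_grid}


def bland_altman_frame(results: dict[float, BlandAltmanResult]) -> pd.DataFrame:
    """Long-format (rq, pair_mean, difference) points for plotting."""
    parts = []
    for rq, res in results.items():
        parts.append(
            pd.DataFrame(
                {"rq": rq, "pair_mean": res.points[:, 0], "difference": res.points[:, 1]}
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_performance_csv(summaries: list[AgreementSummary], ds, path) -> pd.DataFrame:
    """performance_table.csv: the agreement battery per RQ plus coverage
    diagnostics of the paired dataset."""
    frame = performance_frame(summaries)
    frame["mean_coverage"] = float(ds.frame["coverage"].mean())
    frame["n_excluded"] = ds.n_excluded
    frame.to_csv(path, index=False)
    return frame


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def calibration_to_dict(calib: CalibrationResult) -> dict:
    d = {
        "intercept": calib.intercept,
        "slope": calib.slope,
        "lambda": calib.penalty,
        "r2": calib.r2,
        "n": calib.n,
        "simplified": {"intercept": calib.simplified.intercept, "slope": calib.simplified.slope},
        "evaluation": asdict(calib.evaluation) if calib.evaluation is not None else None,
    }
    return _json_safe(d)


def write_calibration_json(calib: CalibrationResult, path) -> None:
    Path(path).write_text(json.dumps(calibration_to_dict(calib), indent=2) + "\n")


def _fmt_frac(x: float) -> str:
    return "nan" if not math.isfinite(x) else f"{x:.2f}"


def _fmt_kcal(x: float) -> str:
    return f"{x:.2f}"


def _summary_row(s: AgreementSummary, label: str) -> str:
    cells = [
        label,
        _fmt_kcal(s.mean_difference),
        _fmt_kcal(s.sd_difference),
        _fmt_frac(s.pct_error),
        _fmt_frac(s.pct_difference),
        f"{_fmt_frac(s.pearson_r)} ({_fmt_frac(s.pearson_ci[0])}–{_fmt_frac(s.pearson_ci[1])})",
        f"{_fmt_frac(s.ccc)} ({_fmt_frac(s.ccc_ci[0])}–{_fmt_frac(s.ccc_ci[1])})",
        _fmt_frac(s.agreement),
        _fmt_frac(s.tight_agreement),
    ]
    return "| " + " | ".join(cells) + " |"


def render_report(
    summaries: list[AgreementSummary],
    ba: dict[float, BlandAltmanResult],
    calib: CalibrationResult | None,
    ds,
) -> str:
    """Assemble report.md from already-computed artifacts."""
    n = len(ds)
    lines = [
        "# VCO2-only REE validation report",
        "",
        f"Paired observations: {n} (excluded during pairing: {ds.n_excluded}; "
        f"mean window coverage {ds.frame['coverage'].mean():.3f})",
        "",
        "## Fixed-RQ estimator performance",
        "",
        "Differences are estimate − reference, kcal/day; percentage metrics and",
        "agreement rates are fractions. Agreement band 85–115% of the reference,",
        "tight band 95–105%.",
        "",
        "| Estimator | Mean difference | SD | % Error | % Difference | Correlation | "
        "Concordance | Agreement | Tight agreement |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for s in sorted(summaries, key=lambda s: -(s.rq if s.rq is not None else -1)):
        lines.append(_summary_row(s, f"VCO2 with {s.rq:.2f} RQ"))
    lines += ["", "## Bland–Altman", ""]
    lines.append("| RQ | Bias (kcal/d) | LoA low | LoA high | n |")
    lines.append("|---|---|---|---|---|")
    for rq in sorted(ba, reverse=True):
        r = ba[rq]
        lines.append(
            f"| {rq:.2f} | {_fmt_kcal(r.bias)} | {_fmt_kcal(r.loa_low)} | "
            f"{_fmt_kcal(r.loa_high)} | {len(r.points)} |"
        )
    lines += [
        "",
        "Per-pair (mean, difference) points are in bland_altman.csv; the scatter",
        "of estimate against reference can be rebuilt from paired.csv.",
    ]
    if calib is not None:
        lines += [
            "",
            "## Calibration (ridge regression of REE on VCO2)",
            "",
            f"- fitted line: REE = {calib.intercept:.2f} + {calib.slope:.4f} * VCO2 "
            f"(n = {calib.n}, lambda = {calib.penalty:.4g}, in-sample R² = {calib.r2:.2f})",
            f"- simplified formula: {calib.simplified}",
        ]
        if calib.evaluation is not None:
            lines += [
                "",
                "Simplified-formula performance on the ventilator pairs:",
                "",
                "| Estimator | Mean difference | SD | % Error | % Difference | Correlation | "
                "Concordance | Agreement | Tight agreement |",
                "|---|---|---|---|---|---|---|---|---|",
                _summary_row(calib.evaluation, str(calib.simplified)),
            ]
    lines.append("")
    return "\n".join(lines)


def plot_bland_altman(res: BlandAltmanResult, path, title: str = "Bland–Altman") -> None:
    """Scatter of paired differences against pair means with bias and LoA
    lines (written to ``path``; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(res.points[:, 0], res.points[:, 1], s=8, alpha=0.5)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of estimate and reference (kcal/d)")
    ax.set_ylabel("Estimate − reference (kcal/d)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(est, ref, path, title: str = "Estimate vs reference") -> None:
    """Estimate-versus-reference scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(ref, est, s=8, alpha=0.5)
    lo = min(ref.min(), est.min())
    hi = max(ref.max(), est.max())
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=1)
    ax.set_xlabel("Reference REE (kcal/d)")
    ax.set_ylabel("Estimated REE (kcal/d)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
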