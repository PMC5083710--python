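"""Per-well and per-condition summaries of phenotype predictions.

Aggregates per-cell class assignments, resting intensities and
morphometrics into the screening deliverables: phenotype fractions per
well, replicate-averaged condition tables (mean ± SD of fractions, RFU
and elongation), and the dose-response table of class fractions versus
ATP concentration with a monotonicity report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import PhenotypeClass, WellSpec

__all__ = [
    "Condition",
    "WellSummary",
    "ConditionSummary",
    "class_fractions",
    "aggregate_condition",
    "dose_response_table",
    "plot_dose_response",
]

_FRACTION_METRICS = ("fraction_osc_peak", "fraction_peak", "fraction_other")
_METRICS = (*_FRACTION_METRICS, "mean_rfu", "mean_elongation")


@dataclass(frozen=True)
class Condition:
    """An experimental condition: ATP dose plus optional drug."""

    atp_um: float
    drug: str = "none"
    drug_um: float = 0.0

    @classmethod
    def of(cls, spec: WellSpec) -> "Condition":
        return cls(spec.atp_um, spec.drug, spec.drug_um)


@dataclass
class WellSummary:
    """Per-well deliverables: phenotype fractions, resting RFU,
    elongation and cell count. Fractions are NaN for an empty well."""

    well_id: str
    condition: Condition
    n_cells: int
    fraction_osc_peak: float
    fraction_peak: float
    fraction_other: float
    mean_rfu: float = float("nan")
    mean_elongation: float = float("nan")


def class_fractions(
    predictions: Sequence,
    well_id: str,
    condition: Condition | None = None,
    *,
    rfu: Sequence[float] | None = None,
    elongation: Sequence[float] | None = None,
) -> WellSummary:
    """Phenotype fractions of one well from per-cell predictions.

    ``predictions`` holds one class per cell (PhenotypeClass or its
    string value). The three fractions sum to 1 for a non-empty well;
    an empty well yields n_cells 0 and NaN fractions.
    """
    labels = [p.value if isinstance(p, PhenotypeClass) else str(p) for p in predictions]
    n = len(labels)
    if n == 0:
        f = (float("nan"),) * 3
    else:
        f = tuple(
            labels.count(c.value) / n
            for c in (PhenotypeClass.OSC_PEAK, PhenotypeClass.PEAK, PhenotypeClass.OTHER)
        )
    def _mean(x):
        return float(np.mean(x)) if x is not None and len(x) else float("nan")

    return WellSummary(
        well_id=well_id,
        condition=condition or Condition(atp_um=float("nan")),
        n_cells=n,
        fraction_osc_peak=f[0],
        fraction_peak=f[1],
        fraction_other=f[2],
        mean_rfu=_mean(rfu),
        mean_elongation=_mean(elongation),
    )


@dataclass
class ConditionSummary:
    """Replicate-averaged metrics of one condition (mean and sample SD,
    n-1 denominator; SD is 0 and flagged for a single well)."""

    condition: Condition
    n_wells: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    single_well: bool = False


def aggregate_condition(summaries: Iterable[WellSummary]) -> ConditionSummary:
    """Mean and sample SD of each metric over a condition's wells.

    Wells are averaged unweighted (each independent experiment counts
    once, regardless of its cell count).
    """
    wells = list(summaries)
    if not wells:
        raise ValueError("need at least one well per condition")
    conds = {w.condition for w in wells}
    if len(conds) != 1:
        raise ValueError(f"wells span multiple conditions: {conds}")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for m in _METRICS:
        vals = np.array([getattr(w, m) for w in wells], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            mean[m] = float("nan")
            sd[m] = float("nan")
        else:
            mean[m] = float(vals.mean())
            sd[m] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ConditionSummary(
        condition=wells[0].condition,
        n_wells=len(wells),
        mean=mean,
        sd=sd,
        single_well=len(wells) == 1,
    )


def _monotone_flag(values: np.ndarray, direction: str, tol: float) -> str:
    """Classify a dose profile as increasing/decreasing/flat/non-monotone
    within an absolute tolerance per step."""
    d = np.diff(values)
    if np.all(np.abs(d) <= tol):
        return "flat"
    if direction == "non-increasing":
        return "decreasing" if np.all(d <= tol) else "non-monotone"
    return "increasing" if np.all(d >= -tol) else "non-monotone"


def dose_response_table(
    cond_summaries: Iterable[ConditionSummary],
    *,
    tolerance: float = 0.02,
) -> tuple[pd.DataFrame, dict]:
    """Class fractions versus ATP dose, plus a monotonicity report.

    Rows are ordered by ATP concentration. The report states, per
    class, whether the mean fraction is monotone non-increasing (Other)
    or non-decreasing (OscillationAndPeak, Peak) across doses within an
    absolute per-step tolerance; the headline pattern of this assay is
    a decreasing Other fraction with both responding classes growing.
    """
    summaries = sorted(cond_summaries, key=lambda s: s.condition.atp_um)
    if len(summaries) < 2:
        raise ValueError("need at least two ATP levels")
    doses = [s.condition.atp_um for s in summaries]
    if len(set(doses)) != len(doses):
        raise ValueError(f"duplicate ATP concentrations: {doses}")
    rows = []
    for s in summaries:
        row = {"atp_um": s.condition.atp_um, "n_wells": s.n_wells}
        for m in _METRICS:
            row[m] = s.mean[m]
            row[f"{m}_sd"] = s.sd[m]
        rows.append(row)
    df = pd.DataFrame(rows)
    report = {
        "tolerance": tolerance,
        "atp_um": doses,
        "flags": {
            "fraction_other": _monotone_flag(
                df["fraction_other"].to_numpy(), "non-increasing", tolerance
            ),
            "fraction_osc_peak": _monotone_flag(
                df["fraction_osc_peak"].to_numpy(), "non-decreasing", tolerance
            ),
            "fraction_peak": _monotone_flag(
                df["fraction_peak"].to_numpy(), "non-decreasing", tolerance
            ),
        },
    }
    return df, report


def plot_dose_response(df: pd.DataFrame, path: str) -> None:
    """Grouped bar chart of the three class fractions per ATP dose."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(df))
    width = 0.27
    fig, ax = plt.subplots(figsize=(6, 4))
    for off, (col, label) in zip(
        (-width, 0.0, width),
        [
            ("fraction_osc_peak", "Oscillation & Peak"),
            ("fraction_peak", "Peak"),
            ("fraction_other", "Other"),
        ],
    ):
        ax.bar(x + off, df[col], width, yerr=df[f"{col}_sd"], capsize=3, label=label)
    ax.set_xticks(x)
    ax.set_xticklabels([f"{v:g}" for v in df["atp_um"]])
    ax.set_xlabel("ATP (µM)")
    ax.set_ylabel("fraction of cells")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
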