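"""Phenotypic statistics for high-content chromobody imaging.

The central readout is *segments per cell*: the total number of fiber
segments across all fields of a condition divided by the total number of
segmented nuclei in the same fields (a pooled population-level ratio,
not a mean of per-field ratios).  On top of it sit control
normalization of dose/time series, fold changes, the fraction of
aggregate-positive cells, and the significance tests used for those
readouts (pooled-variance two-sample t-test and the 2x2 Pearson
chi-squared test without continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WellMeasurement",
    "NormalizedSeries",
    "segments_per_cell",
    "segments_per_cell_table",
    "normalize_to_control",
    "fold_change",
    "aggregate_fraction",
    "chi_squared_test",
    "two_sample_ttest",
]


@dataclass
class WellMeasurement:
    """Pooled per-condition measurement."""

    condition: str
    time_h: float
    dose_nM: float
    n_fields: int
    total_segments: int
    total_nuclei: int

    @property
    def segments_per_cell(self) -> float:
        return self.total_segments / self.total_nuclei


@dataclass
class NormalizedSeries:
    """Per-(time, dose) values relative to the control at the same time."""

    table: pd.DataFrame  # columns: condition, time_h, dose_nM, segments_per_cell, relative_value
    control_key: str


def segments_per_cell(total_segments: int, total_nuclei: int) -> float:
    """Population-level ratio of fiber segments to nuclei."""
    if total_nuclei <= 0:
        raise ValueError("total_nuclei must be > 0")
    return total_segments / total_nuclei


def segments_per_cell_table(field_table: pd.DataFrame,
                            grouping=("condition", "time_h", "dose_nM"),
                            min_cells: int = 100,
                            pooled: bool = True) -> list[WellMeasurement]:
    """Aggregate a per-field table into per-condition measurements.

    ``field_table`` needs columns ``n_segments`` and ``n_nuclei`` plus the
    grouping keys.  The pooled ratio (sum of segments / sum of nuclei) is
    the default; ``pooled=False`` gives the unweighted mean of per-field
    ratios instead.  Conditions below ``min_cells`` total nuclei trigger a
    warning, conditions with zero nuclei an error.
    """
    grouping = [g for g in grouping if g in field_table.columns]
    if not grouping:
        raise ValueError("no grouping columns present in field table")
    out: list[WellMeasurement] = []
    for key, grp in field_table.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(grouping, key))
        tot_seg = int(grp["n_segments"].sum())
        tot_nuc = int(grp["n_nuclei"].sum())
        cond = str(info.get("condition", "?"))
        if tot_nuc == 0:
            raise ValueError(f"condition {info} has zero segmented nuclei")
        if tot_nuc < min_cells:
            warnings.warn(
                f"condition {info}: only {tot_nuc} nuclei (< {min_cells})",
                stacklevel=2)
        m = WellMeasurement(
            condition=cond,
            time_h=float(info.get("time_h", np.nan)),
            dose_nM=float(info.get("dose_nM", np.nan)),
            n_fields=len(grp),
            total_segments=tot_seg,
            total_nuclei=tot_nuc,
        )
        if not pooled:
            ratios = grp["n_segments"] / grp["n_nuclei"]
            object.__setattr__(m, "_mean_of_ratios", float(ratios.mean()))
        out.append(m)
    return out


def normalize_to_control(measurements: list[WellMeasurement],
                         control_key: str) -> NormalizedSeries:
    """Divide each measurement by the control condition at the same time point.

    Emulates normalizing drug-response series to the untreated (0 nM)
    control; the control's relative value is 1.0 at every time point.
    """
    rows = [{
        "condition": m.condition, "time_h": m.time_h, "dose_nM": m.dose_nM,
        "total_segments": m.total_segments, "total_nuclei": m.total_nuclei,
        "segments_per_cell": m.segments_per_cell,
    } for m in measurements]
    df = pd.DataFrame(rows)
    ctrl = df[df["condition"] == control_key].set_index("time_h")["segments_per_cell"]
    if ctrl.empty:
        raise KeyError(f"control condition {control_key!r} not found")
    missing = set(df["time_h"]) - set(ctrl.index)
    if missing:
        raise KeyError(
            f"control {control_key!r} missing at time points {sorted(missing)}")
    df["relative_value"] = df.apply(
        lambda r: r["segments_per_cell"] / ctrl.loc[r["time_h"]], axis=1)
    return NormalizedSeries(df, control_key)


def fold_change(treated: WellMeasurement, reference: WellMeasurement) -> float:
    """Ratio of segments-per-cell, treated over reference."""
    ref = reference.segments_per_cell
    if ref <= 0:
        raise ValueError("reference segments_per_cell must be > 0")
    return treated.segments_per_cell / ref


def aggregate_fraction(per_cell_granule_counts, granule_threshold: int = 3):
    """Fraction of cells classified aggregate-positive.

    A cell is positive when it carries at least ``granule_threshold``
    detected puncta.  Returns (percentage, (n_positive, n_cells)) so the
    raw counts remain available for the chi-squared test.
    """
    counts = np.asarray(list(per_cell_granule_counts), dtype=int)
    if counts.size == 0:
        raise ValueError("need at least one cell")
    pos = int(np.sum(counts >= granule_threshold))
    return 100.0 * pos / counts.size, (pos, counts.size)


def chi_squared_test(counts_a: tuple[int, int], counts_b: tuple[int, int]):
    """Pearson chi-squared on a 2x2 positive/negative table, 1 df, no
    continuity correction.  Inputs are (n_positive, n_total) per group."""
    pos_a, n_a = counts_a
    pos_b, n_b = counts_b
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group totals must be > 0")
    if not (0 <= pos_a <= n_a and 0 <= pos_b <= n_b):
        raise ValueError("positives cannot exceed totals")
    table = np.array([[pos_a, n_a - pos_a], [pos_b, n_b - pos_b]])
    if table.sum(axis=0).min() == 0:
        raise ValueError("degenerate 2x2 table (an outcome never occurs)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def plot_time_course(series: NormalizedSeries, path, ylabel="relative segments per cell"):
    """Plot relative segments-per-cell versus time, one line per dose."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    df = series.table.sort_values("time_h")
    for dose, grp in df.groupby("dose_nM"):
        ax.plot(grp["time_h"], grp["relative_value"], marker="o",
                label=f"{dose:g} nM")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def two_sample_ttest(replicates_a, replicates_b):
    """Two-tailed pooled-variance (Student's) t-test.

    When both groups have zero variance and equal means the statistic is
    taken as 0 with p = 1 (no evidence of a difference).
    """
    a = np.asarray(list(replicates_a), dtype=float)
    b = np.asarray(list(replicates_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
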