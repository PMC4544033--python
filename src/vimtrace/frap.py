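"""FRAP recovery analysis and binding-kinetics arithmetic.

Raw fluorescence-recovery-after-photobleaching traces (bleached region,
background, whole cell) are double-normalized — background-corrected and
corrected for the total loss of fluorescence over the acquisition — then
fitted with a single-exponential recovery

    I(t) = A * (1 - exp(-k t))

where ``A`` is the end value of the normalized intensity (the mobile
fraction) and ``k`` the rate constant; the half-time of recovery is
``ln 2 / k``.  Incomplete bleaching is handled by rescaling the
postbleach samples so the first postbleach frame sits at zero before
fitting, then mapping the plateau back to the original normalized scale.

Also includes the 1:1 binding relation K_D = k_off / k_on used to turn
association/dissociation rate constants into an affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "NormalizedFrapTrace",
    "FrapFit",
    "KineticRates",
    "normalize_frap",
    "fit_recovery",
    "analyze_trace",
    "half_time",
    "kd_from_rates",
]

LN2 = math.log(2.0)


@dataclass
class FrapTrace:
    """Raw FRAP intensities versus time.

    ``bleach_index`` is the index of the first postbleach frame; frames
    before it are prebleach.
    """

    time_s: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    whole_cell: np.ndarray
    bleach_index: int

    def validate(self) -> None:
        n = len(self.time_s)
        if not (len(self.roi) == len(self.background) == len(self.whole_cell) == n):
            raise ValueError("trace arrays must share one length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not 0 < self.bleach_index < n:
            raise ValueError("bleach_index must split the trace")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "time_s": self.time_s, "roi": self.roi,
            "background": self.background, "whole_cell": self.whole_cell,
        })
        with open(path, "w") as fh:
            fh.write(f"# bleach_index={self.bleach_index}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrapTrace":
        """Read a trace CSV; the bleach frame comes from a
        ``# bleach_index=N`` header line, else from the largest
        single-frame drop in the ROI signal."""
        path = Path(path)
        bleach = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "bleach_index=" in first:
            bleach = int(first.split("bleach_index=")[1].strip())
        df = pd.read_csv(path, comment="#")
        roi = df["roi"].to_numpy(float)
        if bleach is None:
            bleach = int(np.argmin(np.diff(roi)) + 1)
        return cls(df["time_s"].to_numpy(float), roi,
                   df["background"].to_numpy(float),
                   df["whole_cell"].to_numpy(float), bleach)


@dataclass
class NormalizedFrapTrace:
    """Double-normalized trace; time 0 is the first postbleach frame."""

    time_s: np.ndarray  # full axis, negative for prebleach frames
    intensity: np.ndarray
    bleach_index: int

    @property
    def postbleach(self) -> tuple[np.ndarray, np.ndarray]:
        i = self.bleach_index
        return self.time_s[i:], self.intensity[i:]


def normalize_frap(trace: FrapTrace,
                   min_prebleach: int = 3) -> NormalizedFrapTrace:
    """Background-correct and acquisition-bleaching-correct a FRAP trace.

    Double normalization:

        I_norm(t) = (roi(t) - bg(t)) / (roi_pre - bg_pre)
                    * (whole_pre - bg_pre) / (whole(t) - bg(t))

    with ``*_pre`` the prebleach means.  The first factor normalizes the
    bleached region to its prebleach level; the second divides out the
    total loss of fluorescence caused by imaging, so the prebleach mean
    is 1 by construction and the normalization is invariant to rescaling
    all three raw channels by a common factor.
    """
    trace.validate()
    if trace.bleach_index < min_prebleach:
        raise ValueError(f"need >= {min_prebleach} prebleach frames")
    i = trace.bleach_index
    roi = np.asarray(trace.roi, float)
    bg = np.asarray(trace.background, float)
    whole = np.asarray(trace.whole_cell, float)
    if np.any(whole <= bg):
        raise ValueError("whole-cell signal at or below background: "
                         "nonphysical trace")
    roi_pre = roi[:i].mean()
    bg_pre = bg[:i].mean()
    whole_pre = whole[:i].mean()
    if roi_pre <= bg_pre:
        raise ValueError("prebleach ROI at or below background")
    inorm = (roi - bg) / (roi_pre - bg_pre) * (whole_pre - bg_pre) / (whole - bg)
    t = np.asarray(trace.time_s, float) - trace.time_s[i]
    return NormalizedFrapTrace(t, inorm, i)


@dataclass
class FrapFit:
    A: float  # plateau, end value of normalized intensity
    k: float  # 1/s
    t_half: float  # s, always ln2/k
    r_squared: float
    converged: bool
    bleach_depth: float = float("nan")  # first postbleach normalized value
    message: str = ""


def _recovery_model(t, i0, a, k):
    """Exponential recovery from residual bleach depth i0 to plateau a."""
    return i0 + (a - i0) * (1.0 - np.exp(-k * t))


def fit_recovery(norm: NormalizedFrapTrace,
                 min_postbleach: int = 10) -> FrapFit:
    """Least-squares fit of the single-exponential recovery.

    Fits ``I(t) = I0 + (A - I0) (1 - exp(-k t))`` on the postbleach
    samples, i.e. the recovery model with a residual bleach-depth offset
    I0 (incomplete bleaching), so that ``A`` keeps its meaning as the end
    value of the normalized intensity.  I0 is a fitted parameter rather
    than the first postbleach sample: with a single noisy frame fixing
    the offset, small-amplitude recoveries become ill-posed and the
    optimum can run away along the slow-ramp ridge (k -> 0, A at its
    bound).  Bounds: I0 in [-0.2, 0.95], A in [0, 1.2], k in (0, 10].
    Several rate starting values are tried and the lowest-residual
    solution returned.
    """
    t, y = norm.postbleach
    if len(t) < min_postbleach:
        raise ValueError(f"need >= {min_postbleach} postbleach samples")
    y0 = float(y[0])
    if y0 >= 1.0:
        return FrapFit(float("nan"), float("nan"), float("nan"), 0.0, False,
                       y0, "no bleach detected: first postbleach value >= 1")

    i0_start = float(np.clip(y0, -0.19, 0.94))
    a0 = float(np.clip(np.mean(y[-10:]), 0.01, 1.19))
    rise = a0 - i0_start
    k0 = 1.0
    if rise > 0:
        above = np.nonzero(y >= i0_start + rise * (1.0 - math.e ** -1))[0]
        if len(above) and t[above[0]] > 0:
            k0 = 1.0 / t[above[0]]
    starts = {float(np.clip(k0, 1e-3, 10.0)), 0.05, 0.5, 2.0}

    best = None
    for ks in sorted(starts):
        try:
            popt, _ = curve_fit(
                _recovery_model, t, y, p0=(i0_start, a0, ks),
                bounds=([-0.2, 0.0, 1e-9], [0.95, 1.2, 10.0]),
                xtol=1e-10, ftol=1e-12, gtol=1e-10, maxfev=500 * 4,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _recovery_model(t, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:  # pragma: no cover - pathological traces
        return FrapFit(float("nan"), float("nan"), float("nan"), 0.0, False,
                       y0, "fit did not converge from any starting point")
    (i0, a, k), ss_res = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    converged = True
    msg = ""
    if a >= 1.2 - 1e-6 or k <= 1e-8 or k >= 10.0 - 1e-6:
        # a solution pinned at a parameter bound means the plateau/rate
        # pair is not identifiable from this trace (e.g. the recovery
        # never levels off within the acquisition window)
        converged = False
        msg = "parameter at bound: recovery not identifiable from trace"
    return FrapFit(float(a), float(k), half_time(float(k)), r2, converged,
                   float(i0), msg)


def analyze_trace(trace: FrapTrace) -> FrapFit:
    """Normalize a raw trace and fit the recovery in one step."""
    return fit_recovery(normalize_frap(trace))


def half_time(k: float) -> float:
    """Half-time of a single-exponential recovery: ln 2 / k."""
    if k <= 0:
        raise ValueError("k must be > 0")
    return LN2 / k


@dataclass
class KineticRates:
    """1:1 binding rate constants; K_D = k_off / k_on."""

    k_on: float  # 1/(M s)
    k_off: float  # 1/s

    @property
    def kd_M(self) -> float:
        return kd_from_rates(self.k_on, self.k_off, unit="M")


def kd_from_rates(k_on: float, k_off: float, unit: str = "nM") -> float:
    """Equilibrium dissociation constant from association/dissociation rates.

    ``unit`` selects the reporting scale ("M" or "nM").
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be > 0")
    kd = k_off / k_on
    if unit == "M":
        return kd
    if unit == "nM":
        return kd * 1e9
    raise ValueError(f"unknown unit {unit!r}")
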