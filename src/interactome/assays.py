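"""Functional-assay quantification: FRAP, internalization ELISA, permeability.

Three readouts and one comparison statistic:

* FRAP — normalize each photobleached ROI trace to 100% (pre-bleach mean)
  and 0% (first post-bleach frame) and estimate the mobile fraction
  Mf = (plateau - F0) / (F_pre - F0).
* Surface-biotinylation internalization — capture-ELISA optical densities
  converted to percent of the surface pool internalized.
* Transendothelial tracer flux — per-timepoint transported fraction and a
  through-origin least-squares slope (fraction per hour).
* percent_change — the signed percent reduction between a control and a
  treated estimate, with a delta-method standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "FrapTrace",
    "ElisaPlate",
    "PermeabilityTimecourse",
    "normalize_frap",
    "mobile_fraction",
    "MobileFraction",
    "internalization_percent",
    "permeability_flux",
    "FluxResult",
    "percent_change",
    "PercentChange",
]

PRE, BLEACH, POST = "pre", "bleach", "post"


@dataclass(frozen=True)
class FrapTrace:
    """One cell's ROI fluorescence time series with phase labels."""

    cell_id: str
    time_s: np.ndarray
    intensity: np.ndarray
    phase: np.ndarray  # str array over {pre, bleach, post}

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        if not (np.diff(t) > 0).all():
            raise ValueError(f"trace {self.cell_id}: times must be strictly increasing")
        phases = np.asarray(self.phase)
        if (phases == PRE).sum() < 1:
            raise ValueError(f"trace {self.cell_id}: needs at least one pre-bleach frame")
        if (phases == POST).sum() < 2:
            raise ValueError(f"trace {self.cell_id}: needs at least two post-bleach frames")

    def frames(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        mask = np.asarray(self.phase) == phase
        return np.asarray(self.time_s, float)[mask], np.asarray(self.intensity, float)[mask]

    @staticmethod
    def from_long_frame(df: pd.DataFrame) -> list["FrapTrace"]:
        """Build traces from long-format columns (cell_id, time_s, intensity, phase)."""
        traces = []
        for cell_id, sub in df.groupby("cell_id", sort=True):
            sub = sub.sort_values("time_s")
            traces.append(
                FrapTrace(
                    cell_id=str(cell_id),
                    time_s=sub["time_s"].to_numpy(float),
                    intensity=sub["intensity"].to_numpy(float),
                    phase=sub["phase"].to_numpy(),
                )
            )
        return traces


def _pre_and_floor(trace: FrapTrace, f0_frames: int) -> tuple[float, float]:
    _, pre = trace.frames(PRE)
    _, post = trace.frames(POST)
    f_pre = float(pre.mean())
    f0 = float(post[: max(1, f0_frames)].mean())
    if f_pre == f0:
        raise ValueError(f"trace {trace.cell_id}: no bleach depth (pre mean equals post floor)")
    return f_pre, f0


def normalize_frap(trace: FrapTrace, *, f0_frames: int = 1) -> pd.DataFrame:
    """Affinely map post-bleach frames so pre-bleach mean = 100 and first post frame = 0.

    ``f0_frames`` > 1 averages the first few post frames for the 0% anchor,
    which is more robust under noise.  Returns (time_s, recovery_percent)
    with time measured from the first post-bleach frame.
    """
    f_pre, f0 = _pre_and_floor(trace, f0_frames)
    t, post = trace.frames(POST)
    recovery = (post - f0) / (f_pre - f0) * 100.0
    return pd.DataFrame({"time_s": t - t[0], "recovery_percent": recovery})


class MobileFraction(NamedTuple):
    value: float  # clipped to [0, 1]
    raw: float


def mobile_fraction(
    trace: FrapTrace,
    *,
    plateau_frames: int = 5,
    f0_frames: int = 1,
    method: str = "plateau",
) -> MobileFraction:
    """Fraction of the bleached pool that recovers: (plateau - F0)/(F_pre - F0).

    ``method="plateau"`` estimates the recovered level as the mean of the
    last ``plateau_frames`` post-bleach frames.  ``method="expfit"`` instead
    fits the normalized recovery with Mf * (1 - exp(-t/tau)) and reports the
    fitted plateau — a cross-check when the recovery has not visibly
    saturated.
    """
    f_pre, f0 = _pre_and_floor(trace, f0_frames)
    t, post = trace.frames(POST)
    if method == "plateau":
        recovered = float(post[-plateau_frames:].mean())
        raw = (recovered - f0) / (f_pre - f0)
    elif method == "expfit":
        rel = (post - f0) / (f_pre - f0)
        tt = t - t[0]

        def model(x, mf, tau):
            return mf * (1.0 - np.exp(-x / tau))

        span = max(tt[-1], 1.0)
        popt, _ = scipy.optimize.curve_fit(
            model, tt, rel, p0=[0.5, span / 5], bounds=([0.0, 1e-6], [2.0, 100 * span])
        )
        raw = float(popt[0])
    else:
        raise ValueError(f"unknown mobile-fraction method {method!r}")
    return MobileFraction(value=float(np.clip(raw, 0.0, 1.0)), raw=float(raw))


# ---------------------------------------------------------------------------
# internalization ELISA


@dataclass(frozen=True)
class ElisaPlate:
    """Capture-ELISA optical densities for one condition.

    ``internalized`` — ODs after surface stripping (protected pool only);
    ``total`` — ODs of the fully labeled surface pool (no stripping);
    ``background`` — strip-immediately control ODs (stripping efficiency).
    """

    condition: str
    internalized: np.ndarray
    total: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        for name in ("internalized", "total", "background"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size < 1:
                raise ValueError(f"{name} wells empty for condition {self.condition!r}")
            if (arr < 0).any():
                raise ValueError(f"negative OD in {name} wells of {self.condition!r}")


class PercentEstimate(NamedTuple):
    value: float
    se: float


def internalization_percent(plate: ElisaPlate) -> PercentEstimate:
    """Percent of the labeled surface pool internalized, background-corrected.

    % = (mean internalized OD - mean background OD) /
        (mean total OD - mean background OD) * 100, with a delta-method SE
    from the per-well-type SEMs.
    """
    i = np.asarray(plate.internalized, float)
    tot = np.asarray(plate.total, float)
    b = np.asarray(plate.background, float)
    num = i.mean() - b.mean()
    den = tot.mean() - b.mean()
    if den <= 0:
        raise ValueError(
            f"condition {plate.condition!r}: total OD does not exceed background OD"
        )
    value = num / den * 100.0

    def sem(a: np.ndarray) -> float:
        return float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0

    s_i, s_t, s_b = sem(i), sem(tot), sem(b)
    # f = (i - b)/(t - b); df/di = 1/den, df/dt = -num/den^2, df/db = (num - den)/den^2
    g = np.array([1.0 / den, -num / den**2, (num - den) / den**2]) * 100.0
    se = float(np.sqrt(g[0] ** 2 * s_i**2 + g[1] ** 2 * s_t**2 + g[2] ** 2 * s_b**2))
    return PercentEstimate(value=float(value), se=se)


# ---------------------------------------------------------------------------
# transendothelial permeability


@dataclass(frozen=True)
class PermeabilityTimecourse:
    """Basal-compartment tracer signal over time for one transwell condition."""

    condition: str
    time_h: np.ndarray
    basal_signal: np.ndarray
    apical_input: float
    aliquot_volume_ul: float | None = None
    basal_volume_ul: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        if t.size < 2:
            raise ValueError("permeability timecourse needs at least 2 timepoints")
        if not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if (np.asarray(self.basal_signal, float) < 0).any():
            raise ValueError("basal signals must be >= 0")


class FluxResult(NamedTuple):
    time_h: np.ndarray
    fraction: np.ndarray  # transported fraction of the apical input per timepoint
    slope_per_h: float  # least-squares slope through the origin


def permeability_flux(tc: PermeabilityTimecourse) -> FluxResult:
    """Transported tracer fraction per timepoint and a through-origin slope.

    When aliquot and basal volumes are supplied, sequential-sampling
    depletion is corrected: the amount removed with each earlier aliquot is
    added back, so the fraction reflects cumulative transport.  Without
    volume metadata the raw signals are used.
    """
    if tc.apical_input <= 0:
        raise ValueError("apical input amount must be > 0")
    signal = np.asarray(tc.basal_signal, dtype=float).copy()
    if tc.aliquot_volume_ul is not None and tc.basal_volume_ul:
        frac_removed = tc.aliquot_volume_ul / tc.basal_volume_ul
        removed = 0.0
        corrected = np.empty_like(signal)
        for j, s in enumerate(signal):
            corrected[j] = s + removed
            removed += frac_removed * s
        signal = corrected
    t = np.asarray(tc.time_h, dtype=float)
    fraction = signal / tc.apical_input
    slope = float((t @ fraction) / (t @ t))
    return FluxResult(time_h=t, fraction=fraction, slope_per_h=slope)


# ---------------------------------------------------------------------------
# condition comparison


class PercentChange(NamedTuple):
    value: float  # 100 * (ctrl - treat) / ctrl; positive = reduction
    se: float


def percent_change(
    ctrl: float,
    treat: float,
    *,
    ctrl_se: float = 0.0,
    treat_se: float = 0.0,
) -> PercentChange:
    """Signed percent reduction of a treated estimate relative to control.

    Positive values are reductions, negative values increases.  The SE is
    propagated by the delta method from the two estimates' standard errors:
    Var = (100 * treat / ctrl^2)^2 Var(ctrl) + (100 / ctrl)^2 Var(treat).
    """
    if ctrl == 0:
        raise ValueError("control estimate is 0; percent change undefined")
    value = 100.0 * (ctrl - treat) / ctrl
    se = math.hypot(100.0 * treat / ctrl**2 * ctrl_se, 100.0 / ctrl * treat_se)
    return PercentChange(value=float(value), se=float(se))
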