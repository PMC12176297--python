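"""FRAP recovery analysis.

Normalizes fluorescence-recovery-after-photobleaching traces to the
pre-bleach mean and fits a single-exponential recovery

    F(t) = F_inf - (F_inf - F0) * exp(-k * (t - t_bleach))

where ``F0`` is the normalized first post-bleach intensity, ``F_inf`` the
fitted plateau, and ``k`` the recovery rate. Reported kinetics are the
half-time ``t_half = ln(2) / k`` and the immobile fraction
``(1 - F_inf) / (1 - F0)`` (the complement of the mobile fraction with the
pre-bleach level normalized to 1). Per-condition summaries average fitted
parameters over cells and build a point-wise mean +/- SD recovery curve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["FrapTrace", "FrapFit", "normalize_trace", "fit_recovery", "summarize_condition"]


@dataclass
class FrapTrace:
    """A time-intensity series with a marked pre-bleach segment."""

    times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray
    n_prebleach: int
    background: np.ndarray | None = None
    cell_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=np.float64)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.times.size <= self.n_prebleach:
            raise ValueError("trace must extend past the bleach")

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_prebleach:]

    @property
    def post_intensities(self) -> np.ndarray:
        return self.intensities[self.n_prebleach:]


@dataclass
class FrapFit:
    """Fitted recovery kinetics for one cell."""

    t_half: float
    k: float
    f0: float
    f_inf: float
    immobile_fraction: float
    residual_sd: float
    converged: bool
    cell_id: str | None = None
    condition: str | None = None


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Background-subtract (if provided) and scale to pre-bleach mean 1.

    Idempotent: normalizing an already-normalized trace is a no-op (the
    pre-bleach mean of the output is exactly 1, and the background has been
    consumed).
    """
    inten = trace.intensities
    if trace.background is not None:
        inten = inten - trace.background
    pre = inten[: trace.n_prebleach].mean()
    if pre <= 0:
        raise ValueError("pre-bleach mean must be positive after background subtraction")
    return replace(trace, intensities=inten / pre, background=None)


def _init_guess(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting point: F0 from the first post-bleach point,
    F_inf from the tail mean, k from a log-linear fit of the residual decay."""
    f0 = f[0]
    n_tail = max(1, len(f) // 10)
    f_inf = f[-n_tail:].mean()
    if f_inf <= f0:
        return f0, f0, 1.0
    resid = (f_inf - f) / (f_inf - f0)
    ok = resid > 1e-6
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
        k = max(-slope, 1e-6)
    else:
        k = 1.0
    return f0, f_inf, k


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Least-squares single-exponential fit of a normalized trace.

    Time is measured from the first post-bleach frame. Non-convergence is
    flagged on the result rather than silently replaced with defaults.
    """
    post_t = trace.post_times
    post_f = trace.post_intensities
    if post_t.size < 10:
        raise ValueError("need at least 10 post-bleach frames")
    t = post_t - post_t[0]
    f0_g, finf_g, k_g = _init_guess(t, post_f)

    def model(tt, f0, f_inf, k):
        return f_inf - (f_inf - f0) * np.exp(-k * tt)

    converged = True
    try:
        popt, _ = curve_fit(
            model,
            t,
            post_f,
            p0=[f0_g, finf_g, k_g],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        f0, f_inf, k = (float(v) for v in popt)
    except RuntimeError:
        converged = False
        f0, f_inf, k = f0_g, finf_g, k_g

    resid = post_f - model(t, f0, f_inf, k)
    if f0 >= 1.0:
        immobile = 0.0
    else:
        immobile = float(np.clip((1.0 - f_inf) / (1.0 - f0), 0.0, 1.0))
    return FrapFit(
        t_half=float(np.log(2) / k),
        k=k,
        f0=f0,
        f_inf=f_inf,
        immobile_fraction=immobile,
        residual_sd=float(resid.std(ddof=0)),
        converged=converged,
        cell_id=trace.cell_id,
        condition=trace.condition,
    )


def summarize_condition(
    fits_by_condition: Mapping[str, Sequence[FrapFit]],
    traces_by_condition: Mapping[str, Sequence[FrapTrace]] | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-condition kinetic means and the averaged recovery curve.

    Returns a table with per-condition mean/SD of ``t_half`` and the
    immobile fraction, and (when traces are supplied) one DataFrame per
    condition with the point-wise mean +/- SD normalized recovery on the
    common post-bleach grid. Traces on ragged grids are linearly resampled
    to the first trace's grid, and the output notes how many were resampled.
    """
    rows = []
    for cond, fits in fits_by_condition.items():
        if len(fits) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 cells")
        th = np.array([f.t_half for f in fits])
        im = np.array([f.immobile_fraction for f in fits])
        rows.append(
            {
                "condition": cond,
                "n_cells": len(fits),
                "t_half_mean_s": th.mean(),
                "t_half_sd_s": th.std(ddof=1),
                "immobile_mean": im.mean(),
                "immobile_sd": im.std(ddof=1),
            }
        )
    table = pd.DataFrame(rows)

    curves: dict[str, pd.DataFrame] = {}
    if traces_by_condition:
        for cond, traces in traces_by_condition.items():
            ref = traces[0].post_times - traces[0].post_times[0]
            mat, n_resampled = [], 0
            for tr in traces:
                t = tr.post_times - tr.post_times[0]
                f = tr.post_intensities
                if t.shape == ref.shape and np.allclose(t, ref):
                    mat.append(f)
                else:
                    mat.append(np.interp(ref, t, f))
                    n_resampled += 1
            mat = np.vstack(mat)
            df = pd.DataFrame(
                {
                    "time_s": ref,
                    "mean": mat.mean(axis=0),
                    "sd": mat.std(axis=0, ddof=1) if mat.shape[0] > 1 else 0.0,
                }
            )
            df.attrs["n_resampled"] = n_resampled
            curves[cond] = df
    return table, curves


def read_trace_csv(path, n_prebleach: int = 10, cell_id=None, condition=None) -> FrapTrace:
    """Read a trace CSV with columns ``time_s, intensity[, background]``."""
    df = pd.read_csv(path)
    bg = df["background"].to_numpy() if "background" in df.columns else None
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        n_prebleach=n_prebleach,
        background=bg,
        cell_id=cell_id,
        condition=condition,
    )
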