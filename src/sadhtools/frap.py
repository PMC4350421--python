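"""FRAP recovery-curve normalization and single-exponential fitting.

Fluorescence recovery after photobleaching (FRAP) traces are normalized so
the pre-bleach mean is 1 and time zero is the first post-bleach frame, then
fitted with the single-exponential recovery model

    Y(t) = Y0 + (Ymax - Y0) * (1 - exp(-k t))

where ``Y0`` is the post-bleach floor, ``Ymax`` the recovery plateau and
``k`` the rate constant (1/s).  Derived quantities:

    t_half = ln(2) / k          half-time of recovery
    Mf     = (Ymax - Y0) / (1 - Y0)   mobile fraction

Note on the model: the source protocol prints the recovery equation as
``Y(t) = (Ymax - Ymin)(1 - e^{2kt}) - Ymin``, which diverges as written;
it is read here as the standard bounded single-exponential above, with the
printed ``Ymin`` identified with the post-bleach floor ``Y0``.  This
interpretation is the only one consistent with the mobile-fraction
definition and with the cited fitting reference, and it is recorded rather
than silently assumed.

No acquisition-photobleaching correction or reference region is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "FrapFit",
    "GroupSummary",
    "FrapError",
    "NormalizationError",
    "FitConvergenceError",
    "normalize_trace",
    "fit_recovery",
    "summarize_group",
    "recovery_model",
]

LN2 = float(np.log(2.0))


class FrapError(ValueError):
    pass


class NormalizationError(FrapError):
    pass


class FitConvergenceError(FrapError):
    def __init__(self, message: str, initial_guess=None, residual=None):
        super().__init__(message)
        self.initial_guess = initial_guess
        self.residual = residual


@dataclass
class FrapTrace:
    """Raw time-intensity FRAP record.

    ``bleach_index`` is the index of the first post-bleach frame.  At least
    3 pre-bleach and 5 post-bleach frames are required for a stable
    normalization and fit.
    """

    times: np.ndarray
    intensities: np.ndarray
    bleach_index: int
    background: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise FrapError("times and intensities must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise FrapError("times must be strictly increasing")
        if self.bleach_index < 3:
            raise FrapError("need >= 3 pre-bleach frames")
        if len(self.times) - self.bleach_index < 5:
            raise FrapError("need >= 5 post-bleach frames")


@dataclass
class NormalizedTrace:
    """Post-bleach trace with t = 0 at the bleach and pre-bleach mean = 1."""

    times: np.ndarray
    y: np.ndarray


@dataclass
class FrapFit:
    k: float  # 1/s
    Y0: float
    Ymax: float
    t_half: float  # s, = ln2/k
    Mf: float  # mobile fraction
    residual_norm: float


@dataclass
class GroupSummary:
    n: int
    t_half_mean: float
    t_half_sem: float
    mf_mean: float
    mf_sem: float


def recovery_model(t: np.ndarray, k: float, y0: float, ymax: float) -> np.ndarray:
    """Single-exponential recovery Y(t) = Y0 + (Ymax - Y0)(1 - e^{-kt})."""
    return y0 + (ymax - y0) * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def normalize_trace(trace: FrapTrace) -> NormalizedTrace:
    """Background-subtract and scale so the pre-bleach mean is 1.

    y = (intensity - background) / (pre-bleach mean - background); the
    post-bleach frames are kept with time re-zeroed at the first of them.
    """
    pre = trace.intensities[: trace.bleach_index]
    denom = float(pre.mean()) - trace.background
    if denom <= 0:
        raise NormalizationError(
            f"pre-bleach mean ({pre.mean():.3g}) minus background "
            f"({trace.background:.3g}) is non-positive"
        )
    post_t = trace.times[trace.bleach_index :]
    post_i = trace.intensities[trace.bleach_index :]
    y = (post_i - trace.background) / denom
    return NormalizedTrace(times=post_t - post_t[0], y=y)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    y0 = float(y[0])
    ymax = float(np.mean(y[-3:]))
    halfway = y0 + 0.5 * (ymax - y0)
    if ymax > y0:
        idx = np.argmax(y >= halfway)
        t_half_guess = float(t[idx]) if t[idx] > 0 else float(t[1])
    else:
        t_half_guess = float(t[len(t) // 2]) or float(t[1])
    k0 = LN2 / max(t_half_guess, 1e-6)
    return k0, y0, ymax


def fit_recovery(trace: NormalizedTrace) -> FrapFit:
    """Least-squares fit of the single-exponential recovery model.

    Returns the rate constant ``k`` (bounded positive), the floor ``Y0``,
    the plateau ``Ymax``, and the derived ``t_half = ln2/k`` and mobile
    fraction ``Mf = (Ymax - Y0)/(1 - Y0)``.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.y, dtype=float)
    if len(t) < 5:
        raise FrapError("need >= 5 post-bleach points to fit")
    guess = _initial_guess(t, y)
    bounds = ([1e-8, -1.0, -1.0], [np.inf, 2.0, 2.0])
    try:
        popt, _ = curve_fit(
            recovery_model, t, y, p0=guess, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        resid = float(np.sqrt(np.mean((recovery_model(t, *guess) - y) ** 2)))
        raise FitConvergenceError(
            f"recovery fit did not converge: {exc}",
            initial_guess=guess,
            residual=resid,
        ) from exc
    k, y0, ymax = (float(v) for v in popt)
    if k <= 0:
        raise FitConvergenceError(
            f"non-positive rate constant k = {k:.3g}", initial_guess=guess
        )
    resid = float(np.sqrt(np.mean((recovery_model(t, k, y0, ymax) - y) ** 2)))
    return FrapFit(
        k=k,
        Y0=y0,
        Ymax=ymax,
        t_half=LN2 / k,
        Mf=(ymax - y0) / (1.0 - y0),
        residual_norm=resid,
    )


def summarize_group(fits: Sequence[FrapFit]) -> GroupSummary:
    """Mean, standard error and n for t_half and the mobile fraction."""
    if not fits:
        raise FrapError("no fits to summarize")
    t_half = np.array([f.t_half for f in fits])
    mf = np.array([f.Mf for f in fits])
    n = len(fits)
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(
        n=n,
        t_half_mean=float(t_half.mean()),
        t_half_sem=sem(t_half),
        mf_mean=float(mf.mean()),
        mf_sem=sem(mf),
    )
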