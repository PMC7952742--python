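"""Exponential least-squares fitting of echo trains.

Fallback estimators that model the echo train as a sum of pure
exponentials, ignoring stimulated-echo pathways: a double-exponential
water+fat model S(t) = A * [(1-ff) exp(-t/wT2) + ff exp(-t/fatT2)] with
fixed fat T2, and a mono-exponential A exp(-t/T2). These cannot correct
for B1 inhomogeneity or the slice profile — with imperfect refocusing
the apparent decay is slower than exp(-t/T2), so the fitted T2
overestimates the true one — but they require no sequence knowledge and
are useful when the EPG model is unstable or the true slice profile is
unknown. The fat fraction can optionally be fixed per voxel from an
external map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["BiexpFitResult", "MonoexpFitResult", "fit_biexponential", "fit_monoexponential", "fit_volume"]

WT2_BOUNDS = (1.0, 100.0)
MONO_T2_BOUNDS = (1.0, 10000.0)


@dataclass(frozen=True)
class BiexpFitResult:
    wt2: float  # ms
    ff: float  # fraction
    amplitude: float  # signal units
    rss: float  # residual sum of squares
    converged: bool


@dataclass(frozen=True)
class MonoexpFitResult:
    t2: float  # ms
    amplitude: float
    rss: float
    converged: bool


def _failed_biexp() -> BiexpFitResult:
    return BiexpFitResult(np.nan, np.nan, np.nan, np.nan, False)


def fit_biexponential(
    signal: np.ndarray,
    echo_times: np.ndarray,
    fat_t2: float = 151.0,
    ff_fixed: float | None = None,
) -> BiexpFitResult:
    """Bounded nonlinear least-squares fit of the water+fat biexponential.

    Free parameters are the amplitude A >= 0, wT2 in [1, 100] ms and
    (unless ``ff_fixed`` is given) the fat fraction in [0, 1]; the fat T2
    is always fixed. Starts from A = first echo, wT2 = 35 ms, ff = 0.2.
    Non-convergence is reported via ``converged=False`` with NaN
    parameters rather than an exception, so volume fits can continue.
    """
    signal = np.asarray(signal, float)
    echo_times = np.asarray(echo_times, float)
    if signal.shape != echo_times.shape:
        raise ValueError("signal and echo_times must have the same length")
    if fat_t2 <= 0:
        raise ValueError("fat_t2 must be positive")
    min_echoes = 2 if ff_fixed is not None else 3
    if signal.size < min_echoes:
        raise ValueError(f"need at least {min_echoes} echoes for this fit")
    if ff_fixed is not None and not 0.0 <= ff_fixed <= 1.0:
        raise ValueError("ff_fixed must lie within [0, 1]")

    a0 = max(float(signal[0]), 1e-12)

    if ff_fixed is None:
        def residuals(p):
            a, wt2, ff = p
            model = a * ((1 - ff) * np.exp(-echo_times / wt2) + ff * np.exp(-echo_times / fat_t2))
            return model - signal

        x0 = [a0, 35.0, 0.2]
        lb = [0.0, WT2_BOUNDS[0], 0.0]
        ub = [np.inf, WT2_BOUNDS[1], 1.0]
    else:
        ff = float(ff_fixed)

        def residuals(p):
            a, wt2 = p
            model = a * ((1 - ff) * np.exp(-echo_times / wt2) + ff * np.exp(-echo_times / fat_t2))
            return model - signal

        x0 = [a0, 35.0]
        lb = [0.0, WT2_BOUNDS[0]]
        ub = [np.inf, WT2_BOUNDS[1]]

    try:
        sol = least_squares(
            residuals, x0, bounds=(lb, ub), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
            x_scale=[max(a0, 1e-6), 10.0, 0.1][: len(x0)],
        )
    except Exception:
        return _failed_biexp()
    if not sol.success:
        return _failed_biexp()
    rss = float(np.sum(sol.fun**2))
    if ff_fixed is None:
        a, wt2, ff_hat = sol.x
    else:
        (a, wt2), ff_hat = sol.x, ff_fixed
    return BiexpFitResult(float(wt2), float(ff_hat), float(a), rss, True)


def fit_monoexponential(signal: np.ndarray, echo_times: np.ndarray) -> MonoexpFitResult:
    """Bounded least-squares fit of A * exp(-t/T2).

    A degenerate (e.g. constant) signal drives T2 to its upper bound;
    that case is flagged with ``converged=False``.
    """
    signal = np.asarray(signal, float)
    echo_times = np.asarray(echo_times, float)
    if signal.shape != echo_times.shape:
        raise ValueError("signal and echo_times must have the same length")
    if signal.size < 2:
        raise ValueError("need at least 2 echoes")

    a0 = max(float(signal[0]), 1e-12)

    def residuals(p):
        a, t2 = p
        return a * np.exp(-echo_times / t2) - signal

    try:
        sol = least_squares(
            residuals,
            [a0, 50.0],
            bounds=([0.0, MONO_T2_BOUNDS[0]], [np.inf, MONO_T2_BOUNDS[1]]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
        )
    except Exception:
        return MonoexpFitResult(np.nan, np.nan, np.nan, False)
    a, t2 = sol.x
    at_bound = t2 >= MONO_T2_BOUNDS[1] * (1 - 1e-6)
    ok = bool(sol.success) and not at_bound
    return MonoexpFitResult(float(t2), float(a), float(np.sum(sol.fun**2)), ok)


def fit_volume(
    volume: np.ndarray,
    echo_times: np.ndarray,
    mask: np.ndarray,
    method: str = "biexp",
    fat_t2: float = 151.0,
    ff_map: np.ndarray | None = None,
):
    """Voxelwise exponential fitting over a masked 4D volume.

    Returns (wt2_map, ff_map_out, n_failed). For ``method='monoexp'``
    the wT2 map holds the mono-exponential T2 and the FF map is NaN. A
    per-voxel fat-fraction constraint (``ff_map``) fixes ff in the
    biexponential model; NaN constraint values fall back to the
    unconstrained fit.
    """
    if method not in ("biexp", "monoexp"):
        raise ValueError(f"unknown method {method!r}")
    volume = np.asarray(volume, float)
    echo_times = np.asarray(echo_times, float)
    wt2_out = np.full(volume.shape[:3], np.nan)
    ff_out = np.full(volume.shape[:3], np.nan)
    n_failed = 0
    for s, r, c in np.argwhere(mask):
        sig = volume[s, r, c]
        if method == "monoexp":
            res = fit_monoexponential(sig, echo_times)
            wt2_out[s, r, c] = res.t2 if res.converged else np.nan
            n_failed += 0 if res.converged else 1
        else:
            ff_fixed = None
            if ff_map is not None and np.isfinite(ff_map[s, r, c]):
                ff_fixed = float(np.clip(ff_map[s, r, c], 0.0, 1.0))
            res = fit_biexponential(sig, echo_times, fat_t2=fat_t2, ff_fixed=ff_fixed)
            wt2_out[s, r, c] = res.wt2
            ff_out[s, r, c] = res.ff
            n_failed += 0 if res.converged else 1
    return wt2_out, ff_out, n_failed
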