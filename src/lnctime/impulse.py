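"""Generalized impulse model for time-course expression profiles.

The impulse model describes a gene's response to stimulation as a product of
two logistic transitions: an abrupt departure from an initial level ``h0`` to
a peak (or intermediate) level ``h1``, followed by relaxation to a second
steady state ``h2``.  The generalized form allows the two transitions to have
different slopes ``lambda1`` and ``lambda2``:

    f(t) = (1/h1) * (h0 + (h1-h0)*sigma(lambda1*(t-t1)))
                  * (h2 + (h1-h2)*sigma(-lambda2*(t-t2)))

with ``sigma`` the standard logistic function.  The asymptotes are
``f(-inf) = h0`` and ``f(+inf) = h2``; between the transition centres ``t1``
and ``t2`` the curve plateaus near ``h1``.  Setting ``lambda1 == lambda2``
recovers the original equal-slope six-parameter model.

Fitted impulse curves are used for visualization and, through
:func:`peak_time`, to extract activation-peak times that feed the elongation
rate estimate.  Parameters of the impulse model are weakly identifiable on a
10-minute sampling grid, so the fitted *curve* (not the parameter vector) is
the quantity downstream code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit


class DegenerateProfileError(ValueError):
    """Raised when an operation receives a constant (zero-variance) profile."""


class NoPeakError(ValueError):
    """Raised when an impulse curve has no interior maximum (monotone/plateau)."""


@dataclass(frozen=True)
class ImpulseParams:
    """Parameters of the generalized two-slope impulse model.

    Levels ``h0, h1, h2`` are in expression units; ``t1 <= t2`` are transition
    centres in minutes; ``lambda1, lambda2 > 0`` are transition slopes in
    1/min.  ``sse`` is the residual sum of squares of the fit that produced
    the parameters (NaN when the parameters were not fitted).
    """

    h0: float
    h1: float
    h2: float
    t1: float
    t2: float
    lambda1: float
    lambda2: float
    sse: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.h1 == 0:
            raise ValueError("h1 appears as a divisor and must be nonzero")
        if not (self.lambda1 > 0 and self.lambda2 > 0):
            raise ValueError("lambda1 and lambda2 must be positive")
        if self.t1 > self.t2:
            raise ValueError("t1 must not exceed t2")


def impulse_eval(params: ImpulseParams, t) -> np.ndarray:
    """Evaluate the impulse curve at times ``t`` (minutes; scalar or array)."""
    t = np.asarray(t, dtype=float)
    onset = params.h0 + (params.h1 - params.h0) * expit(params.lambda1 * (t - params.t1))
    offset = params.h2 + (params.h1 - params.h2) * expit(-params.lambda2 * (t - params.t2))
    return onset * offset / params.h1


def _flat_params(level: float, times: np.ndarray, sse: float, degenerate: bool) -> ImpulseParams:
    if level == 0:
        level_h1 = 1e-12
    else:
        level_h1 = level
    lo, hi = float(times[0]), float(times[-1])
    return ImpulseParams(
        h0=level, h1=level_h1, h2=level, t1=lo, t2=hi,
        lambda1=0.1, lambda2=0.1, sse=sse, degenerate=degenerate,
    )


def _initial_starts(times: np.ndarray, values: np.ndarray) -> list[np.ndarray]:
    """Deterministic data-driven start points for the local optimizer.

    h0/h2 from the first/last three observations, h1 from the extremum,
    t1/t2 from half-amplitude crossing times, and slopes from a small grid.
    """
    h0 = float(values[:3].mean())
    h2 = float(values[-3:].mean())
    i_max = int(np.argmax(np.abs(values - (h0 + h2) / 2.0)))
    h1 = float(values[i_max])
    if h1 == 0.0:
        h1 = 1e-6
    half = (h0 + h1) / 2.0
    above = np.nonzero(values >= half if h1 >= h0 else values <= half)[0]
    t1 = float(times[above[0]]) if above.size else float(times[len(times) // 3])
    t2 = float(max(times[i_max], t1))
    starts = []
    for lam1 in (0.05, 0.2, 1.0):
        for lam2 in (0.05, 0.2, 1.0):
            starts.append(np.array([h0, h1, h2, t1, max(t2 - t1, 0.0), lam1, lam2]))
    # a flat start guarantees the fit never does worse than the constant model
    mean = float(values.mean()) or 1e-6
    starts.append(np.array([mean, mean, mean, float(times[0]),
                            float(times[-1] - times[0]), 0.1, 0.1]))
    return starts


def fit_impulse(times, values, n_starts: int | None = None) -> ImpulseParams:
    """Least-squares impulse fit to one expression profile.

    Runs a bounded local optimization from a deterministic set of
    data-informed start points (optionally truncated to ``n_starts``) and
    returns the parameters of the best fit.  The internal parameterization
    uses ``dt = t2 - t1 >= 0`` so the ``t1 <= t2`` constraint always holds.
    Transition centres are bounded to the measurement window padded by 50 min
    and slopes to [1e-3, 10] per minute to exclude degenerate step fits.

    A constant profile yields a flat fit (``h0 = h1 = h2 = mean``) flagged
    degenerate rather than an error, so callers can keep bookkeeping simple.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 7:
        raise ValueError("impulse fit requires at least 7 time points")
    if np.ptp(values) == 0.0:
        return _flat_params(float(values[0]), times, sse=0.0, degenerate=True)

    span = float(values.max() - values.min())
    lo_h = float(values.min() - 2 * span)
    hi_h = float(values.max() + 2 * span)
    t_lo, t_hi = float(times[0] - 50.0), float(times[-1] + 50.0)
    h1_lo = 1e-6 if values.max() > 0 else lo_h  # keep the divisor off zero
    lower = np.array([lo_h, h1_lo, lo_h, t_lo, 0.0, 1e-3, 1e-3])
    upper = np.array([hi_h, hi_h, hi_h, t_hi, t_hi - t_lo, 10.0, 10.0])

    def residuals(theta: np.ndarray) -> np.ndarray:
        h0, h1, h2, t1, dt, lam1, lam2 = theta
        onset = h0 + (h1 - h0) * expit(lam1 * (times - t1))
        offset = h2 + (h1 - h2) * expit(-lam2 * (times - (t1 + dt)))
        return onset * offset / h1 - values

    starts = _initial_starts(times, values)
    if n_starts is not None:
        starts = starts[:n_starts] + [starts[-1]]
    best_theta, best_sse = None, np.inf
    for theta0 in starts:
        theta0 = np.clip(theta0, lower + 1e-9, upper - 1e-9)
        try:
            sol = least_squares(residuals, theta0, bounds=(lower, upper),
                                method="trf", xtol=1e-12, ftol=1e-12)
        except ValueError:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if sse < best_sse:
            best_sse, best_theta = sse, sol.x
    h0, h1, h2, t1, dt, lam1, lam2 = best_theta
    return ImpulseParams(h0=float(h0), h1=float(h1), h2=float(h2), t1=float(t1),
                         t2=float(t1 + dt), lambda1=float(lam1), lambda2=float(lam2),
                         sse=best_sse)


def peak_time(params: ImpulseParams, t_min: float = 0.0, t_max: float = 400.0,
              grid_step: float = 1.0) -> float:
    """Time (minutes) of the impulse curve's interior maximum.

    The maximum is located on a fine grid spanning the measurement window.
    Curves whose maximum sits at either window edge, or that plateau into the
    right edge (sustained induction, ``h2 ~ h1``), carry no usable peak and
    raise :class:`NoPeakError`.
    """
    grid = np.arange(t_min, t_max + grid_step / 2, grid_step)
    f = impulse_eval(params, grid)
    i = int(np.argmax(f))
    fmax = f[i]
    span = float(fmax - f.min())
    if i == 0 or i == len(grid) - 1:
        raise NoPeakError("maximum at window edge: monotone profile")
    if span == 0.0 or (fmax - f[-1]) < 1e-3 * span:
        raise NoPeakError("profile plateaus to the window end (sustained induction)")
    return float(grid[i])
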