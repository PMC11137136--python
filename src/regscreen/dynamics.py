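"""Delayed first-order linear model fitting and scoring for one regulator/target pair.

The screening method models the target transcript y as a single-input,
single-output, first-order linear time-invariant system driven by a candidate
regulator transcript u, with an input delay of an integer number of sampling
steps and a constant bias:

    y[k+1] = alpha * y[k] + beta * u[k - d] + gamma

``alpha`` is the discrete self-coefficient (degradation plus possible
autoregulation; for a stable continuous rate ``a`` sampled every ``step_min``
minutes, ``alpha = exp(a * step_min)``). ``beta`` is the input gain — its sign
classifies the candidate as activator (positive) or repressor (negative).
``gamma`` absorbs the unknown offset left over by background-corrected
intensities. Parameters are estimated by ordinary least squares on the
one-step-ahead prediction error, which is the exact minimiser of the
prediction-error criterion for this model class. The goodness of fit is then
scored on a *free-run* simulation (the model recursed from a single initial
condition, never re-anchored to data) with the normalised fitness

    fitness = 100 * (1 - ||y - yhat|| / ||y - mean(y)||)

which is 100 for a perfect reproduction, 0 for a model no better than the
constant mean predictor, and unbounded below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PairwiseModel",
    "PairwiseFit",
    "SeriesPair",
    "DegenerateFitError",
    "shift_input",
    "simulate",
    "fitness_score",
    "fit_pairwise",
    "fit_with_delay_scan",
]

ACTIVATOR = "activator"
REPRESSOR = "repressor"


class DegenerateFitError(ValueError):
    """Raised when a fit or score is undefined (rank-deficient regressors,
    constant output, or zero input gain)."""


@dataclass(frozen=True)
class PairwiseModel:
    """Discrete-time parameters of one delayed first-order pairwise model."""

    alpha: float
    beta: float
    gamma: float
    delay_steps: int = 0
    step_min: float = 20.0

    def __post_init__(self) -> None:
        if self.delay_steps < 0:
            raise ValueError(f"delay_steps must be >= 0, got {self.delay_steps}")
        for name in ("alpha", "beta", "gamma"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")

    @property
    def delay_min(self) -> float:
        """Input delay in minutes."""
        return self.delay_steps * self.step_min

    @property
    def continuous_a(self) -> float:
        """Continuous-time self-rate ln(alpha)/step (NaN for alpha <= 0)."""
        if self.alpha <= 0:
            return math.nan
        return math.log(self.alpha) / self.step_min

    @property
    def sign(self) -> str | None:
        if self.beta > 0:
            return ACTIVATOR
        if self.beta < 0:
            return REPRESSOR
        return None


@dataclass(frozen=True)
class SeriesPair:
    """An (input, output) pair of equal-length time series on a shared clock."""

    u: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "y", y)
        if u.ndim != 1 or y.ndim != 1:
            raise ValueError("u and y must be one-dimensional series")
        if u.shape != y.shape:
            raise ValueError(f"u and y lengths differ: {u.shape[0]} vs {y.shape[0]}")
        if u.shape[0] < 3:
            raise ValueError("series must have at least 3 points")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(y))):
            raise ValueError("series must be finite")


@dataclass(frozen=True)
class PairwiseFit:
    """One fitted (input, output, donor) model with its free-run fitness.

    ``fitness`` is NaN and ``sign`` is None when ``degenerate`` is set; such
    fits are excluded from ranking.
    """

    model: PairwiseModel
    fitness: float
    sign: str | None
    n_fit_points: int
    degenerate: bool = False
    input_id: str | None = None
    output_id: str | None = None
    donor_id: str | None = None

    def with_labels(self, input_id: str, output_id: str, donor_id: str) -> "PairwiseFit":
        return replace(self, input_id=input_id, output_id=output_id, donor_id=donor_id)


def shift_input(u: Sequence[float] | np.ndarray, d: int) -> np.ndarray:
    """Delay the input by ``d`` steps, truncating to the usable window.

    The returned series is aligned with output indices ``d .. N-1``: entry
    ``i`` of the result is ``u[d + i - d] = u[i]``, i.e. the input sample the
    delayed model pairs with output sample ``d + i``. No padding is ever
    introduced; delaying only shortens the window (length ``N - d``).
    """
    u = np.asarray(u, dtype=float)
    n = u.shape[0]
    if not 0 <= d < n - 2:
        raise ValueError(f"delay of {d} steps leaves no usable window for a series of length {n}")
    return u[: n - d]


def simulate(model: PairwiseModel, u: Sequence[float] | np.ndarray, y0: float) -> np.ndarray:
    """Free-run the model from ``y0`` at the first usable index.

    Returns ``yhat`` of length ``N - d`` aligned with output indices
    ``d .. N-1``: ``yhat[0] = y0`` and
    ``yhat[i+1] = alpha*yhat[i] + beta*u_delayed[i] + gamma``.
    The recursion is never re-anchored to observed data.
    """
    delayed = shift_input(u, model.delay_steps)
    m = delayed.shape[0]
    yhat = np.empty(m, dtype=float)
    yhat[0] = y0
    a, b, g = model.alpha, model.beta, model.gamma
    for i in range(m - 1):
        yhat[i + 1] = a * yhat[i] + b * delayed[i] + g
    return yhat


def fitness_score(y: Sequence[float] | np.ndarray, yhat: Sequence[float] | np.ndarray) -> float:
    """Normalised fitness in percent: 100*(1 - ||y-yhat|| / ||y-mean(y)||).

    100 iff ``yhat`` reproduces ``y`` exactly; 0 for the constant mean
    predictor; negative when the model is worse than the mean. Undefined for a
    constant observed series (zero denominator) — raises
    :class:`DegenerateFitError`.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"series lengths differ: {y.shape} vs {yhat.shape}")
    denom = np.linalg.norm(y - y.mean())
    if denom == 0.0:
        raise DegenerateFitError("fitness undefined for a constant observed series")
    return 100.0 * (1.0 - np.linalg.norm(y - yhat) / denom)


def _ols(X: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, int]:
    """Least-squares solve via SVD; returns (params, rank)."""
    theta, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    return theta, rank


def fit_pairwise(
    pair: SeriesPair,
    d: int = 0,
    step_min: float = 20.0,
) -> PairwiseFit:
    """Fit the delayed first-order model at a fixed delay ``d`` (in steps).

    Solves the one-step-ahead regression
    ``y[k+1] = alpha*y[k] + beta*u[k-d] + gamma`` over ``k = d .. N-2`` by
    ordinary least squares, then scores the free-run simulation started at the
    observed ``y[d]`` over the usable window. Rank-deficient regressors, a
    constant observed window, or an exactly zero input gain yield a degenerate
    fit (fitness NaN) rather than an exception.
    """
    u, y = pair.u, pair.y
    n = y.shape[0]
    delayed = shift_input(u, d)  # validates d; aligned with y[d:]
    window = n - d
    if window < 4:
        raise ValueError(
            f"usable window of {window} points after delay {d} is too short "
            "(need >= 4 points for 3 parameters)"
        )
    y_win = y[d:]
    X = np.column_stack([y_win[:-1], delayed[:-1], np.ones(window - 1)])
    z = y_win[1:]
    theta, rank = _ols(X, z)

    def _degenerate() -> PairwiseFit:
        model = PairwiseModel(0.0, 0.0, 0.0, d, step_min)
        return PairwiseFit(model, math.nan, None, window, degenerate=True)

    if rank < 3:
        return _degenerate()
    alpha, beta, gamma = (float(t) for t in theta)
    if beta == 0.0:
        return _degenerate()
    model = PairwiseModel(alpha, beta, gamma, d, step_min)
    if np.ptp(y_win) == 0.0:
        return _degenerate()
    yhat = simulate(model, u, y0=y_win[0])
    fit = fitness_score(y_win, yhat)
    return PairwiseFit(model, fit, model.sign, window)


def fit_with_delay_scan(
    pair: SeriesPair,
    delays: Sequence[int],
    step_min: float = 20.0,
) -> PairwiseFit:
    """Fit at every delay (in steps) and keep the highest-fitness model.

    Ties are broken toward the smallest delay; degenerate fits are excluded
    from the maximisation. If every delay is degenerate the returned fit is
    degenerate (at the smallest delay).
    """
    if len(delays) == 0:
        raise ValueError("delays must be non-empty")
    best: PairwiseFit | None = None
    first: PairwiseFit | None = None
    for d in sorted(int(d) for d in delays):
        fit = fit_pairwise(pair, d, step_min=step_min)
        if first is None:
            first = fit
        if fit.degenerate:
            continue
        if best is None or fit.fitness > best.fitness:
            best = fit
    return best if best is not None else first  # type: ignore[return-value]
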