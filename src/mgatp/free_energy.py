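"""Free-energy estimation from alchemical sampling output.

Two estimators are provided:

* **BAR** (Bennett acceptance ratio): the maximum-likelihood estimate of
  ΔF from forward and backward work samples.  Sign convention: forward
  values are the work of the 0→1 perturbation and backward values the work
  of the 1→0 perturbation, so for well-sampled data the two means bracket
  ±ΔF.  The self-consistency equation

      Σ_f 1/(1 + exp(M + β(W_f − ΔF))) = Σ_r 1/(1 + exp(−M + β(W_r + ΔF)))

  with M = ln(n_f/n_r) is solved by bracketed root finding (Brent) to a
  residual below 1e-10.  The reported uncertainty is the asymptotic
  (inverse-Fisher-information) standard error of the logistic likelihood.

* **TI** (thermodynamic integration): trapezoidal quadrature of the
  per-window mean ∂H/∂λ over the λ grid, after a per-window equilibration
  discard (default 100 ps of each 500 ps window).

A time-slice convergence check re-runs an estimator on sub-intervals of the
per-window time series (default full 100-500 ps, early 100-300 ps and late
300-500 ps slices) and flags estimates that drift beyond their combined
statistical errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import constants
from .errors import AnalysisError, ConvergenceError, MgatpError
from .structures import SampleSeries, Trajectory

__all__ = [
    "WorkSet",
    "LambdaSeries",
    "FreeEnergyEstimate",
    "discard_equilibration",
    "bar_estimate",
    "ti_integrate",
    "forward_backward_sd",
    "slice_convergence",
    "subsample_snapshots",
]


@dataclass
class WorkSet:
    """Forward/backward work samples and the inverse temperature.

    ``beta`` must be expressed in the inverse of the work unit; the default
    corresponds to 300 K with work in kJ/mol.
    """

    forward: np.ndarray
    backward: np.ndarray
    beta: float = constants.beta(300.0, "kJ/mol")
    unit_tag: str = "kJ/mol"

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if self.beta <= 0:
            raise MgatpError("beta must be positive")
        for name, arr in (("forward", self.forward), ("backward", self.backward)):
            if arr.size == 0:
                raise MgatpError(f"{name} work list is empty")
            if not np.all(np.isfinite(arr)):
                raise MgatpError(f"{name} work list contains non-finite values")


@dataclass
class LambdaSeries:
    """Per-window ∂H/∂λ sample series over a strictly increasing λ grid."""

    lambda_values: np.ndarray
    dhdl_samples: list[SampleSeries]

    def __post_init__(self):
        self.lambda_values = np.asarray(self.lambda_values, dtype=float)
        if self.lambda_values.size != len(self.dhdl_samples):
            raise MgatpError("one sample series required per lambda window")
        if self.lambda_values.size and (
            self.lambda_values.min() < 0 or self.lambda_values.max() > 1
        ):
            raise MgatpError("lambda values must lie in [0, 1]")
        if np.any(np.diff(self.lambda_values) <= 0):
            raise MgatpError("lambda grid must be strictly increasing")


@dataclass
class FreeEnergyEstimate:
    """A ΔG estimate with its uncertainty and provenance."""

    delta_g: float
    uncertainty: float
    method: str
    unit_tag: str = "kJ/mol"
    n_forward: int = 0
    n_backward: int = 0
    slices: list["FreeEnergyEstimate"] | None = None

    def __post_init__(self):
        if self.uncertainty < 0:
            raise MgatpError("uncertainty must be non-negative")


def discard_equilibration(series: SampleSeries, t_eq_ps: float) -> SampleSeries:
    """Drop samples with time < ``t_eq_ps`` (per-window equilibration)."""
    if t_eq_ps < 0:
        raise MgatpError("equilibration time must be non-negative")
    mask = series.times >= t_eq_ps
    if not np.any(mask):
        raise AnalysisError(
            f"no samples remain after discarding the first {t_eq_ps} ps"
        )
    return SampleSeries(
        times=series.times[mask], values=series.values[mask],
        unit_tag=series.unit_tag,
    )


def _bar_residual(delta_f: float, wf: np.ndarray, wr: np.ndarray,
                  beta: float, m_offset: float) -> float:
    lhs = expit(-(m_offset + beta * (wf - delta_f))).sum()
    rhs = expit(-(-m_offset + beta * (wr + delta_f))).sum()
    return lhs - rhs


def bar_estimate(work_set: WorkSet, tol: float = 1e-10) -> FreeEnergyEstimate:
    """Bennett-acceptance-ratio estimate of ΔF from a :class:`WorkSet`.

    The root of the self-consistency residual is bracketed by geometric
    expansion around the symmetric work midpoint and polished with Brent's
    method.  Raises :class:`ConvergenceError` with an overlap diagnostic when
    the work distributions do not overlap enough to bracket the root.
    """
    wf, wr, beta = work_set.forward, work_set.backward, work_set.beta
    m_offset = np.log(wf.size / wr.size)
    center = 0.5 * (wf.mean() - wr.mean())
    spread = max(wf.std(), wr.std(), 1.0 / beta)

    def g(x: float) -> float:
        return _bar_residual(x, wf, wr, beta, m_offset)

    # g is strictly increasing in delta_f; expand the bracket geometrically.
    half = spread
    lo, hi = center - half, center + half
    for _ in range(200):
        if g(lo) < 0 < g(hi):
            break
        half *= 2.0
        lo, hi = center - half, center + half
    else:
        raise ConvergenceError(
            "BAR root could not be bracketed; forward/backward work "
            "distributions do not overlap",
            diagnostic={
                "forward_mean": float(wf.mean()),
                "backward_mean": float(wr.mean()),
                "gap": float(wf.mean() + wr.mean()),
                "forward_sd": float(wf.std()),
                "backward_sd": float(wr.std()),
            },
        )
    delta_f = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=500)
    # Polish check: residual below tolerance relative to sample count.
    if abs(g(delta_f)) > tol * (wf.size + wr.size):
        raise ConvergenceError(
            f"BAR residual {g(delta_f):.3e} above tolerance", diagnostic={}
        )
    # Asymptotic SE: inverse Fisher information of the logistic likelihood.
    # Vanishing information means the residual plateaus at zero over a wide
    # interval — the distributions do not overlap and the root is arbitrary.
    p_f = expit(m_offset + beta * (wf - delta_f))
    p_r = expit(m_offset + beta * (-wr - delta_f))
    info = beta ** 2 * (np.sum(p_f * (1 - p_f)) + np.sum(p_r * (1 - p_r)))
    if not np.isfinite(info) or info <= 1e-8:
        raise ConvergenceError(
            "work distributions do not overlap: the BAR likelihood carries "
            "no information about the free-energy difference",
            diagnostic={
                "forward_mean": float(wf.mean()),
                "backward_mean": float(wr.mean()),
                "gap": float(wf.mean() + wr.mean()),
                "fisher_information": float(info),
            },
        )
    se = float(1.0 / np.sqrt(info))
    return FreeEnergyEstimate(
        delta_g=float(delta_f), uncertainty=se, method="BAR",
        unit_tag=work_set.unit_tag, n_forward=int(wf.size), n_backward=int(wr.size),
    )


def exponential_averaging_bounds(work_set: WorkSet) -> tuple[float, float]:
    """Forward and reverse exponential-averaging (Zwanzig) estimates, which
    bracket the BAR estimate on overlapping data."""
    wf, wr, beta = work_set.forward, work_set.backward, work_set.beta
    fwd = -(1.0 / beta) * _logmeanexp(-beta * wf)
    rev = (1.0 / beta) * _logmeanexp(-beta * wr)
    return float(fwd), float(rev)


def _logmeanexp(x: np.ndarray) -> float:
    xmax = x.max()
    return float(xmax + np.log(np.mean(np.exp(x - xmax))))


def ti_integrate(
    lambda_series: LambdaSeries,
    t_eq_ps: float = 0.0,
) -> FreeEnergyEstimate:
    """Trapezoidal TI estimate: integrate per-window mean ∂H/∂λ over λ.

    ``t_eq_ps`` discards the start of every window before averaging.
    The returned uncertainty is 0; combine forward and backward runs with
    :func:`forward_backward_sd` for the two-point spread.
    """
    if lambda_series.lambda_values.size < 2:
        raise MgatpError("TI requires at least two lambda windows")
    means = []
    unit = "kJ/mol"
    for s in lambda_series.dhdl_samples:
        retained = discard_equilibration(s, t_eq_ps) if t_eq_ps > 0 else s
        means.append(float(retained.values.mean()))
        unit = s.unit_tag
    delta_g = float(np.trapezoid(means, lambda_series.lambda_values))
    return FreeEnergyEstimate(
        delta_g=delta_g, uncertainty=0.0, method="TI", unit_tag=unit,
        n_forward=sum(len(s) for s in lambda_series.dhdl_samples),
    )


def forward_backward_sd(estimate_fwd: float | FreeEnergyEstimate,
                        estimate_bwd: float | FreeEnergyEstimate) -> float:
    """Two-point sample SD of a forward and a backward estimate of the same
    quantity: |a − b| / sqrt(2)."""
    a = estimate_fwd.delta_g if isinstance(estimate_fwd, FreeEnergyEstimate) else float(estimate_fwd)
    b = estimate_bwd.delta_g if isinstance(estimate_bwd, FreeEnergyEstimate) else float(estimate_bwd)
    return abs(a - b) / np.sqrt(2.0)


DEFAULT_SLICES: tuple[tuple[float, float], ...] = ((100.0, 500.0), (100.0, 300.0), (300.0, 500.0))


@dataclass
class SliceReport:
    """Per-time-slice estimates plus a drift flag."""

    slices: list[FreeEnergyEstimate | None]
    windows: list[tuple[float, float]]
    errors: list[str | None]
    spread: float
    drift_flagged: bool


def _slice_series(series: SampleSeries, lo: float, hi: float) -> SampleSeries:
    mask = (series.times >= lo) & (series.times < hi)
    if not np.any(mask):
        raise AnalysisError(f"time slice [{lo}, {hi}) ps contains no samples")
    return SampleSeries(series.times[mask], series.values[mask], series.unit_tag)


def slice_convergence(
    data,
    slice_windows: Sequence[tuple[float, float]] = DEFAULT_SLICES,
    beta: float = constants.beta(300.0, "kJ/mol"),
    drift_nsigma: float = 3.0,
) -> SliceReport:
    """Re-run an estimator on time slices of its input.

    ``data`` is either a ``(forward SampleSeries, backward SampleSeries)``
    pair (BAR per slice) or a :class:`LambdaSeries` (TI per slice; windows
    are sliced in time).  A slice with no samples yields an error entry while
    the other slices are still reported.  Estimates further apart than
    ``drift_nsigma`` combined standard errors raise the drift flag.
    """
    estimates: list[FreeEnergyEstimate | None] = []
    errors: list[str | None] = []
    for lo, hi in slice_windows:
        try:
            if isinstance(data, LambdaSeries):
                sliced = LambdaSeries(
                    lambda_values=data.lambda_values,
                    dhdl_samples=[_slice_series(s, lo, hi) for s in data.dhdl_samples],
                )
                est = ti_integrate(sliced)
            else:
                fwd, bwd = data
                ws = WorkSet(
                    forward=_slice_series(fwd, lo, hi).values,
                    backward=_slice_series(bwd, lo, hi).values,
                    beta=beta, unit_tag=fwd.unit_tag,
                )
                est = bar_estimate(ws)
            estimates.append(est)
            errors.append(None)
        except (AnalysisError, ConvergenceError, MgatpError) as exc:
            estimates.append(None)
            errors.append(str(exc))
    valid = [e for e in estimates if e is not None]
    spread = max((e.delta_g for e in valid), default=0.0) - min(
        (e.delta_g for e in valid), default=0.0
    )
    flagged = False
    for i in range(len(valid)):
        for j in range(i + 1, len(valid)):
            combined = np.hypot(valid[i].uncertainty, valid[j].uncertainty)
            if combined > 0 and abs(valid[i].delta_g - valid[j].delta_g) > drift_nsigma * combined:
                flagged = True
    return SliceReport(
        slices=estimates, windows=list(slice_windows), errors=errors,
        spread=float(spread), drift_flagged=flagged,
    )


def subsample_snapshots(
    trajectory: Trajectory | Sequence[float],
    start_ps: float,
    stride_ps: float,
) -> list[int]:
    """Frame indices at times >= ``start_ps`` taken every ``stride_ps``.

    Works on a :class:`Trajectory` or a plain time list.  Robust to uneven
    spacing: the next retained frame is the first one at or beyond the next
    grid target.  This is the snapshot schedule used for post-equilibration
    endpoint analyses (e.g. 900 snapshots of 90 ns at a 100 ps stride after
    a 10 ns equilibration).
    """
    if stride_ps <= 0:
        raise MgatpError("stride must be positive")
    times = trajectory.times if isinstance(trajectory, Trajectory) else np.asarray(trajectory, dtype=float)
    indices: list[int] = []
    target = start_ps
    for i, t in enumerate(times):
        if t >= target - 1e-9:
            indices.append(i)
            target = t + stride_ps
    return indices
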