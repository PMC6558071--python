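"""Logistic growth curves and per-individual least-squares fits.

The longitudinal trait is modelled by the three-parameter logistic law

    g(t) = a / (1 + b * exp(-r * t))

where ``a`` is the asymptote (trait units), ``b`` shapes the initial
condition (g(0) = a / (1 + b)) and ``r`` is the relative growth rate per
time unit.  Genotype mean vectors for the joint dynamic + static model are
the curve evaluated on the measurement grid with the static-trait mean
appended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LogisticParams",
    "TimeGrid",
    "CurveFit",
    "logistic",
    "fit_logistic_ls",
    "genotype_mean_vector",
]


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic growth curve g(t) = a / (1 + b e^{-rt}).

    a : asymptote, trait units, must be > 0
    b : initial-condition shape parameter, dimensionless, > -1 so the
        denominator stays positive for t >= 0
    r : relative growth rate per time unit
    """

    a: float
    b: float
    r: float

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.r)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite logistic parameters {vals}")
        if self.a <= 0:
            raise ValueError(f"asymptote a must be positive, got {self.a}")
        if self.b <= -1:
            raise ValueError(f"shape b must exceed -1, got {self.b}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.r], dtype=float)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing measurement times; at least 3 points are needed
    to identify the three logistic parameters."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("times must be a 1-D vector")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class CurveFit:
    """Result of a per-individual logistic least-squares fit."""

    params: LogisticParams
    r_squared: float
    residuals: np.ndarray
    sse: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def logistic(t, p: LogisticParams):
    """Evaluate g(t) = a / (1 + b e^{-rt}); vectorised over ``t``.

    Raises ValueError if the denominator is non-positive anywhere on ``t``.
    """
    t = np.asarray(t, dtype=float)
    denom = 1.0 + p.b * np.exp(-p.r * t)
    if np.any(denom <= 0):
        raise ValueError(
            f"logistic denominator non-positive for params {p} on given times"
        )
    out = p.a / denom
    return out if out.ndim else float(out)


def _logistic_raw(t: np.ndarray, a: float, b: float, r: float) -> np.ndarray:
    return a / (1.0 + b * np.exp(-r * t))


def fit_logistic_ls(
    y: np.ndarray,
    grid: TimeGrid,
    r_starts: tuple[float, ...] = (0.1, 0.5, 1.0),
) -> CurveFit:
    """Deterministic multi-start least-squares logistic fit of one series.

    Starting values are data driven: a0 = 1.05 * max(y); r0 runs over
    ``r_starts``; b0 is solved from the first observation under (a0, r0).
    Each start is refined by bounded trust-region least squares inside the
    box a in (0, 10*max(y)], b in (-0.99, 1e3], r in [-5, 5]; the best SSE
    wins, ties broken by start order.  Degenerate (near-constant) series are
    returned with an explanatory flag rather than raising.
    """
    t = grid.times
    y = np.asarray(y, dtype=float)
    if y.shape != t.shape:
        raise ValueError(f"series length {y.size} != grid length {t.size}")
    if len(grid) < 3:
        raise ValueError("need at least 3 time points to fit 3 parameters")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")

    ymax = float(np.max(y))
    flags: list[str] = []
    if ymax <= 0 or np.ptp(y) < 1e-12 * max(1.0, abs(ymax)):
        # constant / non-positive series: logistic degenerates to a flat line
        a0 = max(abs(ymax), 1e-6)
        p = LogisticParams(a=2 * a0, b=1.0 - 1e-9 if ymax <= 0 else (2 * a0 / max(ymax, 1e-12) - 1.0), r=0.0)
        resid = y - logistic(t, p)
        return CurveFit(
            params=p,
            r_squared=0.0,
            residuals=resid,
            sse=float(resid @ resid),
            converged=False,
            flags=["degenerate-series"],
        )

    a0 = 1.05 * ymax
    lo = np.array([1e-8, -0.99, -5.0])
    hi = np.array([10.0 * ymax, 1e3, 5.0])

    best = None
    for r0 in r_starts:
        # b0 from the first point: y1 = a0/(1 + b0 e^{-r0 t1})
        y1 = y[0] if y[0] > 1e-8 * ymax else 1e-8 * ymax
        b0 = (a0 / y1 - 1.0) * np.exp(r0 * t[0])
        x0 = np.clip(np.array([a0, b0, r0]), lo + 1e-10, hi - 1e-10)
        try:
            sol = least_squares(
                lambda th: _logistic_raw(t, *th) - y,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, sol)

    if best is None:
        p = LogisticParams(a=a0, b=1.0, r=0.1)
        resid = y - logistic(t, p)
        return CurveFit(p, 0.0, resid, float(resid @ resid), False, ["no-start-converged"])

    sse, sol = best
    a, b, r = sol.x
    p = LogisticParams(a=float(a), b=float(b), r=float(r))
    resid = y - logistic(t, p)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    if abs(r) < 1e-6:
        flags.append("near-zero-rate")
    if not sol.success:
        flags.append("optimizer-not-converged")
    return CurveFit(
        params=p,
        r_squared=float(r2),
        residuals=resid,
        sse=sse,
        converged=bool(sol.success),
        flags=flags,
    )


def genotype_mean_vector(p: LogisticParams, mu_z: float, grid: TimeGrid) -> np.ndarray:
    """Genotype mean vector (g(t_1), ..., g(t_T), mu_z) of length T + 1.

    This is the mean of the joint dynamic + static observation vector for
    one genotype class: the logistic curve on the grid with the static-trait
    mean appended as the last coordinate.
    """
    g = np.atleast_1d(logistic(grid.times, p))
    return np.concatenate([g, [float(mu_z)]])
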