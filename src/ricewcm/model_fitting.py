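"""Curve fitting for the panicle-layer yield chain.

Three fits feed the yield pipeline:

* a saturating backscatter-water curve ``sigma0 = C - exp(-(x - a)/b)``
  fitted against panicle-layer areal water x = W1*h1 (dB domain by default);
* ordinary linear calibrations of ear wet weight (kg/m^2) and grain density
  (grains/m^2) against W1*h1;
* a linear relation between stem-leaf and panicle areal water used to split
  a total-canopy-water retrieval into its two layers.

All fits report R^2 = 1 - SS_res/SS_tot (pseudo-R^2 for the nonlinear
curve) and, for the curve, the residual RMSE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats

from .wcm_core import InversionCoeffs, SaturationError, Scale

__all__ = [
    "LinearCalibration",
    "WCMCurveFit",
    "StemLeafRelation",
    "DegenerateFitError",
    "CurveFitFailure",
    "fit_linear_calibration",
    "predict_linear",
    "fit_wcm_curve",
    "invert_wcm_curve",
    "split_total_water",
]


class DegenerateFitError(ValueError):
    """Regression inputs carry no usable variation."""


class CurveFitFailure(RuntimeError):
    """Nonlinear fit did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class LinearCalibration:
    """An ordinary least-squares line y = slope*x + intercept with its R^2."""

    slope: float
    intercept: float
    r2: float
    x_name: str = "x"
    y_name: str = "y"
    n_samples: int = 0
    degenerate_y: bool = False  # SS_tot == 0: r2 reported as 0 by convention

    def predict(self, x):
        return predict_linear(self, x)


@dataclass(frozen=True)
class WCMCurveFit:
    """Fitted saturating backscatter curve sigma0 = C - exp(-(x - a)/b)."""

    coeffs: InversionCoeffs
    r2: float
    rmse: float
    sigma0_scale: Scale = Scale.DB
    n_samples: int = 0

    @property
    def C(self) -> float:
        return self.coeffs.C

    @property
    def a(self) -> float:
        return self.coeffs.a

    @property
    def b(self) -> float:
        return self.coeffs.b

    def forward(self, w1h1):
        """Model prediction sigma0(x) = C - exp(-(x - a)/b)."""
        x = np.asarray(w1h1, dtype=float)
        out = self.C - np.exp(-(x - self.a) / self.b)
        return float(out) if np.isscalar(w1h1) else out

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "C": self.C,
                    "a": self.a,
                    "b": self.b,
                    "r2": self.r2,
                    "rmse": self.rmse,
                    "scale": self.sigma0_scale.value,
                    "n": self.n_samples,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "WCMCurveFit":
        obj = json.loads(Path(path).read_text())
        scale = Scale(obj.get("scale", "dB"))
        return cls(
            coeffs=InversionCoeffs(a=obj["a"], b=obj["b"], C=obj["C"], scale=scale),
            r2=obj.get("r2", float("nan")),
            rmse=obj.get("rmse", float("nan")),
            sigma0_scale=scale,
            n_samples=obj.get("n", 0),
        )


@dataclass(frozen=True)
class StemLeafRelation:
    """Linear relation w2h2 = p*w1h1 + q between the layer areal waters."""

    p: float
    q: float
    r2: float = float("nan")

    @classmethod
    def from_calibration(cls, cal: LinearCalibration) -> "StemLeafRelation":
        return cls(p=cal.slope, q=cal.intercept, r2=cal.r2)


def _as_finite_1d(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float).ravel()
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} contains non-finite values")
    return out


def fit_linear_calibration(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
) -> LinearCalibration:
    """OLS line through (x, y) with R^2 = 1 - SS_res/SS_tot.

    Constant y is reported with slope 0 and r2 = 0 (flagged ``degenerate_y``);
    constant x is an error since no slope is identifiable.
    """
    xv = _as_finite_1d(x, "x")
    yv = _as_finite_1d(y, "y")
    if xv.size != yv.size:
        raise ValueError(f"x and y lengths differ: {xv.size} vs {yv.size}")
    if xv.size < 3:
        raise ValueError(f"need at least 3 samples, got {xv.size}")
    if np.ptp(xv) == 0:
        raise DegenerateFitError("x has zero variance; slope unidentifiable")

    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0.0:
        return LinearCalibration(
            slope=0.0, intercept=float(yv[0]), r2=0.0,
            x_name=x_name, y_name=y_name, n_samples=xv.size, degenerate_y=True,
        )
    res = stats.linregress(xv, yv)
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        x_name=x_name,
        y_name=y_name,
        n_samples=xv.size,
    )


def predict_linear(cal: LinearCalibration, x):
    """Evaluate the calibration line at x (scalar or array)."""
    out = cal.slope * np.asarray(x, dtype=float) + cal.intercept
    return float(out) if np.isscalar(x) else out


def _curve_residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    C, a, b = theta
    return (C - np.exp(-(x - a) / b)) - y


def _curve_jacobian(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    C, a, b = theta
    e = np.exp(-(x - a) / b)
    jac = np.empty((x.size, 3))
    jac[:, 0] = 1.0
    jac[:, 1] = -e / b
    jac[:, 2] = -e * (x - a) / b**2
    return jac


def fit_wcm_curve(
    w1h1: Sequence[float],
    sigma0_db: Sequence[float],
    init: Optional[Tuple[float, float, float]] = None,
    sigma0_scale: Scale = Scale.DB,
    max_restarts: int = 5,
    seed: int = 0,
) -> WCMCurveFit:
    """Nonlinear least squares of sigma0 = C - exp(-(x - a)/b) on plot data.

    Trust-region reflective least squares with the analytic Jacobian and the
    bound C > max(sigma0) (the asymptote must sit above every observation for
    the log inversion to exist), b > 0. Default start: C = max(sigma0) + 1,
    b = half the x range, a solved exactly from the median point. Up to
    ``max_restarts`` jittered restarts before declaring failure.
    """
    xv = _as_finite_1d(w1h1, "w1h1")
    yv = _as_finite_1d(sigma0_db, "sigma0")
    if xv.size != yv.size:
        raise ValueError("w1h1 and sigma0 lengths differ")
    if np.unique(xv).size < 4:
        raise ValueError(f"need >= 4 distinct w1h1 values, got {np.unique(xv).size}")

    y_max = float(yv.max())
    eps = 1e-9 + 1e-6 * max(1.0, abs(y_max))
    # physically motivated box; it also keeps the near-flat (saturated-curve)
    # likelihood valley from running away. C within 30 dB above the data;
    # b = cos(theta)/2D stays under 10 kg/m^2 for any plausible crop
    # attenuation; a = b*ln(C - sigma0_bg) then stays within ~50 of the data.
    lower = np.array([y_max + eps, float(xv.min()) - 50.0, 1e-6])
    upper = np.array([y_max + 30.0, float(xv.max()) + 50.0, 10.0])

    if init is None:
        C0 = y_max + 1.0
        b0 = max(float(np.ptp(xv)) / 2.0, 1e-3)
        i_med = int(np.argsort(xv)[xv.size // 2])
        # a from the exact curve through the median point at (C0, b0)
        gap = max(C0 - yv[i_med], eps)
        a0 = xv[i_med] + b0 * math.log(gap)
        theta0 = np.array([C0, a0, b0])
    else:
        theta0 = np.asarray(init, dtype=float)
        theta0[0] = max(theta0[0], y_max + 2 * eps)
        theta0[2] = max(theta0[2], 1e-6)

    rng = np.random.default_rng(seed)
    best = None
    attempts = []
    for attempt in range(max_restarts + 1):
        start = theta0.copy()
        if attempt > 0:
            start[0] = y_max + eps + abs(start[0] - y_max) * rng.uniform(0.3, 3.0)
            start[1] = start[1] + rng.normal(0.0, max(abs(start[1]), 0.5))
            start[2] = start[2] * rng.uniform(0.3, 3.0)
        start = np.clip(start, lower + 1e-12, upper - 1e-12)
        try:
            res = optimize.least_squares(
                _curve_residuals,
                start,
                jac=_curve_jacobian,
                bounds=(lower, upper),
                args=(xv, yv),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-10,
                max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - solver-internal failure
            attempts.append({"start": start.tolist(), "error": str(exc)})
            continue
        attempts.append({"start": start.tolist(), "cost": float(res.cost), "status": int(res.status)})
        # status 0 (iteration budget) still yields a usable point in the
        # saturated regime where the cost surface is nearly flat; keep the
        # lowest-cost finite solution across attempts
        if np.all(np.isfinite(res.x)) and (best is None or res.cost < best.cost):
            best = res
        # a proper convergence flag from the analytic start is final; only
        # iteration-budget exits (flat saturated valley) warrant restarts
        if best is not None and best.status > 0:
            break

    if best is None:
        raise CurveFitFailure(
            "saturating-curve fit failed to converge after restarts",
            diagnostics={"attempts": attempts, "n": int(xv.size)},
        )

    C, a, b = (float(v) for v in best.x)
    resid = _curve_residuals(best.x, xv, yv)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rmse = math.sqrt(ss_res / xv.size)
    return WCMCurveFit(
        coeffs=InversionCoeffs(a=a, b=b, C=C, scale=sigma0_scale),
        r2=r2,
        rmse=rmse,
        sigma0_scale=sigma0_scale,
        n_samples=int(xv.size),
    )


def invert_wcm_curve(sigma0_db, fit: WCMCurveFit):
    """Panicle-layer areal water from backscatter: a - b*ln(C - sigma0).

    Exact inverse of the fitted curve; raises :class:`SaturationError` if any
    value reaches the asymptote C. Accepts scalars or arrays.
    """
    s = np.asarray(sigma0_db, dtype=float)
    if np.any(s >= fit.C):
        raise SaturationError(f"sigma0 at or above fitted asymptote C={fit.C}")
    out = fit.a - fit.b * np.log(fit.C - s)
    return float(out) if np.isscalar(sigma0_db) else out


def split_total_water(total: float, rel: StemLeafRelation) -> Tuple[float, float]:
    """Split total canopy areal water into (w1h1, w2h2) via the layer relation.

    With w2h2 = p*w1h1 + q, total = w1h1 + w2h2 gives
    w1h1 = (total - q)/(1 + p); the split conserves the total exactly.
    A negative panicle share (total below the relation's intercept) is
    returned unclipped — callers treat it as an out-of-domain flag.
    """
    if rel.p == -1.0:
        raise ZeroDivisionError("stem-leaf slope p = -1 makes the split singular")
    w1h1 = (total - rel.q) / (1.0 + rel.p)
    w2h2 = total - w1h1
    return w1h1, w2h2
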