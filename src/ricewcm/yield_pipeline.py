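"""Yield estimation and verification arithmetic.

Chains a fitted backscatter-water curve and a linear calibration into
per-parcel yield (kg/mu), converts between Chinese land units
(1 hm^2 = 15 mu, 1 mu = 666.667 m^2), applies wet-to-dry grain conversion,
and scores estimates against field truth with absolute error, relative
error and precision = 100% - RE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model_fitting import LinearCalibration, WCMCurveFit, invert_wcm_curve, predict_linear
from .sar_raster import BackscatterRaster, PlotFootprint, extract_plot_sigma0

__all__ = [
    "M2_PER_MU",
    "MU_PER_HM2",
    "FieldTruthRecord",
    "YieldEstimate",
    "AccuracyReport",
    "SaturationWarning",
    "wet_ear_yield_per_mu",
    "dry_from_wet",
    "grain_yield_per_mu",
    "kg_per_hm2_to_kg_per_mu",
    "kg_per_mu_to_kg_per_hm2",
    "parcel_average",
    "accuracy_report",
    "estimate_parcel_yield",
    "verification_table",
]

M2_PER_MU = 666.667
MU_PER_HM2 = 15.0

# wet->dry mass retention of harvested grain, calibration-site specific
MOISTURE_FACTOR_MATURE = 0.69
MOISTURE_FACTOR_GROUTING = 0.72


class SaturationWarning(UserWarning):
    """A large share of pixels sat at/above the curve asymptote."""


@dataclass(frozen=True)
class FieldTruthRecord:
    """Measured yield components for one parcel.

    ``effective_ears`` is in 10^4 ears/hm^2; ``total_output`` kg/hm^2;
    ``yield_per_mu`` the dried yield in kg/mu.
    """

    parcel_id: str
    effective_ears: float
    grains_per_ear_total: float
    grains_per_ear_filled: float
    thousand_grain_weight: float
    total_output: float
    yield_per_mu: float

    def __post_init__(self) -> None:
        if self.grains_per_ear_filled > self.grains_per_ear_total:
            raise ValueError("filled grains per ear cannot exceed total grains per ear")
        for name in (
            "effective_ears", "grains_per_ear_total", "grains_per_ear_filled",
            "thousand_grain_weight", "total_output", "yield_per_mu",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def filled_fraction(self) -> float:
        return self.grains_per_ear_filled / self.grains_per_ear_total

    def check_unit_consistency(self, tol_kg_mu: float = 0.5) -> Optional[str]:
        """Flag a printed kg/mu that disagrees with total_output/15."""
        implied = kg_per_hm2_to_kg_per_mu(self.total_output)
        if abs(implied - self.yield_per_mu) > tol_kg_mu:
            return (
                f"parcel {self.parcel_id}: printed {self.yield_per_mu} kg/mu vs "
                f"{implied:.2f} kg/mu implied by {self.total_output} kg/hm^2"
            )
        return None


@dataclass(frozen=True)
class YieldEstimate:
    """Model yield for one parcel, kg/mu; wet weight absent for the grain model."""

    parcel_id: str
    model_name: str
    dry_yield_mu: float
    wet_yield_mu: Optional[float] = None
    source: str = "wet_ear_model"
    n_units: int = 0
    n_saturated: int = 0

    def __post_init__(self) -> None:
        if self.wet_yield_mu is not None and self.dry_yield_mu > self.wet_yield_mu + 1e-9:
            raise ValueError("dry yield cannot exceed wet yield")


@dataclass(frozen=True)
class AccuracyReport:
    """Estimated vs measured yield with AE (kg/mu), RE (%) and precision (%)."""

    estimated: float
    measured: float
    ae: float
    re: float
    precision: float

    def rounded(self, ndigits: int = 2) -> "AccuracyReport":
        """Display copy rounded half-up to ``ndigits`` (report formatting)."""
        def r(v: float) -> float:
            from decimal import ROUND_HALF_UP, Decimal
            return float(Decimal(repr(float(v))).quantize(Decimal(f"1e-{ndigits}"), ROUND_HALF_UP))
        return AccuracyReport(r(self.estimated), r(self.measured), r(self.ae), r(self.re), r(self.precision))


def wet_ear_yield_per_mu(ear_wet_kg_m2: float) -> float:
    """Areal ear wet weight (kg/m^2) -> wet yield per mu (kg/mu)."""
    if ear_wet_kg_m2 < 0:
        raise ValueError("ear wet weight must be >= 0")
    return ear_wet_kg_m2 * M2_PER_MU


def dry_from_wet(wet_kg_mu: float, moisture_factor: float) -> float:
    """Dried grain yield from wet yield via a mass-retention factor in (0, 1]."""
    if not 0.0 < moisture_factor <= 1.0:
        raise ValueError(f"moisture_factor must be in (0, 1], got {moisture_factor}")
    return wet_kg_mu * moisture_factor


def grain_yield_per_mu(
    grains_m2: float,
    thousand_grain_weight_g: float,
    filled_fraction: float = 1.0,
) -> float:
    """Grain density (grains/m^2) -> dry yield (kg/mu).

    grains/m^2 x filled fraction x TGW/1000 gives g/m^2, scaled by
    666.667 m^2/mu and /1000 g/kg.
    """
    if grains_m2 < 0 or thousand_grain_weight_g <= 0:
        raise ValueError("grain density must be >= 0 and TGW positive")
    if not 0.0 < filled_fraction <= 1.0:
        raise ValueError(f"filled_fraction must be in (0, 1], got {filled_fraction}")
    g_per_m2 = grains_m2 * filled_fraction * thousand_grain_weight_g / 1000.0
    return g_per_m2 * M2_PER_MU / 1000.0


def kg_per_hm2_to_kg_per_mu(x: float) -> float:
    """kg per hectare -> kg per mu (15 mu per hectare)."""
    if x < 0:
        raise ValueError("yield must be >= 0")
    return x / MU_PER_HM2


def kg_per_mu_to_kg_per_hm2(x: float) -> float:
    if x < 0:
        raise ValueError("yield must be >= 0")
    return x * MU_PER_HM2


def parcel_average(values: Sequence[float]) -> float:
    """Arithmetic mean across fields making up a combined parcel."""
    vals = list(values)
    if not vals:
        raise ValueError("parcel_average needs at least one value")
    return float(np.mean(vals))


def accuracy_report(estimated_kg_mu: float, measured_kg_mu: float) -> AccuracyReport:
    """Score an estimate: AE = |est - meas|, RE = 100*AE/meas, P = 100 - RE."""
    if measured_kg_mu <= 0:
        raise ValueError("measured yield must be positive")
    ae = abs(estimated_kg_mu - measured_kg_mu)
    re = 100.0 * ae / measured_kg_mu
    return AccuracyReport(
        estimated=estimated_kg_mu,
        measured=measured_kg_mu,
        ae=ae,
        re=re,
        precision=100.0 - re,
    )


def _sigma0_from_source(
    source: Union[pd.DataFrame, Tuple[BackscatterRaster, Iterable[PlotFootprint]]],
) -> np.ndarray:
    """Collect per-unit sigma0 (dB) from a plot table or (raster, footprints)."""
    if isinstance(source, pd.DataFrame):
        if "sigma0_db" not in source.columns:
            raise ValueError("plot table must carry a sigma0_db column")
        if len(source) == 0:
            raise ValueError("plot table is empty")
        return source["sigma0_db"].to_numpy(dtype=float)
    raster, footprints = source
    fps = list(footprints)
    if not fps:
        raise ValueError("no plot footprints supplied")
    return np.array([extract_plot_sigma0(raster, fp).sigma0_db for fp in fps])


def estimate_parcel_yield(
    source: Union[pd.DataFrame, Tuple[BackscatterRaster, Iterable[PlotFootprint]]],
    fit: WCMCurveFit,
    calibration: LinearCalibration,
    parcel_id: str = "parcel",
    model_name: str = "wet_ear",
    source_kind: str = "wet_ear_model",
    moisture_factor: float = MOISTURE_FACTOR_MATURE,
    thousand_grain_weight_g: float = 25.0,
    filled_fraction: float = 1.0,
    saturation_margin_db: float = 1e-9,
) -> Tuple[YieldEstimate, pd.DataFrame]:
    """Parcel yield from backscatter via the fitted curve and calibration.

    Per unit (plot row or footprint): sigma0 -> W1*h1 (curve inversion) ->
    calibration prediction -> unit conversions -> parcel mean. Units whose
    sigma0 reaches the curve asymptote are counted as saturated and dropped
    from the mean; past 50% saturated a :class:`SaturationWarning` is issued.

    Returns the parcel :class:`YieldEstimate` and a per-unit table with the
    intermediate chain (sigma0_db, w1h1, prediction, yield).
    """
    sigma0 = _sigma0_from_source(source)
    saturated = sigma0 >= fit.C - saturation_margin_db
    n_sat = int(saturated.sum())
    if n_sat == sigma0.size:
        raise ValueError("every unit is saturated; no yield can be inverted")
    if n_sat > 0.5 * sigma0.size:
        warnings.warn(
            f"{parcel_id}: {n_sat}/{sigma0.size} units saturated (sigma0 >= C)",
            SaturationWarning,
            stacklevel=2,
        )

    ok = ~saturated
    w1h1 = np.full(sigma0.shape, np.nan)
    w1h1[ok] = invert_wcm_curve(sigma0[ok], fit)
    pred = np.full(sigma0.shape, np.nan)
    pred[ok] = predict_linear(calibration, w1h1[ok])
    pred[ok] = np.maximum(pred[ok], 0.0)

    per_unit = pd.DataFrame({"sigma0_db": sigma0, "saturated": saturated, "w1h1": w1h1})
    if source_kind == "wet_ear_model":
        wet = np.where(ok, pred * M2_PER_MU, np.nan)
        dry = wet * moisture_factor
        per_unit["ear_wet_kg_m2"] = pred
        per_unit["wet_yield_mu"] = wet
        per_unit["dry_yield_mu"] = dry
        estimate = YieldEstimate(
            parcel_id=parcel_id,
            model_name=model_name,
            wet_yield_mu=float(np.nanmean(wet)),
            dry_yield_mu=float(np.nanmean(dry)),
            source=source_kind,
            n_units=int(sigma0.size),
            n_saturated=n_sat,
        )
    elif source_kind == "grain_model":
        dry = np.where(
            ok,
            [grain_yield_per_mu(g, thousand_grain_weight_g, filled_fraction) if np.isfinite(g) else np.nan
             for g in np.maximum(pred, 0.0)],
            np.nan,
        )
        per_unit["grains_m2"] = pred
        per_unit["dry_yield_mu"] = dry
        estimate = YieldEstimate(
            parcel_id=parcel_id,
            model_name=model_name,
            wet_yield_mu=None,
            dry_yield_mu=float(np.nanmean(dry)),
            source=source_kind,
            n_units=int(sigma0.size),
            n_saturated=n_sat,
        )
    else:
        raise ValueError(f"unknown source_kind: {source_kind!r}")
    return estimate, per_unit


def verification_table(
    estimates: List[YieldEstimate],
    truths: List[FieldTruthRecord],
) -> pd.DataFrame:
    """Join estimates to field truth and score each, mirroring a yield
    verification table (estimated wet/dry, measured, AE, RE, precision)."""
    truth_by_id = {t.parcel_id: t for t in truths}
    rows = []
    for est in estimates:
        truth = truth_by_id.get(est.parcel_id)
        if truth is None:
            raise KeyError(f"no field truth for parcel {est.parcel_id}")
        rep = accuracy_report(est.dry_yield_mu, truth.yield_per_mu)
        rows.append(
            {
                "parcel_id": est.parcel_id,
                "model": est.model_name,
                "wet_yield_mu": est.wet_yield_mu,
                "dry_yield_mu": est.dry_yield_mu,
                "measured_mu": truth.yield_per_mu,
                "ae_kg_mu": rep.ae,
                "re_pct": rep.re,
                "precision_pct": rep.precision,
            }
        )
    return pd.DataFrame(rows)
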