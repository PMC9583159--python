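"""Synthetic plot surveys, field truth and speckled rasters.

The generator reproduces the statistical structure the analysis assumes so
every pipeline stage can be exercised without field data:

* panicle-layer areal water ``w1h1`` uniform over the survey range
  (0.3-0.8 kg/m^2 for a mature parcel, 0.5-1.7 kg/m^2 at grouting stage);
* stem-leaf water linearly tied to panicle water, ``w2h2 = p*w1h1 + q``,
  plus truncated Gaussian noise;
* backscatter following the saturating curve ``sigma0 = C - exp(-(x-a)/b)``
  in dB plus additive Gaussian noise (the domain the curve is fitted in);
* ear wet weight and grain density as linear calibrations of ``w1h1`` with
  truncated Gaussian noise;
* rasters built by nearest-plot assignment of the plot backscatter field
  with multiplicative gamma speckle (shape = equivalent number of looks)
  applied in linear power.

Two presets mirror the two study conditions: a fully mature parcel
("parcel B mode") and a grouting-stage composite parcel ("C+D+E mode"),
with truth parameters equal to the respective fitted models. Everything is
deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_fitting import StemLeafRelation
from .sar_raster import BackscatterRaster, PlotFootprint, db_to_linear
from .wcm_core import InversionCoeffs, Scale
from .yield_pipeline import MU_PER_HM2, FieldTruthRecord, grain_yield_per_mu

__all__ = [
    "SimulationConfig",
    "parcel_b_config",
    "parcel_cde_config",
    "simulate_plots",
    "simulate_raster",
    "simulate_field_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Truth parameters and noise levels for one simulated parcel.

    Defaults are the mature-parcel preset; see :func:`parcel_b_config` and
    :func:`parcel_cde_config`. Noise standard deviations: ``sigma_db_noise``
    on backscatter (dB), ``ear_noise`` kg/m^2, ``grain_noise`` grains/m^2,
    ``w2h2_noise`` kg/m^2; ``speckle_enl`` is the equivalent number of looks
    (``inf`` disables speckle).
    """

    seed: int = 0
    parcel_id: str = "B"
    n_plots: int = 28
    # saturating backscatter curve (dB): sigma0 = C - exp(-(w1h1 - a)/b)
    curve_C: float = -10.57
    curve_a: float = -1.58
    curve_b: float = 0.6638
    # stem-leaf areal water relation w2h2 = p*w1h1 + q
    stemleaf_p: float = 4.4297
    stemleaf_q: float = 0.1408
    # linear calibrations against w1h1
    ear_slope: float = 2.5404       # kg/m^2 per kg/m^2
    ear_intercept: float = 0.2943   # kg/m^2
    grain_slope: float = 78315.0    # grains/m^2 per kg/m^2
    grain_intercept: float = 5015.5
    # sampling range of panicle-layer areal water, kg/m^2
    w1h1_range: Tuple[float, float] = (0.3, 0.8)
    # noise levels
    sigma_db_noise: float = 0.05
    ear_noise: float = 0.05
    grain_noise: float = 3000.0
    w2h2_noise: float = 0.3
    speckle_enl: float = 4.0
    # grain biology for field-truth records
    grains_per_ear_total: float = 158.9
    filled_fraction: float = 0.8886
    thousand_grain_weight_g: float = 23.6
    # raster geometry
    pixel_size_m: float = 0.3
    plot_side_m: float = 1.5
    plot_spacing_px: int = 10
    raster_margin_px: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.w1h1_range
        if not 0 <= lo < hi:
            raise ValueError("w1h1_range must be increasing and non-negative")
        if self.speckle_enl < 1:
            raise ValueError("speckle_enl must be >= 1")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        for name in ("sigma_db_noise", "ear_noise", "grain_noise", "w2h2_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.filled_fraction <= 1:
            raise ValueError("filled_fraction must be in (0, 1]")

    @property
    def curve_coeffs(self) -> InversionCoeffs:
        return InversionCoeffs(a=self.curve_a, b=self.curve_b, C=self.curve_C, scale=Scale.DB)

    @property
    def stemleaf(self) -> StemLeafRelation:
        return StemLeafRelation(p=self.stemleaf_p, q=self.stemleaf_q)

    def noise_free(self) -> "SimulationConfig":
        return replace(
            self,
            sigma_db_noise=0.0,
            ear_noise=0.0,
            grain_noise=0.0,
            w2h2_noise=0.0,
            speckle_enl=float("inf"),
        )


def parcel_b_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Mature-parcel preset (harvest-ready rice, 18 fit + 10 validation plots)."""
    return replace(SimulationConfig(seed=seed), **overrides) if overrides else SimulationConfig(seed=seed)


def parcel_cde_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Grouting-stage composite-parcel preset (20 fit + 10 validation plots)."""
    cfg = SimulationConfig(
        seed=seed,
        parcel_id="CDE",
        n_plots=30,
        curve_C=-15.44,
        curve_a=-1.203,
        curve_b=0.4669,
        stemleaf_p=3.2385,
        stemleaf_q=1.255,
        ear_slope=2.8169,
        ear_intercept=0.1464,
        grain_slope=94399.0,
        grain_intercept=-6380.9,
        w1h1_range=(0.5, 1.7),
        grains_per_ear_total=445.6,
        filled_fraction=0.6897,
        thousand_grain_weight_g=25.7,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _truncated_normal(rng: np.ndarray, size: int, sd: float, lower_shift: np.ndarray) -> np.ndarray:
    """Gaussian noise resampled so that signal + noise stays >= 0."""
    noise = rng.normal(0.0, sd, size) if sd > 0 else np.zeros(size)
    bad = noise < -lower_shift
    tries = 0
    while np.any(bad) and tries < 100:
        noise[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = noise < -lower_shift
        tries += 1
    return np.maximum(noise, -lower_shift)


def simulate_plots(config: SimulationConfig) -> pd.DataFrame:
    """Draw a plot-survey table from the configured truth relations.

    Columns: plot_id, w1h1, w2h2, sigma0_db, ear_wet_kg_m2, grains_m2.
    With all noise levels zero, the rows satisfy the generating curve and
    calibrations exactly; identical seeds give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_plots
    lo, hi = config.w1h1_range
    w1h1 = rng.uniform(lo, hi, n)

    w2h2_true = config.stemleaf_p * w1h1 + config.stemleaf_q
    w2h2 = w2h2_true + _truncated_normal(rng, n, config.w2h2_noise, w2h2_true)

    sigma0_true = config.curve_C - np.exp(-(w1h1 - config.curve_a) / config.curve_b)
    sigma0 = sigma0_true + (rng.normal(0.0, config.sigma_db_noise, n) if config.sigma_db_noise > 0 else 0.0)

    ear_true = config.ear_slope * w1h1 + config.ear_intercept
    ear = ear_true + _truncated_normal(rng, n, config.ear_noise, ear_true)

    grain_true = config.grain_slope * w1h1 + config.grain_intercept
    grain = grain_true + _truncated_normal(rng, n, config.grain_noise, grain_true)

    return pd.DataFrame(
        {
            "plot_id": [f"{config.parcel_id}-{i + 1:02d}" for i in range(n)],
            "w1h1": w1h1,
            "w2h2": w2h2,
            "sigma0_db": sigma0,
            "ear_wet_kg_m2": ear,
            "grains_m2": grain,
        }
    )


def simulate_raster(
    config: SimulationConfig,
    plots: pd.DataFrame,
) -> Tuple[BackscatterRaster, List[PlotFootprint]]:
    """Rasterise the plot backscatter field and speckle it.

    Plot footprints are laid out on a regular grid of centres
    ``plot_spacing_px`` pixels apart; every raster pixel takes the linear
    power of its nearest plot (so each footprint window is internally
    homogeneous), then multiplicative gamma speckle with shape
    ``speckle_enl`` and unit mean is applied. Returned raster is in dB.
    """
    n = len(plots)
    if n == 0:
        raise ValueError("plot table is empty")
    px = config.pixel_size_m
    spacing = config.plot_spacing_px
    margin = config.raster_margin_px
    n_side = math.ceil(math.sqrt(n))
    size = 2 * margin + (n_side - 1) * spacing + 1
    nrows = ncols = size
    origin_y = nrows * px  # top edge; world y decreases with row

    centers_rc = []
    for i in range(n):
        r = margin + (i // n_side) * spacing
        c = margin + (i % n_side) * spacing
        centers_rc.append((r, c))
    centers_rc = np.array(centers_rc, dtype=float)

    sigma_lin = db_to_linear(plots["sigma0_db"].to_numpy(dtype=float))
    rows, cols = np.indices((nrows, ncols))
    tree = cKDTree(centers_rc)
    _, nearest = tree.query(np.column_stack([rows.ravel(), cols.ravel()]))
    field_lin = sigma_lin[nearest].reshape(nrows, ncols)

    rng = np.random.default_rng(config.seed + 1)
    if math.isfinite(config.speckle_enl):
        enl = config.speckle_enl
        speckle = rng.gamma(shape=enl, scale=1.0 / enl, size=field_lin.shape)
        field_lin = field_lin * speckle

    raster = BackscatterRaster(
        data=10.0 * np.log10(field_lin),
        scale=Scale.DB,
        pixel_size=px,
        origin_x=0.0,
        origin_y=origin_y,
        crs="local",
    )
    footprints = [
        PlotFootprint(
            plot_id=str(pid),
            x=(c + 0.5) * px,
            y=origin_y - (r + 0.5) * px,
            side_m=config.plot_side_m,
        )
        for pid, (r, c) in zip(plots["plot_id"], centers_rc)
    ]
    return raster, footprints


def simulate_field_truth(config: SimulationConfig, plots: pd.DataFrame) -> FieldTruthRecord:
    """Aggregate a plot table into a parcel-level field-truth record.

    Grain density, ears and total output are internally consistent: the
    record's kg/hm^2 equals the grain-to-mass arithmetic applied to the
    parcel-mean grain density, and its kg/mu is that divided by 15.
    """
    mean_grains = float(plots["grains_m2"].mean())
    grains_total = config.grains_per_ear_total
    grains_filled = grains_total * config.filled_fraction
    ears_per_m2 = mean_grains / grains_total
    yield_mu = grain_yield_per_mu(
        mean_grains, config.thousand_grain_weight_g, config.filled_fraction
    )
    return FieldTruthRecord(
        parcel_id=config.parcel_id,
        effective_ears=ears_per_m2,  # ears/m^2 == 10^4 ears/hm^2
        grains_per_ear_total=grains_total,
        grains_per_ear_filled=grains_filled,
        thousand_grain_weight=config.thousand_grain_weight_g,
        total_output=yield_mu * MU_PER_HM2,
        yield_per_mu=yield_mu,
    )
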