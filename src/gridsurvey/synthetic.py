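"""Synthetic landscapes for exercising the full sample-design pipeline.

The generator produces the three inputs the framework consumes — a gridded
population surface, a settlement mask and a covariate stack — with the
statistical structure the design assumes of real settlement data:

* spatial autocorrelation: a stationary Gaussian random field (smoothed
  white noise) underlies the log population intensity;
* spatial trend / heterogeneity: a few urban cores add Gaussian intensity
  kernels, creating an urban-to-rural gradient;
* discreteness: settlement is a per-cell Bernoulli draw whose probability
  increases monotonically (logistic) with log intensity, and population is
  zero outside the settled mask;
* context: covariates are linear combinations of the standardized log
  intensity and independent noise with a configured correlation, plus
  quantile-binned smooth latent fields for categoricals.

Each cell also carries a ground-truth regime label (core / periphery /
rural) derived from the kernel field, usable as a clustering reference.
The generator emulates the geography of a river-basin settlement system in
structure only; it is not calibrated to any real landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import GridSpec, SettledCellFrame, build_frame
from .stratify import CovariateRaster

__all__ = ["LandscapeConfig", "Landscape", "generate_landscape", "make_fixture"]

CORE, PERIPHERY, RURAL = 0, 1, 2


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Intensity is log-scale: population = exp(background field + core
    kernels) on settled cells.  ``correlation_range`` is the smoothing
    length (cells) of the background field; ``core_decay`` the kernel
    standard deviation (cells); ``settlement_center``/``settlement_scale``
    the logistic parameters mapping log intensity to settlement probability.
    """

    n_rows: int = 30
    n_cols: int = 30
    seed: int = 0
    n_urban_cores: int = 2
    core_intensity: float = 4.0
    core_decay: float = 4.0
    background_mean: float = 0.0
    background_sd: float = 1.0
    correlation_range: float = 3.0
    settlement_center: float = 0.5
    settlement_scale: float = 1.0
    n_continuous: int = 2
    categorical_levels: tuple[int, ...] = ()
    covariate_correlation: float = 0.6
    origin_x: float = 14.0
    origin_y: float = -4.0
    cell_size: float = 1.0 / 1200.0

    def __post_init__(self) -> None:
        if self.background_sd <= 0 or self.core_decay <= 0 or self.correlation_range <= 0:
            raise ValueError("variance/range parameters must be positive")
        if self.settlement_scale <= 0:
            raise ValueError("settlement_scale must be positive")
        if not 0 <= self.covariate_correlation < 1:
            raise ValueError("covariate_correlation must lie in [0, 1)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
        )


@dataclass
class Landscape:
    """A generated landscape: rasters plus ground-truth regime labels."""

    config: LandscapeConfig
    grid: GridSpec
    population: np.ndarray  # float raster, 0 outside mask
    mask: np.ndarray  # bool raster
    covariates: list[CovariateRaster] = field(repr=False)
    regimes: np.ndarray = field(repr=False)  # int raster: 0 core, 1 periphery, 2 rural

    def frame(self) -> SettledCellFrame:
        return build_frame(self.mask, self.population, self.grid)

    def regime_labels(self) -> np.ndarray:
        """Ground-truth regime per settled cell, row-major frame order."""
        return self.regimes[self.mask]


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian random field via kernel-smoothed white noise."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (z - z.mean()) / z.std()


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Draw one landscape; bit-identical for a fixed config (incl. seed)."""
    shape = (config.n_rows, config.n_cols)
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(5)
    rng_field, rng_cores, rng_mask, rng_cov, rng_cat = map(np.random.default_rng, keys)

    background = config.background_mean + config.background_sd * _smooth_field(
        rng_field, shape, sigma=config.correlation_range / 2.0
    )

    ii, jj = np.indices(shape)
    core_field = np.zeros(shape)
    for _ in range(config.n_urban_cores):
        ci = rng_cores.uniform(0.1 * config.n_rows, 0.9 * config.n_rows)
        cj = rng_cores.uniform(0.1 * config.n_cols, 0.9 * config.n_cols)
        d2 = (ii - ci) ** 2 + (jj - cj) ** 2
        core_field += config.core_intensity * np.exp(-d2 / (2 * config.core_decay**2))

    log_intensity = background + core_field
    p_settle = 1.0 / (
        1.0 + np.exp(-(log_intensity - config.settlement_center) / config.settlement_scale)
    )
    mask = rng_mask.uniform(size=shape) < p_settle
    if not mask.any():
        raise ValueError("degenerate configuration: no settled cells generated")
    population = np.where(mask, np.exp(log_intensity), 0.0)

    # regime ground truth from the trend component only
    regimes = np.full(shape, RURAL, dtype=int)
    regimes[core_field >= config.core_intensity / 20.0] = PERIPHERY
    regimes[core_field >= config.core_intensity / 2.0] = CORE

    z = (log_intensity - log_intensity.mean()) / log_intensity.std()
    rho = config.covariate_correlation
    covariates: list[CovariateRaster] = []
    for c in range(config.n_continuous):
        sign = 1.0 if c % 2 == 0 else -1.0  # alternate orientation across covariates
        noise = rng_cov.standard_normal(shape)
        x = sign * rho * z + np.sqrt(1 - rho**2) * noise
        scale = 10.0 ** (c % 3)  # heterogeneous units, as real covariates have
        covariates.append(
            CovariateRaster(name=f"cont_{c}", array=50.0 + scale * x, kind="continuous")
        )
    for c, n_levels in enumerate(config.categorical_levels):
        noise = _smooth_field(rng_cat, shape, sigma=config.correlation_range)
        latent = rho * z + np.sqrt(1 - rho**2) * noise
        qs = np.quantile(latent, np.linspace(0, 1, n_levels + 1)[1:-1])
        levels = np.digitize(latent, qs).astype(float) + 1.0
        covariates.append(CovariateRaster(name=f"cat_{c}", array=levels, kind="categorical"))

    return Landscape(
        config=config,
        grid=config.grid,
        population=population,
        mask=mask,
        covariates=covariates,
        regimes=regimes,
    )


_FIXTURES = {
    # ~150 settled cells on a 30x30 grid, two continuous covariates: unit
    # tests and CLI smoke runs.
    "tiny": LandscapeConfig(
        n_rows=30,
        n_cols=30,
        seed=2020,
        n_urban_cores=1,
        core_intensity=4.0,
        core_decay=3.0,
        background_mean=0.0,
        background_sd=1.0,
        correlation_range=3.0,
        settlement_center=2.05,
        settlement_scale=0.9,
        n_continuous=2,
    ),
    # ~8,000 settled cells on a 200x200 grid; 8 continuous + 2 categorical
    # covariates (4 levels each -> 16 attribute columns), mirroring a
    # ten-dataset covariate suite spanning socio-economic, infrastructural,
    # environmental, physical and climatic classes.
    "medium": LandscapeConfig(
        n_rows=200,
        n_cols=200,
        seed=2020,
        n_urban_cores=4,
        core_intensity=4.5,
        core_decay=12.0,
        background_mean=0.0,
        background_sd=1.2,
        correlation_range=6.0,
        settlement_center=2.2,
        settlement_scale=0.9,
        n_continuous=8,
        categorical_levels=(4, 4),
    ),
}


def make_fixture(name: str, seed: int | None = None) -> Landscape:
    """A bundled landscape: ``tiny`` (unit-test scale) or ``medium``.

    ``seed`` overrides the fixture's default seed, leaving all structural
    parameters fixed.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    config = _FIXTURES[name]
    if seed is not None:
        config = replace(config, seed=seed)
    return generate_landscape(config)
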