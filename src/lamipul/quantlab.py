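"""Growth, cell-density and enzyme-activity quantifications.

Covers the bench-derived numbers of the workflow: maximal specific growth
rate from OD600 time series (sliding log-linear window), microscopy
cell-density scale-up from counting grids to the whole filter, Beer-Lambert
conversion of nitrophenol absorbance slopes to specific beta-glucosidase
activity, linear calibration curves, and substrate-consumption percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GrowthSeries:
    """An OD600 time series (hours), optionally with parallel cell counts."""

    times: np.ndarray
    od: np.ndarray
    cell_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValidationError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly ascending")
        if np.any(self.od < 0):
            raise ValidationError("OD must be >= 0")
        if self.cell_counts is not None:
            self.cell_counts = np.asarray(self.cell_counts, dtype=float)
            if self.cell_counts.shape != self.times.shape:
                raise ValidationError("cell_counts must match times")


@dataclass
class GrowthRateFit:
    """Maximal specific growth rate found by the sliding-window fit."""

    mu: float  # h^-1
    window_indices: tuple[int, int]  # [start, stop) into the series
    r_squared: float
    flags: tuple[str, ...] = ()


def fit_growth_rate(series: GrowthSeries, window: int = 4,
                    min_r2: float = 0.98) -> GrowthRateFit:
    """Maximal specific growth rate: steepest sliding-window ln(OD) slope.

    Every window of ``window`` consecutive positive-OD points is fitted by
    least squares on ln(OD) vs time; mu is the maximum slope among windows
    with r^2 >= ``min_r2`` (the exponential-phase requirement). If no
    window is linear enough, the steepest window overall is returned with a
    ``low_r2`` flag. A window with zero ln(OD) variance (constant OD) has
    slope 0 and is treated as a perfect fit.
    """
    n = len(series.times)
    if n < window:
        raise ValidationError(f"need >= {window} points, got {n}")
    candidates = []  # (slope, r2, start)
    for start in range(n - window + 1):
        od = series.od[start : start + window]
        if np.any(od <= 0):
            continue
        t = series.times[start : start + window]
        y = np.log(od)
        if np.ptp(y) == 0.0:
            candidates.append((0.0, 1.0, start))
            continue
        fit = stats.linregress(t, y)
        candidates.append((float(fit.slope), float(fit.rvalue) ** 2, start))
    if not candidates:
        raise ValidationError("no window with strictly positive OD")
    passing = [c for c in candidates if c[1] >= min_r2]
    flags: tuple[str, ...] = ()
    if not passing:
        passing = candidates
        flags = ("low_r2",)
    slope, r2, start = max(passing, key=lambda c: c[0])
    return GrowthRateFit(mu=slope, window_indices=(start, start + window),
                         r_squared=r2, flags=flags)


@dataclass
class CellDensity:
    cells_per_ml: float
    flags: tuple[str, ...] = ()


def cell_density(grid_counts: Sequence[int], grid_area: float,
                 filter_area: float, sample_volume_ml: float) -> CellDensity:
    """Scale DAPI counting-grid counts to cells/mL of filtered sample.

    density = mean(count per grid) * (filter_area / grid_area) / volume.
    QC flags: fewer than 30 grids counted, or a total of <= 280 cells
    (areas must share a unit, e.g. both in square micrometres).
    """
    if grid_area <= 0 or filter_area <= 0 or sample_volume_ml <= 0:
        raise ConfigError("areas and volume must be > 0")
    counts = np.asarray(grid_counts, dtype=float)
    if counts.size == 0:
        raise ValidationError("no grid counts given")
    flags = []
    if counts.size < 30:
        flags.append("grids<30")
    if counts.sum() <= 280:
        flags.append("total_cells<=280")
    density = counts.mean() * (filter_area / grid_area) / sample_volume_ml
    return CellDensity(float(density), tuple(flags))


@dataclass
class ActivityConfig:
    """Beer-Lambert assay parameters for nitrophenol quantification.

    epsilon defaults to 7,500 M^-1 cm^-1 (nitrophenol at 405 nm).
    """

    epsilon: float = 7500.0  # M^-1 cm^-1
    path_cm: float = 1.0
    assay_volume_l: float = 1e-3
    protein_ug: float = 10.0

    def __post_init__(self) -> None:
        for name in ("epsilon", "path_cm", "assay_volume_l", "protein_ug"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


def beer_lambert_activity(dA_per_s: float, cfg: ActivityConfig) -> float:
    """Specific activity in nmol substrate s^-1 (ug protein)^-1.

    dA/dt [AU/s] / (epsilon * path) gives mol L^-1 s^-1; times the assay
    volume gives mol/s, expressed per microgram of protein.
    """
    if dA_per_s < 0:
        raise ValidationError("dA/dt must be >= 0")
    molar_rate = dA_per_s / (cfg.epsilon * cfg.path_cm)  # M/s
    nmol_per_s = molar_rate * cfg.assay_volume_l * 1e9
    return nmol_per_s / cfg.protein_ug


@dataclass
class Calibration:
    """Least-squares line absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float] = field(default=(0.0, 0.0))

    def quantify(self, absorbance: float) -> tuple[float, bool]:
        """Invert the line; second value flags extrapolation beyond standards."""
        conc = (absorbance - self.intercept) / self.slope
        lo, hi = self.conc_range
        return conc, not (lo <= conc <= hi)


def linear_calibration(
    standards: Sequence[tuple[float, float]]
) -> Calibration:
    """Fit a calibration line from (concentration, absorbance) standards."""
    if len(standards) < 3:
        raise ValidationError("need >= 3 calibration standards")
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absorb = np.asarray([s[1] for s in standards], dtype=float)
    if len(np.unique(conc)) < len(conc):
        raise ValidationError("standard concentrations must be distinct")
    fit = stats.linregress(conc, absorb)
    return Calibration(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def consumption_percent(initial: float, final: float) -> float:
    """Percentage of substrate consumed between two concentrations (g/L)."""
    if initial <= 0:
        raise ValidationError("initial concentration must be > 0")
    if final < 0 or final > initial:
        logger.warning("final concentration %.3g outside [0, initial=%.3g]",
                       final, initial)
    return 100.0 * (initial - final) / initial
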