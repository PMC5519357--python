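"""Area expansion modulus K_A from equilibrium area fluctuations.

For a tensionless membrane simulated at constant temperature and pressure,
the projected box area A fluctuates about its mean A0, and the area
expansion modulus follows from the fluctuation relation

    K_A = kB·T·A0 / ⟨δA²⟩,     ⟨δA²⟩ = ⟨A²⟩ − ⟨A⟩²

with A0 the mean area of the tensionless membrane.  The estimator here uses
the post-equilibration sample mean for A0 and the unbiased (n−1) sample
variance for ⟨δA²⟩; the standard error of K_A is propagated to first order
from the block-average standard error of the variance, which accounts for
the serial correlation of the area time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import units
from .blocking import BlockErrorCurve, block_average_se


class DegenerateSeriesError(ValueError):
    """Raised when an area series carries no usable fluctuation signal."""


@dataclass(frozen=True)
class AreaSeries:
    """An equilibrated time series of instantaneous membrane area.

    Parameters
    ----------
    times:
        Strictly increasing frame times (frame index or ps).
    areas:
        Instantaneous projected membrane areas in nm²; all finite and > 0.
    temperature:
        Absolute temperature of the ensemble in K.
    equilibration_cut:
        Number of leading frames already removed from this series
        (bookkeeping only; the stored arrays are post-cut).
    """

    times: np.ndarray
    areas: np.ndarray
    temperature: float
    equilibration_cut: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "areas", areas)
        if times.ndim != 1 or areas.ndim != 1 or len(times) != len(areas):
            raise ValueError("times and areas must be 1-D and equal length")
        if len(areas) == 0:
            raise ValueError("empty area series")
        if not np.all(np.isfinite(areas)) or np.any(areas <= 0):
            raise ValueError("areas must be finite and > 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.equilibration_cut < 0:
            raise ValueError("equilibration_cut must be >= 0")

    def __len__(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class ModulusEstimate:
    """K_A with uncertainty and the intermediate moments it came from."""

    value_mn_per_m: float
    se_mn_per_m: float
    mean_area_nm2: float
    variance_nm4: float
    variance_se_nm4: float
    temperature: float
    n_frames: int
    block_curve: BlockErrorCurve = field(repr=False, default=None)

    @property
    def value_kbt_per_nm2(self) -> float:
        """K_A expressed in kBT/nm² at the series temperature."""
        return units.mn_per_m_to_j_per_nm2(self.value_mn_per_m) / units.kbt_joule(
            self.temperature
        )


def apply_equilibration_cut(
    series: AreaSeries, cut: int | float, min_remaining: int = 100
) -> AreaSeries:
    """Drop the leading equilibration frames of an area series.

    ``cut`` is either a frame count (int) or a fraction of the series length
    (float in [0, 1)).  The default production fraction is 0.25, matching a
    50 ns discard on a 200 ns run when frames map 1:1 to ns.
    """
    n = len(series)
    if isinstance(cut, float) and not float(cut).is_integer():
        if not 0.0 <= cut < 1.0:
            raise ValueError("fractional cut must lie in [0, 1)")
        n_cut = int(round(cut * n))
    else:
        n_cut = int(cut)
    if n_cut < 0:
        raise ValueError("cut must be non-negative")
    if n_cut >= n:
        raise DegenerateSeriesError(
            f"equilibration cut of {n_cut} frames consumes the whole {n}-frame series"
        )
    if n - n_cut < min_remaining:
        raise DegenerateSeriesError(
            f"cut leaves {n - n_cut} frames; at least {min_remaining} required"
        )
    if n_cut == 0:
        return series
    return replace(
        series,
        times=series.times[n_cut:],
        areas=series.areas[n_cut:],
        equilibration_cut=series.equilibration_cut + n_cut,
    )


def estimate_area_modulus(
    series: AreaSeries,
    stride: int = 1,
    mean_area_override: float | None = None,
) -> ModulusEstimate:
    """Estimate K_A = kB·T·A0/⟨δA²⟩ from an equilibrated area series.

    A0 defaults to the post-cut sample mean of the same series (the mean
    area of the tensionless membrane); ``mean_area_override`` substitutes an
    externally supplied reference area.  ``stride`` subsamples every k-th
    stored frame before estimation.

    Returns a :class:`ModulusEstimate` carrying K_A in mN/m, its standard
    error from the block-average SE of the variance, and the moments used.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    areas = series.areas[::stride]
    n = len(areas)
    if n < 100:
        raise DegenerateSeriesError(
            f"need at least 100 post-cut frames to estimate K_A, got {n}"
        )
    mean_area = float(np.mean(areas))
    variance = float(np.var(areas, ddof=1))
    if variance <= 0.0:
        raise DegenerateSeriesError(
            "area series has zero fluctuation; K_A is undefined, not infinite"
        )
    a0 = mean_area if mean_area_override is None else float(mean_area_override)
    ka_j_per_nm2 = units.kbt_joule(series.temperature) * a0 / variance
    ka_mn_per_m = units.j_per_nm2_to_mn_per_m(ka_j_per_nm2)

    curve = block_average_se(areas, statistic="variance")
    variance_se = curve.plateau_se
    # first-order: δK_A/K_A = δ⟨δA²⟩/⟨δA²⟩ (A0 sampling error is O(1/n) relative)
    ka_se = ka_mn_per_m * variance_se / variance

    return ModulusEstimate(
        value_mn_per_m=ka_mn_per_m,
        se_mn_per_m=ka_se,
        mean_area_nm2=a0,
        variance_nm4=variance,
        variance_se_nm4=variance_se,
        temperature=series.temperature,
        n_frames=n,
        block_curve=curve,
    )
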