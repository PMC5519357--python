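"""Surrogate NPT membrane ensembles with known elastic ground truth.

The fluctuation estimator of K_A depends only on the stationary
distribution of the projected membrane area: Gaussian with mean A0 and
variance kB·T·A0/K_A for a tensionless membrane.  The generator therefore
samples that stationary law directly — optionally as an AR(1) process with
the same stationary variance, to mimic the serial correlation of MD frames
— instead of integrating any dynamical model.  Likewise, leaflet phosphorus
positions are drawn from a symmetric two-Gaussian mixture with peaks at
±d/2, which is all the peak-to-peak thickness measurement can see.

Defaults mirror a 400-lipid, fully hydrated bilayer patch at 30 °C
(A0 ≈ 130 nm², i.e. ≈0.65 nm² per lipid per leaflet; 200 phosphorus atoms
per leaflet), the system size at which all-atom K_A estimates are usually
quoted.

One integer seed controls everything through two spawned, independent
bit-generator streams (one for areas, one for coordinates), so generating
the coordinate table never perturbs the area draws and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import units
from .area import AreaSeries


@dataclass(frozen=True)
class SyntheticMembraneSpec:
    """Ground-truth parameters of a surrogate membrane ensemble.

    Parameters
    ----------
    target_area_modulus:
        True K_A in mN/m.
    reference_area:
        True tensionless mean area A0 in nm².
    temperature:
        Absolute temperature in K.
    n_frames:
        Number of frames to generate.
    correlation_rho:
        Lag-1 autocorrelation of the AR(1) area process, in [0, 1);
        0 gives independent frames.
    thickness_true:
        True peak-to-peak distance d between the leaflet phosphorus
        peaks, nm.
    peak_sigma:
        Width of each leaflet's phosphorus z distribution, nm.
    n_phosphorus:
        Phosphorus atoms per frame (one per lipid; 400 for the default
        bilayer patch).
    seed:
        Integer seed; identical spec + seed gives bit-identical output.
    """

    target_area_modulus: float = 240.0
    reference_area: float = 130.0
    temperature: float = 303.15
    n_frames: int = 20_000
    correlation_rho: float = 0.0
    thickness_true: float = 3.8
    peak_sigma: float = 0.35
    n_phosphorus: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_area_modulus <= 0:
            raise ValueError("target_area_modulus must be > 0 mN/m")
        if self.reference_area <= 0:
            raise ValueError("reference_area must be > 0 nm²")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.correlation_rho < 1.0:
            raise ValueError("correlation_rho must lie in [0, 1)")
        if not self.thickness_true > self.peak_sigma >= 0.0:
            raise ValueError("need thickness_true > peak_sigma >= 0")
        if self.peak_sigma == 0.0 and self.thickness_true <= 0.0:
            raise ValueError("thickness_true must be > 0")

    def stationary_variance(self) -> float:
        """The area variance kB·T·A0/K_A implied by the ground truth, nm⁴."""
        ka_j_per_nm2 = units.mn_per_m_to_j_per_nm2(self.target_area_modulus)
        return units.kbt_joule(self.temperature) * self.reference_area / ka_j_per_nm2

    def _streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        area_seq, coord_seq = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(area_seq), np.random.default_rng(coord_seq)


def generate_area_series(spec: SyntheticMembraneSpec) -> AreaSeries:
    """Draw a stationary (optionally AR(1)-correlated) area time series.

    The marginal law is Gaussian with mean A0 and variance kB·T·A0/K_A;
    for ``correlation_rho = ρ > 0`` successive frames follow
    x_{t+1} = A0 + ρ(x_t − A0) + ε_t with ε_t ~ N(0, σ²(1−ρ²)), which has
    exactly that stationary variance and lag-1 autocorrelation ρ.  The
    first frame is drawn from the stationary law, so the whole series is
    stationary (no burn-in needed).
    """
    rng, _ = spec._streams()
    var = spec.stationary_variance()
    if not np.isfinite(var) or var <= 0:
        raise ValueError("ground-truth variance is not finite and positive")
    sigma = np.sqrt(var)
    rho = spec.correlation_rho
    eps = rng.standard_normal(spec.n_frames)
    if rho == 0.0:
        deviations = sigma * eps
    else:
        innovations = eps * (sigma * np.sqrt(1.0 - rho * rho))
        innovations[0] = eps[0] * sigma  # stationary start
        deviations = lfilter([1.0], [1.0, -rho], innovations)
    areas = spec.reference_area + deviations
    times = np.arange(spec.n_frames, dtype=float)
    return AreaSeries(times=times, areas=areas, temperature=spec.temperature)


def generate_phosphorus_z(spec: SyntheticMembraneSpec) -> pd.DataFrame:
    """Draw per-frame phosphorus z coordinates from the two-leaflet mixture.

    Each coordinate is ±d/2 (leaflet chosen with equal probability, so the
    expected membership per leaflet is equal for any atom count) plus
    Gaussian noise of width ``peak_sigma``.  Returns a tidy table with
    columns ``frame``, ``atom_index``, ``z_nm``.
    """
    if spec.n_phosphorus < 2:
        raise ValueError("need at least 2 phosphorus atoms per frame")
    _, rng = spec._streams()
    n = spec.n_frames * spec.n_phosphorus
    signs = rng.integers(0, 2, size=n) * 2 - 1
    z = signs * (spec.thickness_true / 2.0)
    if spec.peak_sigma > 0.0:
        z = z + spec.peak_sigma * rng.standard_normal(n)
    frames = np.repeat(np.arange(spec.n_frames), spec.n_phosphorus)
    atoms = np.tile(np.arange(spec.n_phosphorus), spec.n_frames)
    return pd.DataFrame({"frame": frames, "atom_index": atoms, "z_nm": z})
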