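"""Bilayer thickness from the phosphorus number-density profile.

The head-group phosphorus atoms of the two leaflets produce a bimodal
density profile along the bilayer normal (z); the peak-to-peak distance of
that profile is the bilayer thickness d used in the bending-rigidity
relation.  Profiles are built by centering each frame at its mean
phosphorus z (removing bilayer drift), histogramming on symmetric uniform
bins, and averaging over frames; peaks are refined to sub-bin precision
with a three-point parabola.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


class ThicknessUndefinedError(ValueError):
    """Profile is not bimodal about the midplane; thickness has no meaning."""


@dataclass(frozen=True)
class DensityProfile:
    """Frame-averaged phosphorus number density along the bilayer normal.

    ``density`` is in atoms per nm per frame, so that
    ``sum(density * bin_width) == n_atoms`` (atoms per frame) exactly.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_frames: int
    n_atoms: float
    bin_width: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", dens)
        if len(edges) != len(dens) + 1:
            raise ValueError("need len(bin_edges) == len(density) + 1")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not np.allclose(widths, self.bin_width, rtol=1e-9):
            raise ValueError("bins must have uniform width")
        total = float(np.sum(dens) * self.bin_width)
        if not np.isclose(total, self.n_atoms, rtol=1e-9):
            raise ValueError(
                f"density integrates to {total}, expected n_atoms={self.n_atoms}"
            )

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def reflected(self) -> "DensityProfile":
        """The profile of the mirrored coordinates z → −z."""
        return DensityProfile(
            bin_edges=-self.bin_edges[::-1],
            density=self.density[::-1],
            n_frames=self.n_frames,
            n_atoms=self.n_atoms,
            bin_width=self.bin_width,
        )


@dataclass(frozen=True)
class ThicknessEstimate:
    """Peak-to-peak thickness with its uncertainty and the two peak positions."""

    value_nm: float
    se_nm: float
    peak_lower_nm: float
    peak_upper_nm: float


def _as_frame_z(z_table) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with frame/z_nm columns or a (frames, z) pair."""
    if isinstance(z_table, pd.DataFrame):
        if not {"frame", "z_nm"}.issubset(z_table.columns):
            raise ValueError("z table needs columns 'frame' and 'z_nm'")
        return (
            z_table["frame"].to_numpy(dtype=int),
            z_table["z_nm"].to_numpy(dtype=float),
        )
    frames, z = z_table
    return np.asarray(frames, dtype=int), np.asarray(z, dtype=float)


def build_density_profile(
    z_table,
    bin_width: float = 0.05,
    center: str = "frame_mean",
) -> DensityProfile:
    """Histogram per-frame phosphorus z coordinates into a density profile.

    ``center='frame_mean'`` subtracts each frame's mean phosphorus z before
    binning, placing the midplane at z = 0 without requiring box geometry;
    ``center='none'`` trusts the input coordinates as already centered.
    Bins are uniform, symmetric about 0, and padded with one empty bin per
    side so every physical peak is interior to the grid.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    frames, z = _as_frame_z(z_table)
    if len(z) < 2:
        raise ValueError("need at least 2 phosphorus coordinates")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z coordinate in table")
    unique_frames, inverse, counts = np.unique(
        frames, return_inverse=True, return_counts=True
    )
    n_frames = len(unique_frames)

    if center == "frame_mean":
        frame_means = np.bincount(inverse, weights=z) / counts
        z = z - frame_means[inverse]
    elif center != "none":
        raise ValueError(f"unknown centering mode {center!r}")

    if np.ptp(z) == 0.0:
        raise ThicknessUndefinedError(
            "all phosphorus z identical after centering; not a bilayer"
        )

    half_bins = int(np.ceil(np.max(np.abs(z)) / bin_width)) + 1  # +1 pad bin
    edges = np.arange(-half_bins, half_bins + 1, dtype=float) * bin_width
    hist, _ = np.histogram(z, bins=edges)
    n_atoms = len(z) / n_frames
    density = hist / (n_frames * bin_width)
    return DensityProfile(
        bin_edges=edges,
        density=density,
        n_frames=n_frames,
        n_atoms=n_atoms,
        bin_width=bin_width,
    )


def _refine_peak(profile: DensityProfile, idx: int) -> tuple[float, float]:
    """Parabolic sub-bin refinement of a peak bin; returns (z, shift)."""
    centers = profile.bin_centers
    y = profile.density
    if idx == 0 or idx == len(y) - 1:
        return float(centers[idx]), 0.0
    denom = y[idx - 1] - 2.0 * y[idx] + y[idx + 1]
    if denom == 0.0:
        return float(centers[idx]), 0.0
    delta = 0.5 * (y[idx - 1] - y[idx + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    shift = delta * profile.bin_width
    return float(centers[idx] + shift), shift


def _side_peak(profile: DensityProfile, side: int) -> int:
    """Index of the highest local maximum with bin center on one side of 0.

    Ties in height are broken toward the midplane, deterministically.
    """
    centers = profile.bin_centers
    peaks, _ = find_peaks(profile.density)
    mask = centers[peaks] * side > 0
    candidates = peaks[mask]
    if len(candidates) == 0:
        raise ThicknessUndefinedError(
            "no local density maximum on the "
            + ("upper" if side > 0 else "lower")
            + " side of the midplane; profile is not bimodal"
        )
    heights = profile.density[candidates]
    best = heights == heights.max()
    tied = candidates[best]
    return int(tied[np.argmin(np.abs(centers[tied]))])


def peak_to_peak_thickness(profile: DensityProfile) -> ThicknessEstimate:
    """Bilayer thickness d as the distance between the two leaflet peaks.

    Each peak is the highest local maximum on its side of the midplane,
    refined by parabolic interpolation through the peak bin and its two
    neighbors.  The uncertainty per peak is half a bin width combined in
    quadrature with the interpolation shift; the two peak uncertainties add
    in quadrature.
    """
    idx_lo = _side_peak(profile, -1)
    idx_hi = _side_peak(profile, +1)
    z_lo, shift_lo = _refine_peak(profile, idx_lo)
    z_hi, shift_hi = _refine_peak(profile, idx_hi)
    half = 0.5 * profile.bin_width
    u_lo = np.hypot(half, shift_lo)
    u_hi = np.hypot(half, shift_hi)
    return ThicknessEstimate(
        value_nm=z_hi - z_lo,
        se_nm=float(np.hypot(u_lo, u_hi)),
        peak_lower_nm=z_lo,
        peak_upper_nm=z_hi,
    )
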