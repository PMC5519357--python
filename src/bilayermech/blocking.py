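"""Block-average standard errors for correlated time series.

Naive standard errors underestimate the uncertainty of averages over MD
time series because successive frames are correlated.  Block averaging
partitions the series into contiguous blocks, computes the statistic per
block, and tracks the standard error of the block statistics as the block
size doubles; once blocks are longer than the correlation time the SE
curve plateaus, and the plateau value is the honest error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: relative SE change under a doubling that counts as "flat"
PLATEAU_RTOL = 0.05
#: minimum number of blocks retained at the largest block size
MIN_BLOCKS = 8


class InsufficientDataError(ValueError):
    """Series too short to support block-average error estimation."""


@dataclass(frozen=True)
class BlockErrorCurve:
    """SE of a statistic versus block size, with plateau selection.

    ``plateau_block``/``plateau_se`` give the selected block size and its SE;
    ``converged`` is False when no plateau was detected and the largest
    admissible block size was reported instead.
    """

    block_sizes: np.ndarray
    se_estimates: np.ndarray
    plateau_block: int
    plateau_se: float
    converged: bool
    statistic: str

    def __post_init__(self) -> None:
        sizes = np.asarray(self.block_sizes, dtype=int)
        ses = np.asarray(self.se_estimates, dtype=float)
        object.__setattr__(self, "block_sizes", sizes)
        object.__setattr__(self, "se_estimates", ses)
        if np.any(np.diff(sizes) <= 0) or sizes[0] < 1:
            raise ValueError("block sizes must be >= 1 and strictly increasing")


def _block_statistic(values: np.ndarray, block_size: int, statistic: str) -> np.ndarray:
    n_blocks = len(values) // block_size
    trimmed = values[: n_blocks * block_size].reshape(n_blocks, block_size)
    if statistic == "mean":
        return trimmed.mean(axis=1)
    if statistic == "variance":
        return trimmed.var(axis=1, ddof=1)
    raise ValueError(f"unknown statistic {statistic!r}; use 'mean' or 'variance'")


def _relative_change(new: float, old: float) -> float:
    if old == 0.0:
        return 0.0 if new == 0.0 else np.inf
    return abs(new - old) / old


def block_average_se(series, statistic: str = "mean") -> BlockErrorCurve:
    """Block-average SE curve of the mean or variance of a series.

    Block sizes double from 1 (from 2 for the variance, whose per-block
    estimate needs two points) up to the largest power of two leaving at
    least ``MIN_BLOCKS`` blocks; the trailing ``n mod b`` points are
    discarded at each size.  The plateau is the smallest block size whose SE
    differs by less than ``PLATEAU_RTOL`` from each of the two preceding
    doublings; if the curve never flattens, the largest admissible block
    size is reported with ``converged=False``.
    """
    values = np.asarray(series, dtype=float)
    if values.ndim != 1:
        raise ValueError("series must be 1-D")
    n = len(values)
    if n < 64:
        raise InsufficientDataError(f"need at least 64 points, got {n}")
    max_block = n // MIN_BLOCKS
    if max_block < 2:
        raise InsufficientDataError(
            f"series of length {n} cannot form {MIN_BLOCKS} blocks at block size 2"
        )

    first = 2 if statistic == "variance" else 1
    sizes = []
    b = first
    while b <= max_block:
        sizes.append(b)
        b *= 2
    sizes = np.array(sizes, dtype=int)

    ses = np.empty(len(sizes))
    for i, b in enumerate(sizes):
        stats = _block_statistic(values, int(b), statistic)
        ses[i] = stats.std(ddof=1) / np.sqrt(len(stats))

    plateau_idx = None
    for i in range(2, len(sizes)):
        if (
            _relative_change(ses[i], ses[i - 1]) < PLATEAU_RTOL
            and _relative_change(ses[i - 1], ses[i - 2]) < PLATEAU_RTOL
        ):
            plateau_idx = i
            break
    converged = plateau_idx is not None
    if plateau_idx is None:
        plateau_idx = len(sizes) - 1

    return BlockErrorCurve(
        block_sizes=sizes,
        se_estimates=ses,
        plateau_block=int(sizes[plateau_idx]),
        plateau_se=float(ses[plateau_idx]),
        converged=converged,
        statistic=statistic,
    )
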