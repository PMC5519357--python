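"""Readers and writers for the text formats the pipeline speaks.

Area time series travel as xvg-style two-column text (the natural export
of MD analysis toolchains; lines starting with ``#`` or ``@`` are
comments) or as CSV/TSV with a header.  Phosphorus coordinates travel as
TSV tables with columns ``frame``, ``atom_index``, ``z_nm``.  Density
profiles and block-error curves are written as CSV for plotting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .area import AreaSeries
from .blocking import BlockErrorCurve
from .thickness import DensityProfile


class TableFormatError(ValueError):
    """A data file violated the expected dialect; message names the line."""


def _parse_xvg(path: Path, temperature: float) -> AreaSeries:
    times, areas = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise TableFormatError(f"{path}:{lineno}: expected two columns")
            try:
                t, a = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-numeric field") from exc
            times.append(t)
            areas.append(a)
    if not times:
        raise TableFormatError(f"{path}: no data rows")
    return AreaSeries(
        times=np.array(times), areas=np.array(areas), temperature=temperature
    )


def _parse_delimited(path: Path, temperature: float) -> AreaSeries:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:
        raise TableFormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: need at least two columns (time, area)")
    time_col, area_col = df.columns[:2]
    for col in (time_col, area_col):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            lineno = int(bad.idxmax()) + 2
            raise TableFormatError(f"{path}:{lineno}: non-numeric field in '{col}'")
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")
    return AreaSeries(
        times=df[time_col].to_numpy(dtype=float),
        areas=df[area_col].to_numpy(dtype=float),
        temperature=temperature,
    )


def read_area_table(path, temperature: float) -> AreaSeries:
    """Read an area time series from xvg-style text or CSV/TSV.

    The dialect is chosen by suffix: ``.csv``/``.tsv`` are delimited with a
    header; anything else is treated as xvg-style whitespace columns.
    ``temperature`` (K) is attached as series metadata — neither format
    carries it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".csv", ".tsv", ".tab"}:
        return _parse_delimited(path, temperature)
    return _parse_xvg(path, temperature)


def write_area_xvg(series: AreaSeries, path) -> None:
    """Write an area series as xvg-style two-column text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# instantaneous membrane area\n")
        fh.write(f"# temperature_K = {series.temperature!r}\n")
        fh.write('@    xaxis  label "time"\n')
        fh.write('@    yaxis  label "area (nm^2)"\n')
        for t, a in zip(series.times, series.areas):
            fh.write(f"{t:.6f} {a:.10f}\n")


def read_z_table(path) -> pd.DataFrame:
    """Read a TSV phosphorus z-table with columns frame, atom_index, z_nm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"frame", "atom_index", "z_nm"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: z table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise TableFormatError(f"{path}: no data rows")
    if pd.to_numeric(df["z_nm"], errors="coerce").isna().any():
        raise TableFormatError(f"{path}: non-numeric z_nm value")
    return df


def write_z_table(table: pd.DataFrame, path) -> None:
    """Write a phosphorus z-table as TSV with a float format stable to 1e-10."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10f")


def write_profile_csv(profile: DensityProfile, path) -> None:
    """Density profile as (z_center, density) CSV for plotting."""
    pd.DataFrame(
        {"z_center_nm": profile.bin_centers, "density_per_nm": profile.density}
    ).to_csv(path, index=False)


def write_block_curve_csv(curve: BlockErrorCurve, path) -> None:
    """Block-error curve as (block_size, se) CSV for diagnostics."""
    pd.DataFrame(
        {"block_size": curve.block_sizes, "se": curve.se_estimates}
    ).to_csv(path, index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
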