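"""TOML run configuration for the end-to-end pipeline.

A run file describes one section per lipid/temperature condition, e.g.::

    [run]
    output_dir = "results"
    d0_nm = 1.0
    bin_width_nm = 0.05
    equilibration_fraction = 0.25

    [lipids.DOPC]
    temperature_C = 30
    area_file = "dopc_area.xvg"
    z_file = "dopc_z.tsv"

    [lipids.DDPC]
    temperature_C = 30
    [lipids.DDPC.synthetic]
    area_modulus_mn_per_m = 190.0
    reference_area_nm2 = 145.0
    thickness_nm = 3.4
    peak_sigma_nm = 0.35
    n_frames = 20000
    n_phosphorus = 400
    correlation_rho = 0.0
    seed = 3

Each section supplies either file paths or a ``synthetic`` sub-table with
ground-truth parameters; temperatures are accepted in °C (as run matrices
are usually written) or K and converted once, here — all physics downstream
is in K.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import units
from .synthetic import SyntheticMembraneSpec


@dataclass(frozen=True)
class LipidSection:
    label: str
    temperature: float  # K
    area_file: Path | None = None
    z_file: Path | None = None
    synthetic: SyntheticMembraneSpec | None = None
    equilibration: int | float | None = None
    stride: int = 1

    def __post_init__(self) -> None:
        has_files = self.area_file is not None and self.z_file is not None
        if has_files == (self.synthetic is not None):
            raise ValueError(
                f"section {self.label!r}: give either area_file+z_file "
                "or a [synthetic] sub-table, not both or neither"
            )


@dataclass(frozen=True)
class RunConfig:
    sections: tuple[LipidSection, ...]
    output_dir: Path
    d0_nm: float = 1.0
    bin_width_nm: float = 0.05
    equilibration: int | float = 0.25
    stride: int = 1
    config_path: Path | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        labels = [(s.label, s.temperature) for s in self.sections]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate (label, temperature) sections in config")
        if not self.sections:
            raise ValueError("config defines no lipid sections")


def _section_temperature(label: str, table: dict) -> float:
    if "temperature_C" in table:
        return units.celsius_to_kelvin(float(table["temperature_C"]))
    if "temperature_K" in table:
        t = float(table["temperature_K"])
        if t <= 0:
            raise ValueError(f"section {label!r}: temperature_K must be > 0")
        return t
    raise ValueError(f"section {label!r}: temperature_C or temperature_K required")


def _synthetic_spec(table: dict, temperature: float) -> SyntheticMembraneSpec:
    return SyntheticMembraneSpec(
        target_area_modulus=float(table["area_modulus_mn_per_m"]),
        reference_area=float(table["reference_area_nm2"]),
        temperature=temperature,
        n_frames=int(table.get("n_frames", 20_000)),
        correlation_rho=float(table.get("correlation_rho", 0.0)),
        thickness_true=float(table["thickness_nm"]),
        peak_sigma=float(table.get("peak_sigma_nm", 0.35)),
        n_phosphorus=int(table.get("n_phosphorus", 400)),
        seed=int(table.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    run = raw.get("run", {})
    base = path.parent
    sections = []
    for label, table in raw.get("lipids", {}).items():
        temperature = _section_temperature(label, table)
        synthetic = None
        area_file = z_file = None
        if "synthetic" in table:
            synthetic = _synthetic_spec(table["synthetic"], temperature)
        else:
            area_file = base / table["area_file"]
            z_file = base / table["z_file"]
            for p in (area_file, z_file):
                if not p.exists():
                    raise FileNotFoundError(f"section {label!r}: {p}")
        sections.append(
            LipidSection(
                label=label,
                temperature=temperature,
                area_file=area_file,
                z_file=z_file,
                synthetic=synthetic,
                equilibration=table.get("equilibration"),
                stride=int(table.get("stride", run.get("stride", 1))),
            )
        )
    return RunConfig(
        sections=tuple(sections),
        output_dir=base / run.get("output_dir", "results"),
        d0_nm=float(run.get("d0_nm", 1.0)),
        bin_width_nm=float(run.get("bin_width_nm", 0.05)),
        equilibration=run.get("equilibration_fraction", run.get("equilibration", 0.25)),
        stride=int(run.get("stride", 1)),
        config_path=path,
    )
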