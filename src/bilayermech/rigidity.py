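"""Bending rigidity from the area modulus and bilayer thickness.

The polymer-brush relation links the bending rigidity κ of a bilayer to
its area expansion modulus K_A and head-group peak-to-peak thickness d:

    κ = K_A (d − d0)² / 24

where d − d0 is the mechanically active ("bending") thickness and the
offset d0 is taken as 1 nm.  κ is reported both in joules and in kBT at
the ensemble temperature; its standard error follows from first-order
propagation of the K_A and d uncertainties.

The comparative report ranks lipid species by κ within each temperature
and attaches a verdict (lower / higher / indistinguishable at ±1 combined
SE) to every labeled pair, which is how orderings such as "di-DHA-PC is
softer than di-oleoyl-PC" are stated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd

from . import units

DEFAULT_D0_NM = 1.0


class UnphysicalThicknessError(ValueError):
    """Thickness below the d0 offset: κ would be imaginary-rooted nonsense."""


@dataclass(frozen=True)
class ElasticityResult:
    """K_A, d and κ for one lipid species at one temperature."""

    lipid_label: str
    temperature: float  # K
    area_modulus_mn_per_m: float
    area_modulus_se: float
    thickness_nm: float
    thickness_se: float
    d0_nm: float
    kappa_joule: float
    kappa_se_joule: float

    @property
    def kappa_kbt(self) -> float:
        return units.joule_to_kbt(self.kappa_joule, self.temperature)

    @property
    def kappa_se_kbt(self) -> float:
        return units.joule_to_kbt(self.kappa_se_joule, self.temperature)

    def as_dict(self) -> dict:
        return {
            "lipid_label": self.lipid_label,
            "temperature_K": self.temperature,
            "area_modulus_mN_per_m": self.area_modulus_mn_per_m,
            "area_modulus_se_mN_per_m": self.area_modulus_se,
            "thickness_nm": self.thickness_nm,
            "thickness_se_nm": self.thickness_se,
            "d0_nm": self.d0_nm,
            "kappa_J": self.kappa_joule,
            "kappa_se_J": self.kappa_se_joule,
            "kappa_kBT": self.kappa_kbt,
            "kappa_se_kBT": self.kappa_se_kbt,
        }


def compute_bending_rigidity(
    area_modulus: float,
    thickness: float,
    temperature: float,
    d0: float = DEFAULT_D0_NM,
    area_modulus_se: float = 0.0,
    thickness_se: float = 0.0,
    lipid_label: str = "",
) -> ElasticityResult:
    """κ = K_A(d − d0)²/24 with first-order error propagation.

    Parameters are K_A in mN/m, thickness d and offset d0 in nm, and the
    absolute temperature in K (used only to express κ in kBT).  The SE is

        σ_κ² = (∂κ/∂K_A σ_K)² + (∂κ/∂d σ_d)²
             = κ²[(σ_K/K_A)² + (2σ_d/(d−d0))²]   for d > d0.
    """
    if area_modulus <= 0:
        raise ValueError("area modulus must be > 0")
    if thickness < d0:
        raise UnphysicalThicknessError(
            f"thickness {thickness} nm is below the offset d0={d0} nm"
        )
    units.kbt_joule(temperature)  # validates temperature > 0
    bending_thickness_m = (thickness - d0) * 1e-9
    ka_n_per_m = area_modulus * 1e-3
    kappa_j = ka_n_per_m * bending_thickness_m**2 / 24.0

    dk_dka = bending_thickness_m**2 / 24.0 * 1e-3  # per (mN/m)
    dk_dd = ka_n_per_m * bending_thickness_m / 12.0 * 1e-9  # per nm
    kappa_se = math.hypot(dk_dka * area_modulus_se, dk_dd * thickness_se)

    return ElasticityResult(
        lipid_label=lipid_label,
        temperature=temperature,
        area_modulus_mn_per_m=area_modulus,
        area_modulus_se=area_modulus_se,
        thickness_nm=thickness,
        thickness_se=thickness_se,
        d0_nm=d0,
        kappa_joule=kappa_j,
        kappa_se_joule=kappa_se,
    )


def pair_verdict(a: ElasticityResult, b: ElasticityResult) -> str:
    """Compare κ of a against b: 'lower', 'higher', or 'indistinguishable'.

    The indifference band is ±1 combined SE, σ = sqrt(σ_a² + σ_b²): the
    reported errors are purely statistical (block averaging), so a pair is
    called only when its κ difference exceeds the combined error bar.
    """
    band = math.hypot(a.kappa_se_joule, b.kappa_se_joule)
    diff = a.kappa_joule - b.kappa_joule
    if diff < -band:
        return "lower"
    if diff > band:
        return "higher"
    return "indistinguishable"


def comparative_report(results: list[ElasticityResult]) -> dict:
    """Rank species by κ per temperature and summarize the spread across T.

    Returns a dict with:

    - ``per_temperature``: for each temperature (K), the results sorted by
      κ ascending and a verdict for every ordered pair of labels;
    - ``double_bond_effect``: per temperature, the spread max κ − min κ
      (in kBT) between the labeled species — the size of the composition
      effect on rigidity, which shrinks as temperature rises when thermal
      softening overtakes the unsaturation difference.

    Every temperature group must contain at least two results; comparisons
    never cross temperatures.
    """
    if len(results) < 2:
        raise ValueError("need at least two results to compare")
    by_temp: dict[float, list[ElasticityResult]] = {}
    for r in results:
        by_temp.setdefault(r.temperature, []).append(r)
    for temp, group in by_temp.items():
        if len(group) < 2:
            raise ValueError(
                f"temperature {temp} K has a single result; cross-temperature "
                "comparison without a matching group is not meaningful"
            )
        labels = [r.lipid_label for r in group]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate lipid labels at {temp} K: {labels}")

    report: dict = {"per_temperature": {}, "double_bond_effect": {}}
    for temp in sorted(by_temp):
        group = sorted(by_temp[temp], key=lambda r: r.kappa_joule)
        verdicts = [
            {
                "a": a.lipid_label,
                "b": b.lipid_label,
                "verdict": pair_verdict(a, b),
            }
            for a, b in itertools.permutations(group, 2)
        ]
        kbts = [r.kappa_kbt for r in group]
        report["per_temperature"][temp] = {
            "ranking": [r.as_dict() for r in group],
            "verdicts": verdicts,
        }
        report["double_bond_effect"][temp] = max(kbts) - min(kbts)
    return report


def report_table(report: dict) -> pd.DataFrame:
    """Flatten a comparative report into a tidy per-species table."""
    rows = []
    for temp, block in report["per_temperature"].items():
        for rank, entry in enumerate(block["ranking"]):
            rows.append({"rank_by_kappa": rank, **entry})
    return pd.DataFrame(rows)
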