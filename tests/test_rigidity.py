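"""Bending rigidity: analytic identity, unit consistency, comparative verdicts."""

import dataclasses

import numpy as np
import pytest

from bilayermech import (
    ElasticityResult,
    UnphysicalThicknessError,
    comparative_report,
    compute_bending_rigidity,
    pair_verdict,
    report_table,
)
from bilayermech.units import KB


def test_polymer_brush_relation_worked_example():
    """K_A = 240 mN/m, d = 4.0 nm, d0 = 1 nm:
    κ = 0.240 N/m × (3e-9 m)²/24 = 9.0e-20 J ≈ 21.5 kBT at 303.15 K."""
    r = compute_bending_rigidity(240.0, 4.0, temperature=303.15)
    assert r.kappa_joule == pytest.approx(9.0e-20, rel=1e-12)
    assert r.kappa_kbt == pytest.approx(9.0e-20 / (KB * 303.15), rel=1e-12)
    assert r.kappa_kbt == pytest.approx(21.5, abs=0.01)


def test_default_offset_is_one_nm():
    explicit = compute_bending_rigidity(240.0, 4.0, temperature=303.15, d0=1.0)
    implicit = compute_bending_rigidity(240.0, 4.0, temperature=303.15)
    assert implicit.d0_nm == 1.0
    assert implicit.kappa_joule == explicit.kappa_joule


def test_zero_rigidity_iff_thickness_equals_offset():
    r = compute_bending_rigidity(240.0, 1.0, temperature=303.15)
    assert r.kappa_joule == 0.0
    assert compute_bending_rigidity(240.0, 1.0 + 1e-6, temperature=303.15).kappa_joule > 0


def test_thickness_below_offset_rejected_not_clamped():
    with pytest.raises(UnphysicalThicknessError):
        compute_bending_rigidity(240.0, 0.9, temperature=303.15)


def test_unit_views_self_consistent():
    r = compute_bending_rigidity(
        255.0, 3.7, temperature=323.15, area_modulus_se=4.0, thickness_se=0.03
    )
    assert r.kappa_kbt * KB * r.temperature == pytest.approx(r.kappa_joule, rel=1e-12)
    assert r.kappa_se_kbt * KB * r.temperature == pytest.approx(
        r.kappa_se_joule, rel=1e-12
    )


def test_unit_round_trip_lossless():
    from bilayermech import units

    ka = 240.0  # mN/m
    j_nm2 = units.mn_per_m_to_j_per_nm2(ka)
    assert units.j_per_nm2_to_mn_per_m(j_nm2) == pytest.approx(ka, rel=1e-12)
    e_j = 9.0e-20
    assert units.kbt_to_joule(
        units.joule_to_kbt(e_j, 303.15), 303.15
    ) == pytest.approx(e_j, rel=1e-12)


@pytest.mark.parametrize("d", [1.5, 2.5, 3.5, 4.5])
def test_rigidity_increasing_in_modulus(d):
    kappas = [
        compute_bending_rigidity(ka, d, temperature=303.15).kappa_joule
        for ka in (100.0, 200.0, 300.0, 400.0)
    ]
    assert np.all(np.diff(kappas) > 0)


@pytest.mark.parametrize("ka", [100.0, 240.0, 400.0])
def test_rigidity_increasing_in_thickness(ka):
    kappas = [
        compute_bending_rigidity(ka, d, temperature=303.15).kappa_joule
        for d in (1.5, 2.5, 3.5, 4.5)
    ]
    assert np.all(np.diff(kappas) > 0)


def test_se_propagation_first_order():
    """σ_κ/κ = sqrt((σ_K/K)² + (2σ_d/(d−d0))²)."""
    r = compute_bending_rigidity(
        240.0, 4.0, temperature=303.15, area_modulus_se=12.0, thickness_se=0.06
    )
    expected_rel = np.hypot(12.0 / 240.0, 2 * 0.06 / 3.0)
    assert r.kappa_se_joule / r.kappa_joule == pytest.approx(expected_rel, rel=1e-12)


def _result(label, kappa_kbt, se_kbt, temperature=303.15):
    kbt = KB * temperature
    ka = 240.0
    d = 1.0 + np.sqrt(24.0 * kappa_kbt * kbt / (ka * 1e-3)) * 1e9
    return ElasticityResult(
        lipid_label=label,
        temperature=temperature,
        area_modulus_mn_per_m=ka,
        area_modulus_se=0.0,
        thickness_nm=d,
        thickness_se=0.0,
        d0_nm=1.0,
        kappa_joule=kappa_kbt * kbt,
        kappa_se_joule=se_kbt * kbt,
    )


class TestVerdicts:
    def test_self_comparison_indistinguishable(self):
        r = _result("DOPC", 20.0, 0.5)
        assert pair_verdict(r, r) == "indistinguishable"

    def test_clear_separation_called(self):
        soft = _result("DDPC", 12.0, 0.5)
        stiff = _result("DOPC", 20.0, 0.5)
        assert pair_verdict(soft, stiff) == "lower"
        assert pair_verdict(stiff, soft) == "higher"

    def test_widening_errors_only_moves_toward_indistinguishable(self):
        soft = _result("DDPC", 18.0, 1.0)
        stiff = _result("DOPC", 20.0, 1.0)
        assert pair_verdict(soft, stiff) == "lower"
        soft2 = _result("DDPC", 18.0, 2.0)
        stiff2 = _result("DOPC", 20.0, 2.0)
        assert pair_verdict(soft2, stiff2) == "indistinguishable"
        # never flips lower → higher
        assert pair_verdict(soft2, stiff2) != "higher"


class TestComparativeReport:
    def _trio(self, temperature=303.15):
        return [
            _result("DOPC", 19.2, 0.3, temperature),
            _result("DAPC", 16.8, 0.3, temperature),
            _result("DDPC", 12.6, 0.3, temperature),
        ]

    def test_ranking_sorted_ascending(self):
        report = comparative_report(self._trio())
        ranking = report["per_temperature"][303.15]["ranking"]
        assert [r["lipid_label"] for r in ranking] == ["DDPC", "DAPC", "DOPC"]

    def test_softest_species_verdicts(self):
        report = comparative_report(self._trio())
        verdicts = {
            (v["a"], v["b"]): v["verdict"]
            for v in report["per_temperature"][303.15]["verdicts"]
        }
        assert verdicts[("DDPC", "DOPC")] == "lower"
        assert verdicts[("DDPC", "DAPC")] == "lower"

    def test_double_bond_effect_spread(self):
        report = comparative_report(self._trio())
        assert report["double_bond_effect"][303.15] == pytest.approx(19.2 - 12.6, rel=1e-9)

    def test_spread_shrinks_with_temperature(self):
        cool = self._trio(303.15)
        warm = [
            _result("DOPC", 17.0, 0.3, 343.15),
            _result("DAPC", 15.5, 0.3, 343.15),
            _result("DDPC", 12.9, 0.3, 343.15),
        ]
        report = comparative_report(cool + warm)
        assert (
            report["double_bond_effect"][343.15]
            < report["double_bond_effect"][303.15]
        )

    def test_single_result_group_rejected(self):
        results = self._trio() + [_result("DOPC", 17.0, 0.3, temperature=343.15)]
        with pytest.raises(ValueError):
            comparative_report(results)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            comparative_report([_result("DOPC", 19.0, 0.3), _result("DOPC", 18.0, 0.3)])

    def test_report_table_flattens(self):
        table = report_table(comparative_report(self._trio()))
        assert len(table) == 3
        assert list(table["lipid_label"]) == ["DDPC", "DAPC", "DOPC"]
        assert list(table["rank_by_kappa"]) == [0, 1, 2]
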