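"""Material registry and unit/fraction conversion checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radnano import materials as mat
from radnano.errors import DomainError
from radnano.materials import ConcentrationRecord, REGISTRY, get_material


@pytest.mark.parametrize(
    "ssa,rho,expected,places",
    [
        (114.0, 9.68, 5.4, 1),     # HfO2
        (62.7, 5.40, 17.7, 1),     # TiN
        (6000.0, 1.0, 1.0, 6),     # algebraic identity
        (343.6, 2.65, 6.6, 1),     # SiO2
    ],
)
def test_bet_diameter(ssa, rho, expected, places):
    assert round(mat.bet_diameter(ssa, rho), places) == expected


def test_bet_diameter_identity_and_monotonicity():
    # d * SSA * rho == 6000 exactly, and d decreases in both arguments
    for ssa, rho in [(50.0, 2.0), (235.0, 4.3), (5.9, 19.3)]:
        d = mat.bet_diameter(ssa, rho)
        assert d * ssa * rho == pytest.approx(6000.0, rel=1e-12)
        assert mat.bet_diameter(ssa * 1.1, rho) < d
        assert mat.bet_diameter(ssa, rho * 1.1) < d
    with pytest.raises(DomainError):
        mat.bet_diameter(-1.0, 2.0)


@pytest.mark.parametrize(
    "wt,rho_np,mode,expected",
    [
        (0.05, 19.3, "dilute", 0.00259),   # 5 wt% Au ~ 0.26 vol%
        (0.0, 19.3, "exact", 0.0),
        (0.05, 19.3, "exact", 0.00272),    # exact mixture formula
    ],
)
def test_mass_to_volume_fraction(wt, rho_np, mode, expected):
    out = mat.mass_frac_to_vol_frac(wt, rho_np, 1.0, mode)
    assert out == pytest.approx(expected, abs=5e-6)


def test_mass_volume_round_trip_exact():
    for wt in (0.001, 0.05, 0.3, 0.9):
        for rho in (2.65, 7.16, 19.3):
            vol = mat.mass_frac_to_vol_frac(wt, rho, 1.0, "exact")
            back = mat.vol_frac_to_mass_frac(vol, rho, 1.0)
            assert back == pytest.approx(wt, rel=1e-12)


def test_dilute_vs_exact_bracketing():
    # for rho_np > rho_medium the dilute value underestimates the exact one
    for wt in (0.01, 0.05, 0.2):
        dil = mat.mass_frac_to_vol_frac(wt, 9.68, 1.0, "dilute")
        exact = mat.mass_frac_to_vol_frac(wt, 9.68, 1.0, "exact")
        assert dil <= exact


@pytest.mark.parametrize(
    "sa,ssa,expected",
    [(1840.0, 114.0, 1614.0), (0.0, 235.0, 0.0), (1840.0, 62.7, 2934.6)],
)
def test_surface_to_mass_concentration(sa, ssa, expected):
    assert mat.surface_conc_to_mass_conc(sa, ssa) == pytest.approx(expected, abs=0.5)


def test_metal_content_bound_at_max_surface_exposure():
    # at 1840 cm^2/mL every material of the ROS assay panel stays below
    # 0.3 wt% (Au sits outside the constant-surface design)
    for name in ("SiO2", "TiO2", "TiN", "WO3", "HfO2"):
        ug_ml = mat.surface_conc_to_mass_conc(1840.0, REGISTRY[name].ssa)
        assert ug_ml * 1e-4 < 0.3


@pytest.mark.parametrize(
    "n,d_np,d_ves,expected",
    [(166, 50.0, 400.0, 32.4), (0, 50.0, 400.0, 0.0), (1, 50.0, 400.0, 0.195)],
)
def test_vesicle_packing_fraction(n, d_np, d_ves, expected):
    assert mat.vesicle_packing_fraction(n, d_np, d_ves) == pytest.approx(
        expected, abs=0.05
    )


def test_vesicle_packing_impossible():
    with pytest.raises(DomainError):
        mat.vesicle_packing_fraction(600, 50.0, 400.0)  # >100 vol%


@pytest.mark.parametrize(
    "d,expected,tol",
    [(17.5, 2806.0, 1.0), ((6.0 / math.pi) ** (1 / 3), 1.0, 1e-9), (6.0, 113.1, 0.05)],
)
def test_sphere_volume(d, expected, tol):
    assert mat.sphere_volume(d) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "name,expected",
    [("HfO2", 0.848), ("Au", 1.0), ("TiN", 0.774), ("WO3", 0.793), ("TiO2", 0.599)],
)
def test_metal_mass_fraction(name, expected):
    assert mat.metal_mass_fraction(name) == pytest.approx(expected, abs=5e-4)


def test_unknown_element_rejected():
    with pytest.raises(KeyError):
        mat.parse_formula("Xx2O3")


def test_registry_packing_configuration():
    # the reference vesicle configuration recomputes for every registry
    # material's 50 nm primary spheres in a 400 nm vesicle
    for _ in REGISTRY:
        assert mat.vesicle_packing_fraction(166, 50.0, 400.0) == pytest.approx(
            32.4, abs=0.05
        )


def test_concentration_record_round_trips():
    m = get_material("TiN")
    rec = ConcentrationRecord("surface_cm2_mL", 1840.0, m)
    mass = rec.to("mass_ug_mL")
    assert mass.value == pytest.approx(2934.6, abs=0.1)
    wt = rec.to("wt_percent")
    assert wt.value == pytest.approx(0.2935, abs=1e-3)
    for basis in ("mass_ug_mL", "wt_percent", "vol_percent", "surface_cm2_mL"):
        back = rec.to(basis).to("surface_cm2_mL")
        assert back.value == pytest.approx(1840.0, rel=1e-9)


@settings(max_examples=50, deadline=None)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    ssa=st.floats(min_value=1.0, max_value=500.0),
    rho=st.floats(min_value=0.5, max_value=25.0),
)
def test_dimensional_scaling_properties(scale, ssa, rho):
    # bet_diameter ~ 1/(ssa*rho); surface->mass linear in sa_conc;
    # sphere_volume ~ d^3
    assert mat.bet_diameter(ssa * scale, rho) == pytest.approx(
        mat.bet_diameter(ssa, rho) / scale, rel=1e-9
    )
    assert mat.surface_conc_to_mass_conc(100.0 * scale, ssa) == pytest.approx(
        scale * mat.surface_conc_to_mass_conc(100.0, ssa), rel=1e-9
    )
    d = 3.7
    assert mat.sphere_volume(d * scale) == pytest.approx(
        mat.sphere_volume(d) * scale**3, rel=1e-9
    )


def test_material_spec_validation():
    with pytest.raises(DomainError):
        mat.MaterialSpec("bad", "SiO2", bulk_density=-1.0)
    with pytest.raises(DomainError):
        mat.MaterialSpec("bad", "SiO2", bulk_density=2.65, ssa=-5.0)
    spec = get_material("HfO2")
    assert spec.bet_diameter_nm == pytest.approx(5.4, abs=0.05)
    assert 0.0 < spec.metal_mass_fraction <= 1.0
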