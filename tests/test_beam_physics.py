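"""Spectra, spectrum-weighted coefficients, macroscopic DEF and chi fits."""

import io

import numpy as np
import pytest

from radnano import beam_physics as bp
from radnano.errors import DomainError, FitError, FormatError


def test_spectrum_normalization_and_builtins():
    s = bp.load_spectrum(io.StringIO("energy_keV,weight\n60,5\n"))
    assert s.weights.tolist() == [1.0]
    two = bp.load_spectrum(io.StringIO("energy_keV,weight\n40,1\n80,1\n"))
    assert two.weights.tolist() == [0.5, 0.5]
    kv = bp.load_spectrum("kv150")
    assert kv.energies.max() < 150.0 + 1e-9  # tube-voltage cutoff
    assert np.all(kv.weights >= 0) and kv.weights.sum() == pytest.approx(1.0)
    mv = bp.load_spectrum("mv6")
    assert mv.energies.max() == 6000.0


def test_spectrum_format_errors():
    with pytest.raises(FormatError):
        bp.load_spectrum(io.StringIO("energy_keV,weight\n80,1\n40,1\n"))
    with pytest.raises(FormatError):
        bp.load_spectrum(io.StringIO("energy_keV,weight\n40,-1\n80,1\n"))
    with pytest.raises(FormatError):
        bp.load_spectrum(io.StringIO("energy_keV,weight\n40,abc\n"))


def _mono_table(ratio):
    # scaled copy of the water table on its own grid, so mu_Z = ratio * mu_w
    # holds at every interpolation point
    water = bp.get_coefficient_table("water")
    e = water.energies
    return bp.CoefficientTable("fake", e, water.mu_en_rho * ratio, water.mu_rho)


def test_macroscopic_def_trivial_substitutions():
    mono = bp.PhotonSpectrum(np.array([100.0]), np.array([1.0]))
    fake = _mono_table(10.0)  # mu_Z = 10 mu_w at every energy
    assert bp.macroscopic_def(fake, 0.0, mono) == 1.0
    assert bp.macroscopic_def(fake, 0.1, mono) == pytest.approx(2.0, rel=1e-9)
    assert bp.macroscopic_def(fake, 0.1, mono, mode="mixture") == pytest.approx(
        1.9, rel=1e-9
    )


def test_water_against_itself_gives_unit_ratio():
    for spec in ("kv150", "mv6"):
        s = bp.load_spectrum(spec)
        w = bp.spectrum_mean_coefficient("water", s)
        assert bp.macroscopic_def("water", 0.3, s) == pytest.approx(1.3, rel=1e-12)
        assert bp.macroscopic_def("water", 0.3, s, mode="mixture") == pytest.approx(
            1.0, rel=1e-12
        )
        assert w > 0


def test_def_monotone_in_f_mass_as_printed():
    kv = bp.load_spectrum("kv150")
    defs = [bp.macroscopic_def("Au", f, kv) for f in (0.0, 0.01, 0.05, 0.2, 1.0)]
    assert defs[0] == 1.0
    assert all(a < b for a, b in zip(defs, defs[1:]))
    assert all(d >= 1.0 for d in defs)


def test_kv150_material_ordering():
    """Under the kV tube spectrum, coefficient ratios group by atomic number:
    Au above HfO2/WO3, both far above the titanium compounds, SiO2 lowest."""
    kv = bp.load_spectrum("kv150")
    w = bp.spectrum_mean_coefficient("water", kv)
    r = {
        m: bp.spectrum_mean_coefficient(m, kv) / w
        for m in ("SiO2", "TiO2", "TiN", "WO3", "HfO2", "Au")
    }
    assert r["Au"] > r["HfO2"] >= r["WO3"]
    assert r["WO3"] > r["TiO2"] > r["SiO2"]
    assert r["WO3"] > r["TiN"] > r["SiO2"]
    assert r["SiO2"] > 1.0


def test_mv6_ratios_strongly_reduced_for_high_z():
    kv = bp.load_spectrum("kv150")
    mv = bp.load_spectrum("mv6")
    for m in ("Au", "HfO2", "WO3"):
        r_kv = bp.spectrum_mean_coefficient(m, kv) / bp.spectrum_mean_coefficient(
            "water", kv
        )
        r_mv = bp.spectrum_mean_coefficient(m, mv) / bp.spectrum_mean_coefficient(
            "water", mv
        )
        assert r_kv / r_mv >= 5.0


def test_fluence_vs_energy_fluence_weighting_both_exposed():
    kv = bp.load_spectrum("kv150")
    a = bp.spectrum_mean_coefficient("Au", kv, weighting="energy_fluence")
    b = bp.spectrum_mean_coefficient("Au", kv, weighting="fluence")
    assert a != b  # hardened weighting shifts the mean
    with pytest.raises(DomainError):
        bp.spectrum_mean_coefficient("Au", kv, weighting="bogus")


def test_chi_fit_examples():
    fit = bp.chi_fit([1.5, 2.0, 3.0], [0.1, 0.2, 0.4])
    assert fit.chi == pytest.approx(5.0, rel=1e-12)
    assert fit.ci95 == pytest.approx(0.0, abs=1e-9)
    flat = bp.chi_fit([1.0, 1.0, 1.0], [0.1, 0.2, 0.4])
    assert flat.chi == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(FitError):
        bp.chi_fit([1.5, 2.0], [0.0, 0.0])


def test_chi_fit_recovers_noisy_truth_within_ci(rng):
    true_chi = 10.5
    f = np.array([0.05, 0.1, 0.2, 0.4, 0.8])
    hits = 0
    for _ in range(50):
        d = 1.0 + true_chi * f + rng.normal(0.0, 0.15, size=f.size)
        fit = bp.chi_fit(d, f)
        if abs(fit.chi - true_chi) <= fit.ci95:
            hits += 1
    assert hits >= 40  # ~95% nominal coverage
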