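"""Survival chain: standard curve, LQ fits, LD50, DMR, toxicity, NER/DoP."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radnano import survival as sv
from radnano.errors import DomainError, FitError


def test_luminescence_conversion_as_printed():
    curve = sv.StandardCurve()
    assert sv.luminescence_to_cells(0.0, curve) == 0.0
    assert sv.luminescence_to_cells(1.0e5, curve) == pytest.approx(9723.0, abs=1.0)
    # linear: doubling luminescence doubles cells
    assert sv.luminescence_to_cells(2.0e5, curve) == pytest.approx(
        2 * sv.luminescence_to_cells(1.0e5, curve), rel=1e-12
    )


def test_luminescence_conversion_saturation():
    curve = sv.StandardCurve(form="saturation")
    assert sv.luminescence_to_cells(1.936e6, curve) == pytest.approx(
        3.431e5, rel=1e-6
    )  # y = a/2 returns b
    with pytest.raises(DomainError):
        sv.luminescence_to_cells(4.0e6, curve)  # beyond the plateau


def test_standard_curve_round_trip():
    for form in ("as_printed", "saturation"):
        curve = sv.StandardCurve(form=form)
        x = np.array([10.0, 1e3, 2e4])
        back = curve.to_cells(curve.to_luminescence(x))
        np.testing.assert_allclose(back, x, rtol=1e-12)


def test_surviving_fraction_basics():
    assert sv.surviving_fraction(500.0, 1000.0) == 0.5
    assert sv.surviving_fraction(1000.0, 1000.0) == 1.0
    assert sv.surviving_fraction(1100.0, 1000.0) == pytest.approx(1.1)  # not clipped
    with pytest.raises(DomainError):
        sv.surviving_fraction(10.0, 0.0)


def test_lq_fit_exact_recovery():
    d = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    sf = np.exp(-(0.2 * d + 0.03 * d * d))
    fit = sv.fit_lq(d, sf)
    assert fit.alpha == pytest.approx(0.2, abs=1e-8)
    assert fit.beta == pytest.approx(0.03, abs=1e-8)
    assert fit.sf(0.0) == 1.0


def test_lq_fit_flat_survival():
    d = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    fit = sv.fit_lq(d, np.ones_like(d))
    assert fit.alpha == pytest.approx(0.0, abs=1e-10)
    assert fit.beta == pytest.approx(0.0, abs=1e-10)
    assert math.isinf(fit.ld50) and fit.extrapolated


def test_lq_fit_noisy_recovery(rng):
    d = np.repeat([0.0, 2.0, 4.0, 6.0, 8.0], 3)
    hits = 0
    for _ in range(60):
        sf = np.exp(-(0.2 * d + 0.03 * d * d)) * rng.lognormal(0, 0.1, d.size)
        fit = sv.fit_lq(d, sf)
        sd_a, sd_b = np.sqrt(np.diag(fit.covariance))
        if abs(fit.alpha - 0.2) <= 2 * sd_a and abs(fit.beta - 0.03) <= 2 * sd_b:
            hits += 1
    assert hits >= 48  # >= 80% joint 2-sigma coverage


def test_lq_fit_input_validation():
    with pytest.raises(FitError):
        sv.fit_lq([2.0, 4.0, 6.0], [0.9, 0.7, 0.5])  # no 0 Gy anchor
    with pytest.raises(FitError):
        sv.fit_lq([0.0, 2.0], [1.0, 0.9])


@pytest.mark.parametrize(
    "alpha,beta,expected",
    [
        (math.log(2) / 2.0, 0.0, 2.0),
        (0.1, 0.05, 2.855),
        (0.0, 0.1, 2.633),
    ],
)
def test_ld50_closed_forms(alpha, beta, expected):
    assert sv.ld50(alpha, beta) == pytest.approx(expected, abs=5e-4)


def test_ld50_continuous_at_beta_zero():
    a = 0.2
    assert sv.ld50(a, 1e-14) == pytest.approx(sv.ld50(a, 0.0), rel=1e-10)
    assert math.isinf(sv.ld50(0.0, 0.0))


@settings(max_examples=60, deadline=None)
@given(
    alpha=st.floats(min_value=1e-4, max_value=2.0),
    beta=st.floats(min_value=0.0, max_value=0.5),
)
def test_ld50_inverse_identity(alpha, beta):
    d = sv.ld50(alpha, beta)
    assert math.exp(-(alpha * d + beta * d * d)) == pytest.approx(0.5, abs=1e-9)


def test_dmr_identity_and_scaling():
    d = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    ctrl = sv.fit_lq(d, np.exp(-(0.2 * d + 0.03 * d * d)))
    assert sv.dmr50(ctrl, ctrl) == 1.0
    # dose-scaling law: (alpha, beta) -> (k alpha, k^2 beta) gives DMR = k
    k = 1.7
    scaled = sv.fit_lq(d, np.exp(-(k * 0.2 * d + k * k * 0.03 * d * d)))
    assert sv.dmr50(ctrl, scaled) == pytest.approx(k, rel=1e-6)
    flat = sv.fit_lq(d, np.ones_like(d))
    with pytest.raises(FitError):
        sv.dmr50(ctrl, flat)


def test_toxicity_sigmoid_lc50():
    # a = e^2, b = 1 -> LC50 = 2
    x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
    y = 1.0 - 1.0 / (1.0 + math.e**2 * np.exp(-x))
    tox = sv.fit_toxicity(x, np.clip(y, 1e-6, 1.5))
    assert tox.lc50 == pytest.approx(2.0, rel=1e-3)
    assert tox.included[5.0] is False  # viability ~0.047 < 0.60


def test_toxicity_flat_viability_no_crossing():
    x = np.array([0.0, 50.0, 150.0, 300.0])
    tox = sv.fit_toxicity(x, np.ones_like(x))
    assert math.isinf(tox.lc50)
    assert all(tox.included.values())


def test_toxicity_recovers_tin_like_lc50(rng):
    true_lc50, b = 157.0, 0.03
    a = math.exp(b * true_lc50)
    x = np.array([0.0, 20.0, 40.0, 80.0, 160.0, 320.0])
    y = 1.0 - 1.0 / (1.0 + a * np.exp(-b * x))
    y = np.clip(y * rng.lognormal(0, 0.05, x.size), 1e-6, 1.5)
    tox = sv.fit_toxicity(x, y)
    assert tox.lc50 == pytest.approx(true_lc50, rel=0.10)


def test_ner_and_dop_examples():
    assert sv.ner(0.75, 0.375) == pytest.approx(2.0)
    # printed rounded NER pairs: TiO2-like 2.0 -> 1.3 gives 70% protection
    assert sv.dop(0.9, 0.9 / 1.3, 0.75, 0.375) == pytest.approx(0.70, abs=1e-9)
    # WO3-like: NER unchanged by DMSO -> no protection
    assert sv.dop(0.9, 0.9 / 1.6, 0.75, 0.75 / 1.6) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(DomainError):
        sv.dop(0.9, 0.9, 0.8, 0.9)  # NER_noDMSO < 1: nothing to protect


@settings(max_examples=40, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=5.0))
def test_dop_invariant_under_common_sf_rescaling(scale):
    base = sv.dop(0.9, 0.6, 0.8, 0.4)
    scaled = sv.dop(0.9 * scale, 0.6 * scale, 0.8 * scale, 0.4 * scale)
    assert scaled == pytest.approx(base, rel=1e-9)
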