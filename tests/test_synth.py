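"""Synthetic-data generators: determinism and forward-inverse consistency."""

import numpy as np
import pandas as pd
import pytest

from radnano import survival as sv
from radnano.errors import DomainError
from radnano.synth import (
    GeneratorConfig,
    MaterialTruth,
    dmso_protection,
    expected_dop,
    expected_ner,
    gen_quench_plate,
    gen_ros_plate,
    gen_survival_plate,
    gen_uptake_table,
    truth_for_ner_pair,
)


def test_generators_are_pure_functions_of_config():
    cfg = GeneratorConfig(seed=77)
    for gen in (gen_survival_plate, gen_quench_plate, gen_ros_plate,
                gen_uptake_table):
        a, b = gen(cfg), gen(cfg)
        pd.testing.assert_frame_equal(a, b)
    other = gen_survival_plate(GeneratorConfig(seed=78))
    assert not gen_survival_plate(cfg).equals(other)


def test_plate_design_mirrors_study_layout():
    cfg = GeneratorConfig(seed=1, materials={"HfO2": MaterialTruth()})
    df = gen_survival_plate(cfg)
    ctrl = df[(df["material"] == "none") & (df["batch"] == 1)]
    assert sorted(ctrl["dose_Gy"].unique()) == [0.0, 2.0, 4.0, 6.0, 8.0]
    assert ctrl.groupby("dose_Gy")["replicate"].count().eq(6).all()
    np_wells = df[(df["material"] == "HfO2") & (df["batch"] == 1)]
    assert np_wells.groupby(["conc_ug_mL", "dose_Gy"])["replicate"].count().eq(3).all()


def test_dmso_protection_shape():
    assert dmso_protection(0.0) == 0.0
    assert dmso_protection(0.5) == pytest.approx(1.0)
    assert dmso_protection(1.0) == 1.0
    vals = [dmso_protection(c) for c in (0.0, 0.11, 0.334, 0.667, 1.0)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    with pytest.raises(DomainError):
        dmso_protection(-0.1)


def test_zero_noise_dmr_round_trip_exact():
    cfg = GeneratorConfig(
        seed=9, cv=0.0,
        materials={"Au": MaterialTruth(k_max=2.0, concentrations=(40.0,))},
    )
    res = sv.run_survival_pipeline(gen_survival_plate(cfg))
    assert res["dmr"]["dmr50"].iloc[0] == pytest.approx(2.0, abs=1e-6)


def test_zero_noise_full_quench_gives_unit_ner():
    cfg = GeneratorConfig(
        seed=9, cv=0.0,
        materials={"TiN": MaterialTruth(k_max=1.5, phi=1.0, quench_conc=80.0,
                                        concentrations=(80.0,))},
    )
    quench = sv.run_survival_pipeline(gen_quench_plate(cfg))["quench"]
    at_1m = quench[np.isclose(quench["dmso_M"], 1.0)]
    assert at_1m["ner"].iloc[0] == pytest.approx(1.0, abs=1e-9)
    assert at_1m["dop"].iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_pipeline_dop_matches_closed_form_expectation():
    cfg = GeneratorConfig(
        seed=9, cv=0.0,
        materials={"HfO2": MaterialTruth(k_max=2.0, phi=0.52,
                                         concentrations=(160.0,),
                                         quench_conc=160.0)},
    )
    quench = sv.run_survival_pipeline(gen_quench_plate(cfg))["quench"]
    for _, row in quench.iterrows():
        assert row["ner"] == pytest.approx(
            expected_ner(cfg, "HfO2", row["dmso_M"]), rel=1e-9
        )
        if row["dmso_M"] > 0:
            assert row["dop"] == pytest.approx(
                expected_dop(cfg, "HfO2", row["dmso_M"]), abs=1e-9
            )


def test_truth_for_printed_ner_pair_round_trip():
    # configure the generator so the plate encodes NER 2.0 -> 1.3, then
    # verify the pipeline reads back exactly that pair and DoP = 70%
    k, phi = truth_for_ner_pair(2.0, 1.3)
    cfg = GeneratorConfig(
        seed=1, cv=0.0,
        materials={"TiO2": MaterialTruth(k_max=k, phi=phi,
                                         concentrations=(160.0,),
                                         quench_conc=160.0)},
    )
    assert expected_ner(cfg, "TiO2", 0.0) == pytest.approx(2.0, rel=1e-9)
    assert expected_ner(cfg, "TiO2", 1.0) == pytest.approx(1.3, rel=1e-9)
    quench = sv.run_survival_pipeline(gen_quench_plate(cfg))["quench"]
    at_1m = quench[np.isclose(quench["dmso_M"], 1.0)]
    assert at_1m["dop"].iloc[0] == pytest.approx(0.70, abs=1e-9)


def test_ros_generator_null_slope_covered_by_ci():
    from radnano.ros import analyze_ros_plate

    covered = 0
    for seed in range(10):
        cfg = GeneratorConfig(
            seed=500 + seed, materials={"SiO2": MaterialTruth(ros_slope=0.0)}
        )
        fit = analyze_ros_plate(gen_ros_plate(cfg)).iloc[0]
        covered += fit["ci95_lo"] <= 0.0 <= fit["ci95_hi"]
    assert covered >= 8  # nominal 95% coverage of the zero slope


def test_monotonicity_dmr_in_enhancement_factor():
    dmrs = []
    for k in (1.0, 1.3, 1.8, 2.5):
        cfg = GeneratorConfig(
            seed=33,
            materials={"Au": MaterialTruth(k_max=k, concentrations=(40.0,))},
        )
        res = sv.run_survival_pipeline(gen_survival_plate(cfg))
        dmrs.append(res["dmr"]["dmr50"].iloc[0])
    assert all(b >= a - 0.03 for a, b in zip(dmrs, dmrs[1:]))


def test_toxic_concentration_excluded_from_dmr():
    # LC50 at 60 ug/mL makes 160+ ug/mL wells fail the 60% viability cutoff
    cfg = GeneratorConfig(
        seed=3, cv=0.0,
        materials={"TiN": MaterialTruth(k_max=1.5, lc50_ug_mL=60.0, tox_b=0.05)},
    )
    dmr = sv.run_survival_pipeline(gen_survival_plate(cfg))["dmr"]
    flags = dmr.set_index("conc_ug_mL")["included"]
    assert not flags.loc[160.0]
    assert not flags.loc[320.0]
    assert flags.loc[20.0]
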