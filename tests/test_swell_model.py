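"""Forward simulator: flux laws, equilibria, cohort generation, determinism."""

import numpy as np
import pytest

from oocyteswell import (
    AssayTruth,
    BathCondition,
    CohortSpec,
    ConfigError,
    ConstructSpec,
    EmptyGroupError,
    IntegrationFailureError,
    SimDefaults,
    SwellParams,
    generate_cohort,
    hypotonic_water_bath,
    isotonic_solute_bath,
    simulate_swelling,
    trace_to_volume,
)
from oocyteswell.units import V_W


def test_zero_permeability_gives_flat_trace(water_bath):
    p = SwellParams(p_water_true=0.0, p_solute_true=0.0, noise_sd_frac=0.0)
    tr = simulate_swelling(p, water_bath)
    np.testing.assert_array_equal(tr.diameters, np.full(21, 0.12))
    assert tr.truth is p


def test_constant_mode_matches_linear_closed_form(water_bath):
    """V/V0 = 1 + (P S0 V_w dOsm / V0) t for the frozen-gradient model."""
    p = SwellParams(
        p_water_true=10e-6, gradient_model="constant", noise_sd_frac=0.0, d0=0.12
    )
    vt = trace_to_volume(simulate_swelling(p, water_bath))
    rate = 10e-6 * (6.0 / 0.12) * V_W * 100e-6  # P * (S0/V0) * V_w * dC
    expected = 1.0 + rate * vt.times
    np.testing.assert_allclose(vt.rel_volume, expected, rtol=1e-3)
    # the model is exactly linear, so agreement is in fact machine-precision
    np.testing.assert_allclose(vt.rel_volume, expected, rtol=1e-12)


def test_dilution_equilibrium_doubles_volume(water_bath):
    """Halving external osmolality doubles volume once C_in = C_out."""
    p = SwellParams(
        p_water_true=200e-6,
        gradient_model="dilution",
        noise_sd_frac=0.0,
        dt_sample=2e4,
        duration=2e6,
    )
    vt = trace_to_volume(simulate_swelling(p, water_bath))
    assert vt.rel_volume[-1] == pytest.approx(2.0, abs=1e-3)


def test_dilution_equilibrium_with_non_osmotic_volume(water_bath):
    """V_f/V0 = v + (1 - v) osm_in0/osm_out with osmotically dead fraction v."""
    v = 0.3
    p = SwellParams(
        p_water_true=200e-6,
        vb_frac=v,
        gradient_model="dilution",
        noise_sd_frac=0.0,
        dt_sample=2e4,
        duration=2e6,
    )
    vt = trace_to_volume(simulate_swelling(p, water_bath))
    assert vt.rel_volume[-1] == pytest.approx(v + (1 - v) * 2.0, rel=5e-3)


def test_dilution_swelling_strictly_monotone(water_bath):
    p = SwellParams(p_water_true=50e-6, gradient_model="dilution", noise_sd_frac=0.0)
    vt = trace_to_volume(simulate_swelling(p, water_bath))
    assert np.all(np.diff(vt.rel_volume) > 0)


def test_solute_entry_drives_swelling_in_dilution_mode(urea_bath):
    """With a fast-water membrane, solute influx produces sustained swelling."""
    p = SwellParams(
        p_water_true=5e-3,  # water equilibrates quickly relative to solute entry
        p_solute_true=5e-6,
        gradient_model="dilution",
        noise_sd_frac=0.0,
    )
    vt = trace_to_volume(simulate_swelling(p, urea_bath))
    assert np.all(np.diff(vt.rel_volume) > 0)
    assert vt.rel_volume[-1] > 1.001


def test_runaway_shrinkage_raises_integration_failure(water_bath):
    p = SwellParams(p_water_true=-0.1, gradient_model="constant", noise_sd_frac=0.0)
    with pytest.raises(IntegrationFailureError):
        simulate_swelling(p, water_bath)


def test_noise_is_seed_reproducible(water_bath):
    p = SwellParams(p_water_true=10e-6, gradient_model="constant", seed=7)
    a = simulate_swelling(p, water_bath)
    b = simulate_swelling(p, water_bath)
    np.testing.assert_array_equal(a.diameters, b.diameters)
    c = simulate_swelling(SwellParams(p_water_true=10e-6, gradient_model="constant", seed=8), water_bath)
    assert not np.array_equal(a.diameters, c.diameters)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(mode="hypotonic", osm_out=100.0, solute="urea", sol_out=180.0),
        dict(mode="isotonic_solute", osm_out=200.0, solute="none", sol_out=180.0, osm_total=200.0),
        dict(mode="isotonic_solute", osm_out=200.0, solute="urea", sol_out=0.0, osm_total=200.0),
        dict(mode="hypotonic", osm_out=-5.0),
        dict(mode="nonsense", osm_out=100.0),
    ],
)
def test_bath_invariants_enforced(kwargs):
    with pytest.raises(ConfigError):
        BathCondition(**kwargs)


def test_assay_labels(water_bath, urea_bath):
    assert water_bath.assay_label == "water"
    assert urea_bath.assay_label == "urea"
    assert isotonic_solute_bath("glycerol").assay_label == "glycerol"


# --- cohort generation ------------------------------------------------------


def _one_group_spec(n=5, mean=10.0, sd=0.0, seed=1):
    return CohortSpec(
        constructs=(ConstructSpec("X", {"water": AssayTruth(n=n, mean=mean, sd=sd)}),),
        seed=seed,
    )


def test_zero_sd_cohort_draws_equal_the_mean():
    _, manifest = generate_cohort(_one_group_spec(n=5, mean=10.0, sd=0.0))
    assert len(manifest) == 5
    np.testing.assert_array_equal(manifest["p_true_1e6"], np.full(5, 10.0))


def test_cohort_is_deterministic_under_fixed_seed():
    spec = _one_group_spec(n=4, mean=5.0, sd=2.0, seed=123)
    traces_a, man_a = generate_cohort(spec)
    traces_b, man_b = generate_cohort(spec)
    assert man_a.equals(man_b)
    for a, b in zip(traces_a, traces_b):
        np.testing.assert_array_equal(a.diameters, b.diameters)
    _, man_c = generate_cohort(_one_group_spec(n=4, mean=5.0, sd=2.0, seed=124))
    assert not man_a["p_true_1e6"].equals(man_c["p_true_1e6"])


def test_empty_group_rejected():
    with pytest.raises(EmptyGroupError):
        AssayTruth(n=0, mean=1.0, sd=0.1)


def test_truncated_draws_respect_the_floor():
    """Draws are floored at -(mean + 3 sd), admitting mild negative leak only."""
    spec = CohortSpec(
        constructs=(ConstructSpec("C", {"urea": AssayTruth(n=400, mean=0.1, sd=0.4)}),),
        seed=11,
    )
    _, manifest = generate_cohort(spec)
    assert manifest["p_true_1e6"].min() >= -(0.1 + 3 * 0.4)
    assert (manifest["p_true_1e6"] < 0).any()  # negatives are representable


def test_cohort_traces_carry_matching_truth_and_ids():
    spec = CohortSpec(
        constructs=(
            ConstructSpec(
                "Y",
                {
                    "water": AssayTruth(n=3, mean=8.0, sd=1.0),
                    "glycerol": AssayTruth(n=2, mean=20.0, sd=5.0),
                },
            ),
        ),
        seed=3,
    )
    traces, manifest = generate_cohort(spec)
    assert len(traces) == 5
    truth_by_id = dict(zip(manifest["oocyte_id"], manifest["p_true_1e6"]))
    for tr in traces:
        assert tr.oocyte_id in truth_by_id
        label = tr.bath.assay_label
        truth = tr.truth.p_water_true if label == "water" else tr.truth.p_solute_true
        assert truth == pytest.approx(truth_by_id[tr.oocyte_id] * 1e-6, rel=1e-12)


def test_unknown_assay_in_construct_rejected():
    with pytest.raises(ConfigError):
        ConstructSpec("X", {"ethanol": AssayTruth(n=3, mean=1.0, sd=0.1)})


def test_sim_defaults_are_the_assay_design():
    d = SimDefaults()
    assert d.dt_sample == 30.0 and d.duration == 600.0 and d.d0 == 0.12
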