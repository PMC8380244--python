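"""Identifier parsing, de-aggregation, unit conversion and urine cumulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alumtk.curation import (ConversionError, MOLAR_MASS_AL26, ParseError,
                             convert_to_fid, curate_dataset, deaggregate,
                             fid_to_unit, parse_identifier, urine_cumulative)

PUBLISHED_IDENTIFIERS = [
    "Steinhausen2004-AlChl-po-hum-75kg",
    "Steinhausen2004-AlChl-iv-hum-79kg",
    "Yokel2001b-AlChl-po-rat-fasted-hardwater-280g",
    "Drueeke1997-AlChl-po-rat-addcit-275g",
    "Beck1997-AlChl-iv-rat-300g",
    "Priest1995-AlCit-iv-hum-77kg",
    "Edwardson1993-AlCit-po-hum-73kg",
]


@pytest.mark.parametrize("text", PUBLISHED_IDENTIFIERS)
def test_identifier_round_trip(text):
    assert parse_identifier(text).serialise() == text


def test_identifier_fields():
    ident = parse_identifier("Steinhausen2004-AlChl-po-hum-75kg")
    assert (ident.study, ident.salt, ident.route) == ("Steinhausen2004", "AlChl", "po")
    assert ident.species == "hum" and ident.comments == ()
    assert ident.body_weight_kg == 75.0

    ident = parse_identifier("Yokel2001b-AlChl-po-rat-fasted-hardwater-280g")
    assert ident.comments == ("fasted", "hardwater")
    assert ident.species == "rat"
    assert ident.body_weight_kg == pytest.approx(0.280)

    # nominal field order (comments before species) also parses and round-trips
    alt = "Yokel2001b-AlChl-po-fasted-hardwater-rat-280g"
    assert parse_identifier(alt).serialise() == alt


@pytest.mark.parametrize("bad", [
    "Study-AlOx-po-hum-75kg",        # unknown salt
    "Study-AlChl-sc-hum-75kg",       # unknown route
    "Study-AlChl-po-mouse-20g",      # unknown species
    "Study-AlChl-po-frozen-hum-75kg",  # unknown comment token
    "Study-AlChl-po-hum-75lbs",      # unparseable body weight
    "Study-AlChl-po",                # too short
])
def test_identifier_parse_errors(bad):
    with pytest.raises(ParseError):
        parse_identifier(bad)


# ---------------------------------------------------------------------------
# de-aggregation


def test_deaggregate_exact_log_moments():
    N, m, sd = 5, 10.0, 2.0
    values = deaggregate(N, m, sd, seed=3)
    sigma2 = math.log(sd**2 / m**2 + 1.0)
    mu = math.log(m) - sigma2 / 2.0
    logs = np.log(values)
    assert logs.mean() == pytest.approx(mu, abs=1e-12)
    assert np.std(logs, ddof=1) == pytest.approx(math.sqrt(sigma2), abs=1e-12)
    assert sigma2 == pytest.approx(math.log(1.04))


def test_deaggregate_degenerate_and_errors():
    assert np.all(deaggregate(4, 7.5, 0.0, seed=0) == 7.5)
    with pytest.raises(Exception):
        deaggregate(1, 10.0, 2.0, seed=0)
    with pytest.raises(Exception):
        deaggregate(5, -1.0, 2.0, seed=0)


def test_deaggregate_deterministic_and_sized():
    a = deaggregate(16, 3.0, 0.9, seed=11)
    b = deaggregate(16, 3.0, 0.9, seed=11)
    assert len(a) == 16 and np.array_equal(a, b)  # a 16-sample summary -> 16 records
    c = deaggregate(16, 3.0, 0.9, seed=12)
    assert not np.array_equal(a, c)


@given(st.integers(2, 50), st.floats(0.01, 1e3), st.floats(0.0, 10.0),
       st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_deaggregate_moment_property(N, m, sd_frac, seed):
    sd = sd_frac * m / 10.0
    values = deaggregate(N, m, sd, seed=seed)
    assert np.all(values > 0)
    if sd > 0:
        sigma2 = math.log(sd**2 / m**2 + 1.0)
        logs = np.log(values)
        assert logs.mean() == pytest.approx(math.log(m) - sigma2 / 2.0, rel=1e-9, abs=1e-9)
        assert np.std(logs, ddof=1) == pytest.approx(math.sqrt(sigma2), rel=1e-9, abs=1e-9)


def test_deaggregate_arithmetic_moments_converge():
    values = deaggregate(20000, 10.0, 2.0, seed=5)
    assert values.mean() == pytest.approx(10.0, rel=0.02)
    assert values.std(ddof=1) == pytest.approx(2.0, rel=0.05)


# ---------------------------------------------------------------------------
# unit conversion


def test_convert_to_fid_rules(human_male):
    dose_g = 4e-4
    assert convert_to_fid(0.37, "fid", "liv", human_male) == 0.37
    # blood concentration: c x V_blo / dose
    assert convert_to_fid(1e-6, "g_per_L", "blo", human_male, dose_g) == \
        pytest.approx(1e-6 * 5.30 / dose_g)
    # plasma uses V_blo x (1 - Hct)
    assert convert_to_fid(1e-6, "g_per_L", "pla", human_male, dose_g) == \
        pytest.approx(1e-6 * 5.30 * 0.57 / dose_g)
    # fid per litre -> whole compartment
    assert convert_to_fid(0.01, "fid_per_L", "bon", human_male) == pytest.approx(0.01 * 8.07)
    # fid per gram -> whole-organ mass in g (V x D x 1000)
    assert convert_to_fid(1e-5, "fid_per_g", "bon", human_male) == \
        pytest.approx(1e-5 * 8.07 * 1.3 * 1000)
    # percent of dose per kg -> organ mass / 100
    assert convert_to_fid(2.0, "percent_dose_per_kg", "bon", human_male) == \
        pytest.approx(2.0 * 8.07 * 1.3 / 100)
    assert convert_to_fid(1e-7, "g_per_g", "liv", human_male, dose_g) == \
        pytest.approx(1e-7 * 1800.0 / dose_g)


def test_per_gram_misreading_inflates_recovery(human_male):
    # a plausible per-kg bone reading misread as per-gram overstates the
    # recovered dose by 1e5, tripping the > 100% plausibility check
    per_kg = 4.0  # percent of dose per kg
    ok = convert_to_fid(per_kg, "percent_dose_per_kg", "bon", human_male)
    misread = convert_to_fid(per_kg / 100.0, "fid_per_g", "bon", human_male)
    assert ok < 1.0
    assert misread > 4.0


def test_convert_to_fid_errors(human_male):
    with pytest.raises(ConversionError):
        convert_to_fid(1.0, "fid_per_g", "uri", human_male)       # per-gram urine
    with pytest.raises(ConversionError):
        convert_to_fid(1.0, "g_per_L", "blo", human_male, None)   # missing dose
    with pytest.raises(ConversionError):
        convert_to_fid(1.0, "g_per_L", "uri", human_male, 1e-4)   # missing volume


@given(st.floats(1e-8, 0.9), st.sampled_from(["blo", "pla", "liv", "bon"]),
       st.sampled_from(["g_per_L", "fid_per_L", "fid"]))
@settings(max_examples=60, deadline=None)
def test_unit_round_trip(fid, matrix, unit):
    from alumtk.physiology import reference_for

    ref = reference_for("human", "male")
    if unit == "g_per_L" and matrix not in ("blo", "pla"):
        unit = "fid_per_L"
    dose_g = 3.7e-4
    reported = fid_to_unit(fid, unit, matrix, ref, dose_g)
    back = convert_to_fid(reported, unit, matrix, ref, dose_g)
    assert back == pytest.approx(fid, rel=1e-12)


def test_urine_cumulative():
    assert urine_cumulative(0.0, 1.5, 1e-6) == 0.0
    assert urine_cumulative(1e-9, 1.5, 1e-6) == pytest.approx(1.5e-3)
    with pytest.raises(ConversionError):
        urine_cumulative(1e-9, -1.0, 1e-6)


# ---------------------------------------------------------------------------
# dataset-level pipeline


def test_observation_record_invariants(human_male):
    from alumtk.curation import ObservationRecord
    from alumtk.physiology import InvalidInputError

    ident = parse_identifier("Beck1997-AlChl-iv-rat-300g")
    rec = ObservationRecord(ident, "g1", 24.0, "bon", 0.02, "fid",
                            dose_total_mol=6e-7)
    assert not rec.is_summary
    assert rec.dose_total_g == pytest.approx(6e-7 * MOLAR_MASS_AL26)
    summary = ObservationRecord(ident, "g1", 24.0, "bon", None, "fid",
                                n=16, mean=0.02, sd=0.004)
    assert summary.is_summary
    with pytest.raises(InvalidInputError):
        ObservationRecord(ident, "g1", 1e-6, "bon", 0.02, "fid")  # below 1 s
    with pytest.raises(InvalidInputError):
        ObservationRecord(ident, "g1", 24.0, "lung", 0.02, "fid")
    with pytest.raises(InvalidInputError):
        ObservationRecord(ident, "g1", 24.0, "bon", -0.1, "fid")


def _frame(rows):
    base = {"identifier": "Test2020-AlChl-iv-hum-73kg", "group_id": "g1",
            "matrix": "pla", "unit": "fid", "n": np.nan, "mean": np.nan,
            "sd": np.nan, "dose_mol_per_kg": 1e-6, "dose_total_mol": 7.3e-5,
            "complete_collection": True, "collected_volume_L": 1.5, "sex": "male"}
    return pd.DataFrame([{**base, **r} for r in rows])


def test_curate_rejects_implausible_times_and_incomplete_urine():
    df = _frame([
        {"time_h": 1e-5, "value": 0.5},                       # < 1 s
        {"time_h": 24.0, "value": 0.01},
        {"time_h": 24.0, "matrix": "uri", "unit": "g_per_L", "value": 1e-9,
         "complete_collection": False},
    ])
    curated, rejected = curate_dataset(df)
    assert len(curated) == 1 and len(rejected) == 2
    assert set(rejected["reject_reason"]) == {"implausible sampling time <= 1 s",
                                              "incomplete urine collection"}


def test_curate_urine_running_sum():
    dose_g = 7.3e-5 * MOLAR_MASS_AL26
    df = _frame([
        {"time_h": 24.0, "matrix": "uri", "unit": "g_per_L", "value": 2e-9},
        {"time_h": 48.0, "matrix": "uri", "unit": "g_per_L", "value": 1e-9},
    ])
    curated, _ = curate_dataset(df)
    c1 = 2e-9 * 1.5 / dose_g
    c2 = c1 + 1e-9 * 1.5 / dose_g
    got = curated.sort_values("time_h")["value"].to_numpy()
    assert got == pytest.approx([c1, c2])


def test_curate_expands_summary_rows_and_flags():
    df = _frame([
        {"time_h": 24.0, "value": np.nan, "n": 16, "mean": 0.02, "sd": 0.005},
        {"time_h": 48.0, "value": 1.4},   # > 1 dose -> flagged, kept
    ])
    curated, rejected = curate_dataset(df, seed=4)
    assert len(curated) == 17
    assert curated["flag_above_unity"].sum() == 1
    assert len(rejected) == 0
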