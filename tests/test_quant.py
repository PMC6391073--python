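"""iBAQ normalization, absolute calibration and complex copy numbers."""

import math

import numpy as np
import pandas as pd
import pytest

from cyanoecon import (CalibrationSpec, calibrate_absolute,
                       complex_copy_number, load_complex_library,
                       normalize_ibaq, parse_stoichiometry)
from cyanoecon.quant import (MOLECULES_PER_FMOL, StoichiometryParseError,
                             complex_table)

REFS = ("Q55806", "P72587", "P73505", "Q59978")


def make_ibaq(rng, n_extra=6, n_samples=5):
    ids = list(REFS) + [f"X{i}" for i in range(n_extra)]
    data = rng.lognormal(10, 1, (len(ids), n_samples))
    return pd.DataFrame(data, index=ids,
                        columns=[f"s{j}" for j in range(n_samples)])


def spec(**kw):
    kw.setdefault("anchor_id", "P73505")
    kw.setdefault("cells_per_volume", 2.0e4)
    return CalibrationSpec(**kw)


class TestNormalizeIbaq:
    def test_reference_sum_becomes_one(self, rng):
        norm = normalize_ibaq(make_ibaq(rng), spec())
        sums = norm.loc[list(REFS)].sum(axis=0)
        assert np.allclose(sums, 1.0)

    def test_scale_invariance_and_idempotence(self, rng):
        ibaq = make_ibaq(rng)
        scaled = ibaq.copy()
        scaled["s2"] *= 10.0
        norm = normalize_ibaq(ibaq, spec())
        assert np.allclose(normalize_ibaq(scaled, spec()), norm)
        assert np.allclose(normalize_ibaq(norm, spec()), norm)

    def test_planted_sample_scales_removed(self, rng):
        """Between-sample ratios after normalization equal the planted
        biological ratios, regardless of per-sample scale factors."""
        ibaq = make_ibaq(rng)
        scales = rng.uniform(0.2, 5.0, ibaq.shape[1])
        distorted = ibaq * scales
        norm_a = normalize_ibaq(ibaq, spec())
        norm_b = normalize_ibaq(distorted, spec())
        assert np.allclose(norm_a, norm_b)

    def test_missing_reference_errors_name_sample(self, rng):
        ibaq = make_ibaq(rng)
        ibaq.loc["Q55806", "s3"] = np.nan
        with pytest.raises(ValueError, match="s3"):
            normalize_ibaq(ibaq, spec())
        with pytest.raises(KeyError):
            normalize_ibaq(ibaq.drop(index="P72587"), spec())


class TestCalibrateAbsolute:
    def test_linearity_in_anchor_amount(self, rng):
        norm = normalize_ibaq(make_ibaq(rng), spec())
        c1 = calibrate_absolute(norm, spec(anchor_amount=104.0))
        c2 = calibrate_absolute(norm, spec(anchor_amount=208.0))
        assert np.allclose(c2, 2.0 * c1)
        c3 = calibrate_absolute(norm, spec(anchor_amount=104.0,
                                           cells_per_volume=4.0e4))
        assert np.allclose(c3, 0.5 * c1)

    def test_anchor_closed_form(self):
        norm = pd.DataFrame({"s1": [0.37], "s2": [0.37]}, index=["P73505"])
        copies = calibrate_absolute(norm, spec(anchor_amount=104.0,
                                               cells_per_volume=2.0e4))
        expected = 104.0 * MOLECULES_PER_FMOL / 2.0e4
        assert np.allclose(copies, expected)
        assert MOLECULES_PER_FMOL == pytest.approx(6.022e8, rel=1e-3)

    def test_round_trip_planted_copy_numbers(self, rng):
        """Intensities proportional to planted copies are recovered."""
        planted = pd.Series(rng.integers(1e3, 1e6, 10).astype(float),
                            index=list(REFS) + [f"X{i}" for i in range(6)])
        cal = spec(cells_per_volume=3.1e4, anchor_amount=50.0)
        fmol = planted * cal.cells_per_volume / MOLECULES_PER_FMOL
        ibaq = pd.DataFrame({f"s{j}": fmol * rng.uniform(0.5, 2.0)
                             for j in range(4)})
        norm = normalize_ibaq(ibaq, cal)
        anchor_fmol = float(fmol.loc[cal.anchor_id])
        cal_true = spec(cells_per_volume=3.1e4, anchor_amount=anchor_fmol)
        copies = calibrate_absolute(norm, cal_true)
        rel = (copies.sub(planted, axis=0)).div(planted, axis=0).abs()
        assert float(rel.max().max()) < 1e-6


class TestStoichiometryParser:
    @pytest.mark.parametrize("text, expected", [
        ("(RbcL, RbcS)8", {"RbcL": 8, "RbcS": 8}),
        ("TufA", {"TufA": 1}),
        ("TktA2", {"TktA": 2}),
        ("Slr20944", {"Slr2094": 4}),
        ("GlnB3", {"GlnB": 3}),
        ("(PdhA, PdhB)2", {"PdhA": 2, "PdhB": 2}),
        ("Gap2*4", {"Gap2": 4}),
    ])
    def test_examples(self, text, expected):
        assert parse_stoichiometry(text).subunits == expected

    def test_photosystem_one_expands_to_twelve_subunits(self):
        cx = parse_stoichiometry("(PsaA,B,C,D,E,F,I,J,K,L,M,X)3")
        assert len(cx.subunits) == 12
        assert all(v == 3 for v in cx.subunits.values())
        assert "PsaC" in cx.subunits and "PsaX" in cx.subunits

    def test_nested_groups_with_multipliers(self):
        cx = parse_stoichiometry("((CpcA,B)18,C1,C2,D,G)6")
        assert cx.subunits["CpcA"] == 108 and cx.subunits["CpcB"] == 108
        assert cx.subunits["CpcC1"] == 6 and cx.subunits["CpcG"] == 6

    @pytest.mark.parametrize("bad", ["(RbcL", "RbcL)", "A,,B", "", "()4",
                                     "Rbc*L"])
    def test_malformed_input_errors_with_position(self, bad):
        with pytest.raises(StoichiometryParseError) as err:
            parse_stoichiometry(bad)
        assert "position" in str(err.value)

    def test_packaged_library_loads(self):
        lib = load_complex_library()
        assert lib["RuBisCO"].subunits == {"RbcL": 8, "RbcS": 8}
        assert lib["Chaperonine GroEL"].subunits == {"GroL1": 14}
        assert len(lib["Ribosome small subunit"].subunits) == 22


class TestComplexCopyNumber:
    def test_single_subunit_passthrough(self):
        cx = parse_stoichiometry("TufA")
        est = complex_copy_number({"TufA": 250000.0}, cx)
        assert est.weighted == 250000.0
        assert est.lower_bound == est.upper_bound == 250000.0

    def test_homodimer_halves_copies(self):
        cx = parse_stoichiometry("SodB2")
        est = complex_copy_number({"SodB": 30000.0}, cx)
        assert est.weighted == 15000.0

    def test_heterotrimer_hand_calculation(self):
        cx = parse_stoichiometry("Aaa,Bbb,Ccc2")
        est = complex_copy_number({"Aaa": 1000.0, "Bbb": 1200.0,
                                   "Ccc": 2200.0}, cx)
        assert est.weighted == pytest.approx(1100.0)
        assert est.lower_bound == pytest.approx(1000.0)

    def test_weighted_estimate_bounded_by_subunit_ratios(self, rng):
        cx = parse_stoichiometry("(PsaA,B,C,D)3")
        copies = {s: float(c) for s, c in
                  zip(cx.subunits, rng.integers(1e3, 1e5, 4))}
        est = complex_copy_number(copies, cx)
        assert est.lower_bound - 1e-12 <= est.weighted <= est.upper_bound + 1e-12

    def test_missing_subunits_listed_and_undefined_case(self):
        cx = parse_stoichiometry("(RbcL,RbcS)8")
        est = complex_copy_number({"RbcL": 26000.0 * 8}, cx)
        assert est.missing_subunits == ["RbcS"]
        assert est.weighted == pytest.approx(26000.0)
        empty = complex_copy_number({}, cx)
        assert not empty.defined and math.isnan(empty.weighted)

    def test_condition_table(self):
        lib = {"Dimer": parse_stoichiometry("SodB2")}
        table = complex_table(
            {"low": {"SodB": 20000.0}, "high": {"SodB": 50000.0}},
            library=lib)
        row = table.iloc[0]
        assert row["copies_min"] == 10000.0 and row["copies_max"] == 25000.0
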