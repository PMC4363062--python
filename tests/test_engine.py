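"""Dose engine: averaging, equivalent/effective doses, breakdowns, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ankledose.engine import (
    DoseEstimate,
    EffectiveDoseResult,
    compute_effective_dose,
    contribution_breakdown,
    dose_ratio,
    effective_dose,
    equivalent_dose,
    estimate_from_readings,
    mean_dose,
    round_half_up,
)
from ankledose.phantom import (
    Aggregation,
    DosimeterRecord,
    FractionEntry,
    FractionTable,
    PhantomLayer,
    PhantomModel,
    Tissue,
    TissueWeightTable,
    resolve_groups,
)
from conftest import oracle_effective_dose


def _est(no, dose):
    return DoseEstimate(dosimeter_no=no, mean_dose_mGy=dose, rel_sd_pct=0.0,
                        n_exposures=1)


class TestMeanDose:
    def test_constant_readings(self):
        rec = DosimeterRecord(dosimeter_no=1, layer=23, site="s",
                              tissue=Tissue.SKIN, subunit="s",
                              readings=[4.04] * 6)
        est = mean_dose(rec)
        assert est.mean_dose_mGy == pytest.approx(4.04)
        assert est.rel_sd_pct == pytest.approx(0.0)
        assert est.n_exposures == 6

    def test_constructed_low_dose_spread(self):
        """Six readings built to have mean 0.25 mGy and sample SD 0.0825 mGy
        (33 % relative), the spread of the faintest field-edge dosimeter."""
        z = np.array([1.0, -1.0, 1.0, -1.0, np.sqrt(0.5), -np.sqrt(0.5)])
        readings = list(0.25 + 0.0825 * z)
        # independent check of the construction
        assert np.mean(readings) == pytest.approx(0.25)
        assert np.std(readings, ddof=1) == pytest.approx(0.0825)
        est = estimate_from_readings(1, readings)
        assert est.rel_sd_pct == pytest.approx(33.0)

    def test_no_readings_errors(self):
        with pytest.raises(ValueError, match="no readings"):
            estimate_from_readings(1, [])

    def test_zero_mean_nonzero_spread_flagged(self):
        est = estimate_from_readings(1, [0.0, 0.0, 0.0])
        assert est.rel_sd_pct == 0.0


class TestEquivalentDose:
    def test_skin_worked_example(self, groups, estimates):
        """Two skin sites at 3.86 and 7.11 mGy with f = 0.009 / 0.026 give
        H_skin = 219.6 uSv."""
        res = equivalent_dose(groups.groups[Tissue.SKIN], estimates)
        assert res.H_T_uSv == pytest.approx(0.009 * 3.86e3 + 0.026 * 7.11e3)
        assert res.H_T_uSv == pytest.approx(219.6, abs=0.05)

    def test_marrow_mean_then_fraction(self, groups, estimates):
        res = equivalent_dose(groups.groups[Tissue.BONE_MARROW], estimates)
        # tibia mean(0.25,0.48,0.81,4.04)*0.007 + fibula mean(0.73,6.53)*0.001
        # + 4.09*0.001 + 4.25*0.001 + 6.45*0.002, in uSv
        assert res.H_T_uSv == pytest.approx(34.635, abs=1e-9)
        assert res.H_T_uSv == sum(s.contribution_uSv for s in res.subunits)

    def test_all_zero_doses(self, groups):
        zeros = {no: _est(no, 0.0) for no in range(1, 21)}
        res = equivalent_dose(groups.groups[Tissue.SKIN], zeros)
        assert res.H_T_uSv == 0.0

    def test_missing_estimate_names_dosimeter(self, groups, estimates):
        partial = {k: v for k, v in estimates.items() if k != 10}
        with pytest.raises(KeyError, match="10"):
            equivalent_dose(groups.groups[Tissue.SKIN], partial)


class TestEffectiveDose:
    def test_remainder_contributions(self, result):
        """Lymph (mean 10.4/6.15 mGy, f = 0.010) and muscle (f = 0.009)
        under the w_remainder/13 rule round to 0.8 and 0.1 uSv."""
        assert result.tissues[Tissue.LYMPHATIC_NODES] == pytest.approx(
            (0.12 / 13) * 0.010 * ((10.4 + 6.15) / 2) * 1e3
        )
        assert round_half_up(result.tissues[Tissue.LYMPHATIC_NODES], 1) == 0.8
        assert round_half_up(result.tissues[Tissue.MUSCLE], 1) == 0.1

    def test_conservation(self, result):
        assert result.E_uSv == pytest.approx(sum(result.tissues.values()), rel=1e-15)
        display = result.display_percentages()
        assert abs(sum(display.values()) - 100) <= 2

    def test_all_zero_gives_zero(self, groups, weights):
        zeros = {no: _est(no, 0.0) for no in range(1, 21)}
        res = compute_effective_dose(groups, zeros, weights)
        assert res.E_uSv == 0.0
        assert all(c == 0.0 for c in res.tissues.values())

    def test_tissue_without_weight_errors(self, groups, estimates):
        bad = TissueWeightTable(w_T={"remainder": 0.12})
        with pytest.raises(KeyError, match="bone_marrow"):
            compute_effective_dose(groups, estimates, bad)

    def test_duplicate_tissue_rejected(self, groups, estimates, weights):
        res = equivalent_dose(groups.groups[Tissue.SKIN], estimates)
        with pytest.raises(ValueError, match="twice"):
            effective_dose([res, res], weights)


class TestBreakdown:
    def _printed_msct(self):
        tissues = {
            Tissue.BONE_MARROW: 9.5, Tissue.BONE_SURFACE: 7.2, Tissue.SKIN: 3.1,
            Tissue.LYMPHATIC_NODES: 0.9, Tissue.MUSCLE: 0.6,
        }
        return EffectiveDoseResult(
            E_uSv=21.4, tissues=tissues, H_T_uSv={},
            percentages={t: 100 * c / 21.4 for t, c in tissues.items()},
        )

    def test_msct_marrow_share(self):
        rows = contribution_breakdown(self._printed_msct())
        assert rows[0] == (Tissue.BONE_MARROW, 9.5, 44)
        assert rows[1][0] is Tissue.BONE_SURFACE and rows[1][2] == 34

    def test_single_tissue_is_100pct(self):
        res = EffectiveDoseResult(E_uSv=5.0, tissues={Tissue.SKIN: 5.0},
                                  H_T_uSv={}, percentages={Tissue.SKIN: 100.0})
        assert contribution_breakdown(res) == [(Tissue.SKIN, 5.0, 100)]

    def test_zero_E_flagged(self):
        res = EffectiveDoseResult(E_uSv=0.0, tissues={}, H_T_uSv={}, percentages={})
        with pytest.raises(ValueError, match="undefined"):
            contribution_breakdown(res)


class TestDoseRatio:
    def test_msct_vs_radiography(self):
        r = dose_ratio(21.4, 1.5)
        assert r.raw == pytest.approx(14.2667, abs=1e-3)
        assert r.display == "14-fold"

    def test_identity(self):
        assert dose_ratio(3.3, 3.3).raw == 1.0

    def test_below_ten_one_decimal(self):
        r = dose_ratio(14.3, 1.5)
        assert r.raw == pytest.approx(9.5333, abs=1e-3)
        assert r.display == "9.5-fold"

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            dose_ratio(1.0, 0.0)


@st.composite
def random_study(draw):
    """A small random phantom + fraction table + estimates."""
    n = draw(st.integers(min_value=1, max_value=10))
    numbers = list(range(1, n + 1))
    entries = []
    i = 0
    k = 0
    while i < len(numbers):
        size = draw(st.integers(min_value=1, max_value=3))
        members = numbers[i:i + size]
        i += size
        entries.append(FractionEntry(
            tissue=draw(st.sampled_from(list(Tissue))),
            subunit=f"sub{k}",
            f_i=draw(st.floats(min_value=1e-3, max_value=0.05)),
            dosimeters=members,
            aggregation=draw(st.sampled_from(list(Aggregation))),
        ))
        k += 1
    records = [
        DosimeterRecord(dosimeter_no=no, layer=23, site=f"s{no}",
                        tissue=Tissue.SKIN, subunit=f"s{no}")
        for no in numbers
    ]
    model = PhantomModel(layers=[PhantomLayer(index=23)], records=records)
    doses = {
        no: draw(st.floats(min_value=0.0, max_value=20.0)) for no in numbers
    }
    return model, FractionTable(entries=entries), doses


@settings(derandomize=True, max_examples=60, deadline=None)
@given(study=random_study())
def test_engine_matches_bruteforce_oracle(study, weights):
    """A flat-loop recomputation matches the engine to 1e-12 relative."""
    model, fractions, doses = study
    estimates = {no: _est(no, d) for no, d in doses.items()}
    groups = resolve_groups(model, fractions)
    res = compute_effective_dose(groups, estimates, weights)
    expected = oracle_effective_dose(fractions, weights, estimates)
    assert res.E_uSv == pytest.approx(expected, rel=1e-12, abs=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(study=random_study(), k=st.floats(min_value=1e-3, max_value=1e3))
def test_linearity_in_readings(study, k, weights):
    """Scaling every dose by k scales every H_T, contribution and E by k."""
    model, fractions, doses = study
    groups = resolve_groups(model, fractions)
    base = compute_effective_dose(groups, {n: _est(n, d) for n, d in doses.items()}, weights)
    scaled = compute_effective_dose(
        groups, {n: _est(n, k * d) for n, d in doses.items()}, weights
    )
    assert scaled.E_uSv == pytest.approx(k * base.E_uSv, rel=1e-9, abs=1e-12)
    for t in base.tissues:
        assert scaled.tissues[t] == pytest.approx(k * base.tissues[t], rel=1e-9, abs=1e-12)
        assert scaled.H_T_uSv[t] == pytest.approx(k * base.H_T_uSv[t], rel=1e-9, abs=1e-12)
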