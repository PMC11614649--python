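import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from poppk import (PKParameters, SimulationDesign, attainment_probability,
                   conc_steady_state, exceedance_probability, recommend_doses,
                   simulate_virtual_patients, typical_parameters)
from poppk.simulation import CONDITION_FLAGS, PTAResult
import pandas as pd


class TestProbabilities:
    def test_all_inside(self):
        assert attainment_probability([150, 200, 499], (100, 500)) == 1.0

    def test_direct_count(self):
        assert attainment_probability([50, 150, 600], (100, 500)) == \
            pytest.approx(1 / 3)

    def test_counting_oracle(self, rng):
        sample = rng.uniform(0, 1000, 10_000)
        expected = sum(1 for c in sample if 100 <= c <= 500) / len(sample)
        assert attainment_probability(sample, (100, 500)) == expected

    def test_exceedance_cases(self):
        assert exceedance_probability([400, 501], 500) == 0.5
        assert exceedance_probability([100, 499], 500) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            attainment_probability([], (100, 500))
        with pytest.raises(ValueError):
            exceedance_probability([], 500)

    @given(st.lists(st.floats(0.0, 1000.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_partition_identity(self, sample):
        att = attainment_probability(sample, (100.0, 500.0))
        exc = exceedance_probability(sample, 500.0)
        below = np.mean(np.asarray(sample) < 100.0)
        assert att + exc + below == pytest.approx(1.0)


class TestSimulate:
    def test_degenerate_distribution(self, ref_model):
        m = replace(ref_model, omega2_cl=0.0)
        design = SimulationDesign(weight_grid=(70.0,), dose_grid=(12.0,),
                                  n_virtual=50, conditions=("none",), seed=1)
        pta = simulate_virtual_patients(m, design)
        att = pta.cell(70.0, 12.0, "none").attainment
        assert att in (0.0, 1.0)

    def test_zero_dose_all_below(self, ref_model):
        design = SimulationDesign(weight_grid=(70.0,), dose_grid=(0.0,),
                                  n_virtual=20, conditions=("none",), seed=1)
        cell = simulate_virtual_patients(ref_model, design).cell(70.0, 0.0,
                                                                 "none")
        assert cell.attainment == 0.0
        assert cell.below == 1.0

    def test_seed_contract_bit_identical(self, ref_model):
        design = SimulationDesign(n_virtual=100, seed=9)
        a = simulate_virtual_patients(ref_model, design)
        b = simulate_virtual_patients(ref_model, design)
        assert a.table.equals(b.table)
        for key in a.samples:
            np.testing.assert_array_equal(a.samples[key], b.samples[key])

    def test_quadrature_oracle_spot_check(self, ref_model):
        design = SimulationDesign(weight_grid=(60.0,), dose_grid=(12.0,),
                                  n_virtual=1000, conditions=("none",), seed=5)
        pta = simulate_virtual_patients(ref_model, design)
        att = pta.cell(60.0, 12.0, "none").attainment
        expected = quadrature_attainment(ref_model, 60.0, 12.0, "none",
                                         design)
        se = np.sqrt(expected * (1 - expected) / 1000)
        assert abs(att - expected) <= 3 * se + 1e-9

    def test_ddi_ordering_of_exposure(self, ref_model):
        design = SimulationDesign(weight_grid=(80.0,), dose_grid=(12.0,),
                                  n_virtual=500, seed=3)
        pta = simulate_virtual_patients(ref_model, design)
        means = {c: pta.samples[(80.0, 12.0, c)].mean()
                 for c in ("none", "flu", "dul", "both")}
        assert means["both"] > means["flu"] > means["none"]
        assert means["both"] > means["dul"] > means["none"]
        assert means["flu"] == pytest.approx(means["dul"], rel=0.1)

    def test_exceedance_monotone_in_dose(self, ref_model):
        design = SimulationDesign(weight_grid=(60.0, 100.0), n_virtual=300,
                                  conditions=("none", "both"), seed=4)
        pta = simulate_virtual_patients(ref_model, design)
        for cond in ("none", "both"):
            for w in (60.0, 100.0):
                sub = pta.table[(pta.table.condition == cond)
                                & (pta.table.weight == w)].sort_values("dose")
                exc = sub.exceedance.to_numpy()
                assert np.all(np.diff(exc) >= -1e-12)


def quadrature_attainment(m, weight, dose_rate, condition, design):
    """Independent oracle: P(lower <= C(eta) <= upper) by root finding on
    the monotone concentration-in-eta map plus the normal CDF."""
    flu, dul = CONDITION_FLAGS[condition]
    typ = typical_parameters(weight, flu, dul, m)
    dose = dose_rate * weight * design.interval / 24.0
    omega = np.sqrt(m.omega2_value)

    def conc(eta):
        p = PKParameters(cl=typ.cl * np.exp(eta), v=typ.v, ka=typ.ka)
        return conc_steady_state(dose, design.interval, p, 0.0)

    lower, upper = design.window
    # concentration is strictly decreasing in eta
    eta_hi = brentq(lambda e: conc(e) - lower, -20, 20)
    eta_lo = brentq(lambda e: conc(e) - upper, -20, 20)
    return stats.norm.cdf(eta_hi / omega) - stats.norm.cdf(eta_lo / omega)


class TestRecommend:
    def _pta_from_rows(self, rows, weights, doses, conditions=("none",)):
        design = SimulationDesign(weight_grid=weights, dose_grid=doses,
                                  n_virtual=100, conditions=conditions)
        return PTAResult(table=pd.DataFrame(rows), design=design)

    def test_argmax_dose(self):
        rows = [
            {"weight": 70.0, "dose": 4.0, "condition": "none",
             "attainment": 0.99, "exceedance": 0.0, "below": 0.01, "n": 100},
            {"weight": 70.0, "dose": 8.0, "condition": "none",
             "attainment": 0.95, "exceedance": 0.05, "below": 0.0, "n": 100},
        ]
        table = recommend_doses(self._pta_from_rows(rows, (70.0,), (4.0, 8.0)))
        assert len(table.rows) == 1
        assert table.rows[0].dose == 4.0

    def test_tie_goes_to_lower_dose(self):
        rows = [
            {"weight": 70.0, "dose": 4.0, "condition": "none",
             "attainment": 0.952, "exceedance": 0.0, "below": 0.048, "n": 100},
            {"weight": 70.0, "dose": 8.0, "condition": "none",
             "attainment": 0.955, "exceedance": 0.04, "below": 0.005, "n": 100},
        ]
        table = recommend_doses(self._pta_from_rows(rows, (70.0,), (4.0, 8.0)))
        assert table.rows[0].dose == 4.0

    def test_range_merging(self):
        rows = []
        for w, best in [(40.0, 16.0), (60.0, 12.0), (80.0, 12.0),
                        (100.0, 12.0), (120.0, 12.0)]:
            for d in (12.0, 16.0):
                rows.append({"weight": w, "dose": d, "condition": "none",
                             "attainment": 0.9 if d == best else 0.5,
                             "exceedance": 0.02, "below": 0.08, "n": 100})
        table = recommend_doses(self._pta_from_rows(
            rows, (40.0, 60.0, 80.0, 100.0, 120.0), (12.0, 16.0)))
        assert len(table.rows) == 2
        first, second = table.rows
        assert (first.weight_lower, first.weight_upper, first.dose) == \
            (40.0, 40.0, 16.0)
        assert (second.weight_lower, second.weight_upper, second.dose) == \
            (60.0, 120.0, 12.0)

    def test_render_contains_ranges(self):
        rows = [{"weight": 70.0, "dose": 8.0, "condition": "flu",
                 "attainment": 0.993, "exceedance": 0.007, "below": 0.0,
                 "n": 100}]
        table = recommend_doses(self._pta_from_rows(rows, (70.0,), (8.0,),
                                                    ("flu",)))
        text = table.render()
        assert "flu" in text and "99.3" in text
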