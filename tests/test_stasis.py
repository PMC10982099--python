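"""Closed-form stasis laws: effective AUC, stasis triple, MEF and doses."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from stasiskit import (
    DomainError,
    ResistanceError,
    auc_effect,
    mef,
    mef_grid,
    mef_hill,
    stasis_concentrations,
    stasis_condition,
    stasis_dose,
)


def _auc_effect_quadrature(c_max, c_trough, ic50, tau, hill=1.0):
    k = math.log(c_max / c_trough) / tau
    val, _ = quad(
        lambda t: (c_max * math.exp(-k * t)) ** hill
        / ((c_max * math.exp(-k * t)) ** hill + ic50**hill),
        0.0,
        tau,
        epsrel=1e-11,
        limit=300,
    )
    return val


class TestAucEffect:
    def test_worked_example_exactly_12h(self):
        assert auc_effect(100.0, 1.0, 10.0, 24.0) == pytest.approx(12.0, rel=1e-12)

    def test_limits(self):
        assert auc_effect(100.0, 1.0, 1e-12, 24.0) == pytest.approx(24.0, rel=1e-6)
        assert auc_effect(100.0, 1.0, 1e12, 24.0) == pytest.approx(0.0, abs=1e-6)

    def test_constant_infusion_branch(self):
        assert auc_effect(10.0, 10.0, 10.0, 24.0) == pytest.approx(12.0)

    @given(
        ptr=st.floats(1.01, 1000.0),
        ratio=st.floats(1e-3, 1e3),  # IC50 / c_max
        tau=st.floats(6.0, 48.0),
    )
    def test_matches_quadrature(self, ptr, ratio, tau):
        c_max = 100.0
        val = auc_effect(c_max, c_max / ptr, ratio * c_max, tau)
        assert 0.0 < val < tau
        assert val == pytest.approx(
            _auc_effect_quadrature(c_max, c_max / ptr, ratio * c_max, tau), rel=1e-8
        )


def test_stasis_condition_boundary_and_resistance():
    ok, margin = stasis_condition(100.0, 1.0, 10.0, 24.0, g=0.005, d=0.01)
    assert ok and margin == pytest.approx(0.0, abs=1e-9)
    # bounded effect cannot beat g >= d at large IC50
    ok, margin = stasis_condition(100.0, 1.0, 1e6, 24.0, g=0.01, d=0.01)
    assert not ok and margin < 0
    with pytest.raises(ResistanceError):
        stasis_condition(100.0, 1.0, 10.0, 24.0, g=0.005, d=0.0)


class TestStasisConcentrations:
    def test_worked_examples(self):
        c = stasis_concentrations(10.0, 100.0, 0.5)
        assert c.c_trough_stasis == pytest.approx(1.000, abs=1e-3)
        assert c.c_max_stasis == pytest.approx(100.0, rel=1e-6)
        assert c.c_average_stasis == pytest.approx(21.498, abs=1e-3)
        c = stasis_concentrations(10.0, 100.0, 0.4)
        assert c.c_trough_stasis == pytest.approx(0.5667, abs=1e-4)
        assert c.c_max_stasis == pytest.approx(56.67, abs=0.01)
        assert c.c_average_stasis == pytest.approx(12.183, abs=1e-3)

    def test_constant_infusion_limit(self):
        c = stasis_concentrations(10.0, 1.0, 0.4)
        for v in (c.c_trough_stasis, c.c_max_stasis, c.c_average_stasis):
            assert v == pytest.approx(6.6667, abs=1e-3)

    def test_resistance_and_domain_errors(self):
        with pytest.raises(ResistanceError):
            stasis_concentrations(10.0, 100.0, 1.0)
        with pytest.raises(DomainError):
            stasis_concentrations(10.0, 100.0, -0.1)
        with pytest.raises(DomainError):
            stasis_concentrations(10.0, 0.5, 0.4)

    @given(
        ptr=st.floats(1.1, 500.0),
        gd=st.floats(0.05, 0.95),
        tau=st.floats(6.0, 48.0),
    )
    def test_triple_satisfies_stasis_identity(self, ptr, gd, tau):
        """Feeding the stasis triple back into auc_effect returns (g/d)*tau."""
        c = stasis_concentrations(7.7, ptr, gd)
        assert c.c_trough_stasis <= c.c_average_stasis <= c.c_max_stasis
        assert c.c_max_stasis == pytest.approx(ptr * c.c_trough_stasis, rel=1e-12)
        eff = auc_effect(c.c_max_stasis, c.c_trough_stasis, 7.7, tau)
        assert eff == pytest.approx(gd * tau, rel=1e-8)

    @given(ic50=st.floats(1e-2, 1e4), scale=st.floats(1e-3, 1e3))
    def test_linear_in_ic50(self, ic50, scale):
        a = stasis_concentrations(ic50, 50.0, 0.4)
        b = stasis_concentrations(ic50 * scale, 50.0, 0.4)
        assert b.c_average_stasis == pytest.approx(scale * a.c_average_stasis, rel=1e-12)


class TestMEF:
    @pytest.mark.parametrize(
        "ptr, gd, expected",
        [(100.0, 0.4, 1.2183), (150.0, 0.7, 8.251), (1.0, 0.4, 0.66667)],
    )
    def test_values(self, ptr, gd, expected):
        assert mef(ptr, gd) == pytest.approx(expected, abs=5e-4)

    def test_consistency_with_stasis_average(self):
        for ptr, gd in [(1.5, 0.2), (40.0, 0.3), (150.0, 0.7), (500.0, 0.95)]:
            c = stasis_concentrations(7.7, ptr, gd)
            assert mef(ptr, gd) * 7.7 == pytest.approx(c.c_average_stasis, rel=1e-12)

    def test_continuity_at_ptr_one(self):
        assert mef(1.0 + 1e-5, 0.4) == pytest.approx(mef(1.0, 0.4), rel=1e-6)

    @given(gd=st.floats(0.05, 0.95))
    def test_monotone_in_ptr(self, gd):
        ptrs = np.linspace(1.5, 300.0, 50)
        vals = mef(ptrs, gd)
        assert np.all(np.diff(vals) > 0)

    @given(ptr=st.floats(1.1, 300.0))
    def test_monotone_in_gd(self, ptr):
        gds = np.linspace(0.05, 0.95, 50)
        vals = mef(ptr, gds)
        assert np.all(np.diff(vals) > 0)
        c_troughs = [stasis_concentrations(1.0, ptr, g).c_trough_stasis for g in gds]
        assert np.all(np.diff(c_troughs) > 0)


class TestMEFHill:
    @given(ptr=st.floats(1.1, 500.0), gd=st.floats(0.05, 0.95))
    def test_reduces_to_mef_at_hill_one(self, ptr, gd):
        assert mef_hill(ptr, gd, 1.0) == pytest.approx(mef(ptr, gd), rel=1e-12)

    def test_worked_example(self):
        assert mef_hill(100.0, 0.4, 2.0) == pytest.approx(1.3419, abs=5e-4)

    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0, 3.0])
    @pytest.mark.parametrize("ptr, gd", [(1.5, 0.1), (30.0, 0.4), (300.0, 0.9)])
    def test_implied_average_achieves_quadrature_stasis(self, hill, ptr, gd):
        """The mono-exponential profile at mef_hill*IC50 average concentration
        drives the effect integral to exactly (g/d)*tau."""
        ic50, tau = 7.7, 24.0
        c_avg = mef_hill(ptr, gd, hill) * ic50
        if ptr == 1.0:
            c_trough = c_max = c_avg
        else:
            c_trough = c_avg * math.log(ptr) / (ptr - 1.0)
            c_max = ptr * c_trough
        eff = _auc_effect_quadrature(c_max, c_trough, ic50, tau, hill)
        tol = 1e-8 if hill == 1.0 else 1e-4
        assert eff == pytest.approx(gd * tau, rel=tol)


class TestStasisDose:
    def test_worked_example(self):
        assert stasis_dose(10.0, 200.0, 24.0, 100.0, 0.4, 1.0) == pytest.approx(
            1.4620, abs=5e-4
        )

    def test_diverges_towards_resistance(self):
        near = stasis_dose(10.0, 200.0, 24.0, 100.0, 0.999)
        mid = stasis_dose(10.0, 200.0, 24.0, 100.0, 0.5)
        assert near / mid > 10.0
        with pytest.raises(ResistanceError):
            stasis_dose(10.0, 200.0, 24.0, 100.0, 1.0)


class TestMEFGrid:
    def test_default_grid_bounds(self):
        grid = mef_grid()
        assert grid.min == pytest.approx(0.5788, abs=5e-4)
        assert grid.max == pytest.approx(8.251, abs=5e-3)
        assert grid.argmin == pytest.approx((40.0, 0.3))
        assert grid.argmax == pytest.approx((150.0, 0.7))
        assert len(grid.table) == 200 * 200

    def test_grid_monotone_in_ptr_at_fixed_gd(self):
        grid = mef_grid(n=50)
        for _, sub in grid.table.groupby("gd"):
            assert sub.sort_values("ptr")["mef"].is_monotonic_increasing
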