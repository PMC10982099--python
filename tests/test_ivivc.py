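"""Logistic IVIVC: prediction, fitting, empirical stasis dose, stratification."""

import numpy as np
import pandas as pd
import pytest

from stasiskit import (
    DomainError,
    FitError,
    IVIVCFit,
    StasisUnreachableError,
    coverage_factors,
    empirical_stasis_dose,
    fit_ivivc,
    predict_tgi,
    stratify_residuals,
)

PRINTED = dict(tgi_min=0.0, tgi_max=125.0, pd_inflex=0.25, hill_exp=0.89)


@pytest.fixture
def printed_fit():
    return IVIVCFit(**PRINTED)


def _synthetic_records(fit, n, noise_sd, rng, cov_range=(0.01, 30.0)):
    cov = np.exp(rng.uniform(np.log(cov_range[0]), np.log(cov_range[1]), n))
    tgi = predict_tgi(fit, cov) + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"coverage": cov, "tgi": tgi})


class TestPredict:
    def test_midpoint_at_inflection(self, printed_fit):
        assert predict_tgi(printed_fit, 0.25) == pytest.approx(62.5)

    def test_limits(self, printed_fit):
        assert predict_tgi(printed_fit, 1e9) == pytest.approx(125.0, abs=1e-3)
        assert predict_tgi(printed_fit, 1e-9) == pytest.approx(0.0, abs=1e-3)

    def test_monotone(self, printed_fit):
        cov = np.logspace(-3, 3, 100)
        assert np.all(np.diff(predict_tgi(printed_fit, cov)) > 0)

    def test_rejects_nonpositive_coverage(self, printed_fit):
        with pytest.raises(DomainError):
            predict_tgi(printed_fit, 0.0)


class TestFit:
    def test_noise_free_recovery_is_exact(self, printed_fit, rng):
        rec = _synthetic_records(printed_fit, 86, 0.0, rng)
        fit = fit_ivivc(rec)
        assert fit.tgi_max == pytest.approx(125.0, rel=1e-6)
        assert fit.pd_inflex == pytest.approx(0.25, rel=1e-6)
        assert fit.hill_exp == pytest.approx(0.89, rel=1e-6)

    def test_noise_free_recovery_with_free_tgi_min(self, rng):
        gen = IVIVCFit(tgi_min=-10.0, tgi_max=120.0, pd_inflex=0.4, hill_exp=1.2)
        rec = _synthetic_records(gen, 200, 0.0, rng, cov_range=(1e-3, 1e3))
        fit = fit_ivivc(rec, fix_tgi_min=None)
        assert fit.tgi_min == pytest.approx(-10.0, abs=1e-4)
        assert fit.pd_inflex == pytest.approx(0.4, rel=1e-6)

    def test_noisy_recovery_within_10pct(self, printed_fit, rng):
        rec = _synthetic_records(printed_fit, 86, 5.0, rng)
        fit = fit_ivivc(rec)
        assert fit.pd_inflex == pytest.approx(0.25, rel=0.10)

    def test_under_determined_rejected(self):
        with pytest.raises(FitError):
            fit_ivivc(pd.DataFrame({"coverage": [0.1, 10.0], "tgi": [5.0, 110.0]}))

    def test_degenerate_span_rejected(self):
        rec = pd.DataFrame({"coverage": [1.0, 1.1, 1.2, 1.3], "tgi": [50, 55, 60, 65]})
        with pytest.raises(FitError):
            fit_ivivc(rec)

    def test_cavg_and_auc_modes_are_tau_consistent(self, printed_fit, rng):
        """Fitting AUC-based coverage rescales pd_inflex by tau and leaves the
        predicted curve unchanged."""
        tau = 24.0
        rec = _synthetic_records(printed_fit, 86, 0.0, rng)
        fit_c = fit_ivivc(rec, mode="cavg")
        fit_a = fit_ivivc(rec.assign(coverage=rec["coverage"] * tau), mode="auc")
        assert fit_a.pd_inflex == pytest.approx(tau * fit_c.pd_inflex, rel=1e-6)
        assert fit_a.hill_exp == pytest.approx(fit_c.hill_exp, rel=1e-6)
        cov = np.logspace(-2, 1.4, 30)
        np.testing.assert_allclose(
            predict_tgi(fit_a, cov * tau), predict_tgi(fit_c, cov), rtol=1e-6
        )


class TestEmpiricalStasisDose:
    def test_printed_parameter_multiplier(self, printed_fit):
        # dose = multiplier * IC50 / c_average_DN,ub with ic50 = c_avg_dn = 1
        dose = empirical_stasis_dose(printed_fit, ic50=1.0, auc_dn_ub=24.0, tau=24.0)
        assert dose == pytest.approx(1.187, abs=2e-3)

    def test_unreachable_when_tgi_max_at_100(self):
        fit = IVIVCFit(tgi_min=0.0, tgi_max=100.0, pd_inflex=0.25, hill_exp=0.89)
        with pytest.raises(StasisUnreachableError):
            empirical_stasis_dose(fit, 10.0, 200.0, 24.0)

    def test_round_trip_prediction_is_100(self, printed_fit):
        ic50, auc_dn, tau = 7.7, 200.0, 24.0
        dose = empirical_stasis_dose(printed_fit, ic50, auc_dn, tau)
        coverage = dose * (auc_dn / tau) / ic50
        assert predict_tgi(printed_fit, coverage) == pytest.approx(100.0, rel=1e-10)


def test_coverage_factors():
    cavg_f, auc_f = coverage_factors(0.5, 12.0, 7.7, 30.8)
    assert cavg_f == pytest.approx(2.0)
    assert auc_f / cavg_f == pytest.approx(24.0)  # tau consistency
    assert coverage_factors(1.0, 24.0, 5.0, 5.0)[0] == pytest.approx(1.0)


class TestStratifyResiduals:
    def test_xenograft_spread_exceeds_compound_spread(self, printed_fit, rng):
        """With g/d varying across xenografts and PTR shared, residual scatter
        around a common curve stratifies by xenograft, not by compound."""
        rows = []
        gd_by_xeno = {"X1": 0.3, "X2": 0.5, "X3": 0.7}
        for xeno, gd in gd_by_xeno.items():
            # xenograft-specific shift emulating its distance from the pooled curve
            shift = 40.0 * (gd - 0.5)
            for comp in ("C1", "C2", "C3", "C4"):
                cov = np.exp(rng.uniform(np.log(0.05), np.log(20.0), 8))
                tgi = predict_tgi(printed_fit, cov) + shift + rng.normal(0, 2.0, 8)
                rows.append(
                    pd.DataFrame(
                        {
                            "coverage": cov,
                            "tgi": tgi,
                            "xenograft_id": xeno,
                            "compound_id": comp,
                        }
                    )
                )
        rec = pd.concat(rows, ignore_index=True)
        fit = fit_ivivc(rec)
        by_x = stratify_residuals(fit, rec, by="xenograft_id")
        by_c = stratify_residuals(fit, rec, by="compound_id")
        # within-xenograft spread is small (shift removed), within-compound large
        assert by_x["resid_sd"].median() < by_c["resid_sd"].median()

    def test_single_group_one_row(self, printed_fit, rng):
        rec = _synthetic_records(printed_fit, 40, 3.0, rng).assign(xenograft_id="X1")
        fit = fit_ivivc(rec)
        table = stratify_residuals(fit, rec, by="xenograft_id")
        assert len(table) == 1
        assert table.loc[0, "n"] > 0

    def test_identical_groups_equal_spread(self, printed_fit, rng):
        base = _synthetic_records(printed_fit, 30, 4.0, rng)
        rec = pd.concat(
            [base.assign(xenograft_id="A"), base.assign(xenograft_id="B")],
            ignore_index=True,
        )
        fit = fit_ivivc(rec)
        table = stratify_residuals(fit, rec, by="xenograft_id")
        assert table["resid_sd"].nunique() == 1 or np.allclose(
            table["resid_sd"].iloc[0], table["resid_sd"].iloc[1]
        )
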