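import numpy as np
import pytest
from scipy import optimize

from tightknot import synthetic
from tightknot.errors import (DegenerateTitrationError, ValidationError)
from tightknot.kinetics import (
    KineticEstimate, ProgressSeries, TightBindingTitration, TitrationSeries,
    compare_groups, fit_morrison, kd_stoichiometric, molar_from_mass_conc,
    morrison_activity, percent_inhibition, preincubation_plateau,
    relative_potency, titration_equivalence)

from conftest import STUDY_ET, STUDY_KD


def equilibrium_activity_oracle(E, I, K):
    """Independent oracle: numeric root of the free-enzyme mass balance.

    Solves K*[EI] = (E-[EI])*(I-[EI]) for [EI] by bracketing root-finding
    instead of the closed-form quadratic.
    """
    if I == 0:
        return 1.0
    f = lambda EI: K * EI - (E - EI) * (I - EI)
    EI = optimize.brentq(f, 0.0, min(E, I))
    return 1.0 - EI / E


class TestPercentInhibition:
    @pytest.mark.parametrize("test,control,expected",
                             [(0, 100, 100.0), (30, 100, 70.0), (100, 100, 0.0)])
    def test_examples(self, test, control, expected):
        assert percent_inhibition(test, control) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            percent_inhibition(10, 0)


class TestMorrisonActivity:
    def test_no_inhibitor_gives_full_activity(self):
        assert morrison_activity(515, 0.0, 30.25) == pytest.approx(1.0)

    def test_stoichiometric_limit(self):
        # K -> 0, I = E/2: exactly half the enzyme is titrated away
        assert morrison_activity(100, 50, 0.0) == pytest.approx(0.5)

    def test_matches_mass_balance_root(self):
        # closed-form quadratic vs independent numeric root of the balance
        for E, I, K in [(515, 515, 30.25), (515, 250, 30.25), (100, 80, 5.0),
                        (515, 2000, 30.25)]:
            assert morrison_activity(E, I, K) == pytest.approx(
                equilibrium_activity_oracle(E, I, K), rel=1e-9)

    def test_study_point_value(self):
        # frozen from the mass-balance oracle at E = I = 515 nM, K = 30.25 nM
        assert morrison_activity(515, 515, 30.25) == pytest.approx(0.2148, abs=2e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            morrison_activity(515, -1.0, 30.25)


class TestTitrationEquivalence:
    def test_stoichiometric_series_extrapolates_to_enzyme_total(self):
        # K -> 0: activity = 1 - I/E down to zero, then flat; the linear
        # region ends exactly at E and the intercept is exact.
        spec = synthetic.TitrationSimSpec(true_kd=0.0, enzyme_total=500.0,
                                          inhibitor_grid=(0., 125., 250., 375., 500., 625., 750.),
                                          noise_cv=0.0, n_replicates=1)
        eq = titration_equivalence(synthetic.gen_titration(spec))
        assert eq.equivalence_nM == pytest.approx(500.0, rel=1e-6)
        assert eq.activity_at_equivalence == pytest.approx(0.0, abs=1e-9)
        assert eq.rectilinear

    def test_dense_morrison_intercept_within_convexity_bias(self, dense_noiseless_series):
        # The tangent at I=0 crosses at E_t + K; least-squares prefixes land
        # between E_t and a few K above it.
        eq = titration_equivalence(dense_noiseless_series)
        assert STUDY_ET <= eq.equivalence_nM <= STUDY_ET + 5 * STUDY_KD

    def test_too_few_points_rejected(self):
        s = TitrationSeries([0, 100, 200], [1.0, 0.5, 0.1], [0, 0, 0])
        with pytest.raises(ValidationError):
            titration_equivalence(s)

    def test_non_decreasing_series_rejected(self):
        s = TitrationSeries([0, 100, 200, 300], [0.2, 0.5, 0.8, 1.0], [0] * 4)
        with pytest.raises(ValidationError):
            titration_equivalence(s)


class TestKdStoichiometric:
    def test_hand_arithmetic(self):
        # a_eq = 0.5 at E_t = 100 -> E = I = 50, EI = 50, kd = 50
        s = TitrationSeries([0, 50, 100, 150], [1.0, 0.75, 0.5, 0.3], [0] * 4,
                            enzyme_total_nM=100.0)
        est = kd_stoichiometric(s, n_boot=0)
        assert est.kd == pytest.approx(50.0)
        assert est.free_enzyme == est.free_inhibitor == pytest.approx(50.0)
        assert est.complex_conc == pytest.approx(50.0)

    def test_dense_noiseless_recovery_under_one_percent(self, dense_noiseless_series):
        est = kd_stoichiometric(dense_noiseless_series, n_boot=0)
        assert est.kd == pytest.approx(STUDY_KD, rel=0.01)

    def test_kd_identity_holds_exactly(self, coarse_noiseless_series):
        est = kd_stoichiometric(coarse_noiseless_series, n_boot=0)
        assert est.kd == pytest.approx(
            est.free_enzyme * est.free_inhibitor / est.complex_conc, rel=1e-12)

    def test_degenerate_titration_rejected(self):
        # activity still 1.0 at the equivalence point: nothing titrated there
        s = TitrationSeries([0, 100, 200, 300], [1.0, 1.0, 0.95, 0.90],
                            [0] * 4, enzyme_total_nM=50.0)
        with pytest.raises((DegenerateTitrationError, ValidationError)):
            kd_stoichiometric(s, n_boot=0)

    def test_bootstrap_se_available_with_replicates(self):
        spec = synthetic.TitrationSimSpec(noise_cv=0.02, n_replicates=3, seed=7)
        est = kd_stoichiometric(synthetic.gen_titration(spec), n_boot=50, seed=1)
        assert est.se_kd is not None and est.se_kd > 0


class TestFitMorrison:
    def test_noiseless_roundtrip_exact(self, coarse_noiseless_series):
        est = fit_morrison(coarse_noiseless_series)
        assert est.kd == pytest.approx(STUDY_KD, rel=1e-6)

    def test_fits_enzyme_total_jointly_when_unknown(self, dense_noiseless_series):
        s = TitrationSeries(dense_noiseless_series.inhibitor_nM,
                            dense_noiseless_series.activity,
                            dense_noiseless_series.replicate)
        est = fit_morrison(s)
        assert est.kd == pytest.approx(STUDY_KD, rel=1e-3)
        assert est.equivalence_point == pytest.approx(STUDY_ET, rel=1e-3)

    def test_stoichiometric_data_gives_kd_below_grid_resolution(self):
        spec = synthetic.TitrationSimSpec(true_kd=0.0, noise_cv=0.0, n_replicates=1)
        est = fit_morrison(synthetic.gen_titration(spec))
        assert est.kd < 250.0 / 10  # well under one grid step

    def test_concordance_with_stoichiometric(self, dense_noiseless_series):
        fit = fit_morrison(dense_noiseless_series)
        stoich = kd_stoichiometric(dense_noiseless_series, n_boot=0)
        assert abs(fit.kd - stoich.kd) / stoich.kd < 0.10

    def test_too_few_points_rejected(self):
        s = TitrationSeries([0, 100, 200, 300], [1.0, 0.6, 0.3, 0.1], [0] * 4)
        with pytest.raises(ValidationError):
            fit_morrison(s)


class TestModelObject:
    def test_fit_returns_results_with_summary(self, coarse_noiseless_series):
        model = TightBindingTitration(coarse_noiseless_series)
        res = model.fit(method="stoichiometric", n_boot=0)
        assert isinstance(res, KineticEstimate)
        assert "K_D" in res.summary() and "stoichiometric" in res.summary()

    def test_unknown_method_rejected(self, coarse_noiseless_series):
        with pytest.raises(ValidationError):
            TightBindingTitration(coarse_noiseless_series).fit(method="dixon")


class TestPreincubationPlateau:
    def test_constant_series_plateaus_immediately(self):
        s = ProgressSeries([0, 5, 10, 15], [0.3, 0.3, 0.3, 0.3])
        assert preincubation_plateau(s) == 0.0

    def test_exponential_approach_plateaus_at_fifteen_minutes(self):
        # activity decays toward 0.2 and is flat (within 2%) from t = 15 on
        t = np.array([0., 5., 10., 15., 20., 30., 60.])
        a = np.array([1.0, 0.6, 0.35, 0.21, 0.205, 0.202, 0.20])
        assert preincubation_plateau(ProgressSeries(t, a), tol=0.02) == 15.0

    def test_never_plateaus_returns_sentinel(self):
        s = ProgressSeries([0, 10, 20, 30], [1.0, 0.8, 0.6, 0.4])
        assert preincubation_plateau(s, tol=0.05) is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            preincubation_plateau(ProgressSeries([0, 10], [1.0, 0.5]))


class TestCompareGroups:
    def test_identical_groups_give_null_result(self):
        t, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_value(self):
        # pooled SD = 1, df = 4: t = -3/sqrt(2/3) = -3.674, p = 0.0214
        t, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_swapping_groups_flips_sign_only(self):
        t1, p1 = compare_groups([1, 2, 3], [4, 5, 6])
        t2, p2 = compare_groups([4, 5, 6], [1, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_constant_groups_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([2, 2], [2, 2])


def test_enzyme_molarity_from_mass_concentration():
    # 12 ng/uL of a 23,300 Da protease is ~515 nM
    assert molar_from_mass_conc(12.0, 23300.0) == pytest.approx(515.0, rel=2e-3)


def test_relative_potency_is_a_plain_ratio():
    assert relative_potency(30.25, 7.34) == pytest.approx(30.25 / 7.34)
    with pytest.raises(ValidationError):
        relative_potency(-1.0, 2.0)


def test_series_csv_roundtrip(tmp_path, coarse_noiseless_series):
    path = tmp_path / "titration.csv"
    coarse_noiseless_series.to_csv(path)
    back = TitrationSeries.from_csv(path, enzyme_total_nM=STUDY_ET)
    np.testing.assert_allclose(back.inhibitor_nM, coarse_noiseless_series.inhibitor_nM)
    np.testing.assert_allclose(back.activity, coarse_noiseless_series.activity)


def test_micromolar_unit_conversion_on_read(tmp_path):
    import pandas as pd
    pd.DataFrame({"inhibitor_uM": [0.0, 0.25, 0.5, 1.0],
                  "replicate": [0] * 4,
                  "activity_fraction": [1.0, 0.6, 0.3, 0.05]}).to_csv(
        tmp_path / "t.csv", index=False)
    s = TitrationSeries.from_csv(tmp_path / "t.csv")
    np.testing.assert_allclose(s.inhibitor_nM, [0.0, 250.0, 500.0, 1000.0])
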