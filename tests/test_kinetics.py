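"""Kinetic laws, Eadie–Hofstee diagnostics, fitting and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmpkit.errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidParameterError,
)
from dmpkit.kinetics import (
    FitOptions,
    KineticDataset,
    biphasic_velocity,
    clint_from_params,
    eadie_hofstee_transform,
    fit_kinetic_model,
    intrinsic_clearance,
    mm_velocity,
    round_table,
    select_kinetic_model,
    substrate_inhibition_velocity,
)
from conftest import BIPHASIC_TRUTH, HLMS_MM, S_GRID_8, S_GRID_10, SI_TRUTH

from oracles import grid_fit


class TestVelocityLaws:
    @pytest.mark.parametrize(
        "S, expected",
        [(0.0, 0.0), (244.63, 17.535), (100.0, 3507.0 / 344.63)],
    )
    def test_mm_values(self, S, expected):
        assert mm_velocity(S, 35.07, 244.63) == pytest.approx(expected, abs=1e-12)

    def test_mm_saturates_below_vmax(self):
        S = np.geomspace(0.01, 1e6, 50)
        v = mm_velocity(S, 35.07, 244.63)
        assert np.all(np.diff(v) > 0)
        assert np.all(v < 35.07)

    def test_biphasic_reduces_to_mm_when_second_phase_vanishes(self):
        S = S_GRID_8
        np.testing.assert_allclose(
            biphasic_velocity(S, 10.0, 5.0, 0.0, 500.0), mm_velocity(S, 10.0, 5.0)
        )

    def test_biphasic_value_and_low_s_slope(self):
        assert biphasic_velocity(5.0, 10.0, 5.0, 100.0, 500.0) == pytest.approx(5.0 + 500.0 / 505.0)
        # slope at the origin is the biphasic intrinsic clearance Vmax1/Ks1 + Vmax2/Ks2
        s = 1e-9
        slope = biphasic_velocity(s, 10.0, 5.0, 100.0, 500.0) / s
        assert slope == pytest.approx(2.2, rel=1e-6)

    def test_substrate_inhibition_peak(self):
        # maximum sits at S = sqrt(Ks*Ksi) = 100 with value Vmax*100/200
        assert substrate_inhibition_velocity(100.0, 100.0, 50.0, 200.0) == pytest.approx(50.0)
        S = np.linspace(1, 400, 200)
        v = substrate_inhibition_velocity(S, 100.0, 50.0, 200.0)
        assert S[np.argmax(v)] == pytest.approx(100.0, rel=0.02)

    def test_substrate_inhibition_reduces_to_mm_at_large_ksi(self):
        assert substrate_inhibition_velocity(50.0, 100.0, 50.0, 1e12) == pytest.approx(50.0, rel=1e-9)
        assert substrate_inhibition_velocity(0.0, 100.0, 50.0, 200.0) == 0.0

    @pytest.mark.parametrize("func, bad", [
        (lambda: mm_velocity(1.0, 0.0, 10.0), InvalidParameterError),
        (lambda: mm_velocity(1.0, 10.0, -1.0), InvalidParameterError),
        (lambda: substrate_inhibition_velocity(1.0, 10.0, 1.0, 0.0), InvalidParameterError),
        (lambda: biphasic_velocity(1.0, 10.0, 0.0, 1.0, 1.0), InvalidParameterError),
    ])
    def test_invalid_parameters_rejected(self, func, bad):
        with pytest.raises(bad):
            func()

    @given(
        st.floats(0.1, 1e4),
        st.floats(0.1, 1e4),
        st.floats(0.1, 1e4),
        st.floats(0.0, 1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_velocity_nonnegative_and_zero_at_origin(self, Vmax, Km, Ksi, S):
        assert mm_velocity(0.0, Vmax, Km) == 0.0
        assert mm_velocity(S, Vmax, Km) >= 0.0
        assert substrate_inhibition_velocity(S, Vmax, Km, Ksi) >= 0.0
        assert biphasic_velocity(S, Vmax, Km, Vmax, Ksi if Ksi > 0 else 1.0) >= 0.0


class TestEadieHofstee:
    def test_exact_mm_is_collinear(self, mm_dataset):
        eh = eadie_hofstee_transform(mm_dataset)
        assert eh.linearity_r2 == pytest.approx(1.0, abs=1e-12)
        assert eh.slope == pytest.approx(-244.63, rel=1e-9)
        assert eh.intercept == pytest.approx(35.07, rel=1e-9)

    def test_substrate_inhibition_is_curved(self, si_dataset):
        eh = eadie_hofstee_transform(si_dataset)
        assert eh.linearity_r2 < 1.0 - 1e-6

    def test_two_points_insufficient(self):
        ds = KineticDataset("x", "P1", [1.0, 10.0], [0.5, 3.0])
        with pytest.raises(InsufficientDataError):
            eadie_hofstee_transform(ds)


class TestFitting:
    @pytest.mark.parametrize(
        "model, truth, grid, tol",
        [
            ("michaelis_menten", HLMS_MM, S_GRID_8, 1e-6),
            ("substrate_inhibition", SI_TRUTH, S_GRID_10, 1e-5),
            ("biphasic", BIPHASIC_TRUTH, S_GRID_10, 1e-5),
        ],
    )
    def test_noise_free_self_recovery(self, model, truth, grid, tol):
        from dmpkit.kinetics import model_velocity

        ds = KineticDataset("x", "P1", grid, np.asarray(model_velocity(model, grid, truth)))
        fit = fit_kinetic_model(ds, model)
        rel = np.abs(fit.param_vector() - np.asarray(truth)) / np.asarray(truth)
        assert rel.max() < tol
        assert fit.rss < 1e-12

    def test_fit_matches_grid_oracle_on_5_point_noisy_data(self):
        """Trust-region fit and exhaustive grid search agree on rss within 1%."""
        rng = np.random.default_rng(42)
        S5 = np.geomspace(1.0, 200.0, 5)
        from dmpkit.kinetics import model_velocity

        for model, truth in [
            ("michaelis_menten", HLMS_MM),
            ("substrate_inhibition", SI_TRUTH),
            ("biphasic", BIPHASIC_TRUTH),
        ]:
            v = np.asarray(model_velocity(model, S5, truth))
            v = v * (1.0 + rng.normal(0.0, 0.05, size=5))
            ds = KineticDataset("x", "P1", S5, np.maximum(v, 0.0))
            fit = fit_kinetic_model(ds, model)
            _, rss_oracle = grid_fit(model, S5, ds.velocities)
            assert fit.rss <= rss_oracle * 1.01
            assert rss_oracle <= fit.rss * 1.01

    def test_insufficient_points_for_biphasic(self):
        ds = KineticDataset("x", "P1", [1.0, 10.0, 100.0], [1.0, 5.0, 9.0])
        with pytest.raises(InsufficientDataError):
            fit_kinetic_model(ds, "biphasic")

    def test_all_zero_velocities_degenerate(self):
        ds = KineticDataset("x", "P1", S_GRID_8, np.zeros(8))
        with pytest.raises(DegenerateDataError):
            fit_kinetic_model(ds, "michaelis_menten")

    def test_noise_recovery_median_error(self):
        """5% CV noise, 8-point design: median parameter error stays below 15%.

        Uses the recovery-study default truth (Km inside the 1–200 µM design,
        so the saturation plateau is actually sampled).
        """
        from dmpkit.synthetic import simulate_velocity_dataset
        from conftest import RLMS_MM

        errs_vmax, errs_km = [], []
        for seed in range(100):
            ds = simulate_velocity_dataset(
                "michaelis_menten", RLMS_MM, noise_cv=0.05, seed=seed
            )
            fit = fit_kinetic_model(ds, "michaelis_menten")
            errs_vmax.append(abs(fit.params["Vmax"] - RLMS_MM[0]) / RLMS_MM[0])
            errs_km.append(abs(fit.params["Km"] - RLMS_MM[1]) / RLMS_MM[1])
        assert np.median(errs_vmax) < 0.15
        assert np.median(errs_km) < 0.15


class TestSelection:
    def test_substrate_inhibition_beats_mm_on_its_own_data(self, si_dataset):
        ranked = select_kinetic_model(si_dataset, ["michaelis_menten", "substrate_inhibition"])
        assert ranked[0].model == "substrate_inhibition"
        assert ranked[0].rss < ranked[1].rss

    def test_tie_breaks_to_simpler_model_on_mm_data(self, mm_dataset):
        ranked = select_kinetic_model(mm_dataset, ["michaelis_menten", "biphasic"])
        assert ranked[0].model == "michaelis_menten"

    def test_empty_candidate_list(self, mm_dataset):
        with pytest.raises(InvalidArgumentError):
            select_kinetic_model(mm_dataset, [])


class TestIntrinsicClearance:
    @pytest.mark.parametrize(
        "vmax, km, printed",
        [(158.26, 121.13, 1.31), (35.07, 244.63, 0.14)],
    )
    def test_printed_mm_clint(self, vmax, km, printed):
        clint = clint_from_params("michaelis_menten", {"Vmax": vmax, "Km": km})
        assert round_table(clint) == printed

    def test_zero_vmax_invalid(self):
        with pytest.raises(InvalidParameterError):
            clint_from_params("michaelis_menten", {"Vmax": 0.0, "Km": 10.0})

    def test_clint_scale_invariance(self, mm_dataset):
        """Rescaling velocities rescales CLint by the same factor (unit change)."""
        fit = fit_kinetic_model(mm_dataset, "michaelis_menten")
        scaled = KineticDataset(
            "x", "P1", mm_dataset.concentrations, mm_dataset.velocities * 1000.0
        )
        fit_scaled = fit_kinetic_model(scaled, "michaelis_menten")
        assert intrinsic_clearance(fit_scaled) == pytest.approx(
            1000.0 * intrinsic_clearance(fit), rel=1e-6
        )

    def test_biphasic_clint_is_low_s_limit(self):
        clint = clint_from_params(
            "biphasic", {"Vmax1": 10.0, "Ks1": 5.0, "Vmax2": 100.0, "Ks2": 500.0}
        )
        assert clint == pytest.approx(2.2)


class TestDatasetValidation:
    def test_rejects_negative_concentration(self):
        with pytest.raises(InvalidParameterError):
            KineticDataset("x", "P1", [-1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_rejects_duplicate_concentrations(self):
        with pytest.raises(InvalidParameterError):
            KineticDataset("x", "P1", [1.0, 1.0, 3.0], [1.0, 2.0, 3.0])

    def test_sorts_on_construction(self):
        ds = KineticDataset("x", "P1", [10.0, 1.0, 5.0], [3.0, 1.0, 2.0])
        assert list(ds.concentrations) == [1.0, 5.0, 10.0]
        assert list(ds.velocities) == [1.0, 2.0, 3.0]
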