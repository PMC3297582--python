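"""Promoter logic: binding isotherm, drives, transcription propensity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upticksim.params import InvalidParameterError, ModelParams, strain_preset
from upticksim.promoter import (
    ModelConsistencyError,
    Occupant,
    PromoterState,
    fraction_bound,
    global_activity,
    spo0a_drive,
    spo0a_rise,
    transcription_propensity,
)


class TestFractionBound:
    @pytest.mark.parametrize(
        "conc, kd, expected",
        [
            (50.0, 50.0, 0.5),     # half the probe shifts at conc == Kd
            (0.0, 50.0, 0.0),      # no protein, no binding
            (150.0, 50.0, 0.75),   # c/(c+Kd) = 150/200
            (0.0, 1e-6, 0.0),
        ],
    )
    def test_isotherm_values(self, conc, kd, expected):
        assert fraction_bound(conc, kd) == pytest.approx(expected)

    def test_invalid_kd_rejected(self):
        with pytest.raises(InvalidParameterError):
            fraction_bound(10.0, 0.0)
        with pytest.raises(InvalidParameterError):
            fraction_bound(10.0, -5.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            fraction_bound(-1.0, 50.0)

    @given(
        kd=st.floats(0.1, 1e4),
        concs=st.lists(
            st.integers(0, 10**6), min_size=2, max_size=20, unique=True
        ),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_in_concentration(self, kd, concs):
        # integer-grid concentrations (0.01 nM steps) keep successive
        # isotherm values separated beyond float rounding
        concs = [c / 100.0 for c in sorted(concs)]
        vals = [fraction_bound(c, kd) for c in concs]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_strictly_decreasing_in_kd_on_grid(self):
        kds = np.linspace(1.0, 500.0, 40)
        vals = fraction_bound(100.0, kds[0]), *[fraction_bound(100.0, k) for k in kds]
        diffs = np.diff([fraction_bound(100.0, k) for k in kds])
        assert np.all(diffs < 0)


class TestGlobalActivity:
    def test_peak_is_one_at_t0(self, default_params):
        assert global_activity(default_params.t0, default_params) == pytest.approx(1.0)
        grid = np.linspace(0, 6, 1201)
        g = global_activity(grid, default_params)
        assert g.max() == pytest.approx(1.0, abs=1e-3)
        assert abs(grid[np.argmax(g)] - default_params.t0) <= 0.005 + 1e-9

    def test_pre_growth_floor(self, default_params):
        assert global_activity(0.0, default_params) <= 0.2

    def test_monotone_rise_before_t0(self, default_params):
        grid = np.linspace(0.0, default_params.t0, 100)
        g = global_activity(grid, default_params)
        assert np.all(np.diff(g) > 0)

    def test_shoulder_slows_the_late_decline(self, default_params):
        """d(g)/dt is less negative 3 h past the peak than 0.5 h past it,
        and the value stays strictly between the late floor and the peak."""
        p = default_params
        eps = 1e-4

        def slope(t):
            return (global_activity(t + eps, p) - global_activity(t - eps, p)) / (2 * eps)

        assert slope(p.t0 + 3.0) > slope(p.t0 + 0.5)
        val = global_activity(p.t0 + 3.0, p)
        assert p.g_shape.floor_late < val < 1.0

    def test_bounded_in_unit_interval(self, default_params):
        grid = np.linspace(0, 12, 500)
        g = global_activity(grid, default_params)
        assert np.all(g > 0) and np.all(g <= 1.0)


class TestSpo0aDrive:
    def test_knockout_produces_nothing(self, default_params):
        strain = strain_preset("d_spo0A")
        t = np.linspace(0, 6, 50)
        assert np.all(spo0a_drive(t, default_params, strain) == 0)

    def test_cumulative_production_nondecreasing(self, default_params):
        """With zero decay the expected pool is the integral of a
        nonnegative rate, hence nondecreasing."""
        p = default_params.replace(oap_decay=0.0)
        t = np.linspace(0, p.t0 + 4, 400)
        rate = spo0a_drive(t, p, strain_preset("wt"))
        pool = np.cumsum(rate) * (t[1] - t[0])
        assert np.all(np.diff(pool) >= 0)
        assert np.all(rate >= 0)

    def test_drive_is_maintained_after_t0(self, default_params):
        p = default_params
        late = spo0a_rise(np.linspace(p.t0, p.t0 + 3, 20), p)
        assert np.all(late == 1.0)

    def test_activation_threshold_crossed_before_repression_threshold(self, default_params):
        """Choosing the production scale so the pool reaches the A-site Kd
        about half an hour before t0, the R-site Kd is crossed only after
        the A-site Kd (ODE integration as oracle): activation precedes
        repression."""
        p = default_params.replace(oap_decay=0.0)
        t = np.linspace(0, p.t0 + 2, 2000)
        h = spo0a_rise(t, p)
        cum = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2 * np.diff(t))])
        # pick the rate so the pool equals the A-site Kd at t0 - 0.5 h
        i_act = np.searchsorted(t, p.t0 - 0.5)
        rate0 = p.kd_molecules(p.kd_A1) / cum[i_act]
        pool = rate0 * cum
        t_act = t[np.searchsorted(pool, p.kd_molecules(p.kd_A1))]
        t_rep = t[np.searchsorted(pool, p.kd_molecules(p.kd_R1))]
        assert t_act == pytest.approx(p.t0 - 0.5, abs=0.01)
        assert t_act < t_rep
        assert t_rep > p.t0 - 0.25  # repression engages around/after the peak


class TestPromoterState:
    def test_a2_admits_either_competitor(self):
        PromoterState(occ={"A2": Occupant.OAP})
        PromoterState(occ={"A2": Occupant.ROK})

    @pytest.mark.parametrize("site", ["A1", "A3", "R1", "R2"])
    def test_rok_rejected_at_spo0a_only_sites(self, site):
        with pytest.raises(ModelConsistencyError):
            PromoterState(occ={site: Occupant.ROK})

    def test_oap_rejected_at_aux_site(self):
        with pytest.raises(ModelConsistencyError):
            PromoterState(occ={"RokAux": Occupant.OAP})

    def test_unknown_site_rejected(self):
        with pytest.raises(ModelConsistencyError):
            PromoterState(occ={"A9": Occupant.OAP})


class TestTranscriptionPropensity:
    def test_empty_promoter_at_peak_gives_base_rate(self, default_params):
        state = PromoterState()
        a = transcription_propensity(state, default_params.t0, default_params, strain_preset("wt"))
        assert a == pytest.approx(default_params.k_tx_base)

    def test_double_rok_repression(self, default_params):
        state = PromoterState(occ={"A2": Occupant.ROK, "RokAux": Occupant.ROK})
        a = transcription_propensity(state, default_params.t0, default_params, strain_preset("wt"))
        assert a == pytest.approx(default_params.k_tx_base * default_params.rho_rok**2)

    def test_full_activation_boost(self, default_params):
        state = PromoterState(occ={"A1": Occupant.OAP, "A2": Occupant.OAP, "A3": Occupant.OAP})
        a = transcription_propensity(state, default_params.t0, default_params, strain_preset("wt"))
        empty = transcription_propensity(PromoterState(), default_params.t0, default_params, strain_preset("wt"))
        assert a == pytest.approx(default_params.k_tx_base * default_params.alpha**3)
        assert a > empty

    def test_all_or_none_mode_boosts_only_full_occupancy(self, default_params):
        p = default_params.replace(activation_mode="all_or_none")
        partial = PromoterState(occ={"A1": Occupant.OAP})
        full = PromoterState(occ={"A1": Occupant.OAP, "A2": Occupant.OAP, "A3": Occupant.OAP})
        assert transcription_propensity(partial, p.t0, p, strain_preset("wt")) == pytest.approx(p.k_tx_base)
        assert transcription_propensity(full, p.t0, p, strain_preset("wt")) == pytest.approx(p.k_tx_base * p.alpha**3)

    def test_joint_repression_multiplies(self, default_params):
        """Rok and Spo0A~P repression compound: the doubly repressed
        propensity is lower than either single repression."""
        p = default_params
        rok_only = PromoterState(occ={"RokAux": Occupant.ROK})
        oap_only = PromoterState(occ={"R1": Occupant.OAP, "R2": Occupant.OAP})
        both = PromoterState(
            occ={"RokAux": Occupant.ROK, "R1": Occupant.OAP, "R2": Occupant.OAP}
        )
        wt = strain_preset("wt")
        a_rok = transcription_propensity(rok_only, p.t0, p, wt)
        a_oap = transcription_propensity(oap_only, p.t0, p, wt)
        a_both = transcription_propensity(both, p.t0, p, wt)
        assert a_both < min(a_rok, a_oap)
        assert a_both == pytest.approx(p.k_tx_base * p.rho_rok * p.rho_R**2)
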