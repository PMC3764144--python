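"""Aggregation into population tables, constrained Hill fitting, EC_p, washin."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from neuralinertia import (
    DoseResponseTable,
    EndpointCall,
    HillFitError,
    HillModel,
    NeuralInertiaModel,
    WashinParams,
    aggregate,
    ec_p,
    fit_hill,
    washin_time,
)
from neuralinertia.dose_response import _hill
from neuralinertia.synthetic import PopulationParams, generate_traces, sample_population
from _helpers import make_fit


def _call(fly, ind=None, em=None, inducted=True, emerged=True, **kw):
    return EndpointCall(
        fly_id=fly,
        induction_conc=ind,
        emergence_conc=em,
        inducted=inducted,
        emerged=emerged,
        **kw,
    )


class TestAggregate:
    def test_ascending_cumulative_counts(self, toy_protocol):
        calls = [
            _call("a", ind=0.50, em=0.2),
            _call("b", ind=0.75, em=0.2),
            _call("c", ind=0.75, em=0.2),
            _call("d", ind=1.00, em=0.2),
        ]
        tab = aggregate(calls, toy_protocol, "ascending")
        assert tab.concentration.tolist() == [0.25, 0.50, 0.75, 1.00]
        assert tab.fraction.tolist() == [0.0, 0.25, 0.75, 1.0]

    def test_all_never_emerged_gives_flat_one(self, toy_protocol):
        calls = [_call(str(i), ind=0.5, em=None, emerged=False) for i in range(5)]
        tab = aggregate(calls, toy_protocol, "descending")
        assert np.all(tab.fraction == 1.0)

    def test_zero_usable_flies_raises(self, toy_protocol):
        calls = [
            EndpointCall("a", excluded=True, exclusion_reason="inactive_pre")
        ]
        with pytest.raises(ValueError, match="no usable"):
            aggregate(calls, toy_protocol, "ascending")

    def test_recovery_excluded_counts_on_descending_only(self, toy_protocol):
        calls = [
            _call("a", ind=0.50, em=0.4),
            EndpointCall(
                "b", inducted=True, emerged=False,
                excluded=True, exclusion_reason="no_24h_recovery",
            ),
        ]
        asc = aggregate(calls, toy_protocol, "ascending")
        assert asc.n_total[0] == 1  # excluded fly dropped here
        desc = aggregate(calls, toy_protocol, "descending")
        assert desc.n_total[0] == 2  # but retained as a never-emerger here
        # at 0.6: fly a (emerged at 0.4 < 0.6) + never-emerger are anesthetized
        assert desc.fraction.tolist() == [0.5, 0.5, 1.0]  # concs 0.2, 0.4, 0.6

    def test_fractions_match_independent_recount(self, protocol):
        """Cumulative aggregation equals a brute-force per-step recount over
        the raw binarized traces."""
        params = PopulationParams(n_flies=60, seed=42)
        traces = generate_traces(sample_population(params), protocol, params)
        model = NeuralInertiaModel.from_traces(traces, protocol)
        by_id = {t.fly_id: t for t in traces}

        steps = protocol.bins_per_step(5.0)
        n_pre = 3
        bounds, pos = {}, n_pre
        for idx, nb in enumerate(steps):
            bounds[idx] = (pos, pos + nb)
            pos += nb
        asc_idx = [i for i, s in enumerate(protocol.steps) if s.limb == "ascending"]
        desc_idx = [i for i, s in enumerate(protocol.steps) if s.limb == "descending"]

        def active_in(trace, step_ids):
            act = trace.counts > 0
            return any(act[bounds[i][0]:bounds[i][1]].any() for i in step_ids)

        usable = [c for c in model.calls if not c.excluded]
        asc_end = bounds[asc_idx[-1]][1]
        tab = aggregate(model.calls, protocol, "ascending")
        for conc, frac in zip(tab.concentration, tab.fraction):
            # a persistent immobility run counted at step c means silence from
            # the last bin of step c through the end of the ascending limb
            step = max(i for i in asc_idx if protocol.steps[i].concentration == conc)
            last_bin = bounds[step][1] - 1
            immobile = [
                c_ for c_ in usable
                if not (by_id[c_.fly_id].counts[last_bin:asc_end] > 0).any()
            ]
            assert frac == pytest.approx(len(immobile) / len(usable))

        desc_usable = [
            c for c in model.calls
            if (not c.excluded or c.exclusion_reason == "no_24h_recovery")
            and (c.inducted or c.exclusion_reason == "no_24h_recovery")
        ]
        tab_d = aggregate(model.calls, protocol, "descending")
        for conc, frac in zip(tab_d.concentration, tab_d.fraction):
            still_under = [
                c for c in desc_usable
                if not active_in(
                    by_id[c.fly_id],
                    [i for i in desc_idx if protocol.steps[i].concentration >= conc],
                )
            ]
            assert frac == pytest.approx(len(still_under) / len(desc_usable))


class TestHillFit:
    @pytest.mark.parametrize("top", [1.0, 0.8])
    def test_exact_data_identity(self, top):
        conc = np.geomspace(0.1, 10, 9)
        y = _hill(conc, 1.0, 4.0, top, "increasing")
        fit = HillModel(conc, y, direction="increasing").fit()
        assert fit.ec50 == pytest.approx(1.0, rel=1e-6)
        assert fit.hill_n == pytest.approx(4.0, rel=1e-6)
        assert fit.top == pytest.approx(top, rel=1e-6)
        assert fit.converged

    def test_decreasing_exact_identity(self):
        conc = np.geomspace(0.1, 10, 9)
        y = _hill(conc, 0.6, 3.0, 0.9, "decreasing")
        fit = HillModel(conc, y, direction="decreasing").fit()
        assert fit.ec50 == pytest.approx(0.6, rel=1e-6)
        assert fit.hill_n == pytest.approx(3.0, rel=1e-6)

    def test_noisy_fit_beats_grid_search_oracle(self, rng):
        """The optimizer must land at least as low as a dense grid search."""
        conc = np.geomspace(0.2, 5, 8)
        truth = _hill(conc, 1.1, 3.0, 0.95, "increasing")
        y = rng.binomial(200, truth) / 200
        fit = HillModel(conc, y, direction="increasing").fit()

        best = (np.inf, None)
        for e in np.geomspace(0.2, 5, 60):
            for n in np.geomspace(0.5, 20, 40):
                for t in np.linspace(0.5, 1.0, 26):
                    sse = np.sum((_hill(conc, e, n, t, "increasing") - y) ** 2)
                    if sse < best[0]:
                        best = (sse, (e, n, t))
        assert fit.residual_ss <= best[0] + 1e-12
        # and its EC50 lies within one grid cell of the grid argmin
        assert abs(np.log(fit.ec50) - np.log(best[1][0])) <= np.log(5 / 0.2) / 59 + 1e-9

    def test_degenerate_tables_raise(self):
        conc = np.array([0.1, 0.5, 1.0, 2.0])
        with pytest.raises(HillFitError, match="no transition"):
            HillModel(conc, np.zeros(4)).fit()
        with pytest.raises(HillFitError, match="no transition"):
            HillModel(conc, np.ones(4)).fit()
        with pytest.raises(HillFitError, match="4 distinct"):
            HillModel(conc[:3], [0.1, 0.5, 0.9])

    def test_from_table_orientation(self):
        tab = DoseResponseTable(
            "descending",
            np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
            np.full(5, 100),
            np.array([10, 15, 60, 95, 100]),
        )
        model = HillModel.from_table(tab)
        assert model.direction == "decreasing"
        # fraction emerged = 1 - fraction anesthetized
        assert model.response.tolist() == pytest.approx(
            [0.9, 0.85, 0.4, 0.05, 0.0]
        )
        fit = model.fit()
        assert fit.anesthetized_fraction(10.0) == pytest.approx(1.0, abs=0.02)

    def test_summary_mentions_constrained_bottom(self):
        conc = np.geomspace(0.1, 10, 9)
        fit = HillModel(conc, _hill(conc, 1.0, 2.0, 1.0, "increasing")).fit()
        assert "bottom constrained to 0" in fit.summary()
        assert "EC50" in fit.summary()


class TestEcP:
    def test_midpoint_is_ec50(self):
        assert ec_p(make_fit(1.3, 2.7), 50) == pytest.approx(1.3, rel=1e-12)

    def test_closed_form_unit_slope(self):
        assert ec_p(make_fit(1.0, 1.0), 99) == pytest.approx(99.0, rel=1e-12)

    def test_matches_root_finding_oracle(self):
        fit = make_fit(1.0, 8.0, top=0.9)
        target = 0.01 * fit.top  # 1% of the plateau
        root = brentq(lambda c: float(fit.predict(c)) - target, 1e-6, 10.0)
        assert ec_p(fit, 1) == pytest.approx(root, rel=1e-9)

    def test_decreasing_direction_reciprocal(self):
        fit = make_fit(1.0, 2.0, direction="decreasing")
        # response falls with c: 99% of top at low concentration
        assert ec_p(fit, 99) < 1.0 < ec_p(fit, 1)
        root = brentq(lambda c: float(fit.predict(c)) - 0.99, 1e-9, 1.0)
        assert ec_p(fit, 99) == pytest.approx(root, rel=1e-9)

    def test_out_of_range_p(self):
        for p in (0, 100, -5, 120):
            with pytest.raises(ValueError):
                ec_p(make_fit(1.0, 2.0), p)

    @given(
        p=st.floats(1.0, 98.0),
        dp=st.floats(0.5, 1.5),
        n=st.floats(0.5, 10.0),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_strictly_increasing_in_p(self, p, dp, n):
        fit = make_fit(1.0, n)
        assert ec_p(fit, p + dp) > ec_p(fit, p)


class TestWashin:
    def test_standard_tube_equilibrates_within_18_seconds(self):
        t = washin_time(WashinParams(volume=0.75, flow=15.0, tolerance_fraction=0.0025))
        assert t == pytest.approx(17.97, abs=0.01)
        assert t <= 18.0

    def test_half_life(self):
        t = washin_time(WashinParams(volume=0.75, flow=15.0, tolerance_fraction=0.5))
        assert t == pytest.approx((0.75 / 15.0) * np.log(2) * 60, rel=1e-12)

    def test_doubling_flow_halves_time(self):
        t1 = washin_time(WashinParams(flow=15.0))
        t2 = washin_time(WashinParams(flow=30.0))
        assert t1 == pytest.approx(2 * t2, rel=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            WashinParams(volume=0.0)
        with pytest.raises(ValueError):
            WashinParams(tolerance_fraction=1.5)
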