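import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eatdry.errors import DomainError, InvalidStateError, UnreachableMoistureError
from eatdry.kinetics import (
    DryingConditions,
    MoistureState,
    ParamMapConfig,
    ThinLayerParams,
    convert_basis,
    fit_weibull,
    generate_thinlayer_dataset,
    moisture_at_time,
    moisture_ratio,
    params_for_conditions,
    time_for_moisture,
    wb_to_db,
)


@pytest.mark.parametrize("params, t, expected", [
    (ThinLayerParams(0, 1, 0.01, 1), 0.0, 1.0),                       # MR(0) = a+b
    (ThinLayerParams(0, 1, 0.01, 1), 100.0, math.exp(-1)),            # closed form
    # hand evaluation: 0.02 + 0.98*exp(-0.05 * 30**1.2)
    (ThinLayerParams(0.02, 0.98, 0.05, 1.2), 30.0,
     0.02 + 0.98 * math.exp(-0.05 * 30.0 ** 1.2)),
])
def test_moisture_ratio_examples(params, t, expected):
    assert moisture_ratio(params, t) == pytest.approx(expected, rel=1e-12)


def test_moisture_ratio_rejects_negative_time():
    with pytest.raises(DomainError):
        moisture_ratio(ThinLayerParams(0, 1, 0.01, 1), -1.0)


def test_moisture_at_time_examples():
    p = ThinLayerParams(0, 1, 0.01, 1)
    state = MoistureState(M0=30, Me=10)
    assert moisture_at_time(p, state, 0.0) == pytest.approx(30.0)
    assert moisture_at_time(p, state, 100.0) == pytest.approx(10 + 20 * math.exp(-1))
    with pytest.raises(InvalidStateError):
        MoistureState(M0=10, Me=10)


def test_time_for_moisture_inverse_examples():
    p = ThinLayerParams(0, 1, 0.01, 1)
    mt = 10 + 20 * math.exp(-1)
    assert time_for_moisture(p, MoistureState(M0=30, Me=10, Mt=mt)) == pytest.approx(100.0)
    # inverse at the start: MR target = a+b
    assert time_for_moisture(p, MoistureState(M0=30, Me=10, Mt=30)) == pytest.approx(0.0)
    with pytest.raises(UnreachableMoistureError):
        time_for_moisture(ThinLayerParams(0.1, 0.9, 0.05, 1.1),
                          MoistureState(M0=30, Me=10, Mt=10.5))  # MR below offset a


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    a=st.floats(0.0, 0.1),
    b=st.floats(0.9, 1.0),
    k=st.floats(0.01, 5.0),
    N=st.floats(0.5, 2.5),
    frac=st.floats(1e-4, 1.0 - 1e-4),
)
def test_forward_inverse_roundtrip(a, b, k, N, frac):
    """Eq.-(5)/(6) consistency: inverting the curve and re-evaluating it
    recovers the moisture to 1e-9 of the drying span."""
    if a + b > 1.1:
        b = 1.1 - a
    p = ThinLayerParams(a, b, k, N)
    M0, Me = 34.0, 5.0
    mt = Me + (M0 - Me) * (a + 1e-6 + frac * (b - 2e-6))
    t = time_for_moisture(p, MoistureState(M0=M0, Me=Me, Mt=mt))
    assert abs(moisture_at_time(p, MoistureState(M0=M0, Me=Me), t) - mt) < 1e-9 * (M0 - Me)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(k=st.floats(0.01, 5.0), N=st.floats(0.5, 2.5),
       t1=st.floats(0.01, 10.0), dt=st.floats(0.01, 5.0))
def test_mr_strictly_decreasing(k, N, t1, dt):
    p = ThinLayerParams(0.0, 1.0, k, N)
    assert moisture_ratio(p, t1 + dt) < moisture_ratio(p, t1)


@pytest.mark.parametrize("wb, db", [(0.0, 0.0), (50.0, 100.0),
                                    (14.5, 100 * 14.5 / 85.5)])
def test_convert_basis_examples(wb, db):
    assert convert_basis(wb, "wb->db") == pytest.approx(db, abs=1e-9)
    assert convert_basis(db, "db->wb") == pytest.approx(wb, abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(wb=st.floats(0.0, 60.0))
def test_convert_basis_roundtrip(wb):
    assert convert_basis(convert_basis(wb, "wb->db"), "db->wb") == pytest.approx(wb, abs=1e-12)


def test_convert_basis_domain():
    with pytest.raises(DomainError):
        convert_basis(100.0, "wb->db")
    with pytest.raises(DomainError):
        convert_basis(10.0, "sideways")


class TestFitWeibull:
    boundaries = MoistureState(M0=34.0, Me=5.0)

    def _curve(self, p, t, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        mr = p.a + p.b * np.exp(-p.k * np.power(t, p.N))
        if noise:
            mr = mr + rng.normal(0, noise, len(t))
        mt = self.boundaries.Me + (self.boundaries.M0 - self.boundaries.Me) * mr
        return list(zip(t, mt))

    def test_noiseless_recovery(self):
        truth = ThinLayerParams(0, 1, 0.5, 1.1)
        t = np.linspace(0, 6, 40)
        rep = fit_weibull(self._curve(truth, t), self.boundaries)
        assert rep.success and rep.r2 > 1 - 1e-9
        assert rep.params.k == pytest.approx(truth.k, abs=1e-6)
        assert rep.params.N == pytest.approx(truth.N, abs=1e-6)

    def test_noisy_recovery_within_10pct(self):
        truth = ThinLayerParams(0.02, 0.98, 0.4, 1.2)
        t = np.linspace(0.05, 8, 40)
        rep = fit_weibull(self._curve(truth, t, noise=0.005, seed=7), self.boundaries)
        assert rep.success
        assert rep.params.b == pytest.approx(truth.b, rel=0.10)
        assert rep.params.k == pytest.approx(truth.k, rel=0.10)
        assert rep.params.N == pytest.approx(truth.N, rel=0.10)

    def test_constant_curve_fails_gracefully(self):
        curve = [(float(t), 20.0) for t in range(10)]
        rep = fit_weibull(curve, self.boundaries)
        assert not rep.success and "constant" in rep.message

    def test_input_validation(self):
        with pytest.raises(DomainError):
            fit_weibull([(0, 30), (1, 29)], self.boundaries)  # too few points
        with pytest.raises(DomainError):
            fit_weibull([(float(t), 30 - t) for t in (0, 2, 1, 3, 4, 5)],
                        self.boundaries)  # non-monotone time

    def test_parameter_recovery_20_curves(self):
        """Median relative error of b, k, N (and absolute error of a) over
        20 noisy synthetic curves stays within 10%."""
        pmap = ParamMapConfig()
        temps = np.linspace(70, 130, 20)
        errs = {"a": [], "b": [], "k": [], "N": []}
        for i, T in enumerate(temps):
            cond = DryingConditions(T=float(T), RH=0.1, V=0.6, W0=25.5, gamma=0.5)
            truth = params_for_conditions(cond, pmap).params
            t = np.linspace(0.05, 8, 40)
            rep = fit_weibull(self._curve(truth, t, noise=0.005, seed=100 + i),
                              self.boundaries)
            assert rep.success
            errs["a"].append(abs(rep.params.a - truth.a))
            for name in ("b", "k", "N"):
                errs[name].append(abs(getattr(rep.params, name) - getattr(truth, name))
                                  / getattr(truth, name))
        assert np.median(errs["a"]) <= 0.02
        for name in ("b", "k", "N"):
            assert np.median(errs[name]) <= 0.10, name


class TestParamMap:
    def test_anchor_identity(self):
        pmap = ParamMapConfig()
        cond = DryingConditions(T=pmap.T_ref, RH=pmap.RH_ref, V=pmap.V_ref,
                                W0=pmap.W0_ref, gamma=0.5)
        got = params_for_conditions(cond, pmap)
        assert not got.extrapolated
        assert got.params.k == pytest.approx(pmap.k_ref, rel=1e-12)
        assert got.params.N == pytest.approx(pmap.N_ref)

    def test_k_monotone_in_temperature(self):
        pmap = ParamMapConfig()
        ks = [params_for_conditions(
                DryingConditions(T=T, RH=0.1, V=0.6, W0=25.5, gamma=0.5), pmap).params.k
              for T in (60, 80, 100, 120)]
        assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))

    def test_extrapolation_flag(self):
        pmap = ParamMapConfig()
        cond = DryingConditions(T=150.0, RH=0.1, V=0.6, W0=25.5, gamma=0.5)
        assert params_for_conditions(cond, pmap).extrapolated

    def test_shared_truth_with_generator(self):
        """The same map drives the synthetic thin-layer generator and the
        simulator, so a noiseless fit recovers the map exactly on a grid."""
        pmap = ParamMapConfig()
        design = [DryingConditions(T=T, RH=0.1, V=0.6, W0=25.5, gamma=0.5)
                  for T in (70, 85, 100, 115, 130)]
        table = generate_thinlayer_dataset(pmap, design, noise_sd=0.0, seed=0)
        for cid, cond in enumerate(design):
            sub = table[table.condition_id == cid]
            rep = fit_weibull(list(zip(sub.t_h, sub.Mt_db)),
                              MoistureState(M0=wb_to_db(cond.W0), Me=5.0))
            truth = params_for_conditions(cond, pmap).params
            assert rep.params.k == pytest.approx(truth.k, rel=1e-5)


class TestGenerator:
    def test_determinism(self):
        pmap = ParamMapConfig()
        design = [DryingConditions(T=100, RH=0.1, V=0.6, W0=25.5, gamma=0.5)]
        t1 = generate_thinlayer_dataset(pmap, design, noise_sd=0.01, seed=5)
        t2 = generate_thinlayer_dataset(pmap, design, noise_sd=0.01, seed=5)
        assert t1.equals(t2)

    def test_empty_design_rejected(self):
        with pytest.raises(DomainError):
            generate_thinlayer_dataset(ParamMapConfig(), [], seed=0)

    def test_negative_noise_rejected(self):
        design = [DryingConditions(T=100, RH=0.1, V=0.6, W0=25.5, gamma=0.5)]
        with pytest.raises(DomainError):
            generate_thinlayer_dataset(ParamMapConfig(), design, noise_sd=-1, seed=0)


def test_thinlayerparams_invariants():
    with pytest.raises(DomainError):
        ThinLayerParams(0, -1, 0.1, 1)
    with pytest.raises(DomainError):
        ThinLayerParams(0.5, 1.0, 0.1, 1)  # a+b out of [0.9, 1.1]
    with pytest.raises(DomainError):
        DryingConditions(T=100, RH=1.5, V=0.6, W0=25.5, gamma=0.5)
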