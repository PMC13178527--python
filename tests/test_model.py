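"""Motor-neuron pool simulator: single-step behaviour, integration accuracy,
calibration and network-level invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mnpool import params as prm
from mnpool.model import (CalibrationError, PoolConfig, RenshawNetwork,
                          calibrate_constant_drive, default_rate_targets,
                          initial_state, run_simulation, step_pool)


@pytest.fixture(scope="module")
def P():
    return prm.pack_mn_params(prm.default_params())


class TestStepPool:
    def test_leak_equilibrium_is_a_fixed_point(self, P):
        """With all active and synaptic conductances zero and both
        compartments at the leak reversal, one step changes nothing."""
        Pz = P.copy()
        for idx in (prm.P_GNA, prm.P_GKDR, prm.P_GCANS, prm.P_GKCAS,
                    prm.P_GNAP, prm.P_GCAND, prm.P_GCAL, prm.P_GKCAD):
            Pz[idx] = 0.0
        st = initial_state(5, Pz)
        vs0, vd0 = st.VS.copy(), st.VD.copy()
        st, flags = step_pool(st, Pz, np.zeros(5), np.zeros(5), 0.2)
        assert not flags.any()
        np.testing.assert_allclose(st.VS, vs0, atol=1e-9)
        np.testing.assert_allclose(st.VD, vd0, atol=1e-9)

    def test_excitatory_drive_depolarizes_dendrite(self, P):
        """Positive g_excit with V_D below the excitatory reversal moves the
        dendritic potential upward relative to the undriven step."""
        st_a = initial_state(3, P)
        st_b = initial_state(3, P)
        step_pool(st_a, P, np.zeros(3), np.zeros(3), 0.2)
        step_pool(st_b, P, np.full(3, 0.5), np.zeros(3), 0.2)
        assert np.all(st_b.VD > st_a.VD)

    def test_nonfinite_state_raises_with_mn_index(self, P):
        st = initial_state(4, P)
        st.VS[2] = np.nan
        with pytest.raises(FloatingPointError, match="MN 2"):
            step_pool(st, P, np.zeros(4), np.zeros(4), 0.2)

    def test_input_shape_checked(self, P):
        st = initial_state(4, P)
        with pytest.raises(ValueError):
            step_pool(st, P, np.zeros(3), np.zeros(4), 0.2)


def _mn_rhs(P):
    """Independent right-hand side of the single-MN ODE system (gates h, n,
    m_N, h_N, m_L, h_P dynamic; m, m_P instantaneous), for the dense oracle."""
    def winf(V, th, k):
        return 1.0 / (1.0 + np.exp((V - th) / k))

    def rhs(_, y, g_exc):
        VS, VD, h, n, mN, hN, mL, hP, CaS, CaD = y
        m = winf(VS, P[prm.P_M_TH], P[prm.P_M_K])
        mP = winf(VS, P[prm.P_MP_TH], P[prm.P_MP_K])
        tau_h = P[prm.P_H_TS] / (np.exp((VS - P[prm.P_H_TT]) / P[prm.P_H_K1])
                                 + np.exp(-(VS - P[prm.P_H_TT]) / P[prm.P_H_K2]))
        tau_n = P[prm.P_N_TS] / (np.exp((VS - P[prm.P_N_TT]) / P[prm.P_N_K1])
                                 + np.exp(-(VS - P[prm.P_N_TT]) / P[prm.P_N_K2]))
        dh = (winf(VS, P[prm.P_H_TH], P[prm.P_H_K]) - h) / tau_h
        dn = (winf(VS, P[prm.P_N_TH], P[prm.P_N_K]) - n) / tau_n
        dmN = (winf(VS, P[prm.P_MN_TH], P[prm.P_MN_K]) - mN) / P[prm.P_MN_TAU]
        dhN = (winf(VS, P[prm.P_HN_TH], P[prm.P_HN_K]) - hN) / P[prm.P_HN_TAU]
        dmL = (winf(VD, P[prm.P_ML_TH], P[prm.P_ML_K]) - mL) / P[prm.P_ML_TAU]
        dhP = (winf(VS, P[prm.P_HP_TH], P[prm.P_HP_K]) - hP) / P[prm.P_HP_TAU]
        fS = CaS / (CaS + P[prm.P_KD])
        fD = CaD / (CaD + P[prm.P_KD])
        gc_s = P[prm.P_GC] / P[prm.P_P]
        gc_d = P[prm.P_GC] / (1 - P[prm.P_P])
        I_S = (P[prm.P_GNA] * m ** 3 * h * (VS - P[prm.P_VNA])
               + P[prm.P_GKDR] * n ** 4 * (VS - P[prm.P_VK])
               + P[prm.P_GCANS] * mN ** 2 * hN * (VS - P[prm.P_VCA])
               + P[prm.P_GKCAS] * fS * (VS - P[prm.P_VK])
               + P[prm.P_GNAP] * mP ** 3 * hP * (VS - P[prm.P_VNA])
               + P[prm.P_GL] * (VS - P[prm.P_VL]) + gc_s * (VS - VD))
        I_D = (P[prm.P_GCAND] * mN ** 2 * hN * (VD - P[prm.P_VCA])
               + P[prm.P_GCAL] * mL * (VD - P[prm.P_VCA])
               + P[prm.P_GKCAD] * fD * (VD - P[prm.P_VK])
               + P[prm.P_GL] * (VD - P[prm.P_VL]) + gc_d * (VD - VS)
               + g_exc * (VD - P[prm.P_VEXC]))
        ICaS = P[prm.P_GCANS] * mN ** 2 * hN * (VS - P[prm.P_VCA])
        ICaD = (P[prm.P_GCAND] * mN ** 2 * hN + P[prm.P_GCAL] * mL) \
            * (VD - P[prm.P_VCA])
        f, a, k = P[prm.P_CAF], P[prm.P_CAALPHA], P[prm.P_CAK]
        return [-I_S / P[prm.P_CM], -I_D / P[prm.P_CM], dh, dn, dmN, dhN,
                dmL, dhP, f * (-a * ICaS - k * CaS), f * (-a * ICaD - k * CaD)]
    return rhs


def test_exponential_update_matches_dense_ode_oracle(P):
    """100 ms of a single subthreshold-driven MN at the production 0.2 ms
    step stays within 1 mV of an independent high-accuracy ODE solution."""
    g_exc = 0.02  # below rheobase
    cfg = PoolConfig(n_mn=1, duration=0.1, C=np.array([g_exc]), seed=0,
                     renshaw=False, record_voltages=True,
                     params={"motor_neuron": {"drive": {"noise_scale": 0.0}}})
    res = run_simulation(cfg, compute_force=False)
    vs_kernel = res.v_trace[:, 0]

    st = initial_state(1, P)
    y0 = [st.VS[0], st.VD[0], st.W[1, 0], st.W[2, 0], st.W[3, 0],
          st.W[4, 0], st.W[5, 0], st.W[7, 0], 0.0, 0.0]
    t_eval = (np.arange(len(vs_kernel)) + 1) * 0.2e-3 * 1000  # ms
    sol = solve_ivp(_mn_rhs(P), (0.0, 100.0), y0, args=(g_exc,),
                    t_eval=t_eval, rtol=1e-9, atol=1e-10, method="LSODA")
    assert sol.success
    assert np.max(np.abs(sol.y[0] - vs_kernel)) < 1.0


class TestRunSimulation:
    def test_zero_drive_is_silent(self):
        cfg = PoolConfig(n_mn=10, duration=2.0, C=np.zeros(10), seed=1,
                         renshaw=False)
        res = run_simulation(cfg, compute_force=False)
        assert res.mn_spikes.counts().sum() == 0

    def test_fixed_seed_reproduces_spike_trains(self):
        C = np.linspace(0.04, 0.08, 8)
        runs = [run_simulation(PoolConfig(n_mn=8, duration=3.0, C=C, seed=11),
                               compute_force=False) for _ in range(2)]
        for a, b in zip(runs[0].mn_spikes.trains, runs[1].mn_spikes.trains):
            np.testing.assert_array_equal(a, b)

    def test_common_input_rate_mismatch_rejected(self):
        from mnpool.inputs import CommonInputSignal
        cfg = PoolConfig(n_mn=4, duration=1.0, C=np.full(4, 0.05), seed=0)
        bad = CommonInputSignal(np.zeros(cfg.n_steps), 1000.0, "cCI")
        with pytest.raises(ValueError, match="rate"):
            run_simulation(cfg, bad)

    def test_refractory_floor(self, small_pool_result):
        """No interspike interval below 5 ms anywhere in a calibrated-range
        run."""
        for t in small_pool_result.mn_spikes.trains:
            if t.size > 1:
                assert np.diff(t).min() >= 0.005

    def test_rate_monotone_in_drive(self, small_pool_result):
        """Across the drive gradient of the shared run, a 5-point summary of
        rate vs C is non-decreasing."""
        rates = small_pool_result.mn_spikes.rates()
        chunks = np.array_split(rates, 5)
        means = [c.mean() for c in chunks]
        assert all(b >= a - 0.2 for a, b in zip(means, means[1:]))

    def test_renshaw_inhibition_lowers_rates(self):
        C = np.full(12, 0.06)
        on = run_simulation(PoolConfig(n_mn=12, duration=8.0, C=C, seed=3,
                                       renshaw=True), compute_force=False)
        off = run_simulation(PoolConfig(n_mn=12, duration=8.0, C=C, seed=3,
                                        renshaw=False), compute_force=False)
        assert on.rc_spikes.counts().sum() > 0
        assert on.mn_spikes.rates().mean() <= off.mn_spikes.rates().mean()

    def test_spike_times_within_duration_and_increasing(self, small_pool_result):
        sts = small_pool_result.mn_spikes
        for t in sts.trains:
            assert np.all((t >= 0) & (t <= sts.duration))
            assert np.all(np.diff(t) > 0)


class TestRenshawNetwork:
    def test_exact_degrees_and_no_duplicates(self):
        net = RenshawNetwork.build(177, 64, 50, 20, seed=5)
        assert net.mn_to_rc.shape == (64, 50)
        assert net.rc_to_mn.shape == (177, 20)
        for row in net.mn_to_rc:
            assert len(set(row)) == 50 and row.max() < 177
        for row in net.rc_to_mn:
            assert len(set(row)) == 20 and row.max() < 64


class TestCalibration:
    def test_zero_target_gives_zero_drive(self):
        cfg = PoolConfig(n_mn=3, seed=2, renshaw=False)
        C, rep = calibrate_constant_drive(np.zeros(3), cfg, cal_duration=2.0,
                                          max_iter=1)
        np.testing.assert_array_equal(C, 0.0)

    def test_unattainable_target_reported(self):
        cfg = PoolConfig(n_mn=2, seed=2, renshaw=False)
        with pytest.raises(CalibrationError, match="unattainable"):
            calibrate_constant_drive(np.array([10.0, 500.0]), cfg,
                                     cal_duration=3.0, c_max=1.0)

    def test_random_targets_recovered_on_validation_run(self):
        """Seeded random targets are recovered within tolerance of the
        rate-measurement noise on an independent validation run."""
        rng = np.random.default_rng(8)
        targets = rng.uniform(8.0, 13.0, 16)
        cfg = PoolConfig(n_mn=16, seed=21, renshaw=False)
        C, rep = calibrate_constant_drive(targets, cfg, cal_duration=15.0,
                                          max_iter=6)
        val = run_simulation(PoolConfig(n_mn=16, duration=30.0, C=C, seed=99,
                                        renshaw=False), compute_force=False)
        err = val.mn_spikes.rates() - targets
        assert np.abs(err).mean() < 0.45
        assert np.abs(err).max() < 1.2

    def test_default_targets_match_reference_spread(self):
        t = default_rate_targets()
        assert t.size == 177
        assert t.min() == pytest.approx(7.3)
        assert t.max() == pytest.approx(13.4)
        assert t.mean() == pytest.approx(10.4, abs=1e-6)
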