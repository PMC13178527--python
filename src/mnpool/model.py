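"""Two-compartment conductance-based motor-neuron pool with recurrent
Renshaw inhibition.

The pool holds 177 slow-type motor neurons (MNs), each a soma + dendrite
Hodgkin-Huxley model with eight active conductances (somatic Na, K-dr, Ca-N,
K(Ca), NaP; dendritic Ca-L, Ca-N, K(Ca)), plus a population of 64 Renshaw
cells (RCs): each RC is driven by 50 distinct MNs and each MN is inhibited
by 20 distinct RCs.  All membrane and gating equations are integrated with
the exponential (MacGregor) scheme at a 0.2 ms step (5000 Hz).

Every MN *j* receives a dendritic excitatory conductance drive
``m(t) = m_II(t) + m_CI(t)`` where the independent part is
``m_II(t) = C_j + noise_scale * sqrt(C_j) * xi_j(t)`` with one standard
Gaussian sample per step per MN, and ``m_CI(t)`` is an optional common-input
waveform shared by the whole pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from . import params as prm
from .spikes import SpikeTrainSet

__all__ = [
    "PoolConfig",
    "MNPoolState",
    "RenshawNetwork",
    "SimulationResult",
    "CalibrationError",
    "initial_state",
    "step_pool",
    "run_simulation",
    "calibrate_constant_drive",
    "default_rate_targets",
]

# gate row indices in the state matrix W
GM, GH, GN, GMN, GHN, GML, GMP, GHP = range(8)


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True, inline="always", fastmath=True)
def _winf(V, theta, k):
    return 1.0 / (1.0 + np.exp((V - theta) / k))


@njit(cache=True, inline="always", fastmath=True)
def _tau_biexp(V, scale, theta, k1, k2):
    tau = scale / (np.exp((V - theta) / k1) + np.exp(-(V - theta) / k2))
    # floor against overflow at extreme voltages (keeps the update defined)
    return tau if tau > 1e-4 else 1e-4


@njit(cache=True, inline="always", fastmath=True)
def _expstep(V, Vinf_num, G, Cm, dt):
    """Exponential-Euler voltage update: dV/dt = (Vinf_num - G*V)/Cm."""
    a = G / Cm
    if abs(a) > 1e-6:
        Vinf = Vinf_num / G
        return Vinf + (V - Vinf) * np.exp(-a * dt)
    return V + dt * Vinf_num / Cm


@njit(cache=True, fastmath=True)
def _mn_step(P, VS, VD, W, CaS, CaD, g_exc, g_inh, dt):
    """Advance all MNs one step in place (voltages, gates, calcium)."""
    n = VS.shape[0]
    eN = np.exp(-dt / P[prm.P_MN_TAU])
    eHN = np.exp(-dt / P[prm.P_HN_TAU])
    eL = np.exp(-dt / P[prm.P_ML_TAU])
    eHP = np.exp(-dt / P[prm.P_HP_TAU])
    fca = P[prm.P_CAF]
    kca = P[prm.P_CAK]
    eCa = np.exp(-dt * fca * kca)
    m_th, m_k = P[prm.P_M_TH], P[prm.P_M_K]
    h_th, h_k = P[prm.P_H_TH], P[prm.P_H_K]
    h_ts, h_tt, h_k1, h_k2 = P[prm.P_H_TS], P[prm.P_H_TT], P[prm.P_H_K1], P[prm.P_H_K2]
    n_th, n_k = P[prm.P_N_TH], P[prm.P_N_K]
    n_ts, n_tt, n_k1, n_k2 = P[prm.P_N_TS], P[prm.P_N_TT], P[prm.P_N_K1], P[prm.P_N_K2]
    mn_th, mn_k = P[prm.P_MN_TH], P[prm.P_MN_K]
    hn_th, hn_k = P[prm.P_HN_TH], P[prm.P_HN_K]
    ml_th, ml_k = P[prm.P_ML_TH], P[prm.P_ML_K]
    mp_th, mp_k = P[prm.P_MP_TH], P[prm.P_MP_K]
    hp_th, hp_k = P[prm.P_HP_TH], P[prm.P_HP_K]
    gna, gkdr, gcans = P[prm.P_GNA], P[prm.P_GKDR], P[prm.P_GCANS]
    gkcas, gnap = P[prm.P_GKCAS], P[prm.P_GNAP]
    gcand, gcal, gkcad = P[prm.P_GCAND], P[prm.P_GCAL], P[prm.P_GKCAD]
    gl, vl, cm = P[prm.P_GL], P[prm.P_VL], P[prm.P_CM]
    vna, vk, vca = P[prm.P_VNA], P[prm.P_VK], P[prm.P_VCA]
    vexc, vinh = P[prm.P_VEXC], P[prm.P_VINH]
    kd, alpha = P[prm.P_KD], P[prm.P_CAALPHA]
    gc_s = P[prm.P_GC] / P[prm.P_P]
    gc_d = P[prm.P_GC] / (1.0 - P[prm.P_P])
    for j in range(n):
        vs = VS[j]
        vd = VD[j]
        # gate updates from the previous-step voltages
        W[GM, j] = _winf(vs, m_th, m_k)                        # instantaneous
        hinf = _winf(vs, h_th, h_k)
        th = _tau_biexp(vs, h_ts, h_tt, h_k1, h_k2)
        W[GH, j] = hinf + (W[GH, j] - hinf) * np.exp(-dt / th)
        ninf = _winf(vs, n_th, n_k)
        tn = _tau_biexp(vs, n_ts, n_tt, n_k1, n_k2)
        W[GN, j] = ninf + (W[GN, j] - ninf) * np.exp(-dt / tn)
        # Ca-N gates are shared between compartments; driven by somatic V
        mninf = _winf(vs, mn_th, mn_k)
        W[GMN, j] = mninf + (W[GMN, j] - mninf) * eN
        hninf = _winf(vs, hn_th, hn_k)
        W[GHN, j] = hninf + (W[GHN, j] - hninf) * eHN
        mlinf = _winf(vd, ml_th, ml_k)
        W[GML, j] = mlinf + (W[GML, j] - mlinf) * eL
        W[GMP, j] = _winf(vs, mp_th, mp_k)                     # instantaneous
        hpinf = _winf(vs, hp_th, hp_k)
        W[GHP, j] = hpinf + (W[GHP, j] - hpinf) * eHP

        m3h = W[GM, j] ** 3 * W[GH, j]
        n4 = W[GN, j] ** 4
        mn2hn = W[GMN, j] ** 2 * W[GHN, j]
        mp3hp = W[GMP, j] ** 3 * W[GHP, j]
        fS = CaS[j] / (CaS[j] + kd)
        fD = CaD[j] / (CaD[j] + kd)

        # soma
        GS = (gna * m3h + gkdr * n4 + gcans * mn2hn + gkcas * fS
              + gnap * mp3hp + gl + gc_s)
        IS = (gna * m3h * vna + gkdr * n4 * vk + gcans * mn2hn * vca
              + gkcas * fS * vk + gnap * mp3hp * vna
              + gl * vl + gc_s * vd)
        # dendrite
        GD = (gcand * mn2hn + gcal * W[GML, j] + gkcad * fD + gl + gc_d
              + g_exc[j] + g_inh[j])
        ID = (gcand * mn2hn * vca + gcal * W[GML, j] * vca + gkcad * fD * vk
              + gl * vl + gc_d * vs + g_exc[j] * vexc + g_inh[j] * vinh)

        VS[j] = _expstep(vs, IS, GS, cm, dt)
        VD[j] = _expstep(vd, ID, GD, cm, dt)

        # calcium pools: first-order influx/removal
        ICaS = gcans * mn2hn * (vs - vca)
        ICaD = (gcand * mn2hn + gcal * W[GML, j]) * (vd - vca)
        cainfS = -alpha * ICaS / kca
        cainfD = -alpha * ICaD / kca
        CaS[j] = max(cainfS + (CaS[j] - cainfS) * eCa, 0.0)
        CaD[j] = max(cainfD + (CaD[j] - cainfD) * eCa, 0.0)


@njit(cache=True, fastmath=True)
def _rc_step(R, VR, WR, g_e, g_ahp, dt):
    n = VR.shape[0]
    for j in range(n):
        v = VR[j]
        WR[0, j] = _winf(v, R[prm.R_M_TH], R[prm.R_M_K])
        hinf = _winf(v, R[prm.R_H_TH], R[prm.R_H_K])
        th = _tau_biexp(v, R[prm.R_H_TS], R[prm.R_H_TT], R[prm.R_H_K1], R[prm.R_H_K2])
        WR[1, j] = hinf + (WR[1, j] - hinf) * np.exp(-dt / th)
        ninf = _winf(v, R[prm.R_N_TH], R[prm.R_N_K])
        tn = _tau_biexp(v, R[prm.R_N_TS], R[prm.R_N_TT], R[prm.R_N_K1], R[prm.R_N_K2])
        WR[2, j] = ninf + (WR[2, j] - ninf) * np.exp(-dt / tn)

        m3h = WR[0, j] ** 3 * WR[1, j]
        n4 = WR[2, j] ** 4
        G = (R[prm.R_GNA] * m3h + R[prm.R_GK] * n4 + R[prm.R_GL]
             + g_e[j] + g_ahp[j])
        I = (R[prm.R_GNA] * m3h * R[prm.R_VNA]
             + R[prm.R_GK] * n4 * R[prm.R_VK]
             + R[prm.R_GL] * R[prm.R_VL]
             + g_e[j] * R[prm.R_VSYN] + g_ahp[j] * R[prm.R_VK])
        VR[j] = _expstep(v, I, G, R[prm.R_CM], dt)


@njit(cache=True)
def _integrate(P, R, C, common, n_steps, dt, rc_on,
               mn_out_ptr, mn_out_idx, rc_out_ptr, rc_out_idx,
               seed, VS, VD, W, CaS, CaD, VR, WR,
               record_v, v_trace,
               mn_sp_unit, mn_sp_step, rc_sp_unit, rc_sp_step):
    """Full integration loop.  Returns (n_mn_spikes, n_rc_spikes, err_mn)."""
    np.random.seed(seed)
    n_mn = VS.shape[0]
    n_rc = VR.shape[0]
    noise = P[prm.P_NOISE]
    sqC = np.sqrt(C)
    g_exc = np.zeros(n_mn)
    g_inh = np.zeros(n_mn)
    g_e_rc = np.zeros(n_rc)
    g_ahp = np.zeros(n_rc)
    dec_i = np.exp(-dt / R[prm.R_TAU_RCMN])
    dec_e = np.exp(-dt / R[prm.R_TAU_MNRC])
    dec_a = np.exp(-dt / R[prm.R_AHP_TAU])
    lock_mn = int(np.ceil(P[prm.P_LOCKOUT] / dt))
    lock_rc = int(np.ceil(R[prm.R_LOCKOUT] / dt))
    last_mn = np.full(n_mn, -10 * lock_mn, dtype=np.int64)
    last_rc = np.full(n_rc, -10 * lock_rc, dtype=np.int64)
    thr_mn = P[prm.P_THRESH]
    thr_rc = R[prm.R_THRESH]
    oldVS = np.empty(n_mn)
    oldVR = np.empty(n_rc)
    n_sp = 0
    n_rsp = 0
    cap_mn = mn_sp_unit.shape[0]
    cap_rc = rc_sp_unit.shape[0]

    for t in range(n_steps):
        xi = np.random.standard_normal(n_mn)
        for j in range(n_mn):
            g_exc[j] = C[j] + noise * sqC[j] * xi[j] + common[t]
            oldVS[j] = VS[j]
        if rc_on:
            for j in range(n_mn):
                g_inh[j] *= dec_i
            for j in range(n_rc):
                g_e_rc[j] *= dec_e
                g_ahp[j] *= dec_a
        _mn_step(P, VS, VD, W, CaS, CaD, g_exc, g_inh, dt)
        for j in range(n_mn):
            if oldVS[j] < thr_mn and VS[j] >= thr_mn and t - last_mn[j] >= lock_mn:
                last_mn[j] = t
                if n_sp >= cap_mn:
                    return n_sp, n_rsp, -2
                mn_sp_unit[n_sp] = j
                mn_sp_step[n_sp] = t + 1
                n_sp += 1
                if rc_on:
                    for k in range(mn_out_ptr[j], mn_out_ptr[j + 1]):
                        g_e_rc[mn_out_idx[k]] += R[prm.R_W_MNRC]
        if rc_on:
            for j in range(n_rc):
                oldVR[j] = VR[j]
            _rc_step(R, VR, WR, g_e_rc, g_ahp, dt)
            for j in range(n_rc):
                if oldVR[j] < thr_rc and VR[j] >= thr_rc and t - last_rc[j] >= lock_rc:
                    last_rc[j] = t
                    g_ahp[j] += R[prm.R_AHP_STEP]
                    if n_rsp >= cap_rc:
                        return n_sp, n_rsp, -2
                    rc_sp_unit[n_rsp] = j
                    rc_sp_step[n_rsp] = t + 1
                    n_rsp += 1
                    for k in range(rc_out_ptr[j], rc_out_ptr[j + 1]):
                        g_inh[rc_out_idx[k]] += R[prm.R_W_RCMN]
        if record_v:
            v_trace[t, 0] = VS[0]
            v_trace[t, 1] = VD[0]
        if t % 5000 == 0:
            for j in range(n_mn):
                if not np.isfinite(VS[j]):
                    return n_sp, n_rsp, j
    for j in range(n_mn):
        if not np.isfinite(VS[j]):
            return n_sp, n_rsp, j
    return n_sp, n_rsp, -1


# ---------------------------------------------------------------------------
# public containers

@dataclass
class RenshawNetwork:
    """Random MN->RC and RC->MN projections with exact in-degrees."""

    mn_to_rc: np.ndarray   # (n_rc, in_degree_mn) MN indices driving each RC
    rc_to_mn: np.ndarray   # (n_mn, out_degree_rc) RC indices inhibiting each MN

    @classmethod
    def build(cls, n_mn: int, n_rc: int, in_degree_mn: int = 50,
              out_degree_rc: int = 20, seed: int = 0) -> "RenshawNetwork":
        rng = np.random.default_rng(seed)
        in_deg = min(in_degree_mn, n_mn)      # clamped for reduced test pools
        out_deg = min(out_degree_rc, n_rc)
        mn_to_rc = np.stack([rng.choice(n_mn, size=in_deg, replace=False)
                             for _ in range(n_rc)])
        rc_to_mn = np.stack([rng.choice(n_rc, size=out_deg, replace=False)
                             for _ in range(n_mn)])
        return cls(mn_to_rc, rc_to_mn)

    def csr(self, n_mn: int, n_rc: int):
        """Outgoing adjacency in CSR form for the kernel:
        per-MN list of driven RCs, per-RC list of inhibited MNs."""
        mn_out = [[] for _ in range(n_mn)]
        for rc, mns in enumerate(self.mn_to_rc):
            for m in mns:
                mn_out[int(m)].append(rc)
        rc_out = [[] for _ in range(n_rc)]
        for mn, rcs in enumerate(self.rc_to_mn):
            for r in rcs:
                rc_out[int(r)].append(mn)
        def _to_csr(lists):
            ptr = np.zeros(len(lists) + 1, dtype=np.int64)
            for i, l in enumerate(lists):
                ptr[i + 1] = ptr[i] + len(l)
            idx = np.concatenate([np.array(l, dtype=np.int64) for l in lists]) \
                if ptr[-1] else np.zeros(0, dtype=np.int64)
            return ptr, idx
        return _to_csr(mn_out), _to_csr(rc_out)


@dataclass
class PoolConfig:
    """Simulation scenario configuration for one pool run."""

    n_mn: int = 177
    duration: float = 30.0
    fs: float = 5000.0
    dt_ms: float = 0.2
    C: Optional[np.ndarray] = None       # per-MN constant drive, mS/cm^2
    seed: int = 0
    renshaw: bool = True
    params: Optional[dict] = None        # parameter overrides / full set
    record_voltages: bool = False
    scenario: str = "control"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if abs(self.dt_ms * self.fs - 1000.0) > 1e-6:
            raise ValueError("integration step and sampling rate inconsistent: "
                             f"dt={self.dt_ms} ms, fs={self.fs} Hz")
        if self.C is not None:
            self.C = np.asarray(self.C, dtype=float)
            if self.C.shape != (self.n_mn,):
                raise ValueError("C must have one entry per MN")
            if np.any(self.C < 0):
                raise ValueError("constant drives C_j must be >= 0")

    def resolved_params(self) -> dict:
        if self.params is None:
            return prm.default_params()
        if "motor_neuron" in self.params and "renshaw" in self.params:
            return prm.load_params(overrides=self.params)
        return prm.load_params(overrides=self.params)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class MNPoolState:
    """Instantaneous state of the MN pool (voltages in mV, Ca in uM)."""

    VS: np.ndarray
    VD: np.ndarray
    W: np.ndarray           # (8, n) gate values, rows m,h,n,m_N,h_N,m_L,m_P,h_P
    CaS: np.ndarray
    CaD: np.ndarray


@dataclass
class SimulationResult:
    mn_spikes: SpikeTrainSet
    rc_spikes: SpikeTrainSet
    force: Optional[np.ndarray]
    config: PoolConfig
    v_trace: Optional[np.ndarray] = None   # (n_steps, 2) V_S, V_D of MN 0

    def realized_rates(self) -> np.ndarray:
        return self.mn_spikes.rates()


class CalibrationError(RuntimeError):
    pass


def initial_state(n_mn: int, P: np.ndarray) -> MNPoolState:
    """Resting state: both compartments at the leak reversal, gates at their
    steady-state values for that voltage, calcium pools empty."""
    VL = P[prm.P_VL]
    VS = np.full(n_mn, VL)
    VD = np.full(n_mn, VL)
    W = np.zeros((8, n_mn))
    gate_par = [(prm.P_M_TH, prm.P_M_K), (prm.P_H_TH, prm.P_H_K),
                (prm.P_N_TH, prm.P_N_K), (prm.P_MN_TH, prm.P_MN_K),
                (prm.P_HN_TH, prm.P_HN_K), (prm.P_ML_TH, prm.P_ML_K),
                (prm.P_MP_TH, prm.P_MP_K), (prm.P_HP_TH, prm.P_HP_K)]
    for row, (th, kk) in enumerate(gate_par):
        W[row, :] = 1.0 / (1.0 + np.exp((VL - P[th]) / P[kk]))
    return MNPoolState(VS, VD, W, np.zeros(n_mn), np.zeros(n_mn))


def step_pool(state: MNPoolState, P: np.ndarray, g_exc: np.ndarray,
              g_inh: np.ndarray, dt_ms: float):
    """Advance the MN pool a single step; returns (state, spike_flags).

    ``g_exc`` / ``g_inh`` hold one dendritic conductance sample per MN.
    Raises on non-finite state, naming the offending MN.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    n = state.VS.shape[0]
    g_exc = np.asarray(g_exc, dtype=float)
    g_inh = np.asarray(g_inh, dtype=float)
    if g_exc.shape != (n,) or g_inh.shape != (n,):
        raise ValueError("need one input sample per MN")
    for name, arr in (("V_S", state.VS), ("V_D", state.VD)):
        bad = ~np.isfinite(arr)
        if np.any(bad):
            j = int(np.argmax(bad))
            raise FloatingPointError(f"non-finite {name} on MN {j}")
    oldVS = state.VS.copy()
    _mn_step(P, state.VS, state.VD, state.W, state.CaS, state.CaD,
             g_exc, g_inh, dt_ms)
    bad = ~np.isfinite(state.VS)
    if np.any(bad):
        j = int(np.argmax(bad))
        raise FloatingPointError(f"non-finite somatic voltage V_S on MN {j}")
    np.clip(state.W, 0.0, 1.0, out=state.W)
    flags = (oldVS < P[prm.P_THRESH]) & (state.VS >= P[prm.P_THRESH])
    return state, flags


def run_simulation(config: PoolConfig, common_input=None,
                   compute_force: bool = True) -> SimulationResult:
    """Run one pool simulation and return MN and RC spike trains plus force.

    ``common_input`` may be ``None``, a raw sample array of length
    ``config.n_steps``, or a :class:`~mnpool.inputs.CommonInputSignal`
    (whose sampling rate must match the pool's).
    """
    pars = config.resolved_params()
    P = prm.pack_mn_params(pars)
    R = prm.pack_rc_params(pars)
    n_steps = config.n_steps
    if common_input is None:
        common = np.zeros(n_steps)
    else:
        samples = getattr(common_input, "samples", common_input)
        rate = getattr(common_input, "fs", config.fs)
        if abs(rate - config.fs) > 1e-9:
            raise ValueError(f"common input rate {rate} != pool rate {config.fs}")
        samples = np.asarray(samples, dtype=float)
        if samples.shape != (n_steps,):
            raise ValueError(f"common input length {samples.shape} != {n_steps} steps")
        common = samples
    C = config.C if config.C is not None else np.zeros(config.n_mn)

    rc_cfg = pars["renshaw"]
    n_rc = int(rc_cfg["count"])
    if config.renshaw:
        net = RenshawNetwork.build(config.n_mn, n_rc,
                                   int(rc_cfg["in_degree_mn"]),
                                   int(rc_cfg["out_degree_rc"]),
                                   seed=config.seed + 777)
        (mn_ptr, mn_idx), (rc_ptr, rc_idx) = net.csr(config.n_mn, n_rc)
    else:
        mn_ptr = np.zeros(config.n_mn + 1, dtype=np.int64)
        mn_idx = np.zeros(0, dtype=np.int64)
        rc_ptr = np.zeros(n_rc + 1, dtype=np.int64)
        rc_idx = np.zeros(0, dtype=np.int64)

    st = initial_state(config.n_mn, P)
    VR = np.full(n_rc, R[prm.R_VL])
    WR = np.zeros((3, n_rc))
    for row, (th, kk) in enumerate([(prm.R_M_TH, prm.R_M_K),
                                    (prm.R_H_TH, prm.R_H_K),
                                    (prm.R_N_TH, prm.R_N_K)]):
        WR[row, :] = 1.0 / (1.0 + np.exp((R[prm.R_VL] - R[th]) / R[kk]))

    cap_mn = int(config.n_mn * (config.duration * 50 + 20))
    cap_rc = int(n_rc * (config.duration * 80 + 20))
    sp_u = np.zeros(cap_mn, dtype=np.int64)
    sp_t = np.zeros(cap_mn, dtype=np.int64)
    rsp_u = np.zeros(cap_rc, dtype=np.int64)
    rsp_t = np.zeros(cap_rc, dtype=np.int64)
    v_trace = np.zeros((n_steps if config.record_voltages else 1, 2))

    n_sp, n_rsp, err = _integrate(
        P, R, C, common, n_steps, config.dt_ms, config.renshaw,
        mn_ptr, mn_idx, rc_ptr, rc_idx, config.seed % (2 ** 31),
        st.VS, st.VD, st.W, st.CaS, st.CaD, VR, WR,
        config.record_voltages, v_trace, sp_u, sp_t, rsp_u, rsp_t)
    if err == -2:
        raise RuntimeError("spike buffer overflow: firing rates far above the "
                           "calibrated regime")
    if err >= 0:
        raise FloatingPointError(f"non-finite somatic voltage V_S on MN {err}")

    dt_s = config.dt_ms / 1000.0
    def _collect(units, steps, count, n_units):
        trains = [[] for _ in range(n_units)]
        for i in range(count):
            trains[units[i]].append(steps[i] * dt_s)
        return [np.array(t) for t in trains]

    mn_sts = SpikeTrainSet(_collect(sp_u, sp_t, n_sp, config.n_mn),
                           config.duration, config.fs, "simulated")
    rc_sts = SpikeTrainSet(_collect(rsp_u, rsp_t, n_rsp, n_rc),
                           config.duration, config.fs, "simulated")
    force = None
    if compute_force:
        from .force import TwitchParams, spikes_to_force
        tw = TwitchParams.default(config.n_mn, pars)
        force = spikes_to_force(mn_sts, tw, config.fs)
    return SimulationResult(mn_sts, rc_sts, force, config,
                            v_trace if config.record_voltages else None)


# ---------------------------------------------------------------------------
# constant-drive calibration

def default_rate_targets(n_mn: int = 177, mean: float = 10.4, sd: float = 1.4,
                         lo: float = 7.3, hi: float = 13.4) -> np.ndarray:
    """Deterministic per-MN target discharge rates: truncated-normal quantiles
    rescaled so the extremes sit exactly at ``lo`` and ``hi`` and the mean at
    ``mean`` — the stated spread of the calibrated pool."""
    from scipy.optimize import brentq
    from scipy.stats import truncnorm
    a, b = (lo - mean) / sd, (hi - mean) / sd
    q = truncnorm.ppf(np.linspace(0.002, 0.998, n_mn), a, b, loc=mean, scale=sd)
    q = lo + (q - q.min()) * (hi - lo) / (q.max() - q.min())
    u = (q - lo) / (hi - lo)
    # warp the interior (extremes fixed) so the sample mean lands on `mean`
    def _mean_err(gamma):
        return lo + (hi - lo) * np.mean(u ** gamma) - mean
    if _mean_err(1.0) != 0.0:
        gamma = brentq(_mean_err, 0.5, 2.0)
        q = lo + (hi - lo) * u ** gamma
    return q


def _probe_fi(config: PoolConfig, grid: np.ndarray, duration: float,
              seed: int) -> np.ndarray:
    """Realized rate for each drive value in ``grid`` (no recurrent
    inhibition; one probe MN per grid value)."""
    probe = PoolConfig(n_mn=grid.size, duration=duration, fs=config.fs,
                       dt_ms=config.dt_ms, C=grid, seed=seed, renshaw=False,
                       params=config.params)
    res = run_simulation(probe, compute_force=False)
    return res.mn_spikes.rates()


def calibrate_constant_drive(targets: np.ndarray, config: PoolConfig,
                             tol: float = 0.3, max_iter: int = 8,
                             cal_duration: float = 12.0,
                             c_max: float = 3.0):
    """Find per-MN constant drives ``C_j`` whose realized mean rates match
    ``targets`` within ``tol`` Hz (on calibration runs of ``cal_duration`` s).

    A probe run maps the drive-rate curve without recurrent inhibition; the
    inverse map seeds damped secant iterations on full-network runs.  Raises
    :class:`CalibrationError` naming saturated MNs when a target cannot be
    reached below ``c_max``.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any(targets < 0):
        raise ValueError("target rates must be >= 0")
    grid = np.linspace(0.02, c_max, 40)
    fi = _probe_fi(config, grid, max(8.0, cal_duration * 0.75), config.seed + 11)
    # enforce a usable monotone envelope for inversion
    fi_mono = np.maximum.accumulate(fi)
    pos_targets = targets[targets > 0]
    if pos_targets.size and pos_targets.max() > fi_mono[-1] + tol:
        bad = np.where(targets > fi_mono[-1] + tol)[0]
        raise CalibrationError(
            f"targets unattainable below C={c_max} mS/cm^2 for MNs {bad.tolist()}"
        )
    C = np.interp(targets, fi_mono, grid)
    C[targets <= 0] = 0.0
    slope = np.gradient(fi_mono, grid)
    slope = np.clip(slope, 2.0, None)  # Hz per (mS/cm^2), damped update floor
    local_slope = np.interp(C, grid, slope)

    work = PoolConfig(n_mn=config.n_mn, duration=cal_duration, fs=config.fs,
                      dt_ms=config.dt_ms, C=C, seed=config.seed,
                      renshaw=config.renshaw, params=config.params)
    realized = targets.copy()
    for it in range(max_iter):
        work.C = C
        work.seed = config.seed + 100 + it
        res = run_simulation(work, compute_force=False)
        realized = res.mn_spikes.rates()
        err = targets - realized
        if np.max(np.abs(err)) <= tol:
            break
        C = np.clip(C + 0.8 * err / local_slope, 0.0, c_max)
        C[targets <= 0] = 0.0
    report = {
        "targets": targets, "realized": realized, "iterations": it + 1,
        "max_abs_error": float(np.max(np.abs(targets - realized))),
        "converged": bool(np.max(np.abs(targets - realized)) <= tol),
    }
    return C, report
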