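"""Parameter file handling for the motor-neuron pool model.

The default parameter set ships with the package as a YAML file
(``mnpool/data/default_params.yaml``).  :func:`load_params` returns it as a
nested dictionary; any value can be overridden by passing a (possibly
partial) nested dictionary of the same shape.  The integration kernels take
flat ``float64`` vectors, produced by :func:`pack_mn_params` and
:func:`pack_rc_params`; the index constants below define the layout.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "load_params",
    "default_params",
    "pack_mn_params",
    "pack_rc_params",
    "params_hash",
]


def default_params() -> dict:
    """Return the package default parameter set as a nested dict."""
    ref = importlib.resources.files("mnpool.data").joinpath("default_params.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, override: Mapping[str, Any]) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_params(path: str | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Load a parameter set: package defaults, an optional YAML file on top,
    and an optional override dict on top of that."""
    params = default_params()
    if path is not None:
        with open(path) as fh:
            params = _deep_merge(params, yaml.safe_load(fh))
    if overrides:
        params = _deep_merge(params, overrides)
    _validate(params)
    return params


def _validate(params: dict) -> None:
    mn = params["motor_neuron"]
    p = mn["membrane"]["p"]
    if not 0.0 < p < 1.0:
        raise ValueError(f"soma area ratio p must lie in (0, 1), got {p}")
    for section in ("soma", "dendrite"):
        for name, g in mn[section].items():
            if g < 0:
                raise ValueError(f"conductance {section}.{name} must be >= 0, got {g}")
    if mn["membrane"]["g_L"] < 0 or mn["membrane"]["g_c"] < 0:
        raise ValueError("leak and coupling conductances must be >= 0")
    for gate, spec in mn["gates"].items():
        if spec["k"] == 0:
            raise ValueError(f"gate {gate}: sensitivity k must be non-zero")
        if "tau" in spec and spec["tau"] < 0:
            raise ValueError(f"gate {gate}: tau must be >= 0")


def params_hash(params: dict) -> str:
    """Stable short hash of a parameter set, for provenance records."""
    blob = yaml.safe_dump(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Packed layout for the numba kernels

# Motor neuron vector
P_CM, P_P, P_GC, P_GL, P_VL = 0, 1, 2, 3, 4
P_VNA, P_VK, P_VCA, P_VEXC, P_VINH = 5, 6, 7, 8, 9
P_GNA, P_GKDR, P_GCANS, P_GKCAS, P_GNAP = 10, 11, 12, 13, 14
P_GCAND, P_GCAL, P_GKCAD = 15, 16, 17
P_CAF, P_CAALPHA, P_CAK, P_KD = 18, 19, 20, 21
P_M_TH, P_M_K, P_M_TAU = 22, 23, 24
P_H_TH, P_H_K, P_H_TS, P_H_TT, P_H_K1, P_H_K2 = 25, 26, 27, 28, 29, 30
P_N_TH, P_N_K, P_N_TS, P_N_TT, P_N_K1, P_N_K2 = 31, 32, 33, 34, 35, 36
P_MN_TH, P_MN_K, P_MN_TAU = 37, 38, 39
P_HN_TH, P_HN_K, P_HN_TAU = 40, 41, 42
P_ML_TH, P_ML_K, P_ML_TAU = 43, 44, 45
P_MP_TH, P_MP_K, P_MP_TAU = 46, 47, 48
P_HP_TH, P_HP_K, P_HP_TAU = 49, 50, 51
P_THRESH, P_LOCKOUT, P_NOISE = 52, 53, 54
MN_NPAR = 55

# Renshaw cell vector
R_CM, R_GNA, R_GK, R_GL, R_VL, R_VNA, R_VK = 0, 1, 2, 3, 4, 5, 6
R_M_TH, R_M_K, R_M_TAU = 7, 8, 9
R_H_TH, R_H_K, R_H_TS, R_H_TT, R_H_K1, R_H_K2 = 10, 11, 12, 13, 14, 15
R_N_TH, R_N_K, R_N_TS, R_N_TT, R_N_K1, R_N_K2 = 16, 17, 18, 19, 20, 21
R_AHP_STEP, R_AHP_TAU = 22, 23
R_W_MNRC, R_TAU_MNRC, R_VSYN = 24, 25, 26
R_W_RCMN, R_TAU_RCMN = 27, 28
R_THRESH, R_LOCKOUT = 29, 30
RC_NPAR = 31


def pack_mn_params(params: dict) -> np.ndarray:
    mn = params["motor_neuron"]
    mem, rev = mn["membrane"], mn["reversal"]
    soma, dend, ca, g = mn["soma"], mn["dendrite"], mn["calcium"], mn["gates"]
    v = np.zeros(MN_NPAR)
    v[P_CM], v[P_P], v[P_GC], v[P_GL], v[P_VL] = (
        mem["C_m"], mem["p"], mem["g_c"], mem["g_L"], mem["V_L"])
    v[P_VNA], v[P_VK], v[P_VCA] = rev["V_Na"], rev["V_K"], rev["V_Ca"]
    v[P_VEXC], v[P_VINH] = rev["V_excit"], rev["V_inhib"]
    v[P_GNA], v[P_GKDR], v[P_GCANS] = soma["g_Na"], soma["g_K_dr"], soma["g_Ca_N"]
    v[P_GKCAS], v[P_GNAP] = soma["g_K_Ca"], soma["g_NaP"]
    v[P_GCAND], v[P_GCAL], v[P_GKCAD] = dend["g_Ca_N"], dend["g_Ca_L"], dend["g_K_Ca"]
    v[P_CAF], v[P_CAALPHA], v[P_CAK], v[P_KD] = (
        ca["f"], ca["alpha"], ca["k_ca"], ca["K_d"])
    v[P_M_TH], v[P_M_K], v[P_M_TAU] = g["m"]["theta"], g["m"]["k"], g["m"]["tau"]
    for pre, name in ((P_H_TH, "h"), (P_N_TH, "n")):
        s = g[name]
        v[pre], v[pre + 1] = s["theta"], s["k"]
        v[pre + 2], v[pre + 3] = s["tau_scale"], s["tau_theta"]
        v[pre + 4], v[pre + 5] = s["tau_k1"], s["tau_k2"]
    for pre, name in ((P_MN_TH, "m_N"), (P_HN_TH, "h_N"), (P_ML_TH, "m_L"),
                      (P_MP_TH, "m_P"), (P_HP_TH, "h_P")):
        s = g[name]
        v[pre], v[pre + 1], v[pre + 2] = s["theta"], s["k"], s["tau"]
    sd = mn["spike_detection"]
    v[P_THRESH], v[P_LOCKOUT] = sd["threshold"], sd["lockout_ms"]
    v[P_NOISE] = mn["drive"]["noise_scale"]
    return v


def pack_rc_params(params: dict) -> np.ndarray:
    rc = params["renshaw"]
    mem, g = rc["membrane"], rc["gates"]
    v = np.zeros(RC_NPAR)
    v[R_CM], v[R_GNA], v[R_GK], v[R_GL] = (
        mem["C_m"], mem["g_Na"], mem["g_K"], mem["g_L"])
    v[R_VL], v[R_VNA], v[R_VK] = mem["V_L"], mem["V_Na"], mem["V_K"]
    v[R_M_TH], v[R_M_K], v[R_M_TAU] = g["m"]["theta"], g["m"]["k"], g["m"]["tau"]
    for pre, name in ((R_H_TH, "h"), (R_N_TH, "n")):
        s = g[name]
        v[pre], v[pre + 1] = s["theta"], s["k"]
        v[pre + 2], v[pre + 3] = s["tau_scale"], s["tau_theta"]
        v[pre + 4], v[pre + 5] = s["tau_k1"], s["tau_k2"]
    v[R_AHP_STEP], v[R_AHP_TAU] = rc["adaptation"]["g_step"], rc["adaptation"]["tau"]
    syn = rc["synapse"]
    v[R_W_MNRC], v[R_TAU_MNRC], v[R_VSYN] = (
        syn["w_mn_rc"], syn["tau_mn_rc"], syn["V_syn_rc"])
    v[R_W_RCMN], v[R_TAU_RCMN] = syn["w_rc_mn"], syn["tau_rc_mn"]
    sd = rc["spike_detection"]
    v[R_THRESH], v[R_LOCKOUT] = sd["threshold"], sd["lockout_ms"]
    return v
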