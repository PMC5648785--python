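"""Right-hand side of the four-population thalamocortical mean-field model.

Each population i in {PY, IN, TC, RE} obeys a conductance-based membrane
balance

    C_m dV_i/dt = - sum_syn g_syn (V_i - V_syn) - g_leak (V_i - V_leak),

where each synaptic conductance is the convolution of a bi-exponential
kernel h(t) = A [exp(-a1 t) - exp(-a2 t)] with the presynaptic firing
density.  Tonic firing is a sigmoid of membrane potential; the slow
GABA_B current carries an extra sigmoidal recruitment factor B(F) of the
presynaptic rate; thalamic populations add a low-threshold burst mode
F_B = G_B m_inf(V) [h_n * n_inf(V)](t) with a unit-area kernel h_n.

Every convolution is realised exactly as a second-order linear filter
(two first-order state equations), so apart from the explicit
cortico-thalamic transport delays the model is a finite-dimensional
deterministic dynamical system.  The model output is V_PY, the cortical
(pyramidal) mean membrane potential.

State vector layout (dim 26):
    y[0:4]    V_PY, V_IN, V_TC, V_RE                    (mV)
    y[4:22]   (g, dg/dt) for the 9 conductance filters in
              ``params.FILTER_SLOTS`` order
    y[22:26]  (p, dp/dt) burst kernels of TC then RE
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    FILTER_SLOTS,
    POPULATIONS,
    BurstParams,
    GababActivationParams,
    ModelParameters,
    PopulationParams,
    SynapseParams,
)
from .stimuli import StimulusSet
from .systems import ContinuousSystem

try:  # numba accelerates the RHS ~100x; the pure-Python path is identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = [
    "STATE_DIM",
    "InvalidStateError",
    "firing_rate",
    "gabab_activation",
    "synaptic_kernel",
    "kernel_as_filter",
    "kernel_filter_system",
    "gabab_current",
    "burst_kernel",
    "burst_firing_rate",
    "membrane_rhs",
    "full_rhs",
    "build_system",
    "equilibrium_state",
    "settled_equilibrium",
    "depolarized_state",
    "rebound_kick_state",
    "state_labels",
]

STATE_DIM = 4 + 2 * len(FILTER_SLOTS) + 4
_N_SLOTS = len(FILTER_SLOTS)
_POP_INDEX = {p: i for i, p in enumerate(POPULATIONS)}
_SLOT_INDEX = {slot: i for i, slot in enumerate(FILTER_SLOTS)}
# external-drive source codes used in the flattened coupling table
_SRC_CODE = {**_POP_INDEX, "sensory": 4, "cortical": 5, "reticular": 6}


class InvalidStateError(ValueError):
    """Non-finite membrane potential or firing rate."""


# ---------------------------------------------------------------------------
# elementary operations (reference implementations used directly by tests;
# the compiled RHS below inlines the same formulas)
# ---------------------------------------------------------------------------


def firing_rate(V: float, pop: PopulationParams) -> float:
    """Tonic firing density G_F / (1 + exp(nu_F (V - theta_F))) in pps."""
    if not np.isfinite(V):
        raise InvalidStateError(f"non-finite membrane potential V={V!r}")
    return float(pop.G_F / (1.0 + np.exp(pop.nu_F * (V - pop.theta_F))))


def gabab_activation(F: float, act: GababActivationParams) -> float:
    """GABA_B recruitment B(F) = 1 / (1 + exp(nu_B (F - theta_B)))."""
    if not np.isfinite(F):
        raise InvalidStateError(f"non-finite firing rate F={F!r}")
    return float(1.0 / (1.0 + np.exp(act.nu_B * (F - act.theta_B))))


def synaptic_kernel(t, syn: SynapseParams):
    """Bi-exponential conductance kernel h(t) = A [e^{-a1 t} - e^{-a2 t}].

    Zero at t = 0, positive for t > 0, single interior maximum at
    ln(a2/a1)/(a2 - a1).
    """
    t = np.asarray(t, dtype=float)
    out = syn.A * (np.exp(-syn.a1 * t) - np.exp(-syn.a2 * t))
    return out if out.shape else float(out)


@dataclass(frozen=True)
class FilterCoeffs:
    """Second-order realisation g'' + damping g' + spring g = drive * u of a
    bi-exponential kernel: damping = a1+a2, spring = a1*a2,
    drive = A (a2 - a1).  Driving the filter with a signal u(t) reproduces
    the convolution of the kernel with u exactly."""

    damping: float
    spring: float
    drive: float


def kernel_as_filter(syn: SynapseParams) -> FilterCoeffs:
    return FilterCoeffs(
        damping=syn.a1 + syn.a2,
        spring=syn.a1 * syn.a2,
        drive=syn.A * (syn.a2 - syn.a1),
    )


def kernel_filter_system(syn: SynapseParams, drive) -> ContinuousSystem:
    """The filter realisation of a kernel as an integrable 2-state system
    driven by the callable ``drive(t)`` (used to verify filter-convolution
    equivalence)."""
    c = kernel_as_filter(syn)

    def f(t, y):
        return np.array(
            [y[1], -c.damping * y[1] - c.spring * y[0] + c.drive * drive(t)]
        )

    return ContinuousSystem(name=f"filter[{syn.syn_type}]", dim=2, f=f)


def gabab_current(
    g: float,
    F_pre: float,
    V: float,
    syn: SynapseParams,
    act: GababActivationParams,
) -> float:
    """Slow inhibitory current I = g B(F_pre) (V - V_rev)."""
    return g * gabab_activation(F_pre, act) * (V - syn.V_rev)


def burst_kernel(t, bp: BurstParams):
    """Unit-area burst delay kernel h_n(t) = N [e^{-n1 t} - e^{-n2 t}] with
    N = n1 n2 / (n2 - n1)."""
    t = np.asarray(t, dtype=float)
    N = bp.n1 * bp.n2 / (bp.n2 - bp.n1)
    out = N * (np.exp(-bp.n1 * t) - np.exp(-bp.n2 * t))
    return out if out.shape else float(out)


def _m_inf(V: float, bp: BurstParams) -> float:
    return float(1.0 / (1.0 + np.exp(bp.nu_m * (V - bp.theta_m))))


def _n_inf(V: float, bp: BurstParams) -> float:
    return float(1.0 / (1.0 + np.exp(bp.nu_n * (V - bp.theta_n))))


def burst_firing_rate(V: float, filtered_n: float, bp: BurstParams) -> float:
    """Burst firing density F_B = G_B m_inf(V) * filtered_n, where
    ``filtered_n`` is the h_n-filtered value of n_inf(V(t))."""
    if not np.isfinite(V):
        raise InvalidStateError(f"non-finite membrane potential V={V!r}")
    return bp.G_B * _m_inf(V, bp) * filtered_n


def membrane_rhs(V: float, total_current: float, pop: PopulationParams) -> float:
    """dV/dt = (-I_total - g_leak (V - V_leak)) / C_m in mV/s."""
    return (-total_current - pop.g_leak * (V - pop.V_leak)) / pop.C_m


# ---------------------------------------------------------------------------
# flattening to arrays for the compiled full RHS
# ---------------------------------------------------------------------------

# parameter-vector layout offsets
_O_C, _O_GL, _O_VL, _O_GF, _O_THF, _O_NUF = 0, 4, 8, 12, 16, 20
_O_A, _O_A1, _O_A2, _O_VR = 24, 24 + _N_SLOTS, 24 + 2 * _N_SLOTS, 24 + 3 * _N_SLOTS
_O_BTH, _O_BNU, _O_BSRC = (24 + 4 * _N_SLOTS, 24 + 5 * _N_SLOTS, 24 + 6 * _N_SLOTS)
_O_GB, _O_N1, _O_N2 = 24 + 7 * _N_SLOTS, 28 + 7 * _N_SLOTS, 32 + 7 * _N_SLOTS
_O_THM, _O_NUM, _O_THN, _O_NUN, _O_BON = (
    36 + 7 * _N_SLOTS,
    40 + 7 * _N_SLOTS,
    44 + 7 * _N_SLOTS,
    48 + 7 * _N_SLOTS,
    52 + 7 * _N_SLOTS,
)
_P_LEN = 56 + 7 * _N_SLOTS


def _flatten_params(params: ModelParameters):
    P = np.zeros(_P_LEN)
    for i, name in enumerate(POPULATIONS):
        pp = params.populations[name]
        P[_O_C + i], P[_O_GL + i], P[_O_VL + i] = pp.C_m, pp.g_leak, pp.V_leak
        P[_O_GF + i], P[_O_THF + i], P[_O_NUF + i] = pp.G_F, pp.theta_F, pp.nu_F
    P[_O_BSRC : _O_BSRC + _N_SLOTS] = -1.0
    for j, (target, syn_type) in enumerate(FILTER_SLOTS):
        key = f"{target}.{syn_type}"
        if key not in params.synapses:
            continue  # unwired slot: zero kernel
        syn = params.synapses[key]
        P[_O_A + j], P[_O_A1 + j], P[_O_A2 + j] = syn.A, syn.a1, syn.a2
        P[_O_VR + j] = syn.V_rev
        if syn_type == "GABA_B" and target in params.gabab_activation:
            act = params.gabab_activation[target]
            P[_O_BTH + j], P[_O_BNU + j] = act.theta_B, act.nu_B
            # presynaptic population whose rate drives B: source of the
            # coupling wired into this slot
            for c in params.couplings.values():
                if (c.target, c.syn_type) == (target, syn_type):
                    P[_O_BSRC + j] = float(_SRC_CODE[c.source])
    for name in ("TC", "RE"):
        i = _POP_INDEX[name]
        if name in params.burst:
            bp = params.burst[name]
            P[_O_GB + i], P[_O_N1 + i], P[_O_N2 + i] = bp.G_B, bp.n1, bp.n2
            P[_O_THM + i], P[_O_NUM + i] = bp.theta_m, bp.nu_m
            P[_O_THN + i], P[_O_NUN + i] = bp.theta_n, bp.nu_n
            P[_O_BON + i] = 1.0
    c_slot, c_src, c_val, c_del = [], [], [], []
    for c in params.couplings.values():
        c_slot.append(_SLOT_INDEX[(c.target, c.syn_type)])
        c_src.append(_SRC_CODE[c.source])
        c_val.append(c.value)
        c_del.append(1 if c.delayed else 0)
    return (
        P,
        np.array(c_slot, dtype=np.int64),
        np.array(c_src, dtype=np.int64),
        np.array(c_val, dtype=float),
        np.array(c_del, dtype=np.int64),
    )


def _stim_arrays(stimuli: StimulusSet, channel: str):
    spec = stimuli.sensory if channel == "sensory" else stimuli.cortical
    if stimuli.schedule_channel == channel:
        t0, f, p0 = stimuli.schedule.arrays()
    else:
        t0 = np.array([0.0])
        f = np.array([spec.frequency])
        p0 = np.array([0.0])
    return spec.bias, spec.amplitude, t0, f, p0


@njit(cache=True)
def _drive_at(t, bias, amp, t0, f, p0):
    i = 0
    for k in range(t0.shape[0]):
        if t >= t0[k]:
            i = k
    phase = p0[i] + f[i] * (t - t0[i])
    return bias + amp * math.sin(2.0 * math.pi * phase)


@njit(cache=True)
def _total_rate(y, pop, P):
    """Tonic + burst firing density of population ``pop`` from state ``y``."""
    V = y[pop]
    F = P[_O_GF + pop] / (1.0 + math.exp(P[_O_NUF + pop] * (V - P[_O_THF + pop])))
    if P[_O_BON + pop] > 0.5:
        m = 1.0 / (1.0 + math.exp(P[_O_NUM + pop] * (V - P[_O_THM + pop])))
        p_idx = 22 if pop == 2 else 24
        F += P[_O_GB + pop] * m * y[p_idx]
    return F


@njit(cache=True)
def _tc_rhs_core(
    t, y, y_c2t, y_t2c,
    P, c_slot, c_src, c_val, c_del,
    s_bias, s_amp, s_t0, s_f, s_p0,
    u_bias, u_amp, u_t0, u_f, u_p0,
    phi_re,
):
    dy = np.zeros(y.shape[0])
    # firing densities (current and delayed where a pathway is delayed)
    F_now = np.empty(4)
    for p in range(4):
        F_now[p] = _total_rate(y, p, P)
    F_py_del = _total_rate(y_c2t, 0, P)  # PY rate seen by the thalamus
    F_tc_del = _total_rate(y_t2c, 2, P)  # TC rate seen by the cortex
    u_sens = _drive_at(t, s_bias, s_amp, s_t0, s_f, s_p0)
    u_cort = _drive_at(t, u_bias, u_amp, u_t0, u_f, u_p0)

    # filter drive inputs: weighted presynaptic firing densities
    u_slot = np.zeros(_N_SLOTS)
    for k in range(c_slot.shape[0]):
        src = c_src[k]
        if src == 4:
            sig = u_sens
        elif src == 5:
            sig = u_cort
        elif src == 6:
            sig = phi_re
        elif c_del[k] == 1 and src == 0:
            sig = F_py_del
        elif c_del[k] == 1 and src == 2:
            sig = F_tc_del
        else:
            sig = F_now[src]
        u_slot[c_slot[k]] += c_val[k] * sig

    # synaptic currents summed per target population
    I_tot = np.zeros(4)
    for j in range(_N_SLOTS):
        g = y[4 + 2 * j]
        tgt = _SLOT_POP[j]
        I = g * (y[tgt] - P[_O_VR + j])
        bsrc = P[_O_BSRC + j]
        if bsrc >= 0.0:
            F_pre = F_now[int(bsrc)]
            I *= 1.0 / (1.0 + math.exp(P[_O_BNU + j] * (F_pre - P[_O_BTH + j])))
        I_tot[tgt] += I

    for p in range(4):
        dy[p] = (-I_tot[p] - P[_O_GL + p] * (y[p] - P[_O_VL + p])) / P[_O_C + p]

    # conductance filters: g'' + (a1+a2) g' + a1 a2 g = A (a2-a1) u
    for j in range(_N_SLOTS):
        g = y[4 + 2 * j]
        h = y[5 + 2 * j]
        dy[4 + 2 * j] = h
        dy[5 + 2 * j] = (
            -(P[_O_A1 + j] + P[_O_A2 + j]) * h
            - P[_O_A1 + j] * P[_O_A2 + j] * g
            + P[_O_A + j] * (P[_O_A2 + j] - P[_O_A1 + j]) * u_slot[j]
        )

    # burst kernels (unit-area): p'' + (n1+n2) p' + n1 n2 p = n1 n2 n_inf(V)
    for idx, pop in ((22, 2), (24, 3)):
        if P[_O_BON + pop] > 0.5:
            n_inf = 1.0 / (
                1.0 + math.exp(P[_O_NUN + pop] * (y[pop] - P[_O_THN + pop]))
            )
            q = y[idx + 1]
            dy[idx] = q
            dy[idx + 1] = (
                -(P[_O_N1 + pop] + P[_O_N2 + pop]) * q
                - P[_O_N1 + pop] * P[_O_N2 + pop] * y[idx]
                + P[_O_N1 + pop] * P[_O_N2 + pop] * n_inf
            )
    return dy


_SLOT_POP = np.array([_POP_INDEX[t] for t, _ in FILTER_SLOTS], dtype=np.int64)


@njit(cache=True)
def _tc_rhs_ode(t, y, P, c_slot, c_src, c_val, c_del,
                s_bias, s_amp, s_t0, s_f, s_p0,
                u_bias, u_amp, u_t0, u_f, u_p0, phi_re):
    return _tc_rhs_core(
        t, y, y, y, P, c_slot, c_src, c_val, c_del,
        s_bias, s_amp, s_t0, s_f, s_p0,
        u_bias, u_amp, u_t0, u_f, u_p0, phi_re,
    )


@njit(cache=True)
def _tc_rhs_dde(t, y, ydel, P, c_slot, c_src, c_val, c_del,
                s_bias, s_amp, s_t0, s_f, s_p0,
                u_bias, u_amp, u_t0, u_f, u_p0, phi_re):
    return _tc_rhs_core(
        t, y, ydel[0], ydel[1], P, c_slot, c_src, c_val, c_del,
        s_bias, s_amp, s_t0, s_f, s_p0,
        u_bias, u_amp, u_t0, u_f, u_p0, phi_re,
    )


def build_system(params: ModelParameters, stimuli: StimulusSet) -> ContinuousSystem:
    """Assemble the full thalamocortical model as an integrable system.

    Output observable is V_PY (state index 0).  Stimulus-schedule switch
    times are registered as integrator breakpoints.  With zero delays the
    system is a plain ODE; with positive delays it carries two delayed
    pathways (cortex-to-thalamus acting on the PY firing density seen by
    TC/RE, thalamus-to-cortex acting on the TC density seen by PY/IN).
    """
    P, c_slot, c_src, c_val, c_del = _flatten_params(params)
    s_bias, s_amp, s_t0, s_f, s_p0 = _stim_arrays(stimuli, "sensory")
    u_bias, u_amp, u_t0, u_f, u_p0 = _stim_arrays(stimuli, "cortical")
    args = (
        P, c_slot, c_src, c_val, c_del,
        s_bias, s_amp, s_t0, s_f, s_p0,
        u_bias, u_amp, u_t0, u_f, u_p0,
        float(stimuli.reticular_bias),
    )
    d_c2t = params.network.delay_cortex_to_thalamus
    d_t2c = params.network.delay_thalamus_to_cortex
    if d_c2t > 0 or d_t2c > 0:
        return ContinuousSystem(
            name="thalamocortical",
            dim=STATE_DIM,
            f_delayed=_tc_rhs_dde,
            args=args,
            delays=(d_c2t, d_t2c),
            output_index=0,
            breakpoints=stimuli.switch_times,
            meta={"params_digest": params.digest()},
        )
    return ContinuousSystem(
        name="thalamocortical",
        dim=STATE_DIM,
        f=_tc_rhs_ode,
        args=args,
        delays=(0.0, 0.0),
        f_delayed=_tc_rhs_dde,
        output_index=0,
        breakpoints=stimuli.switch_times,
        meta={"params_digest": params.digest()},
    )


def full_rhs(t, state, params: ModelParameters, stimuli: StimulusSet):
    """Instantaneous state derivative (delayed terms read from ``state``
    itself, i.e. the zero-delay evaluation).  Pure: does not mutate its
    inputs."""
    state = np.asarray(state, dtype=float)
    if state.shape != (STATE_DIM,):
        raise InvalidStateError(
            f"state has shape {state.shape}, expected ({STATE_DIM},)"
        )
    system = build_system(params, stimuli)
    return system.rhs(float(t), state)


def equilibrium_state(params: ModelParameters) -> np.ndarray:
    """Decoupled leak-equilibrium state: V at leak reversal, conductance
    filters at rest, burst kernels settled at n_inf(V_leak)."""
    y = np.zeros(STATE_DIM)
    for i, name in enumerate(POPULATIONS):
        y[i] = params.populations[name].V_leak
    for idx, name in ((22, "TC"), (24, "RE")):
        if name in params.burst:
            y[idx] = _n_inf(params.populations[name].V_leak, params.burst[name])
    return y


def settled_equilibrium(
    params: ModelParameters,
    stimuli: StimulusSet,
    guesses: tuple[tuple[float, float, float, float], ...] = (
        (-64.0, -64.0, -50.0, -70.0),
        (-60.0, -60.0, -60.0, -75.0),
        (-70.0, -70.0, -70.0, -80.0),
    ),
) -> np.ndarray:
    """Fixed point of the model under the *constant* components of the
    stimuli (sinusoidal amplitudes ignored).

    At an equilibrium every conductance filter sits at its DC gain times
    its drive and every burst kernel at n_inf(V), so the root problem
    reduces to the four membrane potentials.  Raises ``InvalidStateError``
    if no root is found from any of the initial guesses.  This is the
    canonical quiet-branch initial condition for scans and sweeps: the
    raw leak state (:func:`equilibrium_state`) transiently charges the
    synaptic filters, which can knock a bistable operating point onto the
    oscillatory attractor.
    """
    from scipy.optimize import root

    drives = {
        "sensory": stimuli.sensory.bias,
        "cortical": stimuli.cortical.bias,
        "reticular": stimuli.reticular_bias,
    }

    def total_rates(V: np.ndarray) -> dict[str, float]:
        F = {}
        for i, name in enumerate(POPULATIONS):
            F[name] = firing_rate(V[i], params.populations[name])
            if name in params.burst:
                bp = params.burst[name]
                F[name] += bp.G_B * _m_inf(V[i], bp) * _n_inf(V[i], bp)
        return F

    def slot_drives(F: dict[str, float]) -> dict[tuple[str, str], float]:
        u = {slot: 0.0 for slot in FILTER_SLOTS}
        for c in params.couplings.values():
            sig = drives[c.source] if c.source in drives else F[c.source]
            u[(c.target, c.syn_type)] += c.value * sig
        return u

    def residual(V: np.ndarray) -> np.ndarray:
        F = total_rates(V)
        u = slot_drives(F)
        I = dict.fromkeys(POPULATIONS, 0.0)
        for (tgt, syn_t), uv in u.items():
            key = f"{tgt}.{syn_t}"
            if key not in params.synapses:
                continue
            syn = params.synapses[key]
            g = syn.A * (1 / syn.a1 - 1 / syn.a2) * uv
            cur = g * (V[_POP_INDEX[tgt]] - syn.V_rev)
            if syn_t == "GABA_B" and tgt in params.gabab_activation:
                src = next(
                    c.source
                    for c in params.couplings.values()
                    if (c.target, c.syn_type) == (tgt, syn_t)
                )
                F_pre = drives[src] if src in drives else F[src]
                cur *= gabab_activation(F_pre, params.gabab_activation[tgt])
            I[tgt] += cur
        out = np.empty(4)
        for i, name in enumerate(POPULATIONS):
            pp = params.populations[name]
            out[i] = -I[name] - pp.g_leak * (V[i] - pp.V_leak)
        return out

    V_star = None
    for guess in guesses:
        sol = root(residual, np.array(guess, dtype=float), method="hybr")
        if sol.success:
            V_star = sol.x
            break
    if V_star is None:
        raise InvalidStateError(
            "no equilibrium found for the given constant inputs"
        )
    F = total_rates(V_star)
    u = slot_drives(F)
    y = np.zeros(STATE_DIM)
    y[:4] = V_star
    for j, (tgt, syn_t) in enumerate(FILTER_SLOTS):
        key = f"{tgt}.{syn_t}"
        if key in params.synapses:
            syn = params.synapses[key]
            y[4 + 2 * j] = syn.A * (1 / syn.a1 - 1 / syn.a2) * u[(tgt, syn_t)]
    for idx, name in ((22, "TC"), (24, "RE")):
        if name in params.burst:
            y[idx] = _n_inf(V_star[_POP_INDEX[name]], params.burst[name])
    return y


def depolarized_state(params: ModelParameters, shift: float = 20.0) -> np.ndarray:
    """Leak equilibrium with all membrane potentials shifted up by
    ``shift`` mV; used as a bistability-probe initial condition."""
    y = equilibrium_state(params)
    y[:4] += shift
    return y


def rebound_kick_state(params: ModelParameters) -> np.ndarray:
    """Leak equilibrium with both thalamic populations hyperpolarised and
    their burst-availability gates fully loaded -- the release-from-
    inhibition condition that triggers a paroxysmal rebound volley.  The
    most effective probe for the oscillatory basin of a bistable
    operating point."""
    y = equilibrium_state(params)
    y[2] -= 20.0  # V_TC
    y[3] -= 5.0   # V_RE
    if "TC" in params.burst:
        y[22] = 1.0
    if "RE" in params.burst:
        y[24] = 1.0
    return y


def state_labels() -> list[str]:
    labels = [f"V_{p}" for p in POPULATIONS]
    for target, syn in FILTER_SLOTS:
        labels += [f"g_{target}.{syn}", f"dg_{target}.{syn}"]
    labels += ["p_TC", "dp_TC", "p_RE", "dp_RE"]
    return labels
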