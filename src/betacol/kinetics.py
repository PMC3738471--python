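"""Voltage-gated channel kinetics for the reduced laminar-cortex cell models.

Each cell class uses one of three kinetic *families* for its spike-generating
currents:

``exc``
    Reduced-Traub kinetics for excitatory cells and L5 pyramidal compartments
    (transient sodium NaF with activation gate ``m`` and inactivation ``h``,
    delayed-rectifier potassium KDR with activation ``n``).
``inh``
    The slightly shifted variant used for slow-inhibitory (LTS/Martinotti-like)
    interneurons; NaF activation is treated as instantaneous.
``fs``
    Wang–Buzsaki fast-spiking interneuron kinetics (instantaneous ``m``,
    temperature factor 5 on ``h`` and ``n``).

Two further currents are family-independent: the muscarinic-sensitive
M-current (gate ``w``, first power) responsible for spike-frequency
adaptation, and the high-threshold calcium current CaH (gate ``q``, squared)
carried by L5 pyramidal apical dendrites, which supports intrinsic bursting.

All rate functions are expressed as ``(x_inf(v), tau_x(v))`` pairs; for gates
specified through forward/backward rates ``alpha/beta`` the standard
identities ``x_inf = alpha/(alpha+beta)`` and ``tau = 1/(alpha+beta)`` are
used.  Voltages are in mV, times in ms.

The bundled table is named ``kramer-reduced-v1``; alternative tables can be
registered and selected through the model config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GateKinetics",
    "gate_steady_state",
    "GATE_TABLE",
    "KINETICS_TABLE_NAME",
    "INSTANTANEOUS_GATES",
]

KINETICS_TABLE_NAME = "kramer-reduced-v1"

_EPS = 1e-9


@dataclass(frozen=True)
class GateKinetics:
    """Identifies one gating variable of one kinetic family.

    Parameters
    ----------
    gate : str
        ``"m"``, ``"h"`` (NaF), ``"n"`` (KDR), ``"w"`` (M) or ``"q"`` (CaH).
    family : str
        ``"exc"``, ``"inh"`` or ``"fs"``.  Ignored for ``w`` and ``q``,
        which are family-independent.
    """

    gate: str
    family: str = "exc"


def _expm1_safe(x):
    # x/(1-exp(-x)) -> 1 as x -> 0; rewrite rate functions via this helper
    x = np.asarray(x, dtype=float)
    return np.where(np.abs(x) < 1e-7, 1.0 + x / 2.0, x / (-np.expm1(-np.where(np.abs(x) < 1e-7, 1.0, x))))


def _linoid(v, vhalf, scale):
    """a*(v-vhalf)/(1-exp(-(v-vhalf)/scale)) without the removable singularity
    (the leading coefficient is applied by the caller)."""
    x = (np.asarray(v, dtype=float) - vhalf) / scale
    return scale * _expm1_safe(x)


# -- transient sodium ---------------------------------------------------------

def _naf_m_exc(v):
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp((-v - 34.5) / 10.0))
    tau = np.where(
        v < -26.5,
        0.025 + 0.14 * np.exp((v + 26.5) / 10.0),
        0.02 + 0.145 * np.exp((-v - 26.5) / 10.0),
    )
    return m_inf, tau


def _naf_h_exc(v):
    v = np.asarray(v, dtype=float)
    h_inf = 1.0 / (1.0 + np.exp((v + 59.4) / 10.7))
    tau = 0.15 + 1.15 / (1.0 + np.exp((v + 33.5) / 15.0))
    return h_inf, tau


def _naf_m_inh(v):
    v = np.asarray(v, dtype=float)
    m_inf = 1.0 / (1.0 + np.exp((-v - 38.0) / 10.0))
    tau = np.full_like(m_inf, 0.02)  # effectively instantaneous
    return m_inf, tau


def _naf_h_inh(v):
    v = np.asarray(v, dtype=float)
    h_inf = 1.0 / (1.0 + np.exp((v + 58.3) / 6.7))
    tau = 0.225 + 1.125 / (1.0 + np.exp((v + 37.0) / 15.0))
    return h_inf, tau


def _naf_m_fs(v):
    v = np.asarray(v, dtype=float)
    alpha = 0.1 * _linoid(v, -35.0, 10.0)
    beta = 4.0 * np.exp(-(v + 60.0) / 18.0)
    return alpha / (alpha + beta + _EPS), 1.0 / (alpha + beta + _EPS)


def _naf_h_fs(v):
    v = np.asarray(v, dtype=float)
    # Wang-Buzsaki rates scaled by phi = 5
    alpha = 5.0 * 0.07 * np.exp(-(v + 58.0) / 20.0)
    beta = 5.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    return alpha / (alpha + beta + _EPS), 1.0 / (alpha + beta + _EPS)


# -- delayed rectifier --------------------------------------------------------

def _kdr_n_exc(v):
    v = np.asarray(v, dtype=float)
    n_inf = 1.0 / (1.0 + np.exp((-v - 29.5) / 10.0))
    tau = 0.25 + 4.35 * np.exp(-np.abs(v + 10.0) / 10.0)
    return n_inf, tau


def _kdr_n_inh(v):
    v = np.asarray(v, dtype=float)
    n_inf = 1.0 / (1.0 + np.exp((-v - 27.0) / 11.5))
    tau = 0.25 + 4.35 * np.exp(-np.abs(v + 10.0) / 10.0)
    return n_inf, tau


def _kdr_n_fs(v):
    v = np.asarray(v, dtype=float)
    alpha = 5.0 * 0.01 * _linoid(v, -34.0, 10.0)
    beta = 5.0 * 0.125 * np.exp(-(v + 44.0) / 80.0)
    return alpha / (alpha + beta + _EPS), 1.0 / (alpha + beta + _EPS)


# -- M-current (muscarinic-sensitive K) ---------------------------------------

def _m_w(v):
    v = np.asarray(v, dtype=float)
    alpha = 0.02 / (1.0 + np.exp((-v - 20.0) / 5.0))
    beta = 0.01 * np.exp((-v - 43.0) / 18.0)
    return alpha / (alpha + beta + _EPS), 1.0 / (alpha + beta + _EPS)


# -- high-threshold calcium ---------------------------------------------------

def _cah_q(v):
    v = np.asarray(v, dtype=float)
    alpha = 1.6 / (1.0 + np.exp(-0.072 * (v - 5.0)))
    # beta = 0.02 (v + 8.9) / (exp((v + 8.9)/5) - 1); removable singularity at -8.9
    u = (v + 8.9) / 5.0
    safe = np.where(np.abs(u) < 1e-7, 1.0, u)
    beta = 0.1 * np.where(np.abs(u) < 1e-7, 1.0 - u / 2.0, safe / np.expm1(safe))
    return alpha / (alpha + beta + _EPS), 1.0 / (alpha + beta + _EPS)


GATE_TABLE = {
    ("m", "exc"): _naf_m_exc,
    ("h", "exc"): _naf_h_exc,
    ("n", "exc"): _kdr_n_exc,
    ("m", "inh"): _naf_m_inh,
    ("h", "inh"): _naf_h_inh,
    ("n", "inh"): _kdr_n_inh,
    ("m", "fs"): _naf_m_fs,
    ("h", "fs"): _naf_h_fs,
    ("n", "fs"): _kdr_n_fs,
    ("w", "exc"): _m_w,
    ("w", "inh"): _m_w,
    ("w", "fs"): _m_w,
    ("q", "exc"): _cah_q,
    ("q", "inh"): _cah_q,
    ("q", "fs"): _cah_q,
}

#: gates treated as instantaneous (set to x_inf rather than integrated)
INSTANTANEOUS_GATES = {("m", "inh"), ("m", "fs")}

FAMILIES = ("exc", "inh", "fs")


def gate_steady_state(v, kin: GateKinetics):
    """Steady-state value and time constant of a gating variable.

    Parameters
    ----------
    v : float or ndarray
        Membrane potential in mV.
    kin : GateKinetics
        Gate/family pair.

    Returns
    -------
    x_inf : ndarray or float in [0, 1]
    tau : ndarray or float, strictly positive, ms

    Raises
    ------
    KeyError
        If the (gate, family) pair is not in the kinetics table.
    """
    key = (kin.gate, kin.family)
    if key not in GATE_TABLE:
        raise KeyError(
            f"unknown gate/family pair {key!r}; supported: {sorted(GATE_TABLE)}"
        )
    x_inf, tau = GATE_TABLE[key](v)
    return x_inf, tau


# channel gating-exponent conventions, shared by the reference implementation
# (cells.py) and the compiled kernel
NAF_M_POWER = 3
KDR_N_POWER = 4
CAH_Q_POWER = 2
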