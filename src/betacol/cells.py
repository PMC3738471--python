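"""Single-compartment and three-compartment conductance-based cell models.

Nine cell classes populate each cortical column: L2/3 RS (regular-spiking
pyramid), L2/3 FS (fast-spiking interneuron), L2/3 SI (slow-inhibitory,
LTS/Martinotti-like), L4 E (stellate/pyramidal), L4 FS, L5 IB (intrinsically
bursting pyramid), L5 RS, L5 FS and L5 SI.  All classes are single
compartments except the L5 pyramids (IB, RS) which have axon, soma and
apical-dendrite compartments joined by electrical coupling; only the dendrite
carries the high-threshold calcium current, and IB dendrites carry more of it
than RS dendrites, which is what makes them burst.

Membrane dynamics follow the usual current-balance equation

    C dV/dt = -I_NaF - I_KDR - I_leak - I_M - I_CaH - I_syn - I_tonic
              + I_epsc + I_couple

with the convention that a *negative* tonic drive depolarizes (the tonic term
enters with a minus sign).  Gates follow dx/dt = (x_inf(V) - x)/tau_x(V) with
the kinetics of :mod:`betacol.kinetics`.

This module holds the parameter containers and a plain-NumPy reference
implementation of the right-hand side used by oracle tests; production runs
go through the compiled kernel in :mod:`betacol._kernel`, which implements
the identical equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import (
    CAH_Q_POWER,
    INSTANTANEOUS_GATES,
    KDR_N_POWER,
    NAF_M_POWER,
    GateKinetics,
    gate_steady_state,
)

__all__ = [
    "CompartmentParams",
    "CellSpec",
    "CompartmentState",
    "resting_state",
    "compartment_derivative",
    "ionic_current",
    "draw_tonic_current",
    "box_muller",
]

GATE_NAMES = ("m", "h", "n", "w", "q")


@dataclass(frozen=True)
class CompartmentParams:
    """Biophysical parameters of one compartment (conductances in mS/cm²,
    reversals in mV, capacitance in µF/cm², currents in µA/cm²)."""

    g_naf: float = 200.0
    g_kdr: float = 20.0
    g_leak: float = 0.1
    g_m: float = 0.0
    g_cah: float = 0.0
    e_na: float = 50.0
    e_k: float = -100.0
    e_leak: float = -67.0
    e_ca: float = 125.0
    c_m: float = 0.9
    tonic_mean: float = 0.0
    tonic_std: float = 0.0
    g_epsc: float = 0.0
    family: str = "exc"

    def __post_init__(self):
        for name in ("g_naf", "g_kdr", "g_leak", "g_m", "g_cah", "tonic_std", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CellSpec:
    """One cell class: an ordered list of compartments plus their coupling.

    ``compartments`` maps compartment name -> :class:`CompartmentParams`; for
    L5 pyramids the order is (axon, soma, dendrite).  ``coupling`` lists
    (comp_a, comp_b, g_c) electrical couplings; the coupling current into
    ``a`` is ``g_c * (V_b - V_a)`` and symmetrically into ``b``.
    ``spike_compartment`` names the compartment whose voltage defines spikes
    and drives this cell's synapses (axon for L5 pyramids).
    """

    cell_class: str
    compartments: dict = field(default_factory=dict)
    coupling: tuple = ()
    spike_compartment: str = "soma"
    excitatory: bool = True

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)


@dataclass
class CompartmentState:
    """Dynamical state of one compartment: voltage + channel gates."""

    v: float
    gates: dict = field(default_factory=dict)

    def clamp(self):
        for k, x in self.gates.items():
            self.gates[k] = min(1.0, max(0.0, x))
        return self


def resting_state(params: CompartmentParams, v: float | None = None) -> CompartmentState:
    """State with all gates at their steady-state values for voltage ``v``
    (defaults to the leak reversal)."""
    v0 = params.e_leak if v is None else v
    gates = {}
    for g in GATE_NAMES:
        x_inf, _ = gate_steady_state(v0, GateKinetics(g, params.family))
        gates[g] = float(x_inf)
    return CompartmentState(v=float(v0), gates=gates)


def ionic_current(state: CompartmentState, params: CompartmentParams) -> float:
    """Total intrinsic ionic current (µA/cm², outward positive)."""
    v = state.v
    fam = params.family
    m = state.gates["m"]
    if ("m", fam) in INSTANTANEOUS_GATES:
        m, _ = gate_steady_state(v, GateKinetics("m", fam))
    i = params.g_leak * (v - params.e_leak)
    i += params.g_naf * (m ** NAF_M_POWER) * state.gates["h"] * (v - params.e_na)
    i += params.g_kdr * (state.gates["n"] ** KDR_N_POWER) * (v - params.e_k)
    if params.g_m > 0:
        i += params.g_m * state.gates["w"] * (v - params.e_k)
    if params.g_cah > 0:
        i += params.g_cah * (state.gates["q"] ** CAH_Q_POWER) * (v - params.e_ca)
    return float(i)


def compartment_derivative(
    state: CompartmentState,
    params: CompartmentParams,
    i_syn: float = 0.0,
    i_epsc: float = 0.0,
    i_tonic: float = 0.0,
    i_couple: float = 0.0,
):
    """Time derivative of one compartment's state.

    ``i_syn`` is the summed chemical synaptic current (outward positive, so it
    is subtracted), ``i_epsc`` the external EPSC-train current (inward
    positive, added), ``i_tonic`` the noisy tonic drive (negative values
    depolarize) and ``i_couple`` the net electrical-coupling current (added).

    Returns
    -------
    (dv_dt, dgates_dt) : (float, dict)
        ``dgates_dt`` omits gates that are instantaneous for this family.

    Raises
    ------
    FloatingPointError
        If the state contains non-finite numbers.
    """
    if not math.isfinite(state.v) or not all(math.isfinite(x) for x in state.gates.values()):
        raise FloatingPointError(f"non-finite state in {params.family} compartment: {state}")
    for name, x in state.gates.items():
        if not (-1e-9 <= x <= 1.0 + 1e-9):
            raise ValueError(f"gate {name}={x} outside [0, 1]")

    dv = (-ionic_current(state, params) - i_syn - i_tonic + i_epsc + i_couple) / params.c_m
    dgates = {}
    for g in GATE_NAMES:
        if (g, params.family) in INSTANTANEOUS_GATES and g == "m":
            continue
        if g == "w" and params.g_m == 0.0:
            continue
        if g == "q" and params.g_cah == 0.0:
            continue
        x_inf, tau = gate_steady_state(state.v, GateKinetics(g, params.family))
        dgates[g] = (float(x_inf) - state.gates[g]) / float(tau)
    return dv, dgates


def box_muller(rng, n: int = 1) -> np.ndarray:
    """Standard-normal samples via the Box–Muller transform.

    Draws pairs of uniforms and maps them through
    ``sqrt(-2 ln u1) * cos(2 pi u2)`` / ``... * sin(2 pi u2)``.
    """
    n_pairs = (n + 1) // 2
    u1 = rng.random(n_pairs)
    u2 = rng.random(n_pairs)
    u1 = np.clip(u1, 1e-300, 1.0)
    r = np.sqrt(-2.0 * np.log(u1))
    z = np.concatenate([r * np.cos(2.0 * np.pi * u2), r * np.sin(2.0 * np.pi * u2)])
    return z[:n]


def draw_tonic_current(mean: float, std: float, rng, n: int = 1) -> np.ndarray:
    """Gaussian tonic-drive sample(s) with the given mean and std (µA/cm²),
    generated by the Box–Muller transform.  ``std = 0`` returns the mean
    exactly.  One draw per cell per run freezes across-cell heterogeneity."""
    if std < 0:
        raise ValueError("std must be non-negative")
    if std == 0.0:
        return np.full(n, float(mean))
    return mean + std * box_muller(rng, n)
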