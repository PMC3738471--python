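"""Chemical synapse gating and external EPSC-train inputs.

Every chemical synapse is a first-order kinetic gate ``s`` driven by the
presynaptic voltage through a saturating sigmoid:

    ds/dt = drive(V_pre) * (1 - s) / tau_rise - s / tau_decay
    drive(V) = 1 / (1 + exp(-(V - v_th) / v_slope)),  v_th = 0 mV, v_slope = 2 mV

so ``tau_rise`` and ``tau_decay`` set how fast the synapse opens during a
presynaptic spike and closes afterwards.  The current onto a postsynaptic
compartment is the sum over incoming synapses of ``g_max * s * (V_post -
E_rev)``.  Receptor classes and their (rise, decay) time constants in ms:

    ============================  =====  ======
    AMPA (all fast excitation)     0.25      1
    GABA from FS cells             0.5       8
    NMDA (slow excitation)         5.0     100
    GABA from SI cells             0.5      20
    L5 pyramid -> L2/3 SI          2.5      50
    ============================  =====  ======

NMDA synapses are modeled as a slow linear conductance (no magnesium-block
nonlinearity) by default; an optional Mg-block factor can be enabled in the
config.

External drive arrives as trains of EPSCs: each arrival resets an AMPA-like
conductance to its maximal value (saturating reset, not summation) after
which it decays exponentially with a 2 ms time constant.  Bottom-up (100 Hz)
and background (50 Hz) trains are independent Poisson processes per target
cell; the top-down train is a single shared periodic 20 Hz train delivered
identically to every targeted L5 pyramidal dendrite of the attended column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseKinetics",
    "GateState",
    "EPSCTrain",
    "RECEPTORS",
    "presyn_drive",
    "gate_derivative",
    "total_synaptic_current",
    "epsc_conductance",
    "poisson_train",
    "synchronous_beta_train",
    "EPSC_DECAY_TAU",
]

#: decay time constant of external EPSC-train conductances (ms)
EPSC_DECAY_TAU = 2.0

DRIVE_V_THRESH = 0.0
DRIVE_V_SLOPE = 2.0


@dataclass(frozen=True)
class SynapseKinetics:
    """Receptor kinetics: rise/decay time constants (ms), maximal conductance
    (mS/cm²) and reversal potential (mV)."""

    receptor: str
    tau_rise: float
    tau_decay: float
    g_max: float = 0.0
    e_rev: float = 0.0

    def __post_init__(self):
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("tau_rise and tau_decay must be positive")


#: bundled receptor table: (tau_rise, tau_decay, E_rev)
RECEPTORS = {
    "ampa": (0.25, 1.0, 0.0),
    "gaba_fs": (0.5, 8.0, -80.0),
    "nmda": (5.0, 100.0, 0.0),
    "gaba_si": (0.5, 20.0, -80.0),
    "slow_exc_l5_to_l23si": (2.5, 50.0, 0.0),
}


def make_kinetics(receptor: str, g_max: float) -> SynapseKinetics:
    """Receptor-table lookup returning a fully specified kinetics object."""
    try:
        tau_r, tau_d, e_rev = RECEPTORS[receptor]
    except KeyError:
        raise KeyError(f"unknown receptor {receptor!r}; supported: {sorted(RECEPTORS)}")
    return SynapseKinetics(receptor, tau_r, tau_d, g_max, e_rev)


@dataclass
class GateState:
    """Open fraction of one synaptic gate, in [0, 1]."""

    s: float = 0.0


def mg_block_factor(v, mg_mm: float = 1.0):
    """Voltage-dependent magnesium-block factor for NMDA conductances,
    1/(1 + [Mg]/3.57 * exp(-0.062 V)).  Only applied when the optional
    Mg-block switch is enabled; by default NMDA is a slow linear
    conductance."""
    return 1.0 / (1.0 + (mg_mm / 3.57) * np.exp(-0.062 * np.asarray(v, dtype=float)))


def presyn_drive(v_pre):
    """Saturating sigmoid of the presynaptic voltage that opens the gate."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v_pre, dtype=float) - DRIVE_V_THRESH) / DRIVE_V_SLOPE))


def gate_derivative(state: GateState, v_pre: float, kin: SynapseKinetics) -> float:
    """ds/dt for one synaptic gate given the presynaptic voltage."""
    if not 0.0 <= state.s <= 1.0:
        raise ValueError(f"gate s={state.s} outside [0, 1]")
    drive = float(presyn_drive(v_pre))
    return drive * (1.0 - state.s) / kin.tau_rise - state.s / kin.tau_decay


def total_synaptic_current(v_post: float, incoming) -> float:
    """Summed synaptic current onto a compartment (µA/cm², outward positive).

    ``incoming`` is an iterable of ``(GateState, SynapseKinetics)`` pairs.
    """
    total = 0.0
    for gate, kin in incoming:
        total += kin.g_max * gate.s * (v_post - kin.e_rev)
    return total


@dataclass
class EPSCTrain:
    """One external EPSC train: sorted arrival times (ms) plus the conductance
    transient each arrival produces.  ``mode="sum"`` (the bundled default)
    superposes one ``g_max``-amplitude exponential per arrival, matching the
    Heaviside-sum drive term of the membrane equation; ``mode="reset"``
    instead jumps the conductance to ``g_max`` at each arrival (a saturating
    synapse that cannot exceed its maximal conductance).  ``shared=True``
    marks a single train object delivered to all of its targets (the
    synchronous top-down signal)."""

    arrival_times: np.ndarray
    g_max: float
    decay_tau: float = EPSC_DECAY_TAU
    shared: bool = False
    mode: str = "sum"

    def __post_init__(self):
        t = np.asarray(self.arrival_times, dtype=float)
        if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) < 0)):
            raise ValueError("arrival times must be a sorted 1-D array")
        if self.mode not in ("sum", "reset"):
            raise ValueError("mode must be 'sum' or 'reset'")
        object.__setattr__(self, "arrival_times", t)


def epsc_conductance(t: float, train: EPSCTrain) -> float:
    """Conductance of an EPSC train at time ``t``: zero before the first
    arrival; in ``sum`` mode the superposition of per-arrival exponentials,
    in ``reset`` mode ``g_max`` at each arrival with exponential decay
    between arrivals.  Closed-form evaluation used as the oracle for the
    kernel's step-wise update."""
    times = train.arrival_times
    k = int(np.searchsorted(times, t, side="right"))
    if k == 0:
        return 0.0
    if train.mode == "sum":
        return float(train.g_max * np.exp(-(t - times[:k]) / train.decay_tau).sum())
    dt = t - times[k - 1]
    return float(train.g_max * np.exp(-dt / train.decay_tau))


def poisson_train(rate: float, duration: float, rng) -> np.ndarray:
    """Homogeneous Poisson arrival times (ms) on ``[0, duration)``.

    ``rate`` is in Hz, ``duration`` in ms.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.random(n) * duration)


def synchronous_beta_train(freq: float = 20.0, duration: float = 1000.0, jitter: float = 0.0, rng=None) -> np.ndarray:
    """Periodic arrival times at ``1000/freq`` ms spacing on ``[0, duration)``.

    The same array object is attached to every targeted cell, so all L5
    pyramidal dendrites of the attended column see identical arrivals.
    Optional Gaussian jitter (ms) perturbs each arrival (still shared).
    """
    if freq <= 0:
        raise ValueError("freq must be positive")
    period = 1000.0 / freq
    times = np.arange(0.0, duration, period)
    if jitter > 0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        times = np.sort(np.clip(times + rng.normal(0.0, jitter, times.size), 0.0, np.nextafter(duration, 0.0)))
    return times
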