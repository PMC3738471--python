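"""Network integration: array compilation, the RK4 run, and spike detection.

`integrate` flattens a realized :class:`~betacol.network.TwoColumnNetwork`
plus a list of EPSC-train stimuli into the packed arrays consumed by the
compiled kernel, advances the whole system with classical fourth-order
Runge-Kutta at a fixed 0.01 ms step, and returns a :class:`SimResult` with
spike events, the per-cell synaptic-current traces onto L2/3 RS cells (the
simulated-LFP sources) and, optionally, downsampled voltage traces.

Spikes are upward crossings of 0 mV with a 2 ms dead time, detected on the
axon compartment for L5 pyramids and on the single compartment otherwise,
with the crossing time linearly interpolated.  Tonic-drive heterogeneity is
frozen per run: one Box–Muller draw per compartment, seeded by the run seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._kernel import SPIKE_DEAD_MS, SPIKE_THRESH, build_lut, run_network
from .cells import draw_tonic_current
from .config import POPULATIONS
from .kinetics import GateKinetics, gate_steady_state
from .network import TwoColumnNetwork

__all__ = ["SimConfig", "Stimulus", "SimResult", "integrate", "detect_spikes", "NumericalDivergenceError"]

FAMILY_CODE = {"exc": 0, "inh": 1, "fs": 2}


class NumericalDivergenceError(RuntimeError):
    """Raised when a membrane potential leaves [-200, 200] mV or turns NaN."""


@dataclass(frozen=True)
class SimConfig:
    """Integration and recording settings.

    dt in ms (0.01 default), duration in ms; ``lfp_dt`` is the sampling
    interval of the recorded synaptic-current (LFP-source) traces and
    ``v_dt`` of the optional voltage traces.  Both must be multiples of dt;
    LFP sources are computed from the full-resolution state at the sample
    instants.
    """

    dt: float = 0.01
    duration: float = 1000.0
    seed: int = 0
    record_lfp: bool = True
    lfp_dt: float = 1.0
    lfp_populations: tuple = ("l23_rs",)
    record_v: bool = False
    v_dt: float = 0.1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("duration", "lfp_dt", "v_dt"):
            val = getattr(self, name)
            if abs(val / self.dt - round(val / self.dt)) > 1e-9:
                raise ValueError(f"{name} must be a multiple of dt")


@dataclass(frozen=True)
class Stimulus:
    """One EPSC-train attachment: arrival times (ms) delivered to one
    compartment of one cell with the given maximal conductance."""

    name: str
    cell_id: int
    compartment: str
    g_max: float
    times: np.ndarray
    mode: str | None = None  # "sum" | "reset"; None -> model default


@dataclass
class SimResult:
    """Output of one seeded run."""

    spikes: pd.DataFrame
    duration: float
    dt: float
    seed: int
    config_hash: str
    pop_cells: dict
    lfp: np.ndarray | None = None
    lfp_cells: np.ndarray | None = None
    lfp_columns: np.ndarray | None = None
    lfp_dt: float = 1.0
    v: np.ndarray | None = None
    v_dt: float = 0.1
    comp_meta: pd.DataFrame | None = None
    stimulus_log: dict = field(default_factory=dict)

    def spikes_of(self, column: int | None = None, population: str | None = None) -> pd.DataFrame:
        s = self.spikes
        if column is not None:
            s = s[s["column"] == column]
        if population is not None:
            s = s[s["population"] == population]
        return s

    def column_lfp(self, column: int) -> np.ndarray:
        """Summed synaptic current onto all recorded L2/3 RS cells of one
        column (the simulated LFP)."""
        if self.lfp is None:
            raise ValueError("LFP sources were not recorded; rerun with record_lfp=True")
        return self.lfp[self.lfp_columns == column].sum(axis=0)


def _config_hash(net: TwoColumnNetwork, cfg: SimConfig, stimuli) -> str:
    h = hashlib.sha256()
    h.update(yaml.safe_dump(net.config.raw, sort_keys=True).encode())
    h.update(json.dumps({
        "dt": cfg.dt, "duration": cfg.duration, "seed": cfg.seed,
        "net_seed": net.seed, "manipulations": [m[0] for m in net.manipulations],
        "stimuli": sorted({s.name for s in stimuli}),
    }, sort_keys=True).encode())
    return h.hexdigest()[:16]


def integrate(net: TwoColumnNetwork, stimuli: list, cfg: SimConfig) -> SimResult:
    """Run the network with the attached stimuli for ``cfg.duration`` ms."""
    config = net.config
    rng = np.random.default_rng(cfg.seed)

    # ---- compartments, in fixed (cell id, compartment) order ----
    active = net.active_cells()
    comp_of = {}
    rows = []
    specs = {pop: config.cell_spec(pop) for pop in POPULATIONS}
    arr = {k: [] for k in ("fam", "g_naf", "g_kdr", "g_leak", "g_m", "g_cah", "e_na", "e_k", "e_leak", "e_ca", "inv_c", "tonic_mean", "tonic_std")}
    det_comp, det_cell = [], []
    cpl_a, cpl_b, cpl_g = [], [], []
    for cell in active:
        pop = net.cell_class[cell]
        col = int(net.cell_column[cell])
        spec = specs[pop]
        tonic_override = net.tonic_overrides.get(pop)
        for name, p in spec.compartments.items():
            idx = len(rows)
            comp_of[(cell, name)] = idx
            rows.append((cell, pop, col, name))
            arr["fam"].append(FAMILY_CODE[p.family])
            arr["g_naf"].append(p.g_naf)
            arr["g_kdr"].append(p.g_kdr)
            arr["g_leak"].append(p.g_leak)
            arr["g_m"].append(p.g_m)
            arr["g_cah"].append(p.g_cah)
            arr["e_na"].append(p.e_na)
            arr["e_k"].append(p.e_k)
            arr["e_leak"].append(p.e_leak)
            arr["e_ca"].append(p.e_ca)
            arr["inv_c"].append(1.0 / p.c_m)
            arr["tonic_mean"].append(p.tonic_mean if tonic_override is None else tonic_override)
            arr["tonic_std"].append(p.tonic_std)
        for a, b, g in spec.coupling:
            cpl_a.append(comp_of[(cell, a)])
            cpl_b.append(comp_of[(cell, b)])
            cpl_g.append(g)
        det_comp.append(comp_of[(cell, spec.spike_compartment)])
        det_cell.append(cell)

    n_comp = len(rows)
    comp_meta = pd.DataFrame(rows, columns=["cell", "population", "column", "compartment"])
    fam = np.array(arr["fam"], dtype=np.int8)
    fa = {k: np.asarray(v, dtype=float) for k, v in arr.items() if k != "fam"}

    # frozen per-compartment tonic drive (Box-Muller), in compartment order
    i_tonic = np.array([
        draw_tonic_current(m, s, rng, 1)[0] for m, s in zip(fa["tonic_mean"], fa["tonic_std"])
    ])

    # ---- synaptic gates (dedup by presynaptic cell x receptor) and edges ----
    spike_comp_of_cell = {c: comp_of[(c, specs[net.cell_class[c]].spike_compartment)] for c in active}
    receptors = config.raw["receptors"]
    gate_index = {}
    gate_pre, gate_tr, gate_td = [], [], []
    edge_gate, edge_post, edge_g, edge_e, edge_mg = [], [], [], [], []
    mg_on = bool(config.raw.get("nmda_mg_block", False))
    for pre_id, post_id, receptor, g_max, post_comp in net.edges[["pre_id", "post_id", "receptor", "g_max", "post_comp"]].itertuples(index=False):
        key = (pre_id, receptor)
        if key not in gate_index:
            gate_index[key] = len(gate_pre)
            gate_pre.append(spike_comp_of_cell[pre_id])
            gate_tr.append(receptors[receptor]["tau_rise"])
            gate_td.append(receptors[receptor]["tau_decay"])
        edge_gate.append(gate_index[key])
        edge_post.append(comp_of[(post_id, post_comp)])
        edge_g.append(g_max)
        edge_e.append(receptors[receptor]["e_rev"])
        edge_mg.append(1 if (mg_on and receptor == "nmda") else 0)
    n_gate = len(gate_pre)

    # ---- EPSC-train attachments ----
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    decay_tau = float(config.external_inputs.get("epsc_decay_tau", 2.0))
    default_mode = config.external_inputs.get("epsc_mode", "sum")
    att_post, att_gmax, att_mode = [], [], []
    ev_step_list, ev_att_list = [], []
    stim_log = {}
    for k, st in enumerate(stimuli):
        if st.cell_id not in spike_comp_of_cell:
            continue  # target removed by a manipulation
        att_post.append(comp_of[(st.cell_id, st.compartment)])
        att_gmax.append(st.g_max)
        att_mode.append(0 if (st.mode or default_mode) == "sum" else 1)
        steps = np.round(np.asarray(st.times, dtype=float) / dt).astype(np.int64)
        steps = steps[(steps >= 0) & (steps < n_steps)]
        ev_step_list.append(steps)
        ev_att_list.append(np.full(steps.size, len(att_post) - 1, dtype=np.int64))
        stim_log[st.name] = stim_log.get(st.name, 0) + steps.size
    if ev_step_list:
        ev_step = np.concatenate(ev_step_list)
        ev_att = np.concatenate(ev_att_list)
        order = np.argsort(ev_step, kind="stable")
        ev_step, ev_att = ev_step[order], ev_att[order]
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_att = np.empty(0, dtype=np.int64)
    att_post = np.asarray(att_post, dtype=np.int64)
    att_gmax = np.asarray(att_gmax, dtype=float)

    # ---- LFP source recording: all synapses onto the chosen populations
    # (every compartment of a recorded cell maps to that cell's slot) ----
    lfp_slot = np.full(n_comp, -1, dtype=np.int64)
    lfp_cells, lfp_cols = [], []
    if cfg.record_lfp:
        for c in (0, 1):
            for pop in cfg.lfp_populations:
                if (c, pop) not in net.populations:
                    continue
                for cell in net.cells_of(c, pop):
                    slot = len(lfp_cells)
                    for comp_name in specs[pop].compartments:
                        lfp_slot[comp_of[(cell, comp_name)]] = slot
                    lfp_cells.append(cell)
                    lfp_cols.append(c)
    edge_post_arr = np.asarray(edge_post, dtype=np.int64)
    lfp_edge_idx = np.nonzero(lfp_slot[edge_post_arr] >= 0)[0].astype(np.int64)
    lfp_att_idx = np.nonzero(lfp_slot[att_post] >= 0)[0].astype(np.int64) if att_post.size else np.empty(0, dtype=np.int64)
    rec_stride = int(round(cfg.lfp_dt / dt))
    n_samp = n_steps // rec_stride + 1
    lfp_out = np.zeros((max(len(lfp_cells), 1), n_samp))

    v_stride = int(round(cfg.v_dt / dt)) if cfg.record_v else 0
    v_out = np.zeros((n_steps // v_stride + 1, n_comp)) if v_stride else np.zeros((1, 1))

    # ---- initial state: rest at the leak reversal, gates at steady state ----
    y = np.zeros(6 * n_comp + n_gate)
    for i in range(n_comp):
        family = ("exc", "inh", "fs")[fam[i]]
        v0 = fa["e_leak"][i]
        y[i] = v0
        for j, gname in enumerate(("m", "h", "n", "w", "q")):
            x_inf, _ = gate_steady_state(v0, GateKinetics(gname, family))
            y[(j + 1) * n_comp + i] = float(x_inf)

    max_spikes = int(len(active) * (cfg.duration / SPIKE_DEAD_MS + 2))
    spike_slot = np.zeros(max_spikes, dtype=np.int64)
    spike_t = np.zeros(max_spikes)

    lut = build_lut()
    n_spk, err_comp, err_step = run_network(
        y, lut, n_comp, fam,
        fa["g_naf"], fa["g_kdr"], fa["g_leak"], fa["g_m"], fa["g_cah"],
        fa["e_na"], fa["e_k"], fa["e_leak"], fa["e_ca"], fa["inv_c"], i_tonic,
        np.asarray(cpl_a, dtype=np.int64), np.asarray(cpl_b, dtype=np.int64), np.asarray(cpl_g, dtype=float),
        np.asarray(gate_pre, dtype=np.int64), 1.0 / np.asarray(gate_tr, dtype=float), 1.0 / np.asarray(gate_td, dtype=float),
        np.asarray(edge_gate, dtype=np.int64), edge_post_arr, np.asarray(edge_g, dtype=float), np.asarray(edge_e, dtype=float), np.asarray(edge_mg, dtype=np.int8),
        att_post, att_gmax, np.asarray(att_mode, dtype=np.int8), np.zeros(att_post.size),
        float(np.exp(-0.5 * dt / decay_tau)), float(np.exp(-dt / decay_tau)),
        ev_step, ev_att, dt, n_steps,
        np.asarray(det_comp, dtype=np.int64), spike_slot, spike_t, max_spikes,
        lfp_edge_idx, lfp_att_idx, lfp_slot, lfp_out,
        rec_stride, 1 if cfg.record_lfp else 0,
        v_out, v_stride,
    )
    if err_comp >= 0:
        cell, pop, col, comp = comp_meta.iloc[err_comp]
        raise NumericalDivergenceError(
            f"voltage diverged in cell {cell} ({pop}, column {col}, {comp}) "
            f"at t = {err_step * dt:.2f} ms (config {_config_hash(net, cfg, stimuli)})"
        )

    det_cell = np.asarray(det_cell)
    cells = det_cell[spike_slot[:n_spk]]
    spikes = pd.DataFrame({
        "time": spike_t[:n_spk],
        "cell": cells,
        "population": [net.cell_class[c] for c in cells],
        "column": net.cell_column[cells] if n_spk else np.empty(0, dtype=int),
    }).sort_values("time", kind="stable").reset_index(drop=True)

    return SimResult(
        spikes=spikes,
        duration=cfg.duration,
        dt=dt,
        seed=cfg.seed,
        config_hash=_config_hash(net, cfg, stimuli),
        pop_cells={k: v.cell_ids.copy() for k, v in net.populations.items()},
        lfp=lfp_out if cfg.record_lfp else None,
        lfp_cells=np.asarray(lfp_cells) if cfg.record_lfp else None,
        lfp_columns=np.asarray(lfp_cols) if cfg.record_lfp else None,
        lfp_dt=cfg.lfp_dt,
        v=v_out if cfg.record_v else None,
        v_dt=cfg.v_dt,
        comp_meta=comp_meta,
        stimulus_log=stim_log,
    )


def detect_spikes(v: np.ndarray, dt: float, thresh: float = SPIKE_THRESH, dead_time: float = SPIKE_DEAD_MS) -> np.ndarray:
    """Spike times (ms) from a uniformly sampled voltage trace: upward
    threshold crossings with a dead time, linearly interpolated."""
    v = np.asarray(v, dtype=float)
    idx = np.nonzero((v[:-1] < thresh) & (v[1:] >= thresh))[0]
    times = []
    last = -np.inf
    for i in idx:
        t = (i + (thresh - v[i]) / (v[i + 1] - v[i])) * dt
        if t - last >= dead_time:
            times.append(t)
            last = t
    return np.asarray(times)
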