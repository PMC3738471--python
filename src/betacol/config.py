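"""Model-definition loading: the bundled laminar-column parameter tables plus
user overrides.

The bundled file ``data/model.yaml`` carries the full model: per-class
compartment parameters (maximal conductances of the M and CaH currents, tonic
drive mean/std, external EPSC conductance), the receptor kinetics table, the
connectivity map, the NMDA and intercolumnar rules, and the external-input
rates.  ``load_model(overrides=...)`` deep-merges a user mapping (or YAML
file) on top, so any cell, synapse, connectivity or stimulus parameter can be
changed without touching the package.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

from .cells import CellSpec, CompartmentParams
from .synapses import SynapseKinetics

__all__ = ["ModelConfig", "load_model", "POPULATIONS"]

#: the nine cell populations of one column, in fixed advance order
POPULATIONS = (
    "l23_rs",
    "l23_fs",
    "l23_si",
    "l4_e",
    "l4_fs",
    "l5_ib",
    "l5_rs",
    "l5_fs",
    "l5_si",
)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


class ModelConfig:
    """Parsed model definition with typed accessors."""

    def __init__(self, raw: dict):
        self.raw = raw
        unknown = set(raw["populations"]) - set(POPULATIONS)
        if unknown:
            raise ValueError(f"unknown populations in config: {sorted(unknown)}")

    # -- cells ---------------------------------------------------------------

    def cell_spec(self, pop: str) -> CellSpec:
        """CellSpec for one population, with defaults applied."""
        d = self.raw["defaults"]
        p = self.raw["populations"][pop]
        family = p["family"]
        e_leak = d["e_leak_exc"] if p["excitatory"] else d["e_leak_inh"]
        comps = {}
        for name, cp in p["compartments"].items():
            g_leak = cp.get("g_leak", d["g_leak"])
            if pop == "l23_rs" and "g_leak" not in cp and d.get("l23_rs_halved_param") == "g_leak":
                g_leak = 0.5 * d["g_leak"]
            g_naf = cp.get("g_naf", d["g_naf"])
            g_kdr = cp.get("g_kdr", d["g_kdr"])
            if pop == "l23_rs":
                if d.get("l23_rs_halved_param") == "g_naf" and "g_naf" not in cp:
                    g_naf = 0.5 * d["g_naf"]
                if d.get("l23_rs_halved_param") == "g_kdr" and "g_kdr" not in cp:
                    g_kdr = 0.5 * d["g_kdr"]
            comps[name] = CompartmentParams(
                g_naf=g_naf,
                g_kdr=g_kdr,
                g_leak=g_leak,
                g_m=cp.get("g_m", 0.0),
                g_cah=cp.get("g_cah", 0.0),
                e_na=cp.get("e_na", d["e_na"]),
                e_k=cp.get("e_k", d["e_k"]),
                e_leak=cp.get("e_leak", e_leak),
                e_ca=cp.get("e_ca", d["e_ca"]),
                c_m=cp.get("c_m", d["c_m"]),
                tonic_mean=cp.get("tonic_mean", 0.0),
                tonic_std=cp.get("tonic_std", 0.0),
                g_epsc=cp.get("g_epsc", 0.0),
                family=family,
            )
        coupling = []
        names = list(comps)
        if len(names) > 1:
            cc = self.raw["coupling"]
            coupling = [
                ("axon", "soma", cc["axon_soma"]),
                ("soma", "dendrite", cc["soma_dendrite"]),
            ]
        return CellSpec(
            cell_class=pop,
            compartments=comps,
            coupling=tuple(coupling),
            spike_compartment=p.get("spike_compartment", "soma"),
            excitatory=p["excitatory"],
        )

    # -- synapses --------------------------------------------------------------

    def receptor(self, name: str, g_max: float) -> SynapseKinetics:
        try:
            r = self.raw["receptors"][name]
        except KeyError:
            raise KeyError(f"unknown receptor {name!r}")
        return SynapseKinetics(name, r["tau_rise"], r["tau_decay"], g_max, r["e_rev"])

    def receptor_for_projection(self, pre: str, post: str) -> str:
        """Receptor class implied by the pre/post cell classes."""
        if pre.endswith("_fs"):
            return "gaba_fs"
        if pre.endswith("_si"):
            return "gaba_si"
        if pre in ("l5_ib", "l5_rs") and post == "l23_si":
            return "slow_exc_l5_to_l23si"
        return "ampa"

    def target_compartment(self, pre: str, post: str, receptor: str) -> str:
        """Compartment receiving a projection (relevant for L5 pyramids):
        excitation and SI-type inhibition contact the apical dendrite,
        FS-type (perisomatic) inhibition contacts the soma."""
        if post not in ("l5_ib", "l5_rs"):
            return "soma"
        return "soma" if receptor == "gaba_fs" else "dendrite"

    @property
    def n_per_population(self) -> int:
        return int(self.raw["n_per_population"])

    @property
    def connectivity(self) -> dict:
        return self.raw["connectivity"]

    @property
    def nmda_rule(self) -> dict:
        return self.raw["nmda_rule"]

    @property
    def intercolumnar(self) -> dict:
        return self.raw["intercolumnar"]

    @property
    def external_inputs(self) -> dict:
        return self.raw["external_inputs"]

    @property
    def synapse_drive(self) -> dict:
        return self.raw["synapse_drive"]

    @property
    def kinetics_table(self) -> str:
        return self.raw["kinetics_table"]

    def with_overrides(self, overrides: dict) -> "ModelConfig":
        return ModelConfig(_deep_merge(self.raw, overrides))


def load_model(path: str | Path | None = None, overrides: dict | None = None) -> ModelConfig:
    """Load the bundled model definition (or a user file) with optional
    overrides deep-merged on top."""
    if path is None:
        text = resources.files("betacol").joinpath("data/model.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if overrides:
        raw = _deep_merge(raw, overrides)
    return ModelConfig(raw)
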