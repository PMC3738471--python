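"""Construction of the two-column network from the connectivity map.

Each column holds nine populations of 20 cells.  Connectivity is specified as
a fixed in-degree per (presynaptic population, postsynaptic population) pair:
every postsynaptic cell draws exactly ``n_pre_per_post`` distinct presynaptic
partners uniformly at random (without replacement, excluding itself within
its own population; a within-population rule demanding as many partners as
the population holds connects all-to-all including the cell itself).  A
quarter of the L2/3 FS and SI cells additionally receive NMDA contacts from
10 L2/3 RS cells.

The two columns interact only through ascending excitation: L5 pyramids (IB
and RS) of one column contact L2/3 FS and SI cells of the other with the
intracolumnar counts and kinetics, except that the intercolumnar projection
onto L2/3 SI cells is 50% stronger.  This projection carries the lateral
inhibition through which the attended column suppresses the unattended one.

Edges are realized per seed; identical seeds give identical edge lists.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import POPULATIONS, ModelConfig, load_model

__all__ = [
    "PopulationSpec",
    "TwoColumnNetwork",
    "build_column",
    "assign_nmda_targets",
    "couple_columns",
    "build_two_column_network",
    "apply_manipulation",
    "MANIPULATIONS",
    "in_degree_table",
]

EDGE_COLUMNS = ["pre_pop", "pre_id", "post_pop", "post_id", "receptor", "g_max", "post_comp", "scope"]


@dataclass(frozen=True)
class PopulationSpec:
    """One population: (column, class) with its global cell ids."""

    name: str
    column: int
    cell_ids: np.ndarray


@dataclass
class TwoColumnNetwork:
    """Realized network: populations, edge list and stimulus-relevant flags.

    ``edges`` has one row per synapse with columns
    (pre_pop, pre_id, post_pop, post_id, receptor, g_max, post_comp, scope);
    ids are global across both columns, scope is "intra" or "inter".
    """

    config: ModelConfig
    populations: dict
    cell_class: list
    cell_column: np.ndarray
    edges: pd.DataFrame
    seed: int | None = None
    tonic_overrides: dict = field(default_factory=dict)
    removed_populations: set = field(default_factory=set)
    async_topdown: bool = False
    manipulations: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_class)

    def cells_of(self, column: int, pop: str) -> np.ndarray:
        return self.populations[(column, pop)].cell_ids

    def active_cells(self) -> np.ndarray:
        ids = [p.cell_ids for p in self.populations.values()]
        return np.sort(np.concatenate(ids)) if ids else np.empty(0, dtype=int)

    def copy(self) -> "TwoColumnNetwork":
        new = copy.copy(self)
        new.populations = dict(self.populations)
        new.edges = self.edges.copy()
        new.tonic_overrides = dict(self.tonic_overrides)
        new.removed_populations = set(self.removed_populations)
        new.manipulations = list(self.manipulations)
        return new

    def export_edges(self, path) -> None:
        """Write the realized edge list as tab-separated text."""
        self.edges.to_csv(path, sep="\t", index=False)

    @staticmethod
    def import_edges(path) -> pd.DataFrame:
        df = pd.read_csv(path, sep="\t")
        missing = set(EDGE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"edge file missing columns: {sorted(missing)}")
        return df


def _sample_partners(rng, candidates: np.ndarray, n: int, self_id: int | None, pool_size: int):
    """Fixed-in-degree partner draw.  ``candidates`` excludes ``self_id``
    already when the rule is within-population."""
    if n == 0:
        return np.empty(0, dtype=int)
    if self_id is not None and n >= pool_size:
        if n > pool_size:
            raise ValueError(
                f"in-degree {n} exceeds presynaptic pool of {pool_size}"
            )
        # count equals the population size: all-to-all including self
        out = np.empty(pool_size, dtype=int)
        out[:-1] = candidates
        out[-1] = self_id
        return np.sort(out)
    if n > candidates.size:
        raise ValueError(f"in-degree {n} exceeds presynaptic pool of {candidates.size}")
    return rng.choice(candidates, size=n, replace=False)


def build_column(config: ModelConfig, column: int, rng, id_offset: int = 0):
    """Build one column: populations (global ids starting at ``id_offset``)
    and its intracolumnar edge rows."""
    n = config.n_per_population
    populations = {}
    cell_class = []
    next_id = id_offset
    for pop in POPULATIONS:
        ids = np.arange(next_id, next_id + n)
        populations[(column, pop)] = PopulationSpec(pop, column, ids)
        cell_class.extend([pop] * n)
        next_id += n

    rows = []
    for pre_pop in POPULATIONS:
        for post_pop, k, g_max in config.connectivity.get(pre_pop, []):
            receptor = config.receptor_for_projection(pre_pop, post_pop)
            post_comp = config.target_compartment(pre_pop, post_pop, receptor)
            pre_ids = populations[(column, pre_pop)].cell_ids
            for post_id in populations[(column, post_pop)].cell_ids:
                if pre_pop == post_pop:
                    cand = pre_ids[pre_ids != post_id]
                    partners = _sample_partners(rng, cand, k, post_id, pre_ids.size)
                else:
                    partners = _sample_partners(rng, pre_ids, k, None, pre_ids.size)
                for pre_id in partners:
                    rows.append((pre_pop, int(pre_id), post_pop, int(post_id), receptor, float(g_max), post_comp, "intra"))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return populations, cell_class, edges


def assign_nmda_targets(config: ModelConfig, populations: dict, column: int, rng) -> pd.DataFrame:
    """NMDA contacts: a fixed fraction (25%) of L2/3 FS and SI cells each
    receive NMDA synapses from ``n_pre`` L2/3 RS cells of their column."""
    rule = config.nmda_rule
    rows = []
    rs_ids = populations[(column, "l23_rs")].cell_ids
    for post_pop, g_max in rule["g_max"].items():
        post_ids = populations[(column, post_pop)].cell_ids
        n_sel = int(round(rule["fraction"] * post_ids.size))
        selected = np.sort(rng.choice(post_ids, size=n_sel, replace=False))
        for post_id in selected:
            partners = rng.choice(rs_ids, size=rule["n_pre"], replace=False)
            for pre_id in partners:
                rows.append(("l23_rs", int(pre_id), post_pop, int(post_id), "nmda", float(g_max), "soma", "intra"))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def couple_columns(config: ModelConfig, populations: dict, rng) -> pd.DataFrame:
    """Intercolumnar ascending excitation, symmetric between the columns;
    the projection onto L2/3 SI cells is boosted by ``si_boost``."""
    inter = config.intercolumnar
    rows = []
    for src_col, dst_col in ((0, 1), (1, 0)):
        for pre_pop, post_pop, k, g_max in inter["rules"]:
            g = float(g_max) * (inter["si_boost"] if post_pop == "l23_si" else 1.0)
            receptor = config.receptor_for_projection(pre_pop, post_pop)
            post_comp = config.target_compartment(pre_pop, post_pop, receptor)
            pre_ids = populations[(src_col, pre_pop)].cell_ids
            for post_id in populations[(dst_col, post_pop)].cell_ids:
                partners = _sample_partners(rng, pre_ids, int(k), None, pre_ids.size)
                for pre_id in partners:
                    rows.append((pre_pop, int(pre_id), post_pop, int(post_id), receptor, g, post_comp, "inter"))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def build_two_column_network(config: ModelConfig | None = None, seed: int = 0) -> TwoColumnNetwork:
    """Realize the full two-column network for one seed."""
    if config is None:
        config = load_model()
    rng = np.random.default_rng(seed)
    n = config.n_per_population
    pops0, classes0, edges0 = build_column(config, 0, rng, id_offset=0)
    pops1, classes1, edges1 = build_column(config, 1, rng, id_offset=n * len(POPULATIONS))
    populations = {**pops0, **pops1}
    nmda0 = assign_nmda_targets(config, populations, 0, rng)
    nmda1 = assign_nmda_targets(config, populations, 1, rng)
    inter = couple_columns(config, populations, rng)
    edges = pd.concat([edges0, edges1, nmda0, nmda1, inter], ignore_index=True)
    cell_column = np.concatenate([np.zeros(len(classes0), dtype=int), np.ones(len(classes1), dtype=int)])
    return TwoColumnNetwork(
        config=config,
        populations=populations,
        cell_class=classes0 + classes1,
        cell_column=cell_column,
        edges=edges,
        seed=seed,
    )


def single_cell_network(config: ModelConfig | None = None, pop: str = "l23_rs", n: int = 1) -> TwoColumnNetwork:
    """A minimal network of ``n`` unconnected cells of one class in column 0,
    used for single-cell characterization and numerical tests."""
    if config is None:
        config = load_model()
    ids = np.arange(n)
    populations = {(0, pop): PopulationSpec(pop, 0, ids)}
    return TwoColumnNetwork(
        config=config,
        populations=populations,
        cell_class=[pop] * n,
        cell_column=np.zeros(n, dtype=int),
        edges=pd.DataFrame(columns=EDGE_COLUMNS),
        seed=None,
    )


def _remove_population(net: TwoColumnNetwork, pop: str) -> None:
    removed_ids = np.concatenate([net.cells_of(c, pop) for c in (0, 1)])
    for c in (0, 1):
        spec = net.populations[(c, pop)]
        net.populations[(c, pop)] = PopulationSpec(pop, c, np.empty(0, dtype=int))
        del spec
    mask = net.edges["pre_id"].isin(removed_ids) | net.edges["post_id"].isin(removed_ids)
    net.edges = net.edges[~mask].reset_index(drop=True)
    net.removed_populations.add(pop)


def _manip_remove_l23_si(net, **_):
    _remove_population(net, "l23_si")


def _manip_remove_ascending_inhibition(net, **_):
    mask = (net.edges["pre_pop"] == "l5_si") & (net.edges["post_pop"] == "l4_fs")
    net.edges = net.edges[~mask].reset_index(drop=True)


def _manip_scale_lateral(net, factor: float = 1.0, **_):
    if not 0.0 <= factor:
        raise ValueError("factor must be non-negative")
    inter = net.edges["scope"] == "inter"
    net.edges.loc[inter, "g_max"] = net.edges.loc[inter, "g_max"] * factor
    if factor == 0.0:
        net.edges = net.edges[~inter].reset_index(drop=True)


def _manip_set_fs_tonic(net, l23: float, l4: float, l5: float, **_):
    net.tonic_overrides.update({"l23_fs": l23, "l4_fs": l4, "l5_fs": l5})


def _manip_asynchronous_topdown(net, **_):
    net.async_topdown = True


MANIPULATIONS = {
    "remove_l23_si": _manip_remove_l23_si,
    "remove_ascending_inhibition": _manip_remove_ascending_inhibition,
    "scale_lateral": _manip_scale_lateral,
    "set_fs_tonic": _manip_set_fs_tonic,
    "asynchronous_topdown": _manip_asynchronous_topdown,
}


def apply_manipulation(net: TwoColumnNetwork, name: str, **params) -> TwoColumnNetwork:
    """Return a modified copy of the network; the base network is untouched."""
    if name not in MANIPULATIONS:
        raise KeyError(f"unknown manipulation {name!r}; supported: {sorted(MANIPULATIONS)}")
    new = net.copy()
    MANIPULATIONS[name](new, **params)
    new.manipulations.append((name, params))
    return new


def in_degree_table(net: TwoColumnNetwork, scope: str = "intra", receptor: str | None = None) -> pd.DataFrame:
    """Mean realized in-degree for every (pre_pop, post_pop) pair, for the
    edge-count audit against the connectivity map."""
    e = net.edges[net.edges["scope"] == scope]
    if receptor is not None:
        e = e[e["receptor"] == receptor]
    else:
        e = e[e["receptor"] != "nmda"]
    counts = e.groupby(["pre_pop", "post_pop", "post_id"]).size().reset_index(name="k")
    return counts.groupby(["pre_pop", "post_pop"])["k"].mean().reset_index(name="mean_in_degree")
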