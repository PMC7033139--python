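"""Summary metrics: cell censuses, vessel morphometry, tumor volume, TGP.

The tumor growth-performance index (TGP) is the number of tumor cells per
angiogenic neo-vessel segment — a measure of how efficiently the tumor
exploits its induced vasculature.  Vessel morphometry follows standard
conventions: a *vascular segment* is the maximal path between junction or
end nodes (graph degree != 2), bifurcation density counts degree >= 3 neo
nodes per tissue volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angiogenesis import VesselNetwork
from .grid import LatticeSpec
from .tumor_cells import CellPopulation

UM3_TO_MM3 = 1e-9


def tumor_volume(population: CellPopulation, lattice: LatticeSpec,
                 live_only: bool = False) -> float:
    """Occupied-site tumor volume in mm^3 (necrotic core included by default)."""
    n = int(population.live_mask().sum()) if live_only else len(population)
    return n * (lattice.h**3) * UM3_TO_MM3


def tgp(total_tc: int, total_neovessels: int) -> float | None:
    """Tumor cells per neo-vessel; None before angiogenesis (no vessels)."""
    if total_neovessels <= 0:
        return None
    return total_tc / total_neovessels


DIAMETER_BINS = np.arange(0.0, 75.0, 5.0)  # 5-um bins, 0-70 um


def _chain_decomposition(network: VesselNetwork):
    """Maximal neo-vessel paths between nodes of degree != 2."""
    g = network.graph
    neo_edges = [(a, b) for a, b, d in g.edges(data=True) if d["kind"] == "neo"]
    if not neo_edges:
        return []
    import networkx as nx

    sub = nx.Graph()
    sub.add_edges_from(neo_edges)
    deg = dict(g.degree())  # degree in the full graph, ring attachments count
    visited = set()
    chains = []

    def walk(start, first):
        chain = [(start, first)]
        prev, cur = start, first
        while deg.get(cur, 0) == 2 and sub.degree(cur) == 2:
            nxt = next(m for m in sub.neighbors(cur) if m != prev)
            chain.append((cur, nxt))
            prev, cur = cur, nxt
            if cur == start:
                break
        return chain

    junctions = [n for n in sub.nodes if deg.get(n, 0) != 2 or sub.degree(n) != 2]
    for j in junctions:
        for m in sub.neighbors(j):
            e0 = frozenset((j, m))
            if e0 in visited:
                continue
            chain = walk(j, m)
            for a, b in chain:
                visited.add(frozenset((a, b)))
            chains.append(chain)
    # pure cycles (every node degree 2) remain
    for a, b in neo_edges:
        if frozenset((a, b)) not in visited:
            chain = walk(a, b)
            for x, y in chain:
                visited.add(frozenset((x, y)))
            chains.append(chain)
    return chains


def vessel_metrics(network: VesselNetwork, use_deformed: bool = False) -> dict:
    """Diameter histogram, vascular-segment-length stats, bifurcation density."""
    g = network.graph
    lat = network.lattice
    key = "d_v_def" if use_deformed else "d_v"
    diam = [d[key] for *_, d in g.edges(data=True) if d["kind"] == "neo"]
    hist, _ = np.histogram(diam, bins=DIAMETER_BINS)

    chains = _chain_decomposition(network)
    lengths_mm = []
    for chain in chains:
        L = sum(g.edges[a, b]["L"] for a, b in chain) * 1e-3  # um -> mm
        lengths_mm.append(L)

    n_neo_nodes = sum(1 for _, d in g.nodes(data=True) if d["kind"] == "neo")
    n_bif = sum(
        1 for n, d in g.nodes(data=True)
        if d["kind"] == "neo" and g.degree(n) >= 3
    )
    ext = lat.extent
    volume_mm3 = ext[0] * ext[1] * ext[2] * UM3_TO_MM3
    return {
        "n_neo_segments": len(diam),
        "n_neo_nodes": n_neo_nodes,
        "diameter_histogram": hist,
        "diameter_bin_edges": DIAMETER_BINS,
        "max_diameter_um": float(max(diam)) if diam else 0.0,
        "n_vascular_segments": len(lengths_mm),
        "mean_segment_length_mm": float(np.mean(lengths_mm)) if lengths_mm else 0.0,
        "min_segment_length_mm": float(np.min(lengths_mm)) if lengths_mm else 0.0,
        "max_segment_length_mm": float(np.max(lengths_mm)) if lengths_mm else 0.0,
        "bifurcation_density_per_mm3": n_bif / volume_mm3,
    }


@dataclass
class MetricsReport:
    """Time series of censuses and morphometry plus one-off event times."""

    records: list[dict] = field(default_factory=list)
    events: dict = field(default_factory=dict)
    parameter_digest: str = ""

    def snapshot(
        self,
        t_days: float,
        population: CellPopulation,
        network: VesselNetwork,
        lattice: LatticeSpec,
        peak_ifp: float = 0.0,
        centroid_drift_um: float = 0.0,
    ) -> dict:
        counts = population.counts()
        vm = vessel_metrics(network)
        row = {
            "t_days": t_days,
            **counts,
            "n_neo_segments": vm["n_neo_segments"],
            "max_diameter_um": vm["max_diameter_um"],
            "mean_segment_length_mm": vm["mean_segment_length_mm"],
            "bifurcation_density_per_mm3": vm["bifurcation_density_per_mm3"],
            "n_neo_nodes": vm["n_neo_nodes"],
            "tumor_volume_mm3": tumor_volume(population, lattice),
            "live_tumor_volume_mm3": tumor_volume(population, lattice, live_only=True),
            # cells per neo-vessel, on both conventions (segments and nodes)
            "tgp": tgp(counts["total"], vm["n_neo_segments"]),
            "tgp_nodes": tgp(counts["total"], vm["n_neo_nodes"]),
            "peak_ifp_mmHg": peak_ifp,
            "centroid_drift_um": centroid_drift_um,
        }
        self.records.append(row)
        return row

    def mark_event(self, name: str, t_days: float) -> None:
        self.events.setdefault(name, t_days)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_tidy_csv(self, path) -> None:
        df = self.to_dataframe().melt(id_vars=["t_days"], var_name="metric",
                                      value_name="value")
        df.to_csv(path, index=False)

    def final(self) -> dict:
        return self.records[-1] if self.records else {}
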