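"""Water-mediated hydrogen-bond connectivity between channel residues.

Per frame, residues and waters (and a hydronium, if present) form the nodes
of a simple undirected graph whose edges are the hydrogen bonds detected in
that frame.  Two protein residues are connected when a shortest-path search
(Dijkstra with unit edge weights, i.e. reachability) finds any path between
them; the connection probability of a pair is the fraction of frames in
which they are connected, replica-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .frames import FrameSeries
from .hbond import DonorAcceptorTable, HBond, HBondCriterion, detect_hbonds, resolve_donors_acceptors
from .hydration import replica_mean_se

__all__ = [
    "ConnectionNetwork",
    "build_hbond_graph",
    "residues_connected",
    "connection_probabilities",
]


@dataclass
class ConnectionNetwork:
    """Pairwise water-mediated connection probabilities between residues."""

    residues: tuple[int, ...]
    probability: np.ndarray  # (n, n) symmetric, diagonal 1
    se: np.ndarray  # (n, n)
    replica_probability: np.ndarray  # (n_replicas, n, n)

    def pair(self, a: int, b: int) -> tuple[float, float]:
        i, j = self.residues.index(a), self.residues.index(b)
        return float(self.probability[i, j]), float(self.se[i, j])


def build_hbond_graph(
    frames: FrameSeries,
    bonds: Iterable[HBond],
    ensure_nodes: Sequence[int] = (),
) -> nx.Graph:
    """Residue-level graph of one frame's hydrogen bonds.

    Nodes are residue ids (protein residues, waters, hydronium alike);
    multiple bonds between two residues collapse to one edge.
    ``ensure_nodes`` adds residues as isolated nodes even when unbonded.
    """
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in ensure_nodes)
    for b in bonds:
        rd = int(frames.resids[b.donor])
        ra = int(frames.resids[b.acceptor])
        if rd != ra:
            g.add_edge(rd, ra)
    return g


def residues_connected(graph: nx.Graph, res_a: int, res_b: int) -> bool:
    """True iff any hydrogen-bonded path joins the two residues.

    Edge weights are unit, so the Dijkstra shortest-path search reduces to
    reachability; a direct residue–residue bond is a path of length 1.
    """
    for r in (res_a, res_b):
        if r not in graph:
            raise KeyError(f"residue {r} is not a node of the bond graph")
    if res_a == res_b:
        return True
    return nx.has_path(graph, res_a, res_b)


def connection_probabilities(
    replicas: Sequence[FrameSeries],
    residues: Sequence[int],
    criterion: HBondCriterion = HBondCriterion(),
    chemistry: dict | None = None,
    tables: Sequence[DonorAcceptorTable] | None = None,
) -> ConnectionNetwork:
    """Fraction of frames each residue pair is hydrogen-bond connected.

    Computed per replica then averaged, with the standard error of the
    replica means.  The diagonal is 1 by convention.
    """
    if len(replicas) < 1:
        raise ValueError("need at least one replica")
    residues = tuple(int(r) for r in residues)
    n = len(residues)
    if tables is None:
        tables = [resolve_donors_acceptors(fr, chemistry=chemistry) for fr in replicas]
    rep = np.zeros((len(replicas), n, n))
    for k, (frames, table) in enumerate(zip(replicas, tables)):
        hits = np.zeros((n, n))
        for t in range(frames.n_frames):
            bonds = detect_hbonds(frames, t, table, criterion)
            g = build_hbond_graph(frames, bonds, ensure_nodes=residues)
            for i in range(n):
                for j in range(i + 1, n):
                    if residues_connected(g, residues[i], residues[j]):
                        hits[i, j] += 1
                        hits[j, i] += 1
        rep[k] = hits / frames.n_frames
        np.fill_diagonal(rep[k], 1.0)
    prob = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            prob[i, j], se[i, j], _ = replica_mean_se(rep[:, i, j])
    return ConnectionNetwork(
        residues=residues, probability=prob, se=se, replica_probability=rep
    )
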