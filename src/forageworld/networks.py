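"""Proximity and visibility networks per round.

Proximity networks are undirected, with edges weighted by the round-average
inverse distance (floored at 1 block) between each pair of players.
Visibility networks are directed: the edge observer -> target is weighted by
the total duration (seconds) the target was inside the observer's field of
view. In-degree therefore measures being watched; out-degree measures
watching others. Eigenvector centrality on the proximity network summarizes
how close a player stays to players who are themselves central.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SocialNetwork:
    """Weighted graph over players; symmetric matrix when undirected."""

    nodes: list[int]
    weights: np.ndarray  # (n, n), zero diagonal
    directed: bool
    kind: str = ""
    meta: dict | None = None

    def edge(self, a: int, b: int) -> float:
        return float(self.weights[self.nodes.index(a), self.nodes.index(b)])

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.nodes)
        for i in range(n):
            for j in range(n):
                if i == j or self.weights[i, j] == 0:
                    continue
                if not self.directed and j < i:
                    continue
                rows.append((self.nodes[i], self.nodes[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def build_networks(session) -> tuple[SocialNetwork, SocialNetwork]:
    """(proximity, visibility) networks from one session's logs."""
    players = session.players
    if len(players) < 2:
        raise ValueError("networks require at least two players")
    times, pos, _ = session.positions_wide()
    n = len(players)
    prox = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(pos[:, i, :] - pos[:, j, :], axis=1)
            w = float((1.0 / np.maximum(d, 1.0)).mean())
            prox[i, j] = prox[j, i] = w
    dt = float(session.meta.get("dt", 0.05))
    vis = np.zeros((n, n))
    vp = session.visibility_log
    vp = vp[vp["kind"] == "player"]
    counts = vp.groupby(["observer", "target"]).size()
    for (obs, tgt), c in counts.items():
        vis[players.index(int(obs)), players.index(int(tgt))] = c * dt
    meta = {"round": session.meta.get("seed"), "condition": session.meta.get("condition")}
    return (
        SocialNetwork(players, prox, directed=False, kind="proximity", meta=meta),
        SocialNetwork(players, vis, directed=True, kind="visibility", meta=meta),
    )


def eigenvector_centrality(net: SocialNetwork) -> dict[int, float]:
    """Principal-eigenvector scores of the (undirected) weight matrix, max-normalized.

    Disconnected graphs are scored per connected component (with a warning),
    then normalized to unit maximum overall. Invariant to uniform weight
    scaling.
    """
    if net.directed:
        raise ValueError("eigenvector centrality is defined here for proximity networks")
    W = net.weights
    n = len(net.nodes)
    # connected components of the nonzero-weight graph
    unvisited = set(range(n))
    components = []
    while unvisited:
        stack = [unvisited.pop()]
        comp = set(stack)
        while stack:
            v = stack.pop()
            for u in range(n):
                if u in unvisited and W[v, u] > 0:
                    unvisited.remove(u)
                    comp.add(u)
                    stack.append(u)
        components.append(sorted(comp))
    if len(components) > 1:
        warnings.warn("proximity network is disconnected; scoring per component")
    scores = np.zeros(n)
    for comp in components:
        sub = W[np.ix_(comp, comp)]
        if len(comp) == 1:
            scores[comp[0]] = 0.0
            continue
        vals, vecs = np.linalg.eigh(sub)
        v = np.abs(vecs[:, -1])
        scores[np.asarray(comp)] = v
    if scores.max() > 0:
        scores = scores / scores.max()
    return {node: float(scores[i]) for i, node in enumerate(net.nodes)}


def degree_summary(net: SocialNetwork) -> pd.DataFrame:
    """Weighted in/out-degree per node; for visibility networks the totals balance."""
    out_deg = net.weights.sum(axis=1)
    in_deg = net.weights.sum(axis=0)
    return pd.DataFrame({"player": net.nodes, "in_degree": in_deg, "out_degree": out_deg})


def average_networks(nets: list[SocialNetwork]) -> SocialNetwork:
    """Mean edge weights across rounds (per individual within a condition)."""
    if not nets:
        raise ValueError("no networks to average")
    nodes = nets[0].nodes
    if any(n.nodes != nodes or n.directed != nets[0].directed for n in nets):
        raise ValueError("networks must share nodes and directedness")
    W = np.mean([n.weights for n in nets], axis=0)
    return SocialNetwork(nodes, W, nets[0].directed, kind=nets[0].kind, meta={"n_rounds": len(nets)})
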