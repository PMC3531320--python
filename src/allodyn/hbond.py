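"""Geometric hydrogen-bond detection, persistence, and network propagation.

A bond is present in a frame when the donor–acceptor distance is at most
r_max (default 3.5 Å) and the H–donor–acceptor angle at most 30°; topologies
without hydrogens (Cα-level synthetic fixtures) fall back to the distance
criterion alone.  Persistence is the fraction of frames, pooled over all
replicas of a state, in which a bond is present.  The network is grown
iteratively from the ligand: residues bonded to the ligand with persistence
>= 30% form level 1, residues bonded to those form level 2, and so on until
no residue is added — tracing candidate signal-transmission paths from the
nucleotide pocket toward a target segment such as the interdomain linker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import Ensemble, Selection, Topology

__all__ = [
    "HBondEvent",
    "HBondGraph",
    "detect_hbonds",
    "pooled_persistence",
    "residue_persistence",
    "propagate_network",
    "PERSISTENCE_THRESHOLD",
]

log = logging.getLogger(__name__)

PERSISTENCE_THRESHOLD = 0.30  # pooled-frame fraction a bond must reach to enter the network


@dataclass
class HBondEvent:
    """One donor→acceptor contact with its per-frame presence mask."""

    donor: int
    acceptor: int
    donor_res: int      # residue index in topology
    acceptor_res: int
    present: np.ndarray  # bool, (n_frames,)

    @property
    def fraction(self) -> float:
        return float(self.present.mean())


def _candidate_pairs(top: Topology, group_a: Selection, group_b: Selection,
                     exclude_neighbors: int) -> list[tuple[int, int]]:
    """Donor/acceptor pairs across the two groups, minus trivial neighbours.

    Bonds within a residue or between sequence neighbours closer than
    ``exclude_neighbors`` in the same chain are skipped (they are sterically
    guaranteed and carry no signal).
    """
    pairs = []
    seen = set()
    a_idx = set(group_a.indices.tolist())
    b_idx = set(group_b.indices.tolist())
    for donors, acceptors in ((a_idx, b_idx), (b_idx, a_idx)):
        for d in donors:
            if not top.atoms[d].is_donor:
                continue
            rd = top.atoms[d].residue_index
            for a in acceptors:
                if not top.atoms[a].is_acceptor or (d, a) in seen:
                    continue
                ra = top.atoms[a].residue_index
                if rd == ra:
                    continue
                res_d, res_a = top.residues[rd], top.residues[ra]
                if (res_d.chain == res_a.chain
                        and abs(res_d.number - res_a.number) <= exclude_neighbors):
                    continue
                seen.add((d, a))
                pairs.append((d, a))
    return pairs


def detect_hbonds(ensemble: Ensemble, group_a: Selection, group_b: Selection,
                  r_max: float = 3.5, angle_max: float = 30.0,
                  heavy_only: bool | None = None,
                  exclude_neighbors: int = 1) -> list[HBondEvent]:
    """Detect hydrogen bonds between two atom groups over all frames.

    ``heavy_only=None`` auto-selects: the angle criterion is applied when the
    topology records donor hydrogens, otherwise only the distance criterion
    is used.  Returns one event per donor→acceptor pair present in at least
    one frame.
    """
    top = ensemble.topology
    if heavy_only is None:
        heavy_only = not top.donor_hydrogens
    pairs = _candidate_pairs(top, group_a, group_b, exclude_neighbors)
    if not pairs:
        log.warning("no donor/acceptor pairs between the two groups")
        return []
    d_idx = np.array([p[0] for p in pairs])
    a_idx = np.array([p[1] for p in pairs])
    diff = ensemble.coords[:, d_idx, :] - ensemble.coords[:, a_idx, :]
    dist = np.sqrt(np.einsum("tpk,tpk->tp", diff, diff))
    present = dist <= r_max

    if not heavy_only:
        cos_max = np.cos(np.deg2rad(angle_max))
        for p, (d, a) in enumerate(pairs):
            if not present[:, p].any():
                continue
            hyds = top.donor_hydrogens.get(d)
            if not hyds:
                present[:, p] = False  # donor without hydrogen cannot satisfy the angle
                continue
            da = ensemble.coords[:, a, :] - ensemble.coords[:, d, :]
            da /= np.linalg.norm(da, axis=1, keepdims=True)
            ok = np.zeros(ensemble.n_frames, dtype=bool)
            for h in hyds:
                dh = ensemble.coords[:, h, :] - ensemble.coords[:, d, :]
                dh /= np.linalg.norm(dh, axis=1, keepdims=True)
                ok |= np.einsum("tk,tk->t", dh, da) >= cos_max
            present[:, p] &= ok

    events = []
    for p, (d, a) in enumerate(pairs):
        if present[:, p].any():
            events.append(HBondEvent(donor=d, acceptor=a,
                                     donor_res=top.atoms[d].residue_index,
                                     acceptor_res=top.atoms[a].residue_index,
                                     present=present[:, p].copy()))
    return events


def pooled_persistence(events_by_replica: list[list[HBondEvent]],
                       frame_counts: list[int] | None = None) -> dict[tuple[int, int], float]:
    """Per-bond persistence pooled over replicas.

    fraction = (present frames summed over replicas) / (total frames over
    replicas).  A bond absent from a replica's event list contributes zero
    present frames but that replica's full frame count to the denominator.
    """
    if frame_counts is None:
        frame_counts = []
        for evs in events_by_replica:
            if not evs:
                raise ValueError("cannot infer frame count for a replica with no events; "
                                 "pass frame_counts explicitly")
            frame_counts.append(len(evs[0].present))
    total = sum(frame_counts)
    if total == 0:
        raise ValueError("zero total frames")
    counts: dict[tuple[int, int], int] = {}
    for evs in events_by_replica:
        for ev in evs:
            key = (ev.donor, ev.acceptor)
            counts[key] = counts.get(key, 0) + int(ev.present.sum())
    return {k: c / total for k, c in counts.items()}


def residue_persistence(events_by_replica: list[list[HBondEvent]],
                        frame_counts: list[int],
                        topology: Topology) -> dict[tuple[int, int], dict]:
    """Residue-pair persistence: the best atom-level bond per residue pair.

    Returns {(res_i, res_j) sorted: {"persistence", "per_replica", "atoms"}}
    where the residue-pair value is the maximum pooled persistence over the
    atom-level bonds connecting the pair, and per-replica fractions come
    from that same bond.
    """
    total = sum(frame_counts)
    per_bond: dict[tuple[int, int], list[int]] = {}
    bond_res: dict[tuple[int, int], tuple[int, int]] = {}
    for r, evs in enumerate(events_by_replica):
        for ev in evs:
            key = (ev.donor, ev.acceptor)
            per_bond.setdefault(key, [0] * len(events_by_replica))[r] = int(ev.present.sum())
            bond_res[key] = (ev.donor_res, ev.acceptor_res)
    out: dict[tuple[int, int], dict] = {}
    for key, counts in per_bond.items():
        ri, rj = bond_res[key]
        rkey = (min(ri, rj), max(ri, rj))
        pooled = sum(counts) / total
        rec = out.get(rkey)
        if rec is None or pooled > rec["persistence"]:
            out[rkey] = {
                "persistence": pooled,
                "per_replica": [c / f for c, f in zip(counts, frame_counts)],
                "atoms": key,
            }
    return out


@dataclass
class HBondGraph:
    """Layered residue network grown from the ligand.

    Nodes are residue indices (the pseudo-node -1 is the ligand source);
    node attribute ``level`` is the iteration at which the residue entered.
    Edge attribute ``persistence`` is the pooled fraction.
    """

    graph: nx.Graph
    threshold: float
    target_range: tuple[int, int] | None = None
    target_reached: bool = False
    target_depth: int | None = None
    meta: dict = field(default_factory=dict)

    SOURCE: int = -1

    def nodes_at_level(self, level: int) -> list[int]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if n != self.SOURCE and d.get("level") == level)

    @property
    def residues(self) -> list[int]:
        return sorted(n for n in self.graph.nodes if n != self.SOURCE)

    def edge_table(self, topology: Topology) -> list[dict]:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append({
                "residue_a": "LIG" if u == self.SOURCE else str(topology.residues[u]),
                "residue_b": "LIG" if v == self.SOURCE else str(topology.residues[v]),
                "persistence": d["persistence"],
                "level": d.get("level", ""),
                "per_replica": d.get("per_replica", []),
            })
        return rows


def propagate_network(ensembles: list[Ensemble], ligand: Selection,
                      target_range: tuple[int, int] | None = None,
                      threshold: float = PERSISTENCE_THRESHOLD,
                      max_depth: int | None = None,
                      r_max: float = 3.5, angle_max: float = 30.0,
                      heavy_only: bool | None = None,
                      exclude_neighbors: int = 1) -> HBondGraph:
    """Grow the persistent H-bond network from the ligand toward a target.

    All replicas must share a topology.  Persistence is pooled over the
    replicas; residue-level edges use the best atom-level bond.  Iteration:
    level 0 is the ligand, level k+1 collects residues bonded at >= threshold
    persistence to any level-k residue and not yet included; it stops when
    nothing is added or ``max_depth`` is hit.  Afterwards every qualifying
    edge among included nodes is reported.
    """
    if len(ligand) == 0:
        raise ValueError("ligand selection is empty")
    top = ensembles[0].topology
    if any(e.topology.n_atoms != top.n_atoms for e in ensembles):
        raise ValueError("replicas do not share a topology")
    for i in ligand.indices:
        if i >= top.n_atoms:
            raise ValueError("ligand selection outside topology")

    all_sel = Selection(np.arange(top.n_atoms), provenance="all atoms")
    events_by_replica = [
        detect_hbonds(e, all_sel, all_sel, r_max=r_max, angle_max=angle_max,
                      heavy_only=heavy_only, exclude_neighbors=exclude_neighbors)
        for e in ensembles
    ]
    frame_counts = [e.n_frames for e in ensembles]
    res_pers = residue_persistence(events_by_replica, frame_counts, top)

    lig_res = {top.atoms[i].residue_index for i in ligand.indices}
    SOURCE = HBondGraph.SOURCE

    # adjacency over the persistence threshold, with ligand residues folded
    # into the single source node
    adj: dict[int, dict[int, dict]] = {}
    for (ri, rj), rec in res_pers.items():
        if rec["persistence"] < threshold:
            continue
        ui = SOURCE if ri in lig_res else ri
        vj = SOURCE if rj in lig_res else rj
        if ui == vj:
            continue
        for u, v in ((ui, vj), (vj, ui)):
            cur = adj.setdefault(u, {}).get(v)
            if cur is None or rec["persistence"] > cur["persistence"]:
                adj[u][v] = rec

    g = nx.Graph()
    g.add_node(SOURCE, level=0, label="LIG")
    frontier = [SOURCE]
    level = 0
    while frontier and (max_depth is None or level < max_depth):
        level += 1
        nxt = []
        for u in frontier:
            for v, rec in sorted(adj.get(u, {}).items()):
                if v not in g:
                    g.add_node(v, level=level, resid=top.residues[v].number)
                    nxt.append(v)
                if not g.has_edge(u, v):
                    g.add_edge(u, v, persistence=rec["persistence"],
                               per_replica=rec["per_replica"], level=level)
        frontier = nxt

    # report every qualifying edge among the included nodes
    for u in list(g.nodes):
        for v, rec in adj.get(u, {}).items():
            if v in g and not g.has_edge(u, v):
                g.add_edge(u, v, persistence=rec["persistence"],
                           per_replica=rec["per_replica"],
                           level=max(g.nodes[u]["level"], g.nodes[v]["level"]))

    reached = False
    depth = None
    if target_range is not None:
        lo, hi = target_range
        hits = [g.nodes[n]["level"] for n in g.nodes
                if n != SOURCE and lo <= top.residues[n].number <= hi]
        if hits:
            reached = True
            depth = min(hits)
    return HBondGraph(graph=g, threshold=threshold, target_range=target_range,
                      target_reached=reached, target_depth=depth,
                      meta={"r_max_A": r_max, "angle_max_deg": angle_max,
                            "replicas": len(ensembles),
                            "frames": frame_counts})
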