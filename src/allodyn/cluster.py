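"""GROMOS conformational clustering and snapshot-to-snapshot RMSD maps.

The clustering counts, for every unassigned frame, how many other frames
lie within an RMSD cutoff after least-squares superposition; the frame
with the most neighbours seeds a cluster, it and its neighbours are
removed, and the procedure repeats until every frame is assigned.  Ties
on the neighbour count go to the earliest frame index so the partition is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble, Selection, select
from .ed import kabsch

__all__ = ["ClusterSet", "pairwise_rmsd", "gromos_cluster", "binding_site_cluster",
           "DOMAIN_CUTOFF", "SITE_CUTOFF"]

DOMAIN_CUTOFF = 5.0  # Å (0.5 nm), whole-domain clustering cutoff
SITE_CUTOFF = 2.0    # Å (0.2 nm), binding-site clustering cutoff


def _fit_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares-fit RMSD between two coordinate sets."""
    R, t = kabsch(a, b)
    d = a @ R.T + t - b
    return float(np.sqrt((d * d).sum() / a.shape[0]))


def pairwise_rmsd(ensemble_a: Ensemble, ensemble_b: Ensemble,
                  selection: Selection) -> np.ndarray:
    """Frame-by-frame least-squares Cα RMSD cross-map (Å).

    Entry (s, t) is the fitted RMSD between frame s of the first ensemble
    and frame t of the second; with the same ensemble twice the map is
    symmetric with a zero diagonal.  The two trajectories may have
    different lengths.
    """
    A = ensemble_a.subset(selection)
    B = ensemble_b.subset(selection)
    if A.shape[1] != B.shape[1]:
        raise ValueError("selection resolves to different atom counts in the two ensembles")
    same = ensemble_a is ensemble_b or (A.shape == B.shape and np.array_equal(A, B))
    out = np.zeros((A.shape[0], B.shape[0]))
    for s in range(A.shape[0]):
        t0 = s + 1 if same else 0
        for t in range(t0, B.shape[0]):
            out[s, t] = _fit_rmsd(A[s], B[t])
    if same:
        out = out + out.T
    return out


@dataclass
class ClusterSet:
    """A GROMOS partition of frames."""

    assignments: np.ndarray     # per-frame cluster id, 0-based, in discovery order
    centers: np.ndarray         # per-cluster representative frame index
    populations: np.ndarray     # per-cluster fraction of frames
    cutoff: float               # Å
    selection: str = ""

    @property
    def n_clusters(self) -> int:
        return int(self.centers.size)


def gromos_cluster(ensemble: Ensemble, selection: Selection, cutoff: float,
                   rmsd_matrix: np.ndarray | None = None) -> ClusterSet:
    """Cluster frames by iterative neighbour counting under an RMSD cutoff.

    The most-connected unassigned frame becomes the cluster centre, taking
    its neighbours with it; ties are broken by the earliest frame index.
    A precomputed RMSD matrix may be supplied to avoid recomputation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ensemble.n_frames < 1:
        raise ValueError("no frames to cluster")
    D = pairwise_rmsd(ensemble, ensemble, selection) if rmsd_matrix is None else rmsd_matrix
    n = D.shape[0]
    neighbor = D <= cutoff
    unassigned = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centers = []
    cid = 0
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the first maximum: earliest index
        members = np.nonzero(neighbor[center] & unassigned)[0]
        assignments[members] = cid
        unassigned[members] = False
        centers.append(center)
        cid += 1
    populations = np.bincount(assignments, minlength=cid) / n
    return ClusterSet(assignments=assignments, centers=np.array(centers),
                      populations=populations, cutoff=cutoff,
                      selection=selection.provenance)


def binding_site_cluster(ensemble: Ensemble, site_residues: str,
                         cutoff: float = SITE_CUTOFF) -> ClusterSet:
    """GROMOS clustering restricted to the Cα atoms of a residue-range site.

    ``site_residues`` is a ;-separated range list, e.g. "2-15;160-225;360-390"
    (the nucleotide-binding site), with the tighter 2 Å (0.2 nm) cutoff.
    """
    sel = select(ensemble.topology, f"CA and resid {site_residues}")
    return gromos_cluster(ensemble, sel, cutoff)
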