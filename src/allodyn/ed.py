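"""Essential-dynamics preprocessing: superposition, Cα PCA, mode filtering.

Each trajectory is rigid-body superposed on the Cα atoms of its starting
conformation, the Cartesian covariance of the Cα coordinates is
eigendecomposed, and the trajectory is reconstructed from the top principal
components (default 10).  The filtered trajectory is the input for the
distance-fluctuation analysis; with all 3N components the filter is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble, Selection

__all__ = ["EDModel", "kabsch", "align", "fit_ed", "filter_trajectory"]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto reference.

    Returns (R, t) such that ``mobile @ R.T + t`` minimises the RMSD to
    ``reference``.  Proper rotation enforced (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (mobile - mu_m).T @ (reference - mu_r)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - mu_m @ R.T
    return R, t


def _check_not_collinear(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise ValueError("alignment needs at least 3 atoms")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("alignment selection is (near-)collinear; superposition is degenerate")


def align(ensemble: Ensemble, selection: Selection, reference: np.ndarray | None = None) -> Ensemble:
    """Superpose every frame onto a reference using the given fit selection.

    The default reference is the first frame (the starting conformation of
    the run).  The rotation/translation fit on the selection is applied to
    all atoms of the frame.
    """
    ref_full = np.asarray(reference, dtype=float) if reference is not None else ensemble.coords[0]
    if ref_full.ndim != 2:
        raise ValueError("reference must be a single coordinate set (n_atoms, 3)")
    if ref_full.shape[0] == len(selection):
        ref_sel = ref_full
    elif ref_full.shape[0] == ensemble.topology.n_atoms:
        ref_sel = ref_full[selection.indices]
    else:
        raise ValueError("reference atom count matches neither topology nor selection")
    _check_not_collinear(ref_sel)

    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        R, t = kabsch(ensemble.coords[f, selection.indices], ref_sel)
        out[f] = ensemble.coords[f] @ R.T + t
    return ensemble.with_coords(out)


@dataclass
class EDModel:
    """Principal components of the Cα Cartesian covariance.

    eigenvalues are in Å², sorted descending; eigenvectors are orthonormal
    columns of a (3N, 3N) matrix with a deterministic sign convention (first
    component of largest magnitude is positive).
    """

    mean: np.ndarray            # (3N,) time-mean of the flattened selection coords
    eigenvalues: np.ndarray     # (3N,) descending, >= 0
    eigenvectors: np.ndarray    # (3N, 3N), columns are modes
    n_components: int = 10
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-8):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(ev < -1e-8):
            raise ValueError("negative eigenvalue beyond tolerance")
        if not (1 <= self.n_components <= ev.size):
            raise ValueError("n_components out of range")


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| component of each mode > 0."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_ed(ensemble: Ensemble, selection: Selection, n_components: int = 10) -> EDModel:
    """Covariance PCA of the aligned Cα coordinates.

    Population (1/T) normalisation; trace(C) equals the eigenvalue sum by
    construction.  Requires at least 2 frames.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    X = ensemble.subset(selection).reshape(ensemble.n_frames, -1)
    mean = X.mean(axis=0)
    D = X - mean
    C = D.T @ D / ensemble.n_frames
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    k = min(n_components, evals.size)
    return EDModel(mean=mean, eigenvalues=evals, eigenvectors=evecs, n_components=k,
                   reference=ensemble.coords[0, selection.indices].copy())


def filter_trajectory(ensemble: Ensemble, model: EDModel, selection: Selection, k: int | None = None) -> Ensemble:
    """Reconstruct the selection coordinates from the first k principal modes.

    Each frame becomes mean + sum over the first k modes of its projection;
    atoms outside the selection are left untouched.  k = 3N reproduces the
    input exactly.
    """
    k = model.n_components if k is None else k
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > model.eigenvalues.size:
        raise ValueError(f"k={k} exceeds the number of modes {model.eigenvalues.size}")
    X = ensemble.subset(selection).reshape(ensemble.n_frames, -1)
    V = model.eigenvectors[:, :k]
    proj = (X - model.mean) @ V
    Xk = model.mean + proj @ V.T
    out = ensemble.coords.copy()
    out[:, selection.indices, :] = Xk.reshape(ensemble.n_frames, len(selection), 3)
    return ensemble.with_coords(out)
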