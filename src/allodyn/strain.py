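"""Geometric strain profiles and conformational mobility.

The strain of residue i in frame t measures how much its local network of
Cα–Cα distances deviates from the time average:

    p_i(t) = sum_j f(<d_ij>) (d_ij(t) - <d_ij>)^2  /  sum_j f(<d_ij>)

where f is a logistic switch, f(d) = 1 / (1 + exp((d - d0)/w)), which
confines the sum to residues within about d0 = 7 Å of residue i.  Hinge
residues, whose neighbourhood rearranges as quasi-rigid domains move
relative to each other, stand out as strain peaks.  Conformational
mobility is the time average of p_i per run, summarised across replicas
by mean and standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Ensemble, Selection
from .fluctuation import _pairwise_distances

__all__ = [
    "StrainParams",
    "StrainProfile",
    "MobilityProfile",
    "MobilityDifference",
    "sigmoid_weight",
    "geometric_strain",
    "mobility",
    "mobility_difference",
    "classify_flexibility",
    "FLEX_LOW",
    "FLEX_HIGH",
]

log = logging.getLogger(__name__)

FLEX_LOW = 0.4   # Å²; below this a residue is classed rigid
FLEX_HIGH = 2.0  # Å²; above this a residue is classed flexible


@dataclass(frozen=True)
class StrainParams:
    """Neighbour-switch parameters for the strain sum.

    d0 is the midpoint of the logistic cutoff (Å); w its steepness (Å).
    ``normalized`` divides by the total neighbour weight so values are
    comparable across residues of different packing density (and to the
    flexibility thresholds); the raw weighted sum is kept as an option.
    """

    d0: float = 7.0
    w: float = 0.5
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.w <= 0:
            raise ValueError("d0 and w must be positive")


def sigmoid_weight(d, params: StrainParams = StrainParams()):
    """Logistic neighbour weight f(d) in [0, 1]; f(d0) = 0.5, decreasing."""
    d = np.asarray(d, dtype=float)
    z = np.clip((d - params.d0) / params.w, -500.0, 500.0)  # avoid exp overflow
    return 1.0 / (1.0 + np.exp(z))


@dataclass
class StrainProfile:
    values: np.ndarray          # (n_frames, n_residues) strain, Å²
    resids: np.ndarray
    params: StrainParams
    mean_distances: np.ndarray  # (n, n) time-averaged distance matrix used for weights
    state: str = ""
    replica: str = ""

    @property
    def time_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


def geometric_strain(ensemble: Ensemble, selection: Selection,
                     params: StrainParams = StrainParams()) -> StrainProfile:
    """Per-residue, per-frame geometric strain on a Cα selection.

    Weights are evaluated on the time-averaged distances so each residue's
    neighbour set is fixed over the run.  A residue with (numerically) no
    neighbours gets strain 0 and a warning.
    """
    if ensemble.n_frames < 2:
        raise ValueError("geometric strain needs at least 2 frames")
    d = _pairwise_distances(ensemble.subset(selection))
    dbar = d.mean(axis=0)
    W = sigmoid_weight(dbar, params)
    np.fill_diagonal(W, 0.0)
    wtot = W.sum(axis=1)
    dev2 = (d - dbar) ** 2
    p = np.einsum("ij,tij->ti", W, dev2)
    if params.normalized:
        isolated = wtot < 1e-12
        if isolated.any():
            log.warning("%d residue(s) have no neighbours within the cutoff; strain set to 0",
                        int(isolated.sum()))
        denom = np.where(isolated, 1.0, wtot)
        p = np.where(isolated[None, :], 0.0, p / denom[None, :])
    resids = ensemble.topology.residue_numbers(selection.indices)
    return StrainProfile(values=p, resids=resids, params=params, mean_distances=dbar,
                         state=ensemble.state, replica=ensemble.replica)


@dataclass
class MobilityProfile:
    """Time-averaged strain per run, with replica mean and standard error."""

    per_run: np.ndarray         # (n_replicas, n_residues) per-run time means, Å²
    resids: np.ndarray
    state: str = ""
    replicas: tuple = ()

    @property
    def mean(self) -> np.ndarray:
        return self.per_run.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        """Standard error of the mean across runs; NaN for a single run."""
        r = self.per_run.shape[0]
        if r < 2:
            return np.full(self.per_run.shape[1], np.nan)
        return self.per_run.std(axis=0, ddof=1) / np.sqrt(r)


def mobility(profiles: list[StrainProfile]) -> MobilityProfile:
    """Combine per-replica strain profiles into a mobility profile."""
    if not profiles:
        raise ValueError("no strain profiles given")
    resids = profiles[0].resids
    for pr in profiles[1:]:
        if not np.array_equal(pr.resids, resids):
            raise ValueError("strain profiles have different residue axes")
    per_run = np.vstack([pr.time_mean for pr in profiles])
    return MobilityProfile(per_run=per_run, resids=resids,
                           state=profiles[0].state,
                           replicas=tuple(pr.replica for pr in profiles))


@dataclass
class MobilityDifference:
    """Significance-filtered per-residue mobility difference between states."""

    delta: np.ndarray           # raw m_a - m_b, Å²
    error: np.ndarray           # propagated SE, sqrt(SE_a^2 + SE_b^2)
    mask: np.ndarray            # True where |delta| <= k * error (not significant)
    resids: np.ndarray
    states: tuple = ("", "")
    k: float = 1.0
    peaks: list = field(default_factory=list)

    @property
    def filtered(self) -> np.ndarray:
        """The reported histogram: masked residues set to 0."""
        return np.where(self.mask, 0.0, self.delta)


def mobility_difference(a: MobilityProfile, b: MobilityProfile, k: float = 1.0) -> MobilityDifference:
    """State difference Δ_i = m_i(a) − m_i(b) with error propagation.

    Differences within k standard errors (default k = 1) are masked to zero;
    the surviving residues are returned as peaks sorted by |Δ|.  A run
    without replicas has undefined SE; its error contribution is treated as
    zero (every difference is then retained) with a warning.
    """
    if not np.array_equal(a.resids, b.resids):
        raise ValueError("mobility profiles have different residue axes")
    delta = a.mean - b.mean
    se_a, se_b = a.se, b.se
    if np.isnan(se_a).any() or np.isnan(se_b).any():
        log.warning("single-replica mobility: SE undefined, treated as 0 in the significance filter")
    err = np.sqrt(np.nan_to_num(se_a) ** 2 + np.nan_to_num(se_b) ** 2)
    mask = np.abs(delta) <= k * err
    order = np.argsort(-np.abs(np.where(mask, 0.0, delta)))
    peaks = [(int(a.resids[i]), float(delta[i])) for i in order if not mask[i] and delta[i] != 0.0]
    return MobilityDifference(delta=delta, error=err, mask=mask, resids=a.resids,
                              states=(a.state, b.state), k=k, peaks=peaks)


def classify_flexibility(mob: MobilityProfile, low: float = FLEX_LOW, high: float = FLEX_HIGH) -> np.ndarray:
    """Three-level flexibility labels per residue.

    Strict inequalities: mobility < low -> "rigid", > high -> "flexible",
    otherwise (boundaries included) -> "intermediate".
    """
    if not low < high:
        raise ValueError("low threshold must be below high threshold")
    m = mob.mean
    labels = np.full(m.shape, "intermediate", dtype=object)
    labels[m < low] = "rigid"
    labels[m > high] = "flexible"
    return labels
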