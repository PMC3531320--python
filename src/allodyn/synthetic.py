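"""Synthetic multi-replica ensembles with planted, analytically known structure.

The generator stands in for molecular dynamics with the statistical
features the analysis pipeline assumes, all planted and therefore
verifiable:

* rigid blocks — helical Cα segments held by stiff elastic-network
  springs, joined by soft hinge residues, so intra-block distance
  fluctuations are small and inter-block ones large;
* state dependence — per-state stiffness multipliers per block and per
  hinge emulate ligand-induced rigidification (apo / ATP / ADP-like
  states);
* persistent contact chains — donor/acceptor pseudo-atoms toggled
  between bonded (2.9 Å) and parked (far) geometry by independent
  Bernoulli draws at a set occupancy, planting a ligand→…→target
  hydrogen-bond path plus low-occupancy decoys.

Frames are drawn exactly from the multivariate Gaussian whose covariance
is the temperature-scaled pseudo-inverse of the elastic-network Hessian
(six rigid-body modes removed), so the sampled fluctuations have a known
closed form.  All randomness flows from integer seeds; regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Atom, Ensemble, Residue, Selection, Topology

__all__ = [
    "ToyProteinSpec",
    "ToyStructure",
    "GeneratedEnsembleSet",
    "build_toy_structure",
    "enm_covariance",
    "rigid_blocks_covariance",
    "model_covariance",
    "sample_ensemble",
    "rigid_body_images",
    "make_state_set",
]

_CA_SPACING = 3.8  # consecutive Cα distance, Å


@dataclass(frozen=True)
class ToyProteinSpec:
    """Blueprint of a toy multi-domain protein and its planted features.

    Spring constants are in units of kT/Å² at ``temperature = 1``;
    the sampled per-mode variance is temperature / (spring eigenvalue).
    Defaults place intra-block pair-distance variances near 0.05 Å² and
    inter-block ones near 1 Å², straddling the 0.3 Å² rigidity threshold.
    """

    block_sizes: tuple[int, ...] = (20, 20)
    hinge_len: int = 1                  # hinge residues between consecutive blocks
    contact_cutoff: float = 8.0         # Å, elastic-network spring range
    block_spring: float = 5.0           # kT/Å², springs within a block
    hinge_spring: float = 0.02          # kT/Å², contact springs involving a hinge or crossing blocks
    background_spring: float = 0.02     # kT/Å², weak all-pair spring; removes the
                                        # torsional soft mode a thin hinge leaves open
    temperature: float = 1.0
    covariance: str = "enm"             # "enm" or "rigid_blocks"
    block_translation_var: float = 0.95  # Å², rigid_blocks: relative inter-block translation variance
    jitter_var: float = 0.025           # Å², rigid_blocks: per-coordinate atomic jitter
    turn_angle: float = 80.0            # degrees, chain direction change at each hinge
    planted_chain: tuple[int, ...] = () # residue numbers: ligand->first->...->last
    chain_occupancy: float = 0.9
    decoy_contacts: tuple[tuple[int, int], ...] = ()  # (donor resnum, acceptor resnum)
    decoy_occupancy: float = 0.1

    def __post_init__(self) -> None:
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not (0 <= self.chain_occupancy <= 1 and 0 <= self.decoy_occupancy <= 1):
            raise ValueError("occupancies must be in [0, 1]")
        if self.block_spring <= 0 or self.hinge_spring <= 0:
            raise ValueError("spring constants must be positive")

    @property
    def n_residues(self) -> int:
        return sum(self.block_sizes) + self.hinge_len * (len(self.block_sizes) - 1)


@dataclass
class ToyStructure:
    topology: Topology
    ref_coords: np.ndarray      # (n_atoms, 3) with all planted bonds off
    ca_indices: np.ndarray
    block_of: np.ndarray        # per residue: block id, -1 for hinge residues
    hinge_residues: np.ndarray  # residue numbers of hinges
    ligand: Selection | None = None


def _helix_steps(n: int) -> np.ndarray:
    """Step vectors of an ideal α-helix-like curve, each of length 3.8 Å."""
    rise = 1.5
    dtheta = np.deg2rad(100.0)
    radius = np.sqrt(_CA_SPACING ** 2 - rise ** 2) / (2.0 * np.sin(dtheta / 2.0))
    t = np.arange(n + 1)
    pts = np.stack([radius * np.cos(dtheta * t), radius * np.sin(dtheta * t), rise * t], axis=1)
    return np.diff(pts, axis=0)


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def build_toy_structure(spec: ToyProteinSpec) -> ToyStructure:
    """Fold the Cα chain and attach donor/acceptor pseudo-atoms.

    Blocks are helical segments (consecutive Cα spacing 3.8 Å throughout);
    the chain direction turns at every hinge so blocks form an open,
    self-avoiding arrangement.  Every residue carries DON and ACC
    pseudo-atoms; acceptors start in the parked (non-bonded) position.
    A LIG residue is appended when a contact chain is planted.
    """
    steps: list[np.ndarray] = []
    kinds: list[int] = []  # block id per residue, -1 for hinge
    frame = np.eye(3)
    for b, size in enumerate(spec.block_sizes):
        for s in _helix_steps(size - 1 if b == 0 else size):
            steps.append(frame @ s)
        kinds.extend([b] * size)
        if b < len(spec.block_sizes) - 1:
            for _ in range(spec.hinge_len):
                steps.append(frame @ np.array([0.0, 0.0, _CA_SPACING]))
            kinds.extend([-1] * spec.hinge_len)
            frame = frame @ _rotation(np.array([0.0, 1.0, 0.0]), spec.turn_angle)
    ca = np.vstack([np.zeros(3), np.cumsum(np.vstack(steps), axis=0)])
    n_res = spec.n_residues
    assert ca.shape[0] == n_res

    # self-avoidance: non-adjacent Cα must keep clearance
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    far = ~np.eye(n_res, dtype=bool) & ~np.eye(n_res, k=1, dtype=bool) & ~np.eye(n_res, k=-1, dtype=bool)
    if d[far].min() < 3.5:
        raise ValueError("infeasible geometry: blocks overlap; change block sizes or turn angle")

    residues = [Residue(chain="A", number=i + 1, name="GLY") for i in range(n_res)]
    atoms: list[Atom] = []
    for i in range(n_res):
        atoms.append(Atom(name="CA", element="C", residue_index=i))
        atoms.append(Atom(name="DON", element="N", residue_index=i, is_donor=True))
        atoms.append(Atom(name="ACC", element="O", residue_index=i, is_acceptor=True))
    ligand = None
    if spec.planted_chain:
        for r in spec.planted_chain:
            if not 1 <= r <= n_res:
                raise ValueError(f"planted chain residue {r} not in topology")
        residues.append(Residue(chain="A", number=n_res + 1, name="LIG"))
        atoms.append(Atom(name="DON", element="N", residue_index=n_res, is_donor=True))
        atoms.append(Atom(name="ACC", element="O", residue_index=n_res, is_acceptor=True))
        ligand = Selection(np.array([3 * n_res, 3 * n_res + 1]), provenance="LIG pseudo-ligand")
    topology = Topology(residues=residues, atoms=atoms, ligand=ligand)

    block_of = np.array(kinds)
    hinges = np.array([i + 1 for i in range(n_res) if kinds[i] == -1])
    struct = ToyStructure(topology=topology, ref_coords=np.zeros((len(atoms), 3)),
                          ca_indices=np.arange(0, 3 * n_res, 3), block_of=block_of,
                          hinge_residues=hinges, ligand=ligand)
    struct.ref_coords = _place_atoms(struct, spec, ca[None, :, :],
                                     bonds_on={})[0]
    return struct


def _pair_springs(spec: ToyProteinSpec, ca: np.ndarray, block_of: np.ndarray,
                  multipliers: dict | None) -> list[tuple[int, int, float]]:
    mult = multipliers or {}
    block_mult = mult.get("blocks", (1.0,) * len(spec.block_sizes))
    hinge_mult = mult.get("hinge", 1.0)
    n = ca.shape[0]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    springs = []
    for i in range(n):
        for j in range(i + 1, n):
            bi, bj = block_of[i], block_of[j]
            if bi == bj and bi >= 0:
                # fully triangulated block: stiff springs at all ranges make
                # the domain genuinely quasi-rigid
                k = spec.block_spring * block_mult[bi]
            elif d[i, j] <= spec.contact_cutoff:
                k = spec.hinge_spring * hinge_mult
            else:
                k = spec.background_spring
            if k > 0:
                springs.append((i, j, k))
    return springs


def enm_covariance(structure: ToyStructure, spec: ToyProteinSpec,
                   multipliers: dict | None = None) -> np.ndarray:
    """Cα covariance (3n × 3n, Å²): temperature × pseudo-inverse Hessian.

    The anisotropic-network Hessian is assembled from pair springs within
    the contact cutoff; exactly six zero modes (rigid body) are removed.
    A seventh near-zero mode means the structure is mechanically
    disconnected and is an error.
    """
    ca = structure.ref_coords[structure.ca_indices]
    n = ca.shape[0]
    H = np.zeros((3 * n, 3 * n))
    for i, j, k in _pair_springs(spec, ca, structure.block_of, multipliers):
        e = ca[i] - ca[j]
        e /= np.linalg.norm(e)
        K = k * np.outer(e, e)
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] += K
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] += K
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= K
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= K
    evals, evecs = np.linalg.eigh(H)
    scale = evals[-1]
    if evals[6] < 1e-9 * scale:
        raise ValueError("elastic network is disconnected (more than six zero modes)")
    inv = np.zeros_like(evals)
    inv[6:] = 1.0 / evals[6:]
    return spec.temperature * (evecs * inv) @ evecs.T


def _rigid_block_mixing(structure: ToyStructure, spec: ToyProteinSpec,
                        multipliers: dict | None):
    """Mixing weights and variances of the rigid-blocks Gaussian model.

    Residue i's displacement is sum_b w_ib T_b + jitter, with T_b the
    isotropic translation of block b (hinge residues take the mean of the
    adjacent blocks).  Returns (W, trans_var, jitter_var_per_residue).
    """
    mult = multipliers or {}
    block_mult = np.asarray(mult.get("blocks", (1.0,) * len(spec.block_sizes)), dtype=float)
    n_blocks = len(spec.block_sizes)
    b = structure.block_of
    n = b.size
    W = np.zeros((n, n_blocks))
    jit = np.empty(n)
    for i in range(n):
        if b[i] >= 0:
            W[i, b[i]] = 1.0
            jit[i] = spec.jitter_var / block_mult[b[i]]
        else:
            prev = b[:i][b[:i] >= 0][-1]
            nxt = b[i:][b[i:] >= 0][0]
            W[i, prev] += 0.5
            W[i, nxt] += 0.5
            jit[i] = spec.jitter_var
    trans_var = (spec.block_translation_var / 2.0) / block_mult
    return W, trans_var * spec.temperature, jit * spec.temperature


def rigid_blocks_covariance(structure: ToyStructure, spec: ToyProteinSpec,
                            multipliers: dict | None = None) -> np.ndarray:
    """Cα covariance of the rigid-blocks model (3n × 3n, Å²)."""
    W, tv, jit = _rigid_block_mixing(structure, spec, multipliers)
    n = W.shape[0]
    Cres = (W * tv) @ W.T + np.diag(jit)  # per-axis residue-residue covariance
    return np.kron(Cres, np.eye(3))


def model_covariance(structure: ToyStructure, spec: ToyProteinSpec,
                     multipliers: dict | None = None) -> np.ndarray:
    """Analytic Cα covariance of the configured sampling model."""
    if spec.covariance == "enm":
        return enm_covariance(structure, spec, multipliers)
    if spec.covariance == "rigid_blocks":
        return rigid_blocks_covariance(structure, spec, multipliers)
    raise ValueError(f"unknown covariance model {spec.covariance!r}")


def _place_atoms(structure: ToyStructure, spec: ToyProteinSpec,
                 ca_frames: np.ndarray, bonds_on: dict) -> np.ndarray:
    """Assemble full-atom coordinates for each frame from Cα positions.

    A bystander DON sits 0.9 Å outward (away from the frame centroid) of
    its Cα.  The contact machinery of planted bonds is realised on a
    detached rail lattice well outside the structure, so that planted
    contacts are, by construction, the only donor–acceptor contacts the
    detection geometry can ever see: each participating donor (including
    the LIG donor) owns a rail slot 8 Å from its neighbours; an acceptor
    whose bond is ON sits 2.9 Å from its partner donor's slot, and every
    other acceptor is parked on a second rail 10 Å above the first.
    Residue-level bond identity, occupancy statistics and detection
    behaviour are exactly as planted; the rail positions carry no other
    signal.
    """
    top = structure.topology
    n_frames = ca_frames.shape[0]
    n_res_chain = structure.block_of.size
    coords = np.zeros((n_frames, top.n_atoms, 3))
    centroid = ca_frames.mean(axis=1)  # (T, 3)

    participating_donors = sorted(
        ({r - 1 for r in spec.planted_chain[:-1]} if spec.planted_chain else set())
        | {d - 1 for d, _ in spec.decoy_contacts}
    )
    if spec.planted_chain:
        participating_donors.append(n_res_chain)  # LIG donor
    slot_of = {r: k for k, r in enumerate(participating_donors)}

    def outward(f, ridx):
        v = ca_frames[f, ridx] - centroid[f]
        nv = np.linalg.norm(v)
        return v / nv if nv > 1e-9 else np.array([1.0, 0.0, 0.0])

    radius = np.linalg.norm(ca_frames[0] - centroid[0], axis=1).max()
    rail = centroid[0] + np.array([1.0, 0.0, 0.0]) * (radius + 15.0)

    def donor_slot(res_idx):
        return rail + np.array([0.0, 8.0 * slot_of[res_idx], 0.0])

    def park_slot(k):
        return rail + np.array([0.0, 8.0 * k, 10.0])

    occ_bonds = bonds_on  # {(donor_res_idx, acceptor_res_idx): bool array (T,)}

    for f in range(n_frames):
        coords[f, structure.ca_indices] = ca_frames[f]
        for i in range(n_res_chain):
            if i in slot_of:
                coords[f, 3 * i + 1] = donor_slot(i)
            else:
                coords[f, 3 * i + 1] = ca_frames[f, i] + 0.9 * outward(f, i)
            coords[f, 3 * i + 2] = park_slot(i)
        if structure.ligand is not None:
            coords[f, structure.ligand.indices[0]] = donor_slot(n_res_chain)
            coords[f, structure.ligand.indices[1]] = park_slot(n_res_chain)
        for (don_res, acc_res), on in occ_bonds.items():
            if on[f]:
                coords[f, 3 * acc_res + 2] = donor_slot(don_res) + np.array([2.9, 0.0, 0.0])
    return coords


def _planted_bonds(structure: ToyStructure, spec: ToyProteinSpec,
                   n_frames: int, rng: np.random.Generator) -> dict:
    """Draw per-frame Bernoulli states for planted chain and decoy bonds."""
    bonds: dict[tuple[int, int], np.ndarray] = {}
    acceptors_used: set[int] = set()
    if spec.planted_chain:
        lig_res = structure.block_of.size  # residue index of LIG
        path = [lig_res] + [r - 1 for r in spec.planted_chain]
        for a, b in zip(path[:-1], path[1:]):
            if b in acceptors_used:
                raise ValueError("a residue's acceptor is used by two planted bonds")
            acceptors_used.add(b)
            bonds[(a, b)] = rng.random(n_frames) < spec.chain_occupancy
    for don, acc in spec.decoy_contacts:
        a, b = don - 1, acc - 1
        if b in acceptors_used:
            raise ValueError("decoy acceptor collides with another planted bond")
        acceptors_used.add(b)
        bonds[(a, b)] = rng.random(n_frames) < spec.decoy_occupancy
    return bonds


def sample_ensemble(structure: ToyStructure, spec: ToyProteinSpec, state: str,
                    n_frames: int, seed, multipliers: dict | None = None,
                    rigid_motion: bool = False, replica: str = "") -> Ensemble:
    """Draw an ensemble from the elastic-network Gaussian of one state.

    ``multipliers`` scales springs per state, e.g.
    ``{"blocks": (1, 1), "hinge": 10}`` for a hinge-stiffened (ATP-like)
    state.  With ``rigid_motion`` each frame additionally gets a random
    global rotation/translation (removed later by alignment).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    ca_ref = structure.ref_coords[structure.ca_indices]
    if spec.covariance == "rigid_blocks":
        W, tv, jit = _rigid_block_mixing(structure, spec, multipliers)
        T = rng.standard_normal((n_frames, len(tv), 3)) * np.sqrt(tv)[None, :, None]
        disp = np.einsum("ib,fbk->fik", W, T)
        disp += rng.standard_normal((n_frames, W.shape[0], 3)) * np.sqrt(jit)[None, :, None]
        ca_frames = ca_ref[None, :, :] + disp
    else:
        C = model_covariance(structure, spec, multipliers)
        evals, evecs = np.linalg.eigh(C)
        evals = np.clip(evals, 0.0, None)
        z = rng.standard_normal((n_frames, C.shape[0]))
        disp = z @ (evecs * np.sqrt(evals)).T
        ca_frames = ca_ref[None, :, :] + disp.reshape(n_frames, -1, 3)

    bonds = _planted_bonds(structure, spec, n_frames, rng)
    coords = _place_atoms(structure, spec, ca_frames, bonds)

    if rigid_motion:
        from scipy.spatial.transform import Rotation
        for f in range(n_frames):
            R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
            t = rng.uniform(-20, 20, size=3)
            coords[f] = coords[f] @ R.T + t
    return Ensemble(topology=structure.topology, coords=coords, state=state, replica=replica)


def rigid_body_images(structure: ToyStructure, n_frames: int, seed) -> Ensemble:
    """Frames that are random rigid-body images of the reference structure."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, structure.topology.n_atoms, 3))
    for f in range(n_frames):
        R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        coords[f] = structure.ref_coords @ R.T + t
    return Ensemble(topology=structure.topology, coords=coords, state="rigid", replica="0")


@dataclass
class GeneratedEnsembleSet:
    """A reproducible (state × replica) grid of synthetic ensembles."""

    structure: ToyStructure
    spec: ToyProteinSpec
    ensembles: dict = field(default_factory=dict)  # (state, replica label) -> Ensemble
    seeds: dict = field(default_factory=dict)

    def replicas(self, state: str) -> list[Ensemble]:
        return [e for (s, _), e in sorted(self.ensembles.items()) if s == state]

    @property
    def states(self) -> list[str]:
        return sorted({s for s, _ in self.ensembles})


def make_state_set(spec: ToyProteinSpec, states: dict[str, dict | None],
                   replicas: int = 3, n_frames: int = 200, base_seed: int = 0,
                   rigid_motion: bool = False) -> GeneratedEnsembleSet:
    """Generate the full study design: every state × replica ensemble.

    ``states`` maps a label to its stiffness multipliers (None for the
    baseline).  Each (state, replica) gets its own child seed derived from
    ``base_seed``, recorded for regeneration.
    """
    if not states:
        raise ValueError("at least one state required")
    structure = build_toy_structure(spec)
    out = GeneratedEnsembleSet(structure=structure, spec=spec)
    for si, (label, mult) in enumerate(states.items()):
        for r in range(replicas):
            seed = [base_seed, si, r]
            rep = str(r + 1)
            out.ensembles[(label, rep)] = sample_ensemble(
                structure, spec, label, n_frames, seed, multipliers=mult,
                rigid_motion=rigid_motion, replica=rep)
            out.seeds[(label, rep)] = tuple(seed)
    return out
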