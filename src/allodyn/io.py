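"""Readers and writers for topologies and coordinate ensembles.

Topologies are standard PDB files.  Trajectories are accepted either as
multi-model PDB or as a binary format mdtraj understands (XTC/DCD/TRR);
binary formats natively in nm are converted to Å on read, so every number
inside the package is in Å.
"""

from __future__ import annotations

import numpy as np

from .core import Atom, Ensemble, Residue, Selection, Topology

__all__ = ["read_ensemble", "write_ensemble_pdb"]

_LIGAND_RESNAMES = {"LIG", "ATP", "ADP", "ANP", "AMP", "GTP", "GDP"}
_PDB_SUFFIXES = (".pdb", ".ent", ".pdb.gz")


def _is_pdb(path: str) -> bool:
    return str(path).lower().endswith(_PDB_SUFFIXES)


def _flag_atoms(mdtop) -> tuple[list[Atom], dict[int, list[int]]]:
    """Derive hydrogen/donor/acceptor flags from atom and residue names.

    Rules: pseudo-atoms DON/ACC are donors/acceptors outright (heavy-atom
    fixtures); otherwise N or O carrying a bonded hydrogen donates, any O
    accepts, and the usual unprotonated ring nitrogens accept.
    """
    h_of: dict[int, list[int]] = {}
    for b in mdtop.bonds:
        a1, a2 = b.atom1, b.atom2
        for heavy, hyd in ((a1, a2), (a2, a1)):
            if (hyd.element is not None and hyd.element.symbol == "H") and (
                heavy.element is None or heavy.element.symbol != "H"
            ):
                h_of.setdefault(heavy.index, []).append(hyd.index)

    acceptor_n = {"ND1", "NE2", "N1", "N3", "N7", "OXT"}
    atoms: list[Atom] = []
    donor_hydrogens: dict[int, list[int]] = {}
    for a in mdtop.atoms:
        el = a.element.symbol if a.element is not None else ""
        name = a.name.upper()
        is_h = el == "H"
        donor = False
        acceptor = False
        if name == "DON":
            donor = True
        elif name == "ACC":
            acceptor = True
        elif not is_h:
            hyds = h_of.get(a.index, [])
            if el in ("N", "O") and hyds:
                donor = True
                donor_hydrogens[a.index] = sorted(hyds)
            if el == "O" or (el == "N" and not hyds and name in acceptor_n):
                acceptor = True
        atoms.append(
            Atom(
                name=a.name,
                element=el,
                residue_index=a.residue.index,
                is_hydrogen=is_h,
                is_donor=donor,
                is_acceptor=acceptor,
            )
        )
    return atoms, donor_hydrogens


def _topology_from_mdtraj(mdtop) -> Topology:
    residues = [
        Residue(chain=(r.chain.chain_id or chr(ord("A") + r.chain.index % 26)), number=r.resSeq, name=r.name)
        for r in mdtop.residues
    ]
    atoms, donor_hydrogens = _flag_atoms(mdtop)
    lig_idx = [
        a.index
        for a in mdtop.atoms
        if a.residue.name.upper() in _LIGAND_RESNAMES
    ]
    ligand = Selection(np.array(lig_idx), provenance="auto: ligand residue") if lig_idx else None
    return Topology(residues=residues, atoms=atoms, ligand=ligand, donor_hydrogens=donor_hydrogens)


def read_ensemble(
    topology_path,
    trajectory_path=None,
    unit_hint: str | None = None,
    state: str = "",
    replica: str = "",
    stride: int = 1,
) -> Ensemble:
    """Load a (state, replica) ensemble from a topology plus trajectory.

    Parameters
    ----------
    topology_path : path
        PDB file defining atoms and residues (may itself hold the frames if
        it is multi-model and no trajectory is given).
    trajectory_path : path, optional
        Multi-model PDB or a binary trajectory (XTC/DCD/TRR) with the same
        atom count as the topology.
    unit_hint : {"angstrom", "nm", None}
        Unit of the coordinate *text* for PDB inputs.  PDB is Å by
        convention; pass ``"nm"`` for nonstandard files written in nm, whose
        coordinates are then multiplied by 10.  Ignored for binary formats,
        which define their own unit.
    """
    import mdtraj as md

    try:
        mdtop = md.load_topology(str(topology_path))
    except Exception as exc:  # pragma: no cover - mdtraj error text varies
        raise ValueError(f"could not read topology PDB {topology_path}: {exc}") from exc

    path = str(trajectory_path) if trajectory_path is not None else str(topology_path)
    try:
        if _is_pdb(path):
            traj = md.load(path, standard_names=False)
        else:
            traj = md.load(path, top=mdtop)
    except Exception as exc:
        raise ValueError(f"could not read trajectory {path} (format tried: {path.rsplit('.', 1)[-1]}): {exc}") from exc

    if traj.n_atoms != mdtop.n_atoms:
        raise ValueError(
            f"trajectory atom count {traj.n_atoms} does not match topology atom count {mdtop.n_atoms}"
        )

    coords = np.asarray(traj.xyz, dtype=float) * 10.0  # mdtraj nm -> Å
    if unit_hint == "nm" and _is_pdb(path):
        coords = coords * 10.0  # file text was nm, not Å
    elif unit_hint not in (None, "angstrom", "A", "nm"):
        raise ValueError(f"unknown unit hint {unit_hint!r}")

    topology = _topology_from_mdtraj(mdtop)
    return Ensemble(topology=topology, coords=coords, state=state, replica=replica, stride=stride)


def write_ensemble_pdb(ensemble: Ensemble, path, frames=None) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    top = ensemble.topology
    lig_resnames = _LIGAND_RESNAMES
    which = range(ensemble.n_frames) if frames is None else frames
    with open(path, "w") as fh:
        for model_no, f in enumerate(which, start=1):
            fh.write(f"MODEL     {model_no:4d}\n")
            serial = 1
            for i, atom in enumerate(top.atoms):
                res = top.residues[atom.residue_index]
                x, y, z = ensemble.coords[f, i]
                record = "HETATM" if res.name.upper() in lig_resnames else "ATOM  "
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{record}{serial:5d} {name:<4s}{res.name:>4s} {res.chain:1s}"
                    f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
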