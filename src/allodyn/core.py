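"""Core data model: topologies, ensembles, selections, residue matrices.

All coordinates are stored internally in ångström (Å); matrices derived from
them carry an explicit units tag (``"A"`` or ``"A^2"``).  Residue numbering is
the author (PDB) numbering, 1-based, and is preserved on every output axis so
results can be read against the structure without index arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Ensemble",
    "Selection",
    "ResidueMatrix",
    "select",
    "write_matrix",
    "read_matrix",
]

# Heavy-atom names that act as H-bond acceptors in standard amino acids /
# nucleotides, besides any oxygen.  Pseudo-atoms named DON/ACC (synthetic
# fixtures) are flagged explicitly.
_ACCEPTOR_N = {"ND1", "NE2", "N1", "N3", "N7"}


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    name: str

    def __str__(self) -> str:  # e.g. "A:GLY45"
        return f"{self.chain}:{self.name}{self.number}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int
    is_hydrogen: bool = False
    is_donor: bool = False
    is_acceptor: bool = False


@dataclass
class Topology:
    """Ordered residues and atoms of a structure.

    ``donor_hydrogens`` maps a donor atom index to the indices of its attached
    hydrogens; empty for heavy-atom-only (e.g. synthetic) topologies.
    """

    residues: list[Residue]
    atoms: list[Atom]
    ligand: "Selection | None" = None
    donor_hydrogens: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for r in self.residues:
            key = (r.chain, r.number)
            if key in seen:
                raise ValueError(f"duplicate residue number {r.number} in chain {r.chain}")
            seen.add(key)
        for a in self.atoms:
            if not (0 <= a.residue_index < len(self.residues)):
                raise ValueError(f"atom {a.name} maps to no residue")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_numbers(self, atom_indices: Iterable[int]) -> np.ndarray:
        return np.array([self.residues[self.atoms[i].residue_index].number for i in atom_indices])


@dataclass(frozen=True)
class Selection:
    """An ordered set of atom indices with a human-readable provenance."""

    indices: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class Ensemble:
    """A (state, replica) coordinate ensemble over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å.  ``stride`` records the
    frame-saving stride of the source trajectory (metadata only; frames are
    always used as provided).
    """

    topology: Topology
    coords: np.ndarray
    state: str = ""
    replica: str = ""
    stride: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {c.shape}")
        if c.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {c.shape[1]} does not match topology atom count "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite coordinates")
        self.coords = c

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def with_coords(self, coords: np.ndarray) -> "Ensemble":
        return replace(self, coords=coords)

    def subset(self, selection: Selection) -> np.ndarray:
        """Coordinates of the selected atoms, shape (n_frames, n_sel, 3)."""
        return self.coords[:, selection.indices, :]


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    ranges = []
    for seg in text.split(";"):
        seg = seg.strip()
        if not seg:
            continue
        m = _RANGE_RE.match(seg)
        if not m:
            raise ValueError(f"bad residue range {seg!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise ValueError(f"inverted residue range {seg!r}")
        ranges.append((lo, hi))
    if not ranges:
        raise ValueError(f"empty residue range expression {text!r}")
    return ranges


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression to atom indices.

    Grammar: clauses joined by ``and``; each clause is an atom-name filter
    (``CA`` or ``name CA``), a residue filter (``resid 2-15;160-225;360-390``),
    or a chain filter (``chain A``).  The result is ordered by atom index with
    duplicates removed.  An empty result is an error — downstream statistics
    are undefined on nothing.
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    for clause in re.split(r"\s+and\s+", expression.strip()):
        clause = clause.strip()
        if not clause:
            raise ValueError("empty clause in selection expression")
        parts = clause.split(None, 1)
        head = parts[0].lower()
        if head == "resid":
            if len(parts) != 2:
                raise ValueError("resid clause needs a range argument")
            ranges = _parse_ranges(parts[1])
            keep = np.array(
                [
                    any(
                        lo <= topology.residues[a.residue_index].number <= hi
                        for lo, hi in ranges
                    )
                    for a in topology.atoms
                ]
            )
        elif head == "chain":
            if len(parts) != 2:
                raise ValueError("chain clause needs a chain id")
            cid = parts[1].strip()
            keep = np.array(
                [topology.residues[a.residue_index].chain == cid for a in topology.atoms]
            )
        else:
            # atom-name filter; allow optional "name" keyword
            name = parts[1].strip() if head == "name" and len(parts) == 2 else clause
            names = {n.strip().upper() for n in name.split(",")}
            keep = np.array([a.name.upper() in names for a in topology.atoms])
        mask &= keep
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"selection {expression!r} matched no atoms")
    return Selection(indices=idx, provenance=expression)


# ---------------------------------------------------------------------------
# Residue matrices and their text round-trip
# ---------------------------------------------------------------------------


@dataclass
class ResidueMatrix:
    """A square matrix over a Cα selection, axes labelled by residue number."""

    values: np.ndarray
    resids: np.ndarray
    units: str = "A^2"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        r = np.asarray(self.resids, dtype=int)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if v.shape[0] != r.size:
            raise ValueError("axis length does not match residue labels")
        self.values = v
        self.resids = r

    def check_symmetric(self, tol: float = 1e-9) -> None:
        if not np.allclose(self.values, self.values.T, atol=tol):
            raise ValueError("matrix is not symmetric")


def write_matrix(matrix: ResidueMatrix, path) -> None:
    """Write a residue matrix as tab-delimited text.

    Layout: ``#``-prefixed metadata lines (units first), then a header row of
    residue numbers, then one row per residue led by its residue number.
    The matrix must be finite and symmetric (checked before any I/O).
    """
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("matrix contains non-finite values")
    matrix.check_symmetric()
    lines = [f"# units: {matrix.units}"]
    for k, v in matrix.meta.items():
        lines.append(f"# {k}: {v}")
    lines.append("resid\t" + "\t".join(str(r) for r in matrix.resids))
    for r, row in zip(matrix.resids, matrix.values):
        lines.append(str(r) + "\t" + "\t".join(f"{x:.10g}" for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_matrix(path) -> ResidueMatrix:
    units = "A^2"
    meta: dict = {}
    rows = []
    resids = []
    header: Sequence[int] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    k, v = k.strip(), v.strip()
                    if k == "units":
                        units = v
                    else:
                        meta[k] = v
                continue
            cells = line.split("\t")
            if header is None:
                if cells[0] != "resid":
                    raise ValueError("matrix file lacks a resid header row")
                header = [int(c) for c in cells[1:]]
                continue
            resids.append(int(cells[0]))
            rows.append([float(c) for c in cells[1:]])
    if header is None or not rows:
        raise ValueError("matrix file has no data")
    if list(header) != resids:
        raise ValueError("row and column residue labels disagree")
    return ResidueMatrix(values=np.array(rows), resids=np.array(resids), units=units, meta=meta)
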