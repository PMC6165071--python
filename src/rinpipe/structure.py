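"""Conformational ensembles as multi-model PDB files.

An :class:`Ensemble` is the universal input of every analysis stage: an
ordered set of frames (conformations) sharing a single atom table.  Frames
may come from a molecular-dynamics trajectory saved as a multi-model PDB,
from an NMR-style multi-model deposition, or from the synthetic generators
in :mod:`rinpipe.synthetic`.

PDB parsing and serialisation are delegated to :mod:`biotite`; this module
adds the fixed atom-table contract (model 1 defines the table, every later
model must match it) and a small atom-selection language::

    expr     = term , { "and" , term } ;
    term     = "backbone" | key , value , { value } ;
    key      = "resid" | "chain" | "name" | "resname" ;
    value    = token | range ;          (* range only for resid *)
    range    = integer , "-" , integer ;

Multiple values after one key are alternatives (OR); terms joined by
``and`` must all hold.  Examples: ``"resid 102 and name OG"``,
``"resid 161-190 and name CA"``, ``"resname ZOL"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Topology",
    "Ensemble",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "subset_atoms",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class Atom:
    """One row of the atom table shared by all frames."""

    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resid: int

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Topology:
    """Ordered atom table plus the residue list derived from it.

    ``residues`` is the unique ordered list of ``(chain, resid, resname)``
    keys appearing in ``atoms``; ``residue_index`` maps every atom to its
    position in that list.
    """

    atoms: list[Atom]
    residues: list[tuple[str, int, str]] = field(init=False)
    residue_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        residues: list[tuple[str, int, str]] = []
        seen: dict[tuple[str, int], int] = {}
        index = np.empty(len(self.atoms), dtype=np.intp)
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resid)
            if key not in seen:
                seen[key] = len(residues)
                residues.append((a.chain, a.resid, a.resname))
            index[i] = seen[key]
        self.residues = residues
        self.residue_index = index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atoms_of_residue(self, res_index: int) -> np.ndarray:
        """Atom indices belonging to residue ``res_index`` (topology order)."""
        return np.flatnonzero(self.residue_index == res_index)

    def index_of(self, resid: int, name: str, chain: str | None = None) -> int:
        """Index of the unique atom matching ``resid``/``name`` (and chain)."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.resid == resid
            and a.name == name
            and (chain is None or a.chain == chain)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"atom resid {resid} name {name!r}: {len(hits)} matches"
            )
        return hits[0]


@dataclass
class Ensemble:
    """Frames x atoms x 3 coordinates (Angstrom) over a fixed topology."""

    topology: Topology
    coords: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords second dimension {self.coords.shape[1]} does not "
                f"match atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues

    def copy(self) -> "Ensemble":
        times = None if self.frame_times is None else np.array(self.frame_times)
        return Ensemble(self.topology, self.coords.copy(), times)


def subset_atoms(ens: Ensemble, indices) -> Ensemble:
    """New ensemble restricted to the given atom indices (topology order)."""
    idx = sorted(set(int(i) for i in indices))
    if not idx:
        raise ValueError("cannot subset to zero atoms")
    atoms = [ens.topology.atoms[i] for i in idx]
    return Ensemble(Topology(atoms), ens.coords[:, idx], ens.frame_times)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _scan_model_atom_counts(path: str) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (one block if no MODEL)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")):
                altloc = line[16] if len(line) > 16 else " "
                if altloc not in (" ", "A"):
                    continue
                if in_model or not saw_model:
                    current += 1
                    if not saw_model and not counts:
                        counts.append(0)
                    if not saw_model:
                        counts[0] = current
    return counts


def read_multimodel_pdb(path: str) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Model 1 defines the atom table; every further model must supply the
    same number of atoms and is matched positionally.  Alternate locations
    other than blank/'A' are dropped with a warning.
    """
    counts = _scan_model_atom_counts(path)
    if not counts or counts[0] == 0:
        raise ValueError(f"{path}: no atoms found")
    for k, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise ValueError(
                f"{path}: model {k} has {c} atoms, expected {counts[0]} "
                f"(model 1)"
            )

    pdb = PDBFile.read(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = pdb.get_structure(model=None, altloc="first")
    # altloc="first" keeps the first altloc id per atom; warn if any other
    # altloc ids were present in the file.
    with open(path) as fh:
        alt_ids = {
            line[16]
            for line in fh
            if line.startswith(("ATOM  ", "HETATM")) and len(line) > 16
        }
    if alt_ids - {" ", "A"}:
        warnings.warn(
            f"{path}: alternate locations {sorted(alt_ids - {' ', 'A'})} "
            "dropped (keeping blank/'A')",
            stacklevel=2,
        )
    return _from_atom_array_stack(stack)


def _from_atom_array_stack(stack) -> Ensemble:
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    atoms = [
        Atom(
            serial=i + 1,
            name=str(stack.atom_name[i]),
            element=str(stack.element[i]),
            resname=str(stack.res_name[i]),
            chain=str(stack.chain_id[i]) or "A",
            resid=int(stack.res_id[i]),
        )
        for i in range(stack.array_length())
    ]
    return Ensemble(Topology(atoms), np.asarray(stack.coord, dtype=float))


def _to_atom_array_stack(ens: Ensemble):
    n = ens.n_atoms
    stack = struc.AtomArrayStack(ens.n_frames, n)
    top = ens.topology
    stack.coord[:] = ens.coords
    stack.chain_id = np.array([a.chain for a in top.atoms], dtype="U4")
    stack.res_id = np.array([a.resid for a in top.atoms], dtype=int)
    stack.res_name = np.array([a.resname for a in top.atoms], dtype="U5")
    stack.atom_name = np.array([a.name for a in top.atoms], dtype="U6")
    stack.element = np.array([a.element for a in top.atoms], dtype="U2")
    stack.hetero = np.array(
        [a.resname in ("ZOL", "LIG", "HOH") for a in top.atoms], dtype=bool
    )
    return stack


def write_multimodel_pdb(ens: Ensemble, path: str) -> str:
    """Write an ensemble as a multi-model PDB (one MODEL block per frame)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(ens))
    # biotite omits MODEL records for single-model stacks; the multi-model
    # contract requires them for every frame.
    if ens.n_frames == 1 and not any(
        line.startswith("MODEL") for line in pdb.lines
    ):
        end = [i for i, l in enumerate(pdb.lines) if l.startswith("END")]
        body = [l for l in pdb.lines if not l.startswith("END")]
        pdb.lines = body + ["ENDMDL"]
        pdb.lines.insert(0, "MODEL        1")
        pdb.lines.append("END")
        del end
    pdb.write(path)
    return path


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_KEYS = ("resid", "chain", "name", "resname")


def _parse_query(query: str) -> list[tuple[str, list]]:
    tokens = query.split()
    if not tokens:
        raise ValueError("empty selection query")
    terms: list[tuple[str, list]] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "and":
            if not terms or i + 1 >= len(tokens):
                raise ValueError(f"misplaced 'and' in query {query!r}")
            i += 1
            continue
        if tok == "backbone":
            terms.append(("backbone", []))
            i += 1
            continue
        if tok not in _KEYS:
            raise ValueError(
                f"unknown selection keyword {tokens[i]!r} in {query!r}"
            )
        key = tok
        i += 1
        values: list = []
        while i < len(tokens) and tokens[i].lower() not in _KEYS + ("and", "backbone"):
            values.append(tokens[i])
            i += 1
        if not values:
            raise ValueError(f"keyword {key!r} requires a value in {query!r}")
        if key == "resid":
            parsed: list[tuple[int, int]] = []
            for v in values:
                if "-" in v[1:]:  # allow leading minus of a negative resid
                    lo, hi = v.rsplit("-", 1) if not v.startswith("-") else (v, v)
                    try:
                        parsed.append((int(lo), int(hi)))
                    except ValueError as exc:
                        raise ValueError(f"bad resid range {v!r}") from exc
                else:
                    try:
                        parsed.append((int(v), int(v)))
                    except ValueError as exc:
                        raise ValueError(f"bad resid value {v!r}") from exc
            terms.append((key, parsed))
        else:
            terms.append((key, values))
    return terms


def select_atoms(top: Topology, query: str) -> list[int]:
    """Evaluate a selection expression; returns sorted atom indices.

    An empty result is not an error — an empty list is returned when
    nothing matches.  A syntactically invalid query raises ``ValueError``.
    """
    terms = _parse_query(query)
    out = []
    for i, a in enumerate(top.atoms):
        ok = True
        for key, values in terms:
            if key == "backbone":
                ok = a.is_backbone
            elif key == "resid":
                ok = any(lo <= a.resid <= hi for lo, hi in values)
            elif key == "chain":
                ok = a.chain in values
            elif key == "name":
                ok = a.name in values
            elif key == "resname":
                ok = a.resname in values
            if not ok:
                break
        if ok:
            out.append(i)
    return out
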