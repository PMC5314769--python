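"""Structure reading/writing, atom selection and crystal-symmetry expansion.

Coordinates are carried in Å.  Atom records keep author residue numbering
(1-based, as deposited); internal indices are 0-based.  Phosphate oxygen
names are normalised to the PDB v3 remediated convention (O1P -> OP1,
O2P -> OP2) on ingest so that selections written either way resolve.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

try:
    import gemmi
except ImportError as _e:  # pragma: no cover
    gemmi = None
    _gemmi_err = _e


class StructureError(Exception):
    """Base class for structure-layer errors."""


class StructureParseError(StructureError):
    pass


class StructureFormatError(StructureError):
    pass


class MissingCellError(StructureError):
    """Raised when an operation needs a crystal cell the structure lacks."""


#: names treated as phosphate-oxygen synonyms (legacy -> remediated)
_PHOSPHATE_SYNONYMS = {"O1P": "OP1", "O2P": "OP2"}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_NUCLEOTIDES = {"DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U", "DI", "I"}
_WATERS = {"HOH", "WAT", "H2O", "DOD"}


def normalize_atom_name(name: str) -> str:
    return _PHOSPHATE_SYNONYMS.get(name.strip().upper(), name.strip())


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian position in Å."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    is_hetero: bool = False
    altloc: str = ""

    def __post_init__(self):
        pos = tuple(float(x) for x in self.position)
        if not all(np.isfinite(pos)):
            raise ValueError(f"non-finite position for atom {self.key}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not self.atom_name:
            raise ValueError("empty atom name")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "atom_name", normalize_atom_name(self.atom_name))

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain, author residue number, atom name) lookup triple."""
        return (self.chain_id, self.residue_number, self.atom_name)


@dataclass
class CrystalCell:
    """Unit cell + space-group operators (rotations and fractional shifts)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"
    #: list of (3x3 rotation on fractional coords, fractional translation, label)
    operators: list[tuple[np.ndarray, np.ndarray, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.operators:
            self.operators = space_group_operators(self.space_group)

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """M with cartesian = M @ fractional (standard PDB convention)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos_al, cos_be, cos_ga = np.cos([al, be, ga])
        sin_ga = np.sin(ga)
        v = np.sqrt(
            1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
        )
        return np.array(
            [
                [self.a, self.b * cos_ga, self.c * cos_be],
                [0.0, self.b * sin_ga, self.c * (cos_al - cos_be * cos_ga) / sin_ga],
                [0.0, 0.0, self.c * v / sin_ga],
            ]
        )

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return cart @ np.linalg.inv(self.orthogonalization_matrix).T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.orthogonalization_matrix.T


def space_group_operators(symbol: str) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """All symmetry operators (incl. centering) for a Hermann–Mauguin symbol."""
    if gemmi is None:  # pragma: no cover
        raise ImportError("gemmi is required for space-group operators") from _gemmi_err
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise StructureFormatError(
            f"unknown space group {symbol!r}; use a Hermann-Mauguin symbol "
            "such as 'P 1', 'P 2', 'P 21', 'R 3 2:H'"
        )
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran, op.triplet()))
    return ops


@dataclass(frozen=True)
class SelectionSpec:
    """Conjunctive atom filter; every field is optional, `None` means no filter.

    An empty spec selects every atom.  Residue ranges are inclusive on both
    ends and use author numbering.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    residue_names: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None
    elements: frozenset[str] | None = None
    hetero: bool | None = None
    kind: str | None = None  # protein | nucleic | water

    @classmethod
    def make(cls, chains=None, residue_ranges=None, residue_names=None,
             atom_names=None, elements=None, hetero=None, kind=None):
        def fs(x):
            return None if x is None else frozenset(x)
        rr = None
        if residue_ranges is not None:
            rr = tuple((int(a), int(b)) for a, b in residue_ranges)
        an = None
        if atom_names is not None:
            an = frozenset(normalize_atom_name(n) for n in atom_names)
        el = None if elements is None else frozenset(e.upper() for e in elements)
        return cls(fs(chains), rr, fs(residue_names), an, el, hetero, kind)

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.elements is not None and atom.element.upper() not in self.elements:
            return False
        if self.hetero is not None and atom.is_hetero != self.hetero:
            return False
        if self.kind is not None:
            rn = atom.residue_name
            if self.kind == "protein" and rn not in _AMINO_ACIDS:
                return False
            if self.kind == "nucleic" and rn not in _NUCLEOTIDES:
                return False
            if self.kind == "water" and rn not in _WATERS:
                return False
        return True


def parse_selection(text: str) -> SelectionSpec:
    """Parse a selection string: clauses joined by '&'.

    Clauses: ``chain A,B`` | ``resi 1-33,40`` | ``resname GLU,LYS`` |
    ``name CA,N`` | ``element P`` | ``protein`` | ``nucleic`` | ``water`` |
    ``hetero`` | ``polymer`` (= not hetero).  ``all`` selects everything.
    """
    kw: dict = {}
    for raw in text.split("&"):
        clause = raw.strip()
        if not clause or clause.lower() == "all":
            continue
        parts = clause.split(None, 1)
        head = parts[0].lower()
        arg = parts[1] if len(parts) > 1 else ""
        items = [s.strip() for s in arg.split(",") if s.strip()]
        if head == "chain":
            kw["chains"] = items
        elif head in ("resi", "resid", "resnum"):
            ranges = []
            for it in items:
                if "-" in it[1:]:  # allow negative numbers
                    lo, hi = it.rsplit("-", 1)
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append((int(it), int(it)))
            kw["residue_ranges"] = ranges
        elif head == "resname":
            kw["residue_names"] = items
        elif head == "name":
            kw["atom_names"] = items
        elif head == "element":
            kw["elements"] = items
        elif head in ("protein", "nucleic", "water"):
            kw["kind"] = head
        elif head == "hetero":
            kw["hetero"] = True
        elif head == "polymer":
            kw["hetero"] = False
        else:
            raise ValueError(f"unknown selection clause {clause!r}")
    return SelectionSpec.make(**kw)


@dataclass
class Structure:
    """Ordered atom list with an optional crystal cell."""

    atoms: list[AtomRecord]
    cell: CrystalCell | None = None
    title: str = ""

    def __post_init__(self):
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of positions in Å (cached)."""
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
            if self._coords.size == 0:
                self._coords = self._coords.reshape(0, 3)
        return self._coords

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=tuple(x)) for a, x in zip(self.atoms, coords)]
        return Structure(atoms, cell=self.cell,
                         title=self.title if title is None else title)

    def select(self, spec: SelectionSpec | str) -> np.ndarray:
        """Strictly increasing indices of atoms matching all spec clauses."""
        if isinstance(spec, str):
            spec = parse_selection(spec)
        return np.array(
            [i for i, a in enumerate(self.atoms) if spec.matches(a)], dtype=int
        )

    def atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Resolve a (chain, resnum, name) triple to a unique atom index."""
        name = normalize_atom_name(atom_name)
        hits = [
            i for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id
            and a.residue_number == int(residue_number)
            and a.atom_name == name
        ]
        if len(hits) != 1:
            raise LookupError(
                f"atom {chain_id}/{residue_number}/{atom_name} resolves to "
                f"{len(hits)} atoms (need exactly 1)"
            )
        return hits[0]

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


def select(structure: Structure, spec: SelectionSpec | str) -> np.ndarray:
    return structure.select(spec)


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom: highest occupancy, ties alphabetically."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        k = (a.chain_id, a.residue_number, a.residue_name, a.atom_name)
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, _alt_rank(a.altloc)) > (b.occupancy, _alt_rank(b.altloc)):
                best[k] = a
    return [replace(best[k], altloc="") for k in order]


def _alt_rank(altloc: str) -> int:
    # higher rank wins ties; blank > 'A' > 'B' ... (alphabetically earliest kept)
    if not altloc:
        return 1000
    return -string.ascii_uppercase.index(altloc.upper()) if altloc.upper() in string.ascii_uppercase else -100


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model of a multi-model file is returned (use
    :func:`resdyn.ensemble.read_trajectory` for ensembles).  Altlocs are
    resolved to the highest-occupancy conformer.
    """
    if gemmi is None:  # pragma: no cover
        raise ImportError("gemmi is required to read structures") from _gemmi_err
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if format not in fmt_map:
        raise StructureFormatError(f"unknown format {format!r}; use pdb/mmcif/auto")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as e:
        raise StructureParseError(f"could not parse {path}: {e}") from e
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")
    return _from_gemmi_model(st, st[0])


def _from_gemmi_model(st, model) -> Structure:
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        is_hetero=het,
                        altloc=at.altloc if at.altloc else "",
                    )
                )
    atoms = _resolve_altlocs(atoms)
    cell = None
    if st.cell and st.cell.a > 1.0 and st.spacegroup_hm:
        try:
            ops = space_group_operators(st.spacegroup_hm)
        except StructureFormatError:
            ops = space_group_operators("P 1")
        cell = CrystalCell(
            st.cell.a, st.cell.b, st.cell.c,
            st.cell.alpha, st.cell.beta, st.cell.gamma,
            space_group=st.spacegroup_hm, operators=ops,
        )
    return Structure(atoms, cell=cell, title=st.name or "")


def write_pdb(structure: Structure, path) -> None:
    """Write a minimal PDB v3 file (CRYST1 + ATOM/HETATM/TER/END)."""
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:70]}")
    if structure.cell is not None:
        c = structure.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {c.space_group:<11s}"
        )
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.atom_name
        # PDB name column convention: 1-2 char element names start in col 14
        pname = f" {name:<3s}" if len(name) < 4 and len(a.element) < 2 else f"{name:<4s}"
        x, y, z = a.position
        lines.append(
            f"{rec}{serial % 100000:5d} {pname}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id[:1]:1s}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# symmetry expansion


def expand_symmetry(
    structure: Structure,
    selection: Sequence[int] | np.ndarray | None = None,
    radius: float = 5.0,
    max_shell: int = 1,
) -> list[tuple[str, Structure]]:
    """Symmetry/lattice images with at least one atom within `radius` (Å) of
    the selection.

    The lattice search covers translations of ``-max_shell .. +max_shell``
    cells along each axis (adjacent cells by default — ample for
    contact-scale radii).  The identity operator with zero translation is
    excluded.  Labels are ``triplet | +(n1,n2,n3)``.
    """
    if structure.cell is None or not structure.cell.operators:
        raise MissingCellError("structure has no crystal cell/operators")
    if radius <= 0:
        return []
    cell = structure.cell
    sel = (
        np.arange(len(structure)) if selection is None else np.asarray(selection, int)
    )
    sel_coords = structure.coords[sel]
    if sel_coords.size == 0:
        return []
    from scipy.spatial import cKDTree

    tree = cKDTree(sel_coords)
    frac = cell.fractionalize(structure.coords)
    images: list[tuple[str, Structure]] = []
    shells = range(-max_shell, max_shell + 1)
    for rot, tran, triplet in cell.operators:
        base = frac @ rot.T + tran
        is_identity = np.allclose(rot, np.eye(3)) and np.allclose(tran % 1.0, 0.0)
        for n1 in shells:
            for n2 in shells:
                for n3 in shells:
                    n = np.array([n1, n2, n3], float)
                    if is_identity and not n.any():
                        continue
                    cart = cell.orthogonalize(base + n)
                    d, _ = tree.query(cart, k=1)
                    if np.min(d) <= radius + 1e-9:
                        label = f"{triplet} | +({n1},{n2},{n3})"
                        images.append(
                            (label, structure.with_coords(
                                cart, title=f"{structure.title} [{label}]"))
                        )
    return images
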