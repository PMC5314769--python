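"""Static geometry analytics on structures.

Contact counting (PDBSum-style long-range interactions), hydrogen-bond
proposal, crystal contacts against symmetry images, key atom-pair
distances, Kabsch superposition RMSD and radius of gyration.

Conventions: contacts are unordered heavy-atom pairs at distance <= cutoff
(inclusive); distances in Å; hydrogen bonds use a donor-acceptor distance
criterion only when no hydrogens are present (as in low-resolution crystal
structures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    MissingCellError,
    SelectionSpec,
    Structure,
    expand_symmetry,
    parse_selection,
)

_HYDROGEN = {"H", "D"}

#: approximate atomic masses (Da) for mass-weighted Rg
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "MG": 24.305, "MN": 54.938, "NA": 22.99, "K": 39.098,
    "CL": 35.45, "ZN": 65.38, "FE": 55.845, "CA": 40.078, "D": 2.014,
}


class OverlappingSelectionError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


def _resolve(structure: Structure, sel) -> np.ndarray:
    if sel is None:
        return np.arange(len(structure))
    if isinstance(sel, (str, SelectionSpec)):
        return structure.select(sel)
    return np.asarray(sel, dtype=int)


def _drop_hydrogens(structure: Structure, idx: np.ndarray) -> np.ndarray:
    return np.array(
        [i for i in idx if structure.atoms[i].element.upper() not in _HYDROGEN],
        dtype=int,
    )


@dataclass
class ContactReport:
    """Unordered contact pairs between two atom sets."""

    pairs: list[tuple[int, int, float]]  # (index in A, index in B, distance Å)
    cutoff: float
    per_chain: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.pairs)


@dataclass
class HBond:
    donor: int
    acceptor: int
    distance: float
    angle: float | None = None
    category: str = ""  # e.g. "K-N..OP1", "S-OG..OP2"


def count_contacts(
    structure: Structure,
    set_a,
    set_b,
    cutoff: float = 5.0,
    include_hydrogens: bool = False,
) -> ContactReport:
    """Count unordered atom pairs (a in A, b in B) with distance <= cutoff.

    Heavy atoms only by default.  The per-chain breakdown attributes each
    pair to the chain of its set-A member (the protein side in
    protein-vs-DNA use).  Overlapping selections are rejected.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ia = _resolve(structure, set_a)
    ib = _resolve(structure, set_b)
    if not include_hydrogens:
        ia = _drop_hydrogens(structure, ia)
        ib = _drop_hydrogens(structure, ib)
    overlap = np.intersect1d(ia, ib)
    if overlap.size:
        raise OverlappingSelectionError(
            f"selections share {overlap.size} atoms; contact ownership ambiguous"
        )
    pairs: list[tuple[int, int, float]] = []
    per_chain: dict[str, int] = {}
    if ia.size and ib.size:
        ca, cb = structure.coords[ia], structure.coords[ib]
        tree = cKDTree(cb)
        for k, hits in enumerate(tree.query_ball_point(ca, r=cutoff * (1 + 1e-12) + 1e-9)):
            for h in hits:
                d = float(np.linalg.norm(ca[k] - cb[h]))
                if d <= cutoff + 1e-9:
                    pairs.append((int(ia[k]), int(ib[h]), d))
                    ch = structure.atoms[ia[k]].chain_id
                    per_chain[ch] = per_chain.get(ch, 0) + 1
    return ContactReport(pairs=pairs, cutoff=cutoff, per_chain=per_chain)


def propose_hbonds(
    structure: Structure,
    donors,
    acceptors,
    dist_cutoff: float = 3.5,
    angle_cutoff: float | None = None,
) -> list[HBond]:
    """Propose hydrogen bonds as N/O donor–acceptor pairs within dist_cutoff.

    Donor and acceptor must belong to different residues.  The angle
    criterion (donor-H...acceptor >= angle_cutoff) is applied only when the
    donor residue actually carries hydrogens; structures without hydrogens
    fall back to the distance-only criterion.  Lysine backbone-N to OP1 and
    serine OG to OP2 pairs — the classes conserved across all four RecU
    monomers in the crystal — are tagged in ``category``.
    """
    idx_d = _resolve(structure, donors)
    idx_a = _resolve(structure, acceptors)
    idx_d = np.array(
        [i for i in idx_d if structure.atoms[i].element.upper() in ("N", "O")], int
    )
    idx_a = np.array(
        [i for i in idx_a if structure.atoms[i].element.upper() in ("N", "O")], int
    )
    out: list[HBond] = []
    if not (idx_d.size and idx_a.size):
        return out
    cd, ca = structure.coords[idx_d], structure.coords[idx_a]
    tree = cKDTree(ca)
    # hydrogens attached to each donor (within 1.25 Å, same residue)
    hyd = [
        i for i, a in enumerate(structure.atoms) if a.element.upper() in _HYDROGEN
    ]
    hyd_coords = structure.coords[hyd] if hyd else np.empty((0, 3))
    for k, hits in enumerate(tree.query_ball_point(cd, r=dist_cutoff + 1e-9)):
        d_atom = structure.atoms[idx_d[k]]
        for h in hits:
            a_atom = structure.atoms[idx_a[h]]
            if (d_atom.chain_id, d_atom.residue_number) == (
                a_atom.chain_id,
                a_atom.residue_number,
            ):
                continue
            dist = float(np.linalg.norm(cd[k] - ca[h]))
            if dist > dist_cutoff + 1e-9:
                continue
            angle = None
            if angle_cutoff is not None and hyd:
                dh = np.linalg.norm(hyd_coords - cd[k], axis=1)
                attached = [
                    j for j, hi in enumerate(hyd)
                    if dh[j] < 1.25
                    and structure.atoms[hi].chain_id == d_atom.chain_id
                    and structure.atoms[hi].residue_number == d_atom.residue_number
                ]
                if attached:
                    best = None
                    for j in attached:
                        v1 = cd[k] - hyd_coords[j]
                        v2 = ca[h] - hyd_coords[j]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                        best = ang if best is None else max(best, ang)
                    angle = best
                    if angle < angle_cutoff:
                        continue
            category = ""
            if (
                d_atom.residue_name == "LYS"
                and d_atom.atom_name == "N"
                and a_atom.atom_name == "OP1"
            ):
                category = "K-N..OP1"
            elif (
                d_atom.residue_name == "SER"
                and d_atom.atom_name == "OG"
                and a_atom.atom_name == "OP2"
            ):
                category = "S-OG..OP2"
            out.append(
                HBond(int(idx_d[k]), int(idx_a[h]), dist, angle, category)
            )
    out.sort(key=lambda b: (b.donor, b.acceptor))
    return out


def crystal_contact_count(
    structure: Structure,
    selection,
    cutoff: float = 5.0,
    include_hydrogens: bool = False,
    max_shell: int = 1,
) -> tuple[int, list[tuple[int, str, int, float]]]:
    """Contacts between a selection and all symmetry images of the structure.

    Counts (selected atom, image atom) pairs at distance <= cutoff over all
    non-identity symmetry/lattice images within reach.  Contacts to other
    chains of the same asymmetric unit are, by construction, not counted.
    Returns (count, [(sel atom index, operator label, image atom index, d)]).
    """
    if structure.cell is None:
        raise MissingCellError("crystal contacts require a crystal cell")
    sel = _resolve(structure, selection)
    if not include_hydrogens:
        sel = _drop_hydrogens(structure, sel)
    if sel.size == 0:
        return 0, []
    heavy_all = (
        np.arange(len(structure))
        if include_hydrogens
        else _drop_hydrogens(structure, np.arange(len(structure)))
    )
    sel_coords = structure.coords[sel]
    tree = cKDTree(sel_coords)
    pairs: list[tuple[int, str, int, float]] = []
    for label, image in expand_symmetry(structure, sel, cutoff, max_shell=max_shell):
        img_coords = image.coords[heavy_all]
        for k, hits in enumerate(tree.query_ball_point(img_coords, r=cutoff + 1e-9)):
            for h in hits:
                d = float(np.linalg.norm(img_coords[k] - sel_coords[h]))
                if d <= cutoff + 1e-9:
                    pairs.append((int(sel[h]), label, int(heavy_all[k]), d))
    return len(pairs), pairs


def atom_pair_distance(structure: Structure, atom_a, atom_b) -> float:
    """Distance (Å) between two atoms given as (chain, resnum, atom_name)."""
    ia = structure.atom_index(*atom_a)
    ib = structure.atom_index(*atom_b)
    return float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))


# ---------------------------------------------------------------------------
# superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns (rmsd, rotation R, translation t) with the proper-rotation
    constraint det(R) = +1; the fitted coordinates are ``mobile @ R.T + t``.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (N, 3) coordinate arrays required")
    if P.shape[0] < 3:
        raise DegenerateFitError("need at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateFitError("mobile selection is collinear/degenerate")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return rmsd, R, t


def superpose_rmsd(
    mobile: Structure,
    reference: Structure,
    mobile_sel=None,
    reference_sel=None,
    atom_map: list[tuple[int, int]] | None = None,
):
    """Kabsch RMSD between paired selections of two structures.

    With no ``atom_map``, selected atoms are paired by their
    (chain, residue number, atom name) keys (common atoms only, in mobile
    order).  Returns (rmsd Å, R, t).
    """
    if atom_map is None:
        im = _resolve(mobile, mobile_sel)
        ir = _resolve(reference, reference_sel)
        ref_lookup = {reference.atoms[i].key: i for i in ir}
        atom_map = [
            (int(i), ref_lookup[mobile.atoms[i].key])
            for i in im
            if mobile.atoms[i].key in ref_lookup
        ]
    if len(atom_map) < 3:
        raise DegenerateFitError("fewer than 3 paired atoms")
    mi = [m for m, _ in atom_map]
    ri = [r for _, r in atom_map]
    return kabsch(mobile.coords[mi], reference.coords[ri])


BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


def dimer_backbone_rmsd(mobile: Structure, reference: Structure,
                        mobile_chains: tuple[str, str],
                        reference_chains: tuple[str, str]) -> float:
    """Backbone RMSD between two dimers, trying both chain-pair assignments.

    Pairs common modeled residues by residue number over N/CA/C/O and
    reports the minimum RMSD of the two possible chain mappings.
    """
    best = None
    a, b = reference_chains
    for ref_pair in ((a, b), (b, a)):
        amap = []
        for mc, rc in zip(mobile_chains, ref_pair):
            ref_lookup = {
                (at.residue_number, at.atom_name): i
                for i, at in enumerate(reference.atoms)
                if at.chain_id == rc and at.atom_name in BACKBONE_ATOMS
            }
            for i, at in enumerate(mobile.atoms):
                if at.chain_id == mc and at.atom_name in BACKBONE_ATOMS:
                    j = ref_lookup.get((at.residue_number, at.atom_name))
                    if j is not None:
                        amap.append((i, j))
        if len(amap) >= 3:
            rmsd, _, _ = superpose_rmsd(mobile, reference, atom_map=amap)
            best = rmsd if best is None else min(best, rmsd)
    if best is None:
        raise DegenerateFitError("no common backbone atoms between dimers")
    return best


def radius_of_gyration(
    coords: np.ndarray | Structure,
    selection=None,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
) -> float:
    """Rg = sqrt( sum w_i |r_i - rbar|^2 / sum w_i ), rbar the weighted mean."""
    if isinstance(coords, Structure):
        idx = _resolve(coords, selection)
        X = coords.coords[idx]
        if mass_weighted and masses is None:
            masses = np.array(
                [ATOMIC_MASSES.get(coords.atoms[i].element.upper(), 12.0) for i in idx]
            )
    else:
        X = np.asarray(coords, float)
        if selection is not None:
            X = X[np.asarray(selection, int)]
    if X.shape[0] < 1:
        raise ValueError("at least one atom required")
    if mass_weighted:
        if masses is None:
            raise ValueError("mass weighting requires masses or a Structure")
        w = np.asarray(masses, float)
    else:
        w = np.ones(X.shape[0])
    center = (w[:, None] * X).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((X - center) ** 2, axis=1)).sum() / w.sum()))
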