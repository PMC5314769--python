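"""Synthetic inputs with known ground truth.

Every generator is seed-deterministic and returns (or embeds) the planted
quantities so tests and pipelines can verify recovery exactly:

* toy protein-like / DNA-like complexes with planted contact and
  hydrogen-bond pairs, an optional catalytic site (Mg2+, glutamate
  carboxylate, scissile phosphate) and a water pool;
* toy crystals with planted cross-image contact pairs;
* Gaussian-linear trajectories: rigid base + planted orthonormal
  displacement modes with chosen variances + isotropic noise (the minimal
  statistical structure a linear-algebraic ensemble pipeline can be tested
  against — deliberately not a physical force field);
* reactive-geometry planting: a chosen fraction of frames receives a
  water satisfying the triple-distance criterion with a safety margin,
  all other frames violate it by at least the margin;
* two-state van't Hoff melt curves with planted Tm, ΔH, baselines and
  Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Trajectory
from .reactive import ReactiveSiteSpec
from .structure_io import AtomRecord, CrystalCell, Structure, space_group_operators
from .thermofluor import CELSIUS_OFFSET, MeltCurve, R_GAS


class RecipeError(ValueError):
    pass


class ConstructionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# toy complexes

# backbone offsets (Å) within a residue, chosen so planted partner atoms at
# the documented stand-off distances touch exactly the intended atoms
_BB = {"N": (0.0, 1.45, 0.0), "CA": (0.0, 0.0, 0.0), "C": (1.5, 0.0, 0.0),
       "O": (1.5, -1.2, 0.0), "CB": (-1.0, -1.0, 0.0)}
_RESIDUE_SPACING = 6.0
_CHAIN_SPACING = 40.0

# active-site local geometry (Å, relative to Mg): a water at the centroid of
# (Mg, OE1, P) satisfies all three 3.3 Å criteria with >= 1 Å to spare
_SITE_OE1 = np.array([3.6, 0.0, 0.0])
_SITE_OE2 = np.array([4.5, 1.5, 0.0])
_SITE_P = np.array([1.8, 3.2, 0.0])


def make_toy_complex(
    n_protein_chains: int = 1,
    n_dna_chains: int = 1,
    seed: int = 1,
    n_residues: int = 10,
    n_nucleotides: int = 8,
    n_contact_pairs: int = 0,
    n_hbond_pairs: int = 0,
    include_site: bool = False,
    n_waters: int = 0,
    jitter: float = 0.0,
) -> tuple[Structure, dict]:
    """Deterministic pseudo-complex with plantable interface features.

    Protein chains (A, B, ...) carry N/CA/C/O/CB backbones with a glutamate
    (OE1/OE2) at residue 101, a lysine at 165 and a serine (OG) at 166;
    DNA chains (E, F, ...) carry P/OP1/OP2/O5'/C1' nucleotides.  Chains are
    laid out far apart so that the planted features below are the only
    inter-molecular geometry:

    * ``n_contact_pairs`` isolated protein–DNA atom pairs at 4.7 Å, each
      contributing exactly one contact at the 5 Å cutoff;
    * ``n_hbond_pairs`` donor–acceptor pairs at 2.9 Å (lysine backbone N to
      OP1, then serine OG to OP2, alternating), each yielding exactly one
      proposed hydrogen bond at the 3.5 Å cutoff;
    * ``include_site`` adds a Mg2+ (chain M) next to the glutamate of chain
      A with a DNA phosphate repositioned into the site (adding exactly two
      protein–DNA pairs within 5 Å, recorded in the truth dict);
    * ``n_waters`` water oxygens (chain W) parked far from everything.

    Returns (structure, truth) where ``truth`` holds every planted count
    and the site/water atom identifiers.
    """
    if n_hbond_pairs > 2:
        raise ConstructionError("at most 2 hbond pairs (one per donor class)")
    if n_contact_pairs > n_nucleotides:
        raise ConstructionError("not enough nucleotides for planted contacts")
    rng = np.random.default_rng(seed)
    protein_ids = [chr(ord("A") + i) for i in range(n_protein_chains)]
    dna_ids = [chr(ord("E") + i) for i in range(n_dna_chains)]
    resnums = [98, 99, 100, 101, 102, 103, 164, 165, 166, 167, 168, 169][:n_residues]
    if n_residues > 12:
        resnums = resnums + list(range(170, 170 + n_residues - 12))
    names = {101: "GLU", 165: "LYS", 166: "SER"}

    ident: list[tuple] = []          # (chain, resnum, resname, name, element, het)
    positions: list[np.ndarray] = []
    index: dict[tuple[str, int, str], int] = {}

    def add(chain, rn, resname, name, element, pos, het=False):
        index[(chain, rn, name)] = len(ident)
        ident.append((chain, rn, resname, name, element, het))
        positions.append(np.asarray(pos, float)
                         + (rng.normal(0, jitter, 3) if jitter > 0 else 0.0))

    centers: dict[tuple[str, int], np.ndarray] = {}
    for ci, chain in enumerate(protein_ids):
        origin = np.array([0.0, 0.0, _CHAIN_SPACING * ci])
        for ri, rn in enumerate(resnums):
            center = origin + np.array([_RESIDUE_SPACING * (ri + 1), 0.0, 0.0])
            centers[(chain, rn)] = center
            resname = names.get(rn, "ALA")
            # CA zig-zags in z so the Cα trace is never collinear
            zig = np.array([0.0, 0.0, 0.25 * (-1) ** ri])
            for an, off in _BB.items():
                add(chain, rn, resname, an, an[0],
                    center + off + (zig if an == "CA" else 0.0))
            if resname == "GLU":
                add(chain, rn, resname, "OE1", "O", center + (-1.0, -2.4, 0.0))
                add(chain, rn, resname, "OE2", "O", center + (-2.0, -2.9, 0.0))
            elif resname == "LYS":
                add(chain, rn, resname, "NZ", "N", center + (-1.0, -2.5, 0.0))
            elif resname == "SER":
                add(chain, rn, resname, "OG", "O", center + (-1.0, -2.3, 0.0))

    dna_offsets = {"P": (0.0, 0.0, 0.0), "OP1": (1.3, 0.8, 0.0),
                   "OP2": (1.3, -0.8, 0.0), "O5'": (-1.2, 0.5, 0.0),
                   "C1'": (-1.2, -1.3, 0.0)}
    for ci, chain in enumerate(dna_ids):
        origin = np.array([0.0, 40.0, _CHAIN_SPACING * ci])
        for nt in range(1, n_nucleotides + 1):
            center = origin + np.array([_RESIDUE_SPACING * nt, 0.0, 0.0])
            resname = "DA" if nt % 2 else "DT"
            for an, off in dna_offsets.items():
                add(chain, nt, resname, an, "P" if an == "P" else an[0],
                    center + off)

    truth: dict = {
        "seed": seed,
        "planted_contact_pairs": n_contact_pairs,
        "planted_hbond_pairs": n_hbond_pairs,
    }

    # planted isolated contacts: an exposed chain-A marker CA paired with a
    # DNA C1' pulled to 4.7 Å below it, both >= 5.5 Å from everything else
    for k in range(n_contact_pairs):
        p = np.array([12.0 * (k + 1), -9.0, -20.0])
        add("A", 900 + k, "GLY", "CA", "C", p)
        positions[index[(dna_ids[0], k + 1, "C1'")]] = p + (0.0, -4.7, 0.0)

    # planted hydrogen bonds (chain A donors, first DNA chain acceptors)
    hbond_pairs = []
    if n_hbond_pairs >= 1:
        dn = positions[index[("A", 165, "N")]]
        positions[index[(dna_ids[0], n_nucleotides, "OP1")]] = dn + (0.0, 2.9, 0.0)
        hbond_pairs.append((("A", 165, "N"), (dna_ids[0], n_nucleotides, "OP1")))
    if n_hbond_pairs >= 2:
        dn = positions[index[("A", 166, "OG")]]
        positions[index[(dna_ids[0], n_nucleotides - 1, "OP2")]] = dn + (0.0, -2.9, 0.0)
        hbond_pairs.append((("A", 166, "OG"), (dna_ids[0], n_nucleotides - 1, "OP2")))
    truth["hbond_pairs"] = hbond_pairs

    site_spec = None
    if include_site:
        mg_pos = centers[("A", 101)] + np.array([0.0, -12.0, 0.0])
        positions[index[("A", 101, "OE1")]] = mg_pos + _SITE_OE1
        positions[index[("A", 101, "OE2")]] = mg_pos + _SITE_OE2
        nt_site = n_nucleotides // 2
        positions[index[(dna_ids[0], nt_site, "P")]] = mg_pos + _SITE_P
        add("M", 1, "MG", "MG", "MG", mg_pos, het=True)
        truth["site_contact_pairs"] = 2  # site P within 5 Å of OE1 and OE2
        site_spec = {
            "mg": ("M", 1, "MG"),
            "carboxylate_oxygens": (("A", 101, "OE1"), ("A", 101, "OE2")),
            "phosphate_atoms": ((dna_ids[0], nt_site, "P"),),
        }
    truth["site"] = site_spec

    water_ids = []
    for w in range(n_waters):
        add("W", w + 1, "HOH", "O", "O", (5.0 * (w + 1), -60.0, 0.0), het=True)
        water_ids.append(("W", w + 1, "O"))
    truth["water_oxygens"] = water_ids

    atoms = [
        AtomRecord(c, rn, rname, an, el, tuple(pos), is_hetero=het)
        for (c, rn, rname, an, el, het), pos in zip(ident, positions)
    ]
    return Structure(atoms, title=f"toy complex seed={seed}"), truth


def site_spec_from_truth(truth: dict, cutoff: float = 3.3) -> ReactiveSiteSpec:
    """Build a ReactiveSiteSpec from a make_toy_complex truth dict."""
    site = truth.get("site")
    if site is None:
        raise ConstructionError("truth dict has no planted site (include_site=False?)")
    return ReactiveSiteSpec(
        mg_atom=tuple(site["mg"]),
        carboxylate_oxygens=tuple(tuple(a) for a in site["carboxylate_oxygens"]),
        phosphate_atoms=tuple(tuple(a) for a in site["phosphate_atoms"]),
        water_oxygens=tuple(tuple(w) for w in truth["water_oxygens"]),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# toy crystals

_SUPPORTED_GROUPS = ("P 1", "P 2", "P 21", "R 3 2:H", "H 3 2")


def make_crystal(
    contents: Structure | None,
    space_group: str = "P 1",
    cell: tuple[float, ...] = (20.0, 20.0, 20.0, 90.0, 90.0, 90.0),
    n_cross_pairs: int = 0,
) -> tuple[Structure, dict]:
    """Attach a crystal cell to a structure, optionally planting contacts.

    With ``n_cross_pairs > 0`` (P 1 only) pairs of marker atoms are added —
    chain X atoms each exactly 4.5 Å from the -a lattice translate of a
    chain Y partner — so that ``crystal_contact_count`` on chain X at a
    5 Å cutoff returns exactly ``n_cross_pairs``.

    Returns (structure with cell, truth dict).
    """
    try:
        ops = space_group_operators(space_group)
    except Exception as e:
        raise ConstructionError(
            f"unsupported space group {space_group!r}; known-good set: "
            f"{_SUPPORTED_GROUPS} (any Hermann-Mauguin symbol gemmi resolves works)"
        ) from e
    a, b, c, al, be, ga = cell
    atoms = list(contents.atoms) if contents is not None else []
    coords = [np.array(at.position) for at in atoms]
    truth: dict = {"planted_cross_pairs": n_cross_pairs,
                   "selection": "chain X" if n_cross_pairs else None}
    if n_cross_pairs:
        if space_group != "P 1":
            raise ConstructionError("cross-pair planting implemented for P 1 only")
        need_b = 6.0 * n_cross_pairs + 8.0
        if b < need_b or a < 12.0 or c < 12.0:
            raise ConstructionError(
                f"cell too small for {n_cross_pairs} planted pairs "
                f"(need a >= 12, b >= {need_b:.0f}, c >= 12)"
            )
        for k in range(n_cross_pairs):
            y = 4.0 + 6.0 * k
            atoms.append(AtomRecord("X", k + 1, "CTA", "C1", "C", (1.0, y, 5.0)))
            coords.append(np.array([1.0, y, 5.0]))
            atoms.append(AtomRecord("Y", k + 1, "CTB", "C2", "C", (a - 3.5, y, 5.0)))
            coords.append(np.array([a - 3.5, y, 5.0]))
    cellobj = CrystalCell(a, b, c, al, be, ga, space_group=space_group, operators=ops)
    out = Structure(atoms, cell=cellobj,
                    title=(contents.title if contents else "toy crystal"))
    return out.with_coords(np.array(coords).reshape(len(atoms), 3)), truth


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectoryRecipe:
    """Gaussian-linear trajectory: base + planted modes + isotropic noise.

    ``modes`` is (K, 3N) with mutually orthonormal rows; ``variances`` (K,)
    are the per-mode amplitude variances (units²).  ``rigid_jitter`` is an
    optional (rotation SD radians, translation SD) pair applied per frame
    to exercise superposition fitting.
    """

    base: Structure
    modes: np.ndarray | None = None
    variances: np.ndarray | None = None
    noise_sd: float = 0.0
    n_frames: int = 100
    seed: int = 0
    units: str = "angstrom"
    rigid_jitter: tuple[float, float] | None = None
    dt_ps: float = 40.0

    def __post_init__(self):
        if self.modes is not None:
            self.modes = np.atleast_2d(np.asarray(self.modes, float))
            self.variances = np.atleast_1d(np.asarray(self.variances, float))
            if self.modes.shape[0] != self.variances.size:
                raise RecipeError("one variance per mode required")
            if self.modes.shape[1] != 3 * len(self.base):
                raise RecipeError("modes must be 3N-vectors over the base atoms")
            G = self.modes @ self.modes.T
            if not np.allclose(G, np.eye(self.modes.shape[0]), atol=1e-8):
                raise RecipeError("modes must be mutually orthonormal (1e-8)")
            if np.any(self.variances < 0):
                raise RecipeError("variances must be non-negative")


def random_orthonormal_modes(n_atoms: int, k: int, seed: int = 0) -> np.ndarray:
    """(k, 3N) mutually orthonormal displacement vectors via QR."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(3 * n_atoms, k))
    Q, _ = np.linalg.qr(M)
    return Q.T


def simulate_trajectory(recipe: TrajectoryRecipe) -> Trajectory:
    """frame_t = base + sum_k a_k(t) mode_k + eps_t, a_k ~ N(0, var_k)."""
    rng = np.random.default_rng(recipe.seed)
    base = recipe.base.coords.reshape(-1)
    T = recipe.n_frames
    X = np.tile(base, (T, 1))
    if recipe.modes is not None:
        amps = rng.normal(size=(T, recipe.modes.shape[0])) * np.sqrt(recipe.variances)
        X = X + amps @ recipe.modes
    if recipe.noise_sd > 0:
        X = X + rng.normal(0.0, recipe.noise_sd, size=X.shape)
    frames = X.reshape(T, -1, 3)
    if recipe.rigid_jitter is not None:
        from scipy.spatial.transform import Rotation

        rot_sd, trans_sd = recipe.rigid_jitter
        center = frames.mean(axis=1, keepdims=True)
        for t in range(T):
            R = Rotation.from_rotvec(rng.normal(0, rot_sd, 3)).as_matrix()
            shift = rng.normal(0, trans_sd, 3)
            frames[t] = (frames[t] - center[t]) @ R.T + center[t] + shift
    return Trajectory(recipe.base, frames, units=recipe.units, dt_ps=recipe.dt_ps)


def plant_reactive_geometry(
    traj: Trajectory,
    site: ReactiveSiteSpec,
    fraction: float,
    margin: float = 0.2,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Overwrite water positions so exactly ceil(fraction*T) frames are reactive.

    In each planted frame one randomly chosen water is placed (from that
    frame's actual site-atom positions) with all three distances at most
    ``cutoff - margin``; in every other frame, and for every other water,
    the Mg distance exceeds ``cutoff + margin``.  Classifier decisions are
    therefore invariant to sub-margin coordinate perturbation.  Returns
    (new trajectory, sorted planted frame indices).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if margin <= 0:
        raise ValueError("margin must be positive")
    res = site.resolve(traj.topology)
    r_ok = min(res.cutoff, res.mg_cutoff) - margin
    if r_ok <= 0:
        raise ConstructionError("margin leaves no feasible radius")
    rng = np.random.default_rng(seed)
    T = traj.n_frames
    n_pos = int(np.ceil(fraction * T))
    planted = np.sort(rng.choice(T, size=n_pos, replace=False)) if n_pos else \
        np.array([], dtype=int)
    planted_set = set(planted.tolist())
    coords = traj.coords.copy()
    anchors = np.array([res.mg, res.oe[0], res.phos[0]])
    for t in range(T):
        frame = coords[t]
        mg = frame[res.mg]
        # park every water far from the site (violates the Mg criterion
        # by construction: 30 Å >> cutoff + margin)
        for j, w in enumerate(res.waters):
            frame[w] = mg + np.array([30.0 + 3.0 * j, 0.0, 0.0])
        if t in planted_set:
            pts = frame[anchors]
            pos = _fit_water(pts, r_ok)
            if pos is None:
                raise ConstructionError(
                    "site atoms too far apart for a common water within "
                    f"{r_ok:.2f} Å of Mg, carboxylate and phosphate"
                )
            w = res.waters[rng.integers(res.waters.size)]
            frame[w] = pos
    return (
        Trajectory(traj.topology, coords, units=traj.units, box=traj.box,
                   dt_ps=traj.dt_ps),
        planted,
    )


def _fit_water(anchors: np.ndarray, radius: float, iters: int = 200):
    """Point within `radius` of all three anchors: centroid + alternating
    projection onto the three balls; None if it fails to converge."""
    p = anchors.mean(axis=0)
    target = 0.98 * radius
    for _ in range(iters):
        moved = False
        for a in anchors:
            d = np.linalg.norm(p - a)
            if d > target:
                p = a + (p - a) * (target / d)
                moved = True
        if not moved:
            break
    if all(np.linalg.norm(p - a) <= radius for a in anchors):
        return p
    return None


# ---------------------------------------------------------------------------
# melt curves


@dataclass
class MeltRecipe:
    """Two-state van't Hoff melt curve with linear baselines and noise.

    ``tm_c`` in °C, ``delta_h_kj`` in kJ/mol; baselines are (intercept,
    slope per °C) for the folded state and — if given — the unfolded state
    (default: folded intercept + amplitude, same zero slope).
    """

    tm_c: float = 58.0
    delta_h_kj: float = 300.0
    baseline_folded: tuple[float, float] = (100.0, 0.0)
    baseline_unfolded: tuple[float, float] | None = None
    amplitude: float = 1000.0
    noise_sd: float = 0.0
    grid: tuple[float, float, float] = (25.0, 100.0, 1.0)
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        start, stop, step = self.grid
        if not (0.0 <= start < stop <= 130.0) or step <= 0:
            raise RecipeError("grid must lie in [0, 130] °C with positive step")


def two_state_fraction(t_c: np.ndarray, tm_c: float, delta_h_kj: float) -> np.ndarray:
    """f(T) = 1 / (1 + exp[(ΔH/R)(1/T − 1/Tm)]), temperatures in kelvin."""
    T = np.asarray(t_c, float) + CELSIUS_OFFSET
    tm = tm_c + CELSIUS_OFFSET
    return 1.0 / (1.0 + np.exp((delta_h_kj * 1000.0 / R_GAS) * (1.0 / T - 1.0 / tm)))


def simulate_melt_curve(recipe: MeltRecipe) -> MeltCurve:
    start, stop, step = recipe.grid
    t = np.arange(start, stop + 0.5 * step, step)
    f = two_state_fraction(t, recipe.tm_c, recipe.delta_h_kj)
    bf_i, bf_s = recipe.baseline_folded
    if recipe.baseline_unfolded is None:
        bu_i, bu_s = bf_i + recipe.amplitude, bf_s
    else:
        bu_i, bu_s = recipe.baseline_unfolded
    F = (1 - f) * (bf_i + bf_s * t) + f * (bu_i + bu_s * t)
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        F = F + rng.normal(0.0, recipe.noise_sd, size=F.size)
    return MeltCurve(t, F, label=recipe.label or f"Tm={recipe.tm_c}")
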