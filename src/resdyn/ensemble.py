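"""Ensemble analyses over MD trajectories.

RMSF profiles, principal component analysis with cross-projection,
Jarvis–Patrick clustering of conformations, atom-pair distance time
series with minimum-image handling, and Functional Mode Analysis (the
linear model tying a per-frame observable to collective motions).

Coordinates carry a unit tag ("angstrom" or "nm"); all analyses are
unit-agnostic and report in the trajectory's units.  MD conventions in
the literature use nm; crystal-structure work uses Å — conversion is
explicit via :meth:`Trajectory.in_units`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import DegenerateFitError, kabsch
from .structure_io import Structure, SelectionSpec, parse_selection

_UNIT_SCALE = {("angstrom", "nm"): 0.1, ("nm", "angstrom"): 10.0}


@dataclass
class Trajectory:
    """Frames of coordinates over a fixed atom topology.

    ``coords`` is (T, N, 3); ``box`` is an optional (T, 3) array of
    orthorhombic box lengths in the same units (used for minimum-image
    distances).  ``dt_ps`` is snapshot cadence metadata only.
    """

    topology: Structure
    coords: np.ndarray
    units: str = "angstrom"
    box: np.ndarray | None = None
    dt_ps: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (T, N, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError("frame atom count does not match topology")
        if self.units not in ("angstrom", "nm"):
            raise ValueError("units must be 'angstrom' or 'nm'")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must be (T, 3) orthorhombic lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def in_units(self, units: str) -> "Trajectory":
        if units == self.units:
            return self
        s = _UNIT_SCALE[(self.units, units)]
        return Trajectory(
            self.topology,
            self.coords * s,
            units=units,
            box=None if self.box is None else self.box * s,
            dt_ps=self.dt_ps,
        )

    def select(self, spec) -> np.ndarray:
        return self.topology.select(spec) if isinstance(spec, (str, SelectionSpec)) \
            else np.asarray(spec, int)


def read_trajectory(path, topology: Structure | None = None,
                    units: str = "angstrom") -> Trajectory:
    """Read a trajectory: multi-model PDB natively, XTC/DCD via mdtraj.

    Multi-model PDB coordinates are in Å.  Binary formats need a topology
    PDB path or Structure and require mdtraj to be installed.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return _read_multimodel_pdb(path)
    try:
        import mdtraj
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            f"reading {suffix} trajectories requires mdtraj"
        ) from e
    if topology is None:
        raise ValueError("binary trajectory formats require a topology")
    top_path = topology if isinstance(topology, (str, Path)) else None
    if top_path is None:
        raise ValueError("pass the topology as a PDB file path for mdtraj formats")
    t = mdtraj.load(str(path), top=str(top_path))
    from .structure_io import read_structure

    struct = read_structure(top_path)
    box = None
    if t.unitcell_lengths is not None:
        box = t.unitcell_lengths * 10.0  # mdtraj nm -> Å
    traj = Trajectory(struct, t.xyz * 10.0, units="angstrom", box=box)
    return traj if units == "angstrom" else traj.in_units(units)


def _read_multimodel_pdb(path) -> Trajectory:
    import gemmi

    from .structure_io import _from_gemmi_model

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    top = _from_gemmi_model(st, st[0])
    frames = np.empty((len(st), len(top), 3))
    for m, model in enumerate(st):
        k = 0
        for chain in model:
            for res in chain:
                for at in res:
                    frames[m, k] = (at.pos.x, at.pos.y, at.pos.z)
                    k += 1
        if k != len(top):
            raise ValueError(f"{path}: model {m + 1} atom count differs")
    return Trajectory(top, frames, units="angstrom")


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write the trajectory as a multi-model PDB (always in Å)."""
    from .structure_io import write_pdb
    import io

    t = traj.in_units("angstrom")
    chunks = []
    for m in range(t.n_frames):
        frame = t.topology.with_coords(t.coords[m])
        buf = Path(str(path) + ".tmp_frame")
        write_pdb(frame, buf)
        body = buf.read_text().rstrip().removesuffix("END").rstrip()
        buf.unlink()
        chunks.append(f"MODEL     {m + 1:4d}\n{body}\nENDMDL")
    Path(path).write_text("\n".join(chunks) + "\nEND\n")


# ---------------------------------------------------------------------------
# fitting and RMSF


def fit_frames(traj: Trajectory, reference: np.ndarray | Structure | None = None,
               selection=None) -> Trajectory:
    """Least-squares superpose every frame onto a reference over a selection.

    The Kabsch transform is computed on the selection and applied to all
    atoms.  Default reference is the trajectory mean (computed after a
    first-pass fit to frame 0, the standard iteration).
    """
    sel = traj.select(selection) if selection is not None else np.arange(traj.n_atoms)
    if sel.size < 3:
        raise DegenerateFitError("selection too small to define a fit")
    if reference is None:
        pre = fit_frames(traj, traj.coords[0], sel)
        return fit_frames(pre, pre.coords.mean(axis=0), sel)
    ref = reference.coords if isinstance(reference, Structure) else np.asarray(reference, float)
    out = np.empty_like(traj.coords)
    for tdx in range(traj.n_frames):
        _, R, tv = kabsch(traj.coords[tdx, sel], ref[sel])
        out[tdx] = traj.coords[tdx] @ R.T + tv
    return Trajectory(traj.topology, out, units=traj.units, box=traj.box,
                      dt_ps=traj.dt_ps)


@dataclass
class RMSFProfile:
    """Per-atom (typically per-residue via Cα) fluctuation profile."""

    residue_numbers: np.ndarray
    chain_ids: list[str]
    rmsf: np.ndarray
    units: str
    region: tuple[int, int] | None = None
    region_mean: float | None = None
    region_se: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chain": self.chain_ids, "residue": self.residue_numbers,
             "rmsf": self.rmsf}
        )


def rmsf_profile(traj: Trajectory, selection, region: tuple[int, int] | None = None
                 ) -> RMSFProfile:
    """RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>_t) for each selected atom.

    Frames must already be superposed onto a common reference.  With a
    residue ``region`` (inclusive author-numbering range) the mean RMSF over
    the region's residues and its standard error (stdev over residues /
    sqrt(n)) are reported — the statistic used for stalk-flexibility
    comparisons.
    """
    sel = traj.select(selection)
    X = traj.coords[:, sel, :]
    if traj.n_frames < 2:
        warnings.warn("single-frame trajectory: RMSF is identically zero")
        vals = np.zeros(sel.size)
    else:
        mean = X.mean(axis=0)
        vals = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    resnums = np.array([traj.topology.atoms[i].residue_number for i in sel])
    chains = [traj.topology.atoms[i].chain_id for i in sel]
    prof = RMSFProfile(resnums, chains, vals, traj.units, region=region)
    if region is not None:
        lo, hi = region
        mask = (resnums >= lo) & (resnums <= hi)
        if mask.sum() == 0:
            raise ValueError(f"no selected atoms in residue range {region}")
        sub = vals[mask]
        prof.region_mean = float(sub.mean())
        prof.region_se = float(sub.std(ddof=1) / np.sqrt(sub.size)) if sub.size > 1 else 0.0
    return prof


# ---------------------------------------------------------------------------
# PCA


@dataclass
class EigenModel:
    """PCA of the Cartesian coordinate covariance of an ensemble.

    ``modes`` columns are orthonormal 3M-vectors sorted by descending
    eigenvalue (units: length^2 of the source trajectory).  ``atom_keys``
    records which atoms (and in which order) the model spans, so other
    ensembles can be mapped onto it.
    """

    atom_keys: list[tuple[str, int, str]]
    mean: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float
    units: str = "angstrom"

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    def summary(self, k: int = 5) -> pd.DataFrame:
        k = min(k, self.eigenvalues.size)
        return pd.DataFrame(
            {
                "mode": np.arange(1, k + 1),
                "eigenvalue": self.eigenvalues[:k],
                "fraction": self.variance_fractions[:k],
                "cumulative": np.cumsum(self.variance_fractions[:k]),
            }
        )


def pca_decompose(trajs: Trajectory | list[Trajectory], selection=None,
                  n_modes: int | None = None) -> EigenModel:
    """Eigendecompose the coordinate covariance of one or more trajectories.

    Frames must be superposed on a common reference beforehand (see
    :func:`fit_frames` / :func:`concatenate_fitted`); replicates are
    concatenated along time.  Covariance is unweighted Cartesian with 1/T
    normalisation.
    """
    tlist = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    if not tlist:
        raise ValueError("no trajectories given")
    sel = tlist[0].select(selection) if selection is not None \
        else np.arange(tlist[0].n_atoms)
    units = tlist[0].units
    blocks = []
    for t in tlist:
        if t.units != units:
            t = t.in_units(units)
        blocks.append(t.coords[:, sel, :].reshape(t.n_frames, -1))
    X = np.concatenate(blocks, axis=0)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least two frames")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_modes is not None:
        evals_keep, evecs = evals[:n_modes], evecs[:, :n_modes]
    else:
        evals_keep = evals
    keys = [tlist[0].topology.atoms[i].key for i in sel]
    return EigenModel(
        atom_keys=keys,
        mean=mean,
        modes=evecs,
        eigenvalues=evals_keep,
        total_variance=float(np.trace(cov)),
        units=units,
    )


def concatenate_fitted(trajs: list[Trajectory], selection=None) -> list[Trajectory]:
    """Fit replicate trajectories to a common reference (replicate-1 mean).

    Replicate 1 is fitted to its own mean (via a frame-0 pre-fit); the
    other replicates are then fitted to that same mean structure.
    """
    sel = trajs[0].select(selection) if selection is not None \
        else np.arange(trajs[0].n_atoms)
    first = fit_frames(trajs[0], None, sel)
    ref = first.coords.mean(axis=0)
    return [first] + [fit_frames(t, ref, sel) for t in trajs[1:]]


class AtomMappingError(KeyError):
    pass


def project_onto_modes(traj: Trajectory, model: EigenModel,
                       mode_indices=None) -> np.ndarray:
    """Project frames onto eigenmodes: p_k(t) = (x(t) - mean) . mode_k.

    The trajectory is mapped onto the model's atom set by
    (chain, residue, atom name); atoms the trajectory lacks raise
    :class:`AtomMappingError` listing them.  Returns (T, K).
    """
    if mode_indices is None:
        mode_indices = np.arange(model.modes.shape[1])
    mode_indices = np.asarray(mode_indices, int)
    lookup = {a.key: i for i, a in enumerate(traj.topology.atoms)}
    missing = [k for k in model.atom_keys if k not in lookup]
    if missing:
        raise AtomMappingError(
            f"trajectory lacks {len(missing)} model atoms, e.g. {missing[:5]}"
        )
    idx = np.array([lookup[k] for k in model.atom_keys], int)
    t = traj if traj.units == model.units else traj.in_units(model.units)
    X = t.coords[:, idx, :].reshape(t.n_frames, -1)
    return (X - model.mean) @ model.modes[:, mode_indices]


def write_mode_extremes(model: EigenModel, topology: Structure, mode: int,
                        amplitude: float, path) -> None:
    """Write a 2-model PDB of the structure displaced ±amplitude along a mode."""
    lookup = {a.key: i for i, a in enumerate(topology.atoms)}
    idx = np.array([lookup[k] for k in model.atom_keys], int)
    base = model.mean.reshape(-1, 3)
    disp = model.modes[:, mode].reshape(-1, 3)
    frames = []
    for sgn in (+1.0, -1.0):
        coords = topology.coords.copy()
        coords[idx] = base + sgn * amplitude * disp
        frames.append(coords)
    scale = 10.0 if model.units == "nm" else 1.0
    sub = Trajectory(topology, np.stack(frames) * scale
                     if scale != 1.0 else np.stack(frames), units="angstrom")
    write_multimodel_pdb(sub, path)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    labels: np.ndarray           # cluster id per frame, 0 = most populated
    representatives: list[int]   # frame index per cluster
    sizes: np.ndarray
    rmsd_cutoff: float
    min_shared: int

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def occupancy_table(self) -> pd.DataFrame:
        frac = self.sizes / self.labels.size
        return pd.DataFrame(
            {"cluster": np.arange(self.n_clusters), "size": self.sizes,
             "occupancy": frac, "representative": self.representatives}
        )


def pairwise_rmsd_matrix(traj: Trajectory, selection=None) -> np.ndarray:
    """All-vs-all RMSD over a selection, each pair optimally superposed."""
    sel = traj.select(selection) if selection is not None else np.arange(traj.n_atoms)
    X = traj.coords[:, sel, :]
    T = traj.n_frames
    out = np.zeros((T, T))
    centered = X - X.mean(axis=1, keepdims=True)
    for i in range(T):
        for j in range(i + 1, T):
            r, _, _ = kabsch(centered[i], centered[j])
            out[i, j] = out[j, i] = r
    return out


def jarvis_patrick_cluster(traj: Trajectory, selection=None,
                           rmsd_cutoff: float = 2.0, min_shared: int = 10,
                           rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """Jarvis–Patrick clustering on pairwise superposed RMSD.

    Frames i, j are neighbours iff RMSD(i, j) <= cutoff (self excluded);
    they join the same cluster iff they are neighbours AND share at least
    ``min_shared`` common neighbours; clusters are the transitive closure
    of that relation, ordered by occupancy.  The representative of a
    cluster is the frame minimising total intra-cluster RMSD.

    ``rmsd_cutoff`` is in the trajectory's units (the literature default
    0.2 nm equals 2 Å).
    """
    D = pairwise_rmsd_matrix(traj, selection) if rmsd_matrix is None else rmsd_matrix
    T = D.shape[0]
    nb = (D <= rmsd_cutoff + 1e-12)
    np.fill_diagonal(nb, False)
    shared = nb.astype(int) @ nb.astype(int)
    adj = nb & (shared >= min_shared)
    from scipy.sparse.csgraph import connected_components

    _, comp = connected_components(adj, directed=False)
    # order clusters by size desc, ties by smallest member frame
    ids, sizes = np.unique(comp, return_counts=True)
    first_member = [int(np.nonzero(comp == c)[0][0]) for c in ids]
    order = sorted(range(len(ids)), key=lambda k: (-sizes[k], first_member[k]))
    relabel = {ids[k]: rank for rank, k in enumerate(order)}
    labels = np.array([relabel[c] for c in comp])
    reps, out_sizes = [], []
    for c in range(len(ids)):
        members = np.nonzero(labels == c)[0]
        sub = D[np.ix_(members, members)]
        reps.append(int(members[np.argmin(sub.sum(axis=1))]))
        out_sizes.append(members.size)
    return ClusterResult(labels, reps, np.array(out_sizes), rmsd_cutoff, min_shared)


# ---------------------------------------------------------------------------
# distances and FMA


def distance_series(traj: Trajectory, atom_a, atom_b):
    """Per-frame distance between two atoms, (series, min, max).

    Atoms are (chain, resnum, atom name) triples or integer indices.
    Minimum-image convention applies when the trajectory carries a box.
    """
    ia = atom_a if isinstance(atom_a, (int, np.integer)) \
        else traj.topology.atom_index(*atom_a)
    ib = atom_b if isinstance(atom_b, (int, np.integer)) \
        else traj.topology.atom_index(*atom_b)
    dv = traj.coords[:, int(ib), :] - traj.coords[:, int(ia), :]
    if traj.box is not None:
        dv = dv - traj.box * np.round(dv / traj.box)
    series = np.linalg.norm(dv, axis=1)
    return series, float(series.min()), float(series.max())


@dataclass
class FMAModel:
    """Functional Mode Analysis: OLS of an observable on mode projections.

    ``beta`` are the per-mode coefficients; the composite functional mode
    (the single collective motion most correlated with the observable) is
    the beta-weighted combination of the eigenmodes when a model is given.
    """

    beta: np.ndarray
    intercept: float
    r_train: float
    r_valid: float
    mode_vector: np.ndarray | None = None
    train_frames: int = 0

    def predict(self, projections: np.ndarray) -> np.ndarray:
        return projections @ self.beta + self.intercept


class ConstantObservableError(ValueError):
    pass


def functional_mode_analysis(projections: np.ndarray, observable: np.ndarray,
                             train_fraction: float = 0.5,
                             model: EigenModel | None = None,
                             mode_indices=None) -> FMAModel:
    """Fit observable(t) ~ intercept + sum_k beta_k p_k(t) by least squares.

    The fit uses the chronologically first ``train_fraction`` of frames;
    Pearson correlation between the model and the observable is reported on
    both the training segment and the held-out remainder.
    """
    P = np.asarray(projections, float)
    y = np.asarray(observable, float)
    if P.ndim != 2 or P.shape[0] != y.size:
        raise ValueError("projections must be (T, K) matching observable length")
    if np.ptp(y) == 0:
        raise ConstantObservableError("observable is constant; correlation undefined")
    T = y.size
    n_train = max(int(round(T * train_fraction)), P.shape[1] + 2)
    n_train = min(n_train, T)
    A = np.column_stack([P[:n_train], np.ones(n_train)])
    coef, *_ = np.linalg.lstsq(A, y[:n_train], rcond=None)
    beta, intercept = coef[:-1], float(coef[-1])
    pred = P @ beta + intercept

    def _corr(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    r_train = _corr(pred[:n_train], y[:n_train])
    r_valid = _corr(pred[n_train:], y[n_train:]) if n_train < T else float("nan")
    vec = None
    if model is not None:
        cols = np.arange(model.modes.shape[1]) if mode_indices is None \
            else np.asarray(mode_indices, int)
        vec = model.modes[:, cols[: beta.size]] @ beta
    return FMAModel(beta, intercept, r_train, r_valid, vec, n_train)
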