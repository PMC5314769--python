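"""Geometric reactive-state detection in resolvase active sites.

A frame is *reactive* when a single water oxygen simultaneously lies
within the cutoff (default 3.3 Å) of (i) the catalytic Mg2+, (ii) at
least one of the two carboxylate oxygens of the catalytic glutamate
(OE1/OE2 of E101 in RecU), and (iii) at least one candidate scissile
phosphate of the DNA backbone.  This is the geometric precondition of the
first step of the proposed cleavage mechanism; occupancy is the percent
of frames classified reactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Trajectory
from .structure_io import Structure

AtomId = "tuple[str, int, str] | int"


class EmptyWaterSetError(ValueError):
    pass


class ConstantSeriesError(ValueError):
    pass


@dataclass
class ReactiveSiteSpec:
    """One active site: Mg2+, the two carboxylate oxygens, candidate
    phosphates, and the water-oxygen pool to scan.

    Atom ids are either integer indices or (chain, resnum, atom name)
    triples resolved against the topology.  ``cutoff`` applies to the
    carboxylate and phosphate criteria; ``mg_cutoff`` (defaulting to
    ``cutoff``) lets the Mg-coordination criterion be tightened separately.
    """

    mg_atom: object
    carboxylate_oxygens: tuple
    phosphate_atoms: tuple
    water_oxygens: tuple
    cutoff: float = 3.3
    mg_cutoff: float | None = None

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if len(self.carboxylate_oxygens) != 2:
            raise ValueError("exactly two carboxylate oxygens required")
        if len(self.phosphate_atoms) < 1:
            raise ValueError("at least one phosphate atom required")

    def resolve(self, topology: Structure) -> "ResolvedSite":
        def one(a):
            return int(a) if isinstance(a, (int, np.integer)) else topology.atom_index(*a)

        waters = np.array([one(w) for w in self.water_oxygens], int)
        if waters.size == 0:
            raise EmptyWaterSetError("water-oxygen pool is empty; cannot classify")
        return ResolvedSite(
            mg=one(self.mg_atom),
            oe=np.array([one(a) for a in self.carboxylate_oxygens], int),
            phos=np.array([one(a) for a in self.phosphate_atoms], int),
            waters=waters,
            cutoff=self.cutoff,
            mg_cutoff=self.cutoff if self.mg_cutoff is None else self.mg_cutoff,
        )


@dataclass
class ResolvedSite:
    mg: int
    oe: np.ndarray
    phos: np.ndarray
    waters: np.ndarray
    cutoff: float
    mg_cutoff: float


def _dist(frame: np.ndarray, i: np.ndarray, j: int, box) -> np.ndarray:
    dv = frame[i] - frame[j]
    if box is not None:
        dv = dv - box * np.round(dv / box)
    return np.linalg.norm(dv, axis=1)


def classify_frame(frame: np.ndarray, site: ResolvedSite | ReactiveSiteSpec,
                   topology: Structure | None = None, box=None):
    """Classify one frame; returns (is_reactive, witness water index or None).

    The witness is the qualifying water closest to Mg (ties broken by atom
    index).  Distances use the minimum image when a box is given.
    """
    if isinstance(site, ReactiveSiteSpec):
        if topology is None:
            raise ValueError("a topology is needed to resolve a ReactiveSiteSpec")
        site = site.resolve(topology)
    d_mg = _dist(frame, site.waters, site.mg, box)
    d_oe = np.min(
        np.stack([_dist(frame, site.waters, int(o), box) for o in site.oe]), axis=0
    )
    d_p = np.min(
        np.stack([_dist(frame, site.waters, int(p), box) for p in site.phos]), axis=0
    )
    ok = (d_mg <= site.mg_cutoff) & (d_oe <= site.cutoff) & (d_p <= site.cutoff)
    if not ok.any():
        return False, None
    cands = np.nonzero(ok)[0]
    # smallest d(w, Mg); ties by atom id
    best = cands[np.lexsort((site.waters[cands], d_mg[cands]))[0]]
    return True, int(site.waters[best])


@dataclass
class ReactiveSeries:
    """Per-frame reactivity flags with witnesses and occupancy percent."""

    flags: np.ndarray
    witnesses: list
    cutoff: float

    @property
    def occupancy(self) -> float:
        """Occupancy in percent: 100 x (reactive frames) / (total frames)."""
        return 100.0 * float(np.count_nonzero(self.flags)) / self.flags.size

    @property
    def reactive_frames(self) -> np.ndarray:
        return np.nonzero(self.flags)[0]


def occupancy_percent(traj: Trajectory, spec: ReactiveSiteSpec) -> ReactiveSeries:
    """Apply :func:`classify_frame` to every frame of a trajectory."""
    site = spec.resolve(traj.topology)
    flags = np.zeros(traj.n_frames, dtype=bool)
    witnesses: list = []
    for t in range(traj.n_frames):
        box = traj.box[t] if traj.box is not None else None
        hit, w = classify_frame(traj.coords[t], site, box=box)
        flags[t] = hit
        witnesses.append(w)
    return ReactiveSeries(flags, witnesses, spec.cutoff)


def union_series(a: ReactiveSeries, b: ReactiveSeries) -> ReactiveSeries:
    """Frames reactive in either site (the two sites of a dimer)."""
    flags = a.flags | b.flags
    wit = [wa if wa is not None else wb for wa, wb in zip(a.witnesses, b.witnesses)]
    return ReactiveSeries(flags, wit, a.cutoff)


def site_correlation(series_a, series_b) -> float:
    """Pearson correlation of two per-frame reactivity indicator series.

    Accepts :class:`ReactiveSeries` or boolean/0-1 arrays of equal length.
    Used to test whether the two active sites of the dimer fire
    independently.
    """
    fa = series_a.flags if isinstance(series_a, ReactiveSeries) else np.asarray(series_a)
    fb = series_b.flags if isinstance(series_b, ReactiveSeries) else np.asarray(series_b)
    fa = fa.astype(float)
    fb = fb.astype(float)
    if fa.size != fb.size:
        raise ValueError("series lengths differ")
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        raise ConstantSeriesError(
            "at least one series is constant; Pearson correlation undefined"
        )
    return float(np.corrcoef(fa, fb)[0, 1])
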