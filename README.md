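# resdyn

Analytics for structural and dynamic studies of protein–DNA complexes,
built around the workflows used to characterise Holliday-junction (HJ)
resolvases such as RecU: static interface geometry on crystal structures,
ensemble statistics over molecular-dynamics trajectories, a geometric
classifier for catalytically "reactive" active-site configurations, and
thermal-shift (thermofluor) melting-curve thermodynamics.

It is aimed at structural biologists and simulators who need these
measurements as reproducible, scriptable steps rather than one-off
interactive sessions — every analysis is a library function with a thin
`resdyn` CLI on top, and every synthetic test input is generated with
known ground truth.

## What it computes

**Static structure** (`structure_io`, `contacts`): PDB/mmCIF reading with
altloc resolution; conjunctive atom selections; crystal-symmetry
expansion from the unit cell and space-group operators; protein–DNA
contact censuses (unordered heavy-atom pairs at distance ≤ cutoff, 5.0 Å
default, with per-chain breakdown); hydrogen-bond proposal
(donor–acceptor N/O pairs ≤ 3.5 Å when no hydrogens are present); crystal
contacts of a selection against all symmetry images; atom-pair distances;
Kabsch superposition RMSD; radius of gyration.

**Ensembles** (`ensemble`): least-squares frame fitting; per-residue RMSF
with region averages ± standard error; PCA of the Cartesian coordinate
covariance, with cross-projection of other ensembles onto a reference
model's eigenvectors; Jarvis–Patrick clustering on pairwise superposed
RMSD (cutoff-neighbourhood variant: neighbours at RMSD ≤ cutoff sharing
≥ `min_shared` common neighbours); atom-pair distance time series with
minimum-image handling; Functional Mode Analysis — ordinary least squares
of a per-frame observable on the leading mode projections,

&nbsp;&nbsp;&nbsp;&nbsp;y(t) ≈ β₀ + Σₖ βₖ pₖ(t),&nbsp;&nbsp;
functional mode = Σₖ βₖ **v**ₖ,

with Pearson correlations reported on chronological train/validation
halves.

**Reactive state** (`reactive`): a frame is reactive when one water
oxygen w simultaneously satisfies

&nbsp;&nbsp;&nbsp;&nbsp;d(w, Mg²⁺) ≤ 3.3 Å ∧ min d(w, OE1/OE2) ≤ 3.3 Å ∧
min d(w, P) ≤ 3.3 Å

— the geometric precondition of the first step of phosphodiester
cleavage. Reported per site as occupancy (% of frames), with witness
waters and inter-site Pearson correlation.

**Thermofluor** (`thermofluor`): 5-point smoothing; Tm from the maximum
of dF/dT with quadratic sub-grid refinement; ΔTm against a control;
two-state unfolded fraction f(T) from linear baselines; van't Hoff
analysis on Keq = f/(1−f):

&nbsp;&nbsp;&nbsp;&nbsp;ln Keq = (−ΔH/R)(1/T) + ΔS/R,&nbsp;&nbsp;
ΔH = −R·slope,&nbsp;&nbsp;ΔS = ΔH/Tm.

**Synthetic data** (`synthetic`): seed-deterministic generators for toy
complexes/crystals with planted contact counts, Gaussian-linear
trajectories with planted orthonormal modes, reactive-geometry planting
with safety margins, and two-state melt curves — each emitting its
ground truth for recovery testing.

## Worked example

```python
import numpy as np
from resdyn import synthetic as syn, ensemble as ens, thermofluor as tf

# a planted two-mode ensemble, variances 4:1
base, _ = syn.make_toy_complex(seed=1)
modes = syn.random_orthonormal_modes(len(base), 2, seed=5)
traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
    base, modes, np.array([4.0, 1.0]), n_frames=5000, seed=2))
model = ens.pca_decompose(traj)
print(model.summary(3).to_string(index=False))

# a thermal-shift pair, planted 10.1 °C apart
grid = (25.0, 100.0, 0.1)
ctrl = syn.simulate_melt_curve(syn.MeltRecipe(tm_c=47.9, grid=grid))
samp = syn.simulate_melt_curve(syn.MeltRecipe(tm_c=58.0, grid=grid))
print(f"delta Tm = {tf.delta_tm(samp, ctrl):.1f} C")
```

prints

```
 mode   eigenvalue     fraction  cumulative
    1 4.098525e+00 8.043574e-01    0.804357
    2 9.968780e-01 1.956426e-01    1.000000
    3 1.047601e-15 2.055973e-16    1.000000
delta Tm = 10.1 C
```

The PCA recovers the planted 4:1 variance spectrum (fractions 0.80/0.20)
and the derivative-Tm pipeline recovers the planted melting-point shift
to 0.1 °C.

The same operations are available from the shell, e.g.

```
resdyn simulate complex --contacts 7 --out toy.pdb
resdyn contacts --in toy.pdb --a protein --b nucleic --cutoff 5.0
resdyn melt --sample hj12.tsv --control ctrl.tsv --report melt.json
```

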