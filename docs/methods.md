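# Methods

This note records the models, conventions and deliberate design choices
behind each analysis, what the synthetic generators do and do not
emulate, and the numerical details a user reproducing or extending the
package needs.

## Structures, selections, symmetry

Structures are ordered atom lists with author residue numbering (as
deposited); parsing goes through gemmi for both PDB and mmCIF. Altloc
groups are collapsed to one conformer — highest occupancy, ties broken
alphabetically — because a deterministic rule is needed and low-resolution
protein–DNA structures rarely justify anything subtler. Hydrogens are
retained when present, but all heavy-atom analyses (contacts, crystal
contacts) exclude element H by default so counts are comparable with
hydrogen-free crystal structures. The legacy phosphate-oxygen names
O1P/O2P are normalised to OP1/OP2 on ingest; selections written either
way resolve identically.

Crystal-symmetry expansion fractionalises coordinates with the standard
orthogonalisation matrix, applies every space-group operator (gemmi's
operator sets, which include the rhombohedral centering translations
(0,0,0), (2/3,1/3,1/3), (1/3,2/3,2/3) for R32 in the hexagonal setting)
and searches lattice translations of ±1 cell per axis by default
(`max_shell` is exposed). Adjacent cells are ample for contact-scale
radii (≈5 Å) with macromolecular cells; the bound also keeps the image
list interpretable — an unbounded search at a radius larger than the
cell would return entire coordination shells of lattice translates.

Contacts are unordered heavy-atom pairs at distance ≤ cutoff
(inclusive), with no exclusion of hydrogen-bonded pairs; per-chain
counts attribute each pair to its set-A (protein-side) member. The
inclusive boundary is a convention choice; generators therefore plant
distances ≥ 0.2 Å away from cutoffs so no test outcome can hinge on it.
Hydrogen-bond proposal is distance-only (donor–acceptor N/O ≤ 3.5 Å,
different residues) unless hydrogens exist and an angle cutoff is
requested; both knobs are exposed. Crystal-contact counting pairs a
selection against all non-identity symmetry images; intra-asymmetric-unit
contacts are excluded by construction.

Superposition is Kabsch (SVD with a det = +1 correction); collinear or
sub-3-point selections raise a degenerate-fit error. Dimer-vs-dimer RMSD
pairs common residues by number over N/CA/C/O, tries both chain-pair
assignments and reports the minimum. An independent quaternion
(Horn closed-form) implementation serves as the test oracle.

## Ensembles

Trajectories carry a unit tag (Å or nm) and all analyses report in the
trajectory's units; MD conventions use nm (an RMSF of 0.12 nm = 1.2 Å),
crystallographic work Å, and conversion is explicit. Multi-model PDB is
read natively; XTC/DCD go through mdtraj when installed.

PCA uses the unweighted Cartesian covariance (1/T normalisation) of the
backbone selection about its mean, eigendecomposed symmetrically; mass
weighting is deliberately omitted as the default because backbone-only
covariance is already nearly uniform in mass and the unweighted form
keeps the projection/eigenvalue identity exact. Frames must be fitted to
a common reference first — `concatenate_fitted` implements the replicate
protocol (fit replicate 1 to its own mean, fit the rest to that mean,
concatenate). Cross-ensemble projection maps atoms by (chain, residue,
name); comparing constructs that lack residues (e.g. an N-terminal
truncation) requires building the reference model on the atom set common
to all constructs — the only self-consistent choice, exercised in the
tests.

RMSF is computed per selected atom (conventionally Cα) after fitting;
region summaries report the mean over residues in an inclusive
author-numbering range and the standard error (SD over residues /√n).
The flexible-stalk convention in resolvase work averages residues 56–89
and excludes the N-terminal region; region bounds are always explicit
parameters here.

Jarvis–Patrick clustering uses the cutoff-neighbourhood variant:
neighbours at pairwise superposed RMSD ≤ cutoff (0.2 nm = 2 Å default),
an edge when two neighbours share ≥ `min_shared` (default 10) common
neighbours, clusters as connected components, representatives minimising
total intra-cluster RMSD. The P-shared-of-M-nearest variant found in
some MD packages is not implemented; the cutoff variant is documented
and invariant to frame order and global rigid motion (both tested).

FMA regresses the observable on the first K mode projections (default
K = 25 in the CLI) with an intercept, fitting on the chronologically
first half and validating on the second — a chronological split because
MD frames are autocorrelated and a random split would leak. Planted
linear models are recovered within 5% at 10% observable noise (tested).

## Reactive-state statistic

"Coordinating with Mg²⁺" is operationalised as the same 3.3 Å cutoff
used for the carboxylate and phosphate criteria (a separate `mg_cutoff`
is exposed). The classifier is the literal existential statement over
the water pool; the witness water is the qualifying water nearest Mg,
ties broken by atom index. Distances are minimum-image when a box is
present. Occupancy is 100 × reactive frames / total frames, reported to
2 significant figures in CLI summaries (full precision in the API).
Because the scissile phosphate is not known a priori, the spec accepts a
list of candidate P atoms and uses the minimum distance. Sites are
evaluated independently (one spec per active site); `union_series`
combines the two sites of a dimer but per-site and union occupancies are
always reported separately, since an ensemble-level "fraction of time
either site is reactive" depends on that aggregation choice. Inter-site
independence is quantified as the Pearson correlation of the two binary
series (undefined, and an error, when a series is constant).

## Thermofluor

The analysis chain mirrors standard thermal-shift practice: 5-point
centred moving average (edges use shrinking symmetric windows, which
preserve linear segments exactly); Tm at the maximum of dF/dT, refined
by a quadratic through the peak and its two grid neighbours — this is
what yields 0.1 °C precision from a 1 °C gradient. Fluorescence is
assumed to rise on unfolding (SYPRO-orange convention); `invert` covers
the opposite sign.

The unfolded fraction divides out linear baselines fitted on the first
and last 15% of the grid; the upper window is truncated at the
fluorescence maximum when post-transition aggregation rollover is
detected and never starts before Tm + 10 °C. Baselines are fitted on the
*raw* curve: smoothing broadens the transition and would bias the van't
Hoff slope low by several percent. f is clipped to [1e-6, 1−1e-6].

Van't Hoff analysis takes Keq = f/(1−f) (the thermodynamically standard
two-state ratio; the equilibrium-constant equation is sometimes printed
with the ratio on the ln side, which cannot be meant literally) and fits
ln Keq against 1/T(K) over the band f ∈ [0.1, 0.9], where the logit is
well conditioned. ΔH = −R·slope with R = 8.314 J/(mol K); Tm is the
ln Keq = 0 crossing of the fitted line unless a derivative Tm is
supplied; ΔS = ΔH/Tm(K) holds by construction (the "conformational
entropy" convention). Kelvin conversion is T(K) = T(°C) + 273.15
throughout. Replicates (typically 4) are averaged point-wise on a common
grid before analysis, with per-replicate Tm spread reported separately.

A subtlety worth knowing: for a two-state transition the derivative
maximum sits ≈ 4R²Tm³/ΔH² below the true midpoint (≈ 0.1 °C at
ΔH = 300 kJ/mol, Tm = 320 K) because f is logistic in 1/T, not in T.
The bias is common-mode between sample and control, so ΔTm is unbiased
to well under 0.01 °C — one reason ΔTm, not absolute Tm, is the robust
read-out of the assay.

## Synthetic generators

The trajectory generator is Gaussian-linear — base structure plus
planted orthonormal displacement modes with chosen variances plus
isotropic noise, optionally wrapped in rigid-body jitter. That is the
minimal statistical structure against which a linear-algebraic pipeline
(fitting, RMSF, PCA, projection, FMA) can be validated with exact ground
truth. It is deliberately *not* physical: no force field, no solvent, no
anharmonicity, no autocorrelation in time. Passing recovery tests
therefore demonstrates the correctness of the estimators, not their
behaviour on rugged real free-energy landscapes; in particular real
ensembles mix slowly, so variance fractions from finite trajectories
carry sampling error these tests do not probe.

Reactive-geometry planting overwrites the water coordinates of every
frame: in planted frames one randomly chosen water is placed from that
frame's actual site-atom positions (centroid of Mg/OE1/P, pulled inside
each 3.3 − margin sphere by alternating projection; infeasible geometry
raises, never fudges), and in all frames every other water is parked
30 Å from Mg. With the default 0.2 Å margin, classifier decisions are
invariant to 0.1 Å coordinate rounding (tested), so planted occupancy is
recovered *exactly* — the classifier and generator share no code path.

Melt curves are generated from the same two-state van't Hoff model the
analyser assumes, f(T) = 1/(1 + exp[(ΔH/R)(1/T − 1/Tm)]), mixed between
two linear baselines with optional Gaussian noise. Recovery is therefore
a round-trip consistency check; it does not validate the two-state
assumption against multi-state or kinetically limited unfolding.

Toy complexes place protein-like and DNA-like chains ~40 Å apart and
plant interface features as isolated geometric motifs (a 4.7 Å contact
pair, a 2.9 Å donor–acceptor pair) spaced so each contributes exactly
one count at the default cutoffs; toy crystals plant cross-image pairs
at 4.5 Å across a P1 cell edge. All generators are seed-deterministic
and return their planted quantities as a truth dictionary (written as a
sidecar JSON by the CLI).

## Problem sizes and defaults

Default parameters follow the values standard in this workflow: 5.0 Å
contact cutoff, 3.5 Å hydrogen bonds, 3.3 Å reactive-state cutoff,
0.2 nm / 10 shared neighbours for Jarvis–Patrick, 25 FMA modes, 5-point
smoothing, 25–100 °C melt grids at 1 °C (0.1 °C for sub-degree shift
recovery), ΔH = 300 kJ/mol for synthetic curves. Statistical recovery
tests use T = 5000 frames (variance-fraction recovery to ±2 points) or
T = 1000 (occupancy), and ~100-atom toy systems — sizes chosen so the
full suite exercises every estimator at meaningful precision while
remaining a desk-scale computation.

## Known limitations

- No interface-area (BSA) computation, schematic interaction rendering,
  free-energy landscapes or cross-correlation maps.
- The symmetry search is bounded (±`max_shell` cells) rather than
  radius-complete for radii larger than the cell.
- No multi-state or kinetic unfolding models; Keq is a fraction ratio.
- Binary trajectory formats depend on mdtraj; the native path is
  multi-model PDB.
- The Jarvis–Patrick implementation is the cutoff-neighbourhood variant
  only.
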