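# Methods

## Model and problem statement

An assembly is N chemically identical molecules ("chains"), each reduced to
the same n points — Cα atoms by default, any atom name or all heavy atoms on
request. The distance between two assemblies x and y under a
molecule-to-molecule mapping P is the RMSD over all N·n point pairs, with
points paired by their within-chain index (the molecules are strictly alike;
no residue-level alignment is attempted, and chains of unequal length are a
hard error rather than being trimmed):

RMSD(x, y; P) = √( 1/(Nn) Σ_{k=1..N} Σ_{l=1..n} ‖x_l^k − y_l^{P_k}‖² ).

The optimal superposition minimizes the summed squared distances over P, a
proper rotation R, and a translation t. Because the optimal t equals the
difference of the geometric centers, both assemblies are centered once on
load and all algorithms work in centered frames; results carry the
translation that reconstitutes the reference's original frame. For fixed P
the optimal R is computed in closed form by the SVD of the 3×3 covariance
with the determinant sign correction (the smallest-singular-value axis is
flipped when the raw solution is a reflection), so a proper rotation is
returned even for degenerate point clouds and mirror images can never reach
zero RMSD.

Four methods share this core:

| method    | mapping                         | cost       |
|-----------|---------------------------------|------------|
| simple    | chains with equal IDs           | 1 SVD      |
| reference | best of all N! permutations     | N! SVDs    |
| lmada     | quaternion grid scan + greedy   | O(N²) scan + 1 SVD |
| lmagda    | permutation-free Φ minimization | O(N²) per iteration |

The reference algorithm is the exact global minimum and the yardstick for
the other three; enumeration is refused above N = 8 by default (10! ≈ 3.6
million mappings), overridable.

## Rotation parameterization and the scan grid

Rotations are quaternions q = (q0, qx, qy, qz); the rotation matrix is the
standard quadratic form in the normalized components, so R(q) = R(cq) for
any c ≠ 0 and q, −q give the same rotation. The scan grid varies
q0 ∈ {0, ½, 1} and qx, qy, qz ∈ {−1, −½, 0, ½, 1} with the all-zero point
removed: 3·5³ − 1 = 374 points, kept in lexicographic order so that ties in
the scan break deterministically toward the earlier point. The grid contains
scalar multiples that normalize to the same unit quaternion (272 distinct
rotations among the 374 points); all 374 are kept — the redundancy is cheap
and the fixed count keeps the procedure exactly reproducible. Empirically
the grid leaves a mean misorientation of ≈ 20° (max ≈ 40°) to a uniformly
random rotation, which bounds how well the scan stage alone can orient an
assembly.

## LMADA

At each grid rotation the chain-to-chain distance matrix
d_ij = √(1/n Σ_k ‖x_k^i − R y_k^j‖²) is computed (squared distances
internally; reported values are Å). A mapping is built greedily: entries are
visited from smallest to largest — ties broken by row, then column index via
a stable sort — and a pair (i, j) is accepted unless i or j is already used.
The mapping is scored by RMSDd = √(1/N Σ_i d_{i,P_i}²); the scan keeps the
strictly best grid point. The retained mapping is completed by one Kabsch
superposition, reported as RMSD1. RMSD1 ≥ RMSDr always, with equality
whenever the scan's mapping is the optimal one.

## LMAGDA

LMAGDA replaces the committed mapping with the overlap objective

Φ(q) = −ln Σ_{i=1..N} Σ_{j=1..N} Σ_{k=1..n} exp(−‖x_k^i − R(q) y_k^j‖²/2σ²),

a measure of the overlap of the two assemblies' point densities, each
represented as a sum of unit Gaussians of width σ. The sum runs over all N²
chain pairs, so Φ is invariant under chain relabeling by construction.
Since every term is at most 1, Φ ≥ −ln(N²n); the optimum is reported on the
distance scale as RMSDΦ = σ√(2(Φ + ln N²n)), which reduces exactly to the
inter-point distance for N = n = 1. Note the floor: even two identical,
perfectly overlapping assemblies satisfy Φ > −ln(N²n) strictly, because only
N of the N² chain pairs coincide; RMSDΦ is therefore a *relative* overlap
score with a nonzero floor (≈ 7 Å for a 4×6 ladder at σ = 8), useful for
ranking, not an absolute deviation. Low-RMSD pairs plateau at this floor.

Φ is multimodal, so minimization starts from the grid-scan quaternion and
uses BFGS over the four raw quaternion components with normalization inside
R(q); the objective is exactly scale-invariant and the analytic gradient
(log-sum-exp/softmax form for numerical stability, chain rule through the
normalization, radial component projected out) has no drift direction. If
the iterate still collapses toward the zero quaternion, a perturbed restart
from the renormalized start is attempted, and the best point seen is always
returned, so Φ(q_opt) ≤ Φ(q_start) unconditionally. The analytic gradient is
verified against central finite differences (≤ 1e−6 relative); a
finite-difference mode is available. Translation is held fixed at the common
centers. At the optimum the greedy mapping, RMSDd, and the full-assembly
RMSD under that mapping are also reported.

### Parameters

| parameter | default | meaning |
|-----------|---------|---------|
| σ         | 8.0 Å   | Gaussian width of Φ. Small σ sticks individual nearest points together; large σ washes out differences. 8.0 is the package default; because the appropriate width is debatable for small assemblies (the floor discussion above), σ is exposed everywhere (`GaussianObjectiveConfig`, `--sigma`). |
| tol_grad  | 1e−6    | BFGS gradient-norm convergence tolerance. |
| max_iter  | 500     | BFGS iteration cap; typical runs converge in < 30. |
| max_N     | 8       | reference-algorithm guard; 8! = 40,320 SVDs is the practical ceiling for bulk use. |
| cutoff    | 6 Å     | similarity threshold for rejection percentages — the classical bound below which two random structures are unlikely to superpose. |

## Evaluation statistics

For an ensemble, every unordered pair is superposed with each requested
method (Np structures → Np(Np−1)/2 pairs). Against the reference RMSDs the
package reports the mean and sample SD (Np − 1 denominator) of
RMSDx − RMSDr and of (RMSDx − RMSDr)/RMSDr, and the rejection percentage:
100 × |{RMSDx ≥ cutoff and RMSDr < cutoff}| / |{RMSDr < cutoff}| (similarity
strict, rejection inclusive; an empty denominator is an explicit error, not
0).

## Synthetic fixtures

The generator emulates the geometry such algorithms are used on: N copies
of an extended n-point chain (3.8 Å spacing, the Cα–Cα virtual bond length
of a trans peptide) stacked into a β-ladder at 4.8 Å pitch with a 2.4 Å
per-strand shear (stagger), optional per-coordinate Gaussian jitter, and a
perturbed counterpart built by a known chain permutation, optional per-chain
direction reversal, a uniform random rotation (normalized 4-D Gaussian
quaternion), a translation, and seeded isotropic noise applied after the
transform. The ground truth (inverse permutation, rotation, translation) is
returned alongside.

The stagger is essential, not cosmetic: a perfectly flat ladder is carried
onto itself by a 180° rotation about the chain axis combined with reversing
the chain order, so the "true" mapping of a permuted copy would not be
unique and no algorithm could be expected to recover it. The 2.4 Å shear
breaks that degeneracy with a margin that exceeds the grid's ≈ 20°
orientation noise floor, making the noiseless ground truth identifiable;
`stagger=0` regenerates the degenerate case deliberately (with it, the
grid-scan mapping lands in the symmetry-partner basin on a substantial
fraction of draws — the same failure mode that produces nonzero rejection
percentages on real ensembles).

What the fixtures do *not* model: real backbone geometry beyond the extended
chain, side chains, sterics, hydrogen bonding, or genuine conformational
ensembles (two simulation snapshots differ by internal motions, not by
rigid transforms plus isotropic noise). Passing tests therefore demonstrate
correctness of the mapping search and superposition machinery under known
ground truth, not performance on any particular real ensemble.

## Numerical choices and degenerate inputs

- All coordinates in Å throughout; float64.
- Rotation matrices are validated at 1e−12 (orthogonality, det +1) in tests.
- Greedy ties and grid ties break deterministically (stable sort; earlier
  grid point wins), so all algorithms are bit-reproducible.
- RMSDΦ clips square-root arguments within 1e−9 below zero to 0 and rejects
  anything lower as an invariant violation.
- PDB I/O via gemmi: first altloc per atom, model 1 by default, chain order
  as in the file (molecule indices must be stable for mappings to be
  meaningful); fixed-point PDB output is exact to 1e−3 Å.
- Unequal selected-point counts across chains raise an "unlike molecules"
  error naming the chains; empty selections and unreadable files are
  distinct errors with distinct CLI exit codes (2 parse/empty, 3 unlike
  molecules/mismatch, 4 permutation guard).

## Problem sizes used in the test suite and acceptance script

Statistical checks run on 102 noisy pairs (N ∈ {3, 4, 5}, n = 6, 0.3 Å
noise), 50 noiseless recovery cases (N = 2..6), and 100-structure pair-count
drivers with minimal 2×2 assemblies; the full suite completes in about a
minute on one CPU. These sizes give exact reference comparisons (N ≤ 5
costs at most 120 enumerated mappings per pair) while keeping runs fast.

## Known limitations

- Assemblies must have equal N and n; mixed-composition assemblies (AxBy
  hetero-oligomers) and unequal molecule counts are out of scope.
- LMADA commits to a single mapping from a 374-point orientation scan; when
  two mapping basins differ by less than the grid's orientation noise it can
  return a sub-optimal mapping (RMSD1 > RMSDr). This is intrinsic to the
  method, not an implementation defect.
- LMAGDA optimizes orientation only; with fixed centers it cannot align
  sub-assemblies whose centroids differ, and RMSDΦ has the floor discussed
  above.
- The greedy assignment is not the optimal assignment for a fixed rotation
  (no Hungarian step, by design).
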