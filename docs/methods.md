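# Methods

## Models

Both elastic network models coarse-grain a protein to one node per residue
at the Cα position, joined by uniform harmonic springs (constant γ) for
every pair within a cutoff distance, all springs at equilibrium in the
input structure. The spring constant is factored out of every matrix; it
re-enters only through the fitted k_BT/γ scale, so all topology-level
quantities are dimensionless and all fluctuation outputs are linear in the
scale.

**GNM.** The Kirchhoff matrix is the contact-graph Laplacian: off-diagonal
−1 for pairs with R_ij ≤ r_c (inclusive comparison), diagonal equal to the
contact degree. Mean-square fluctuations are (3k_BT/γ) times the diagonal
of the pseudo-inverse, computed as the eigenmode sum Σ_k λ_k⁻¹ u_k[i]² over
nonzero modes; the same mode sum with a subset of modes gives per-mode
profiles, and the full off-diagonal pseudo-inverse gives the normalized
cross-correlation map. A connected contact graph has exactly one zero
mode; cross-correlations are refused on disconnected graphs (the relative
fluctuation of residues in different components is undefined).

**ANM.** The Hessian carries the analytic second derivative of the
harmonic pair potential at the input geometry,
H_ij = −(r_j−r_i)(r_j−r_i)ᵀ/d_ij² for contacts, H_ii = −Σ_j H_ij. Residue
mean-square fluctuations are (3k_BT/γ)·trace of the 3×3 diagonal
superelements of the pseudo-inverse. The leading factor of 3 mirrors the
GNM expression; part of the ANM literature uses k_BT/γ·trace instead, a
constant convention difference wholly absorbed by the fitted scale (which
is why the ANM scale fitted to the same data is not directly comparable to
the GNM one). Per-mode output k is λ_k⁻¹|u_k block i|² with the N×3
direction blocks exposed for arrow-style rendering.

Mode ordinals throughout count over *nonzero* modes, 1-based, so "mode 1"
is always the slowest internal motion and rigid-body modes cannot be
selected by accident.

## Parameters

| parameter | default | meaning |
|---|---|---|
| GNM cutoff r_c | 7.3 Å | contact distance for Γ; classic single-residue-shell value |
| fast-mode secondary cutoff | 9.0 Å | re-run of the fast-mode/contact analysis with a larger shell |
| ANM cutoff | 15 Å | larger shell needed for a stable 3D Hessian |
| n fastest modes | 10 | averaged (unweighted) for the hot-residue profile; a λ-weighted variant sits behind a flag |
| difference-distance threshold | 1.5 Å | classify a residue pair as moved |
| hinge threshold | 5% of profile max | a hinge residue must be a ±2-residue local minimum below this floor |
| hot-residue floor | mean + 1 sd | a hot residue must be a strict ±2-residue local maximum above it |
| k_BT/γ | fitted | least squares through the origin, c = Σ B_exp·B_raw / Σ B_raw² |

Hinge and peak detection thresholds are explicit, documented defaults for
what is usually done by eye on mode-shape plots; consecutive qualifying
hinge residues merge into one region reported at its minimum. The scale
fit is the closed-form one-parameter least-squares solution; the Pearson
correlation (the conventional "correlation coefficient" in B-factor work)
is scale-invariant and reported alongside. The slowest-mode fluctuation
difference between two conformers normalizes each profile to unit sum
first, because the two conformers' fitted scales differ and only the mode
*shape* is comparable.

## Rotation angle

The inter-domain rotation between conformers is a two-stage least-squares
estimate: (1) rigid Kabsch superposition of conformer B onto A over the
fixed-domain Cα; (2) Kabsch rotation of the superposed moving domain onto
A's, with the angle taken as the rotation magnitude (equal to
arccos((trace R−1)/2), computed via the quaternion representation, which
is stable near 0°). Reflection-optimal alignments (determinant −1) are
corrected to proper rotations and flagged. Domain memberships are inputs
(author residue-number ranges or index arrays); this is deliberately *not*
a domain-finding algorithm, so results depend on the chosen domains —
comparisons with screw-decomposition tools agree to a few degrees when the
domain definitions match.

## Structure input

PDB parsing is delegated to biotite. One record per residue with a Cα
atom, in file order; author numbering and insertion codes preserved;
HETATM excluded (ligands and waters never enter the network);
non-standard residues with a CA atom kept. Alternate locations resolve to
the highest-occupancy conformer, ties to the alphabetically first altloc
code. Multi-model files default to model 1; with no chain given, the
first chain containing Cα atoms is used and a warning logged. Gzipped
files are accepted. Residues are paired between conformers by
(chain, number, insertion code); unmatched residues are dropped and
coverage reported.

## Synthetic ground truth

The generator emulates the geometry that drives ENM behaviour in a hinged
two-domain protein, not protein chemistry: two compact random clusters
(rejection-sampled to a 3.8 Å minimum separation within a given radius)
face each other across an 8.6 Å gap, joined by an arched linker of
Cα-spaced residues. The gap is chosen between the two cutoffs on purpose:
at 7.3 Å the domains do not touch, so the linker is the only connectivity
path and the slowest GNM mode develops its minimum there (the generated
hinge); at 15 Å the domains interact directly across the gap, so the ANM
has exactly the six rigid-body zero modes — a fully separated
ball-and-stick dumbbell instead has exact zero-energy torsion mechanisms
(verified numerically during design), which no globular protein has. The
linker carries small alternating lateral offsets for the same reason: a
node whose contact directions are collinear or coplanar is an exact local
mechanism of the Hessian.

The closed conformer applies a rigid rotation of domain B about an axis
through the linker–B junction; rotation about a point preserves every
distance to that point, so the contact graph stays connected at any angle.
Synthetic "experimental" B-factors are the scaled GNM prediction plus
i.i.d. Gaussian noise with sd equal to a fraction (default 5%) of the mean
B, negatives clamped to zero; default scale 5.64 Å², a typical fitted
k_BT/γ for a protein of this size. All generators are pure functions of
(spec, seed) using per-call `numpy.random.default_rng`.

What passing on this ground truth does *not* show: real proteins have
backbone connectivity, secondary structure, side-chain packing
heterogeneity and correlated (TLS-like) B-factor error, none of which the
clusters emulate. The synthetic tests validate the machinery —
spectra, fluctuation algebra, map construction, superposition — and the
*qualitative* hinge/hot-residue phenomenology, not quantitative agreement
with any particular crystal structure. Analyses of deposited structure
pairs go through the same code path via `scripts/reproduce_rbp.py`.

## Numerical choices

* Eigendecomposition: dense `scipy.linalg.eigh`; fine for the intended
  N ≲ a few hundred residues (3N ≲ 1000 for the ANM).
* Zero-mode threshold: λ is zero iff λ < 1e-10·max(λ_max, 1) —
  dimensionless and robust across sizes. More zero modes than expected are
  flagged with a warning (disconnected graph or internal mechanism), not
  fatal; operations that *require* connectivity (cross-correlation,
  synthetic B-factors) refuse explicitly.
* Eigenvector sign: largest-magnitude component made positive, so outputs
  are deterministic and regression-testable.
* Coincident Cα positions within the ANM cutoff (d ≈ 0) are an error
  naming the residue pair; the superelement is undefined there.
* Independent-route checks in the test suite use `numpy.linalg.pinv` with
  a relative rcond (1e-8): the default rcond can retain a numerically-zero
  Laplacian mode at larger N and produce garbage pseudo-inverses.
* Problem sizes in tests and the acceptance script (85-residue default
  dumbbell, 200-residue scale-recovery structure, 20 generator seeds)
  were chosen as the smallest sizes at which the two-domain spectral
  phenomenology is unambiguous.

## Known limitations

* Uniform spring constant only; no distance-weighted or sequence-dependent
  variants, no coarse-graining beyond one node per residue.
* The rotation angle depends on user-supplied domain definitions; it does
  not find domains.
* Hinge/hot-residue detection are threshold heuristics on 1-D profiles;
  on profiles with broad shallow minima the merged-region convention can
  report a single residue for what is physically a hinge *segment*.
* The CLI's plotting is intentionally absent from the tested contract;
  per-residue CSV/JSON outputs are the machine interface.
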