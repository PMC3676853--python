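# enmpair

Elastic-network analysis of open/closed protein conformer pairs at Cα
resolution: Gaussian Network Model (GNM) and Anisotropic Network Model
(ANM) construction and eigenanalysis, B-factor prediction with k_BT/γ
scale fitting, slow-mode hinge and fast-mode hot-residue detection,
cross-correlation and difference-distance maps, contact numbers, and a
rigid two-domain rotation angle — plus a synthetic-structure generator so
every stage is testable against known ground truth without downloads.

The package targets hinged two-domain proteins such as the bacterial
periplasmic binding proteins, which close around their ligand by a large
rigid rotation of one domain relative to the other. It is aimed at
structural bioinformaticians who want the full ENM conformer-pair analysis
as a library, a CLI, or a reproducible scripted pipeline.

## The models

Both models place one node per residue (the Cα atom) and join every pair
within a cutoff r_c by a uniform harmonic spring of constant γ.

**GNM.** The topology is the Kirchhoff (graph Laplacian) matrix

    Γ_ij = −1            if i ≠ j and R_ij ≤ r_c   (default r_c = 7.3 Å)
    Γ_ij = 0             if i ≠ j and R_ij > r_c
    Γ_ii = Σ_{j≠i} −Γ_ij (the contact degree)

Residue fluctuations follow from its pseudo-inverse,
⟨ΔR_i·ΔR_j⟩ = (3k_BT/γ)[Γ⁻¹]_ij, and predicted crystallographic B-factors
from B_i = (8π²/3)⟨ΔR_i²⟩. Per-mode fluctuations use
⟨ΔR_i²⟩_k = (3k_BT/γ) λ_k⁻¹ [u_k]_i², and normalized cross-correlations
C_ij = ⟨ΔR_i·ΔR_j⟩ / [⟨ΔR_i²⟩⟨ΔR_j²⟩]^{1/2}.

**ANM.** The 3N×3N Hessian of the network potential (default r_c = 15 Å)
carries 3×3 superelements H_ij = −(r_j−r_i)(r_j−r_i)ᵀ/d_ij² per contact;
its pseudo-inverse gives magnitudes *and directions* of fluctuation,
⟨ΔR_i²⟩ = (3k_BT/γ)·trace([H⁻¹]_ii), with six rigid-body zero modes.

The slowest internal GNM mode vanishes at hinge residues; the fastest
modes localize on tightly packed, kinetically hot residues. Between two
conformers the package computes the difference-distance map
ΔR_ij = R_ij(A) − R_ij(B) (±1.5 Å classification), the slowest-mode
fluctuation difference, and the inter-domain rotation angle by a two-stage
least-squares superposition: superpose conformer B on A over the fixed
domain, then extract the residual optimal rotation of the moving domain.

## Worked example

Generate a ground-truth two-domain conformer pair and analyse it
(equivalently through the CLI: `enmpair synth`, `enmpair gnm`,
`enmpair compare`):

```sh
python analysis/01_simulate_conformers.py
python analysis/02_bfactor_fit.py
python analysis/04_maps_and_rotation.py
```

which prints (seed 1):

```
wrote 85-residue open/closed pair to .../results/synthetic
  linker residues 41–45, hinge rotation 41.3°, B-factor scale 5.64 Å² + 5% noise

conformer model  kbt_over_gamma_A2  pearson_r  n_residues
     open   GNM             5.6189     0.9834          85
     open   ANM             6.3382     0.4328          85
   closed   GNM             5.6557     0.9827          85
   closed   ANM             1.3909     0.6237          85

difference-distance: intra-domain max 1.50e-03 Å (rigid), 86% of cross-domain
pairs move ≥ 1.5 Å
mean inter-domain cross-correlation -0.573 (anticorrelated domains)
recovered rotation angle 41.300876° (truth 41.3°)
```

Reading the numbers: the GNM fit recovers the generating k_BT/γ = 5.64 Å²
to within 0.4% with Pearson r ≈ 0.98 against the noisy synthetic B-factor
column (the synthetic truth is GNM-generated, hence the lower ANM r); the
difference-distance map shows both domains internally rigid while
cross-domain distances change by many Å; the two domains move in opposite
senses (mean C_ij ≈ −0.57); and the two-stage superposition recovers the
generator's 41.3° hinge rotation to under 0.001° (the residual comes from
PDB coordinate rounding). `analysis/03_slow_modes_hinges.py` and
`analysis/05_fast_modes_contacts.py` cover hinge detection (found at
residue 44, inside the labelled 41–45 linker) and fast-mode hot residues.

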