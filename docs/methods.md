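# Methods

## Model

gnmkit implements the isotropic Gaussian Network Model (GNM). A structure is
reduced to a network of nodes — one per amino acid at the Cα position, and
up to three per nucleotide at the P (phosphate), C4' (sugar) and C2 (base)
atoms — connected by identical harmonic springs wherever two nodes lie
within a cutoff distance r_c. The model assumes fluctuations about the
native structure are Gaussian and isotropic, so the entire dynamics is
determined by the contact topology, encoded in the Kirchhoff (graph
Laplacian) matrix Γ:

    Γ_ij = −1           if i ≠ j and ‖r_i − r_j‖ ≤ r_c
    Γ_ij = 0            if i ≠ j and ‖r_i − r_j‖ > r_c
    Γ_ii = Σ_{j≠i} −Γ_ij   (the degree of node i)

With eigenpairs Γ u_k = λ_k u_k (ascending; a connected network has exactly
one zero mode), the fluctuation statistics follow from the pseudo-inverse

    <ΔR_i · ΔR_j> = (3k_BT/γ) [Γ⁻¹]_ij,   Γ⁻¹ = Σ_{λ_k>0} λ_k⁻¹ u_k u_kᵀ

Everything internal is computed in units where 3k_BT/γ = 1; the spring
constant γ only rescales amplitudes and cancels from correlations and
collectivity (tested as the γ-invariance property). Derived quantities:

- **mean-square fluctuations** msf_i = [Γ⁻¹]_ii, with per-mode shapes
  λ_k⁻¹ u_{k,i}² summing exactly to msf;
- **per-mode contribution** [C]_k = λ_k⁻¹ u_k u_kᵀ (rank 1, trace λ_k⁻¹),
  so the softest mode dominates;
- **B-factors** B_i = (8π²/3)·c·msf_i, where c is either 1 (`unit`) or the
  least-squares scalar fitted to experimental B (`fit`; the Pearson
  correlation reported alongside is invariant to c);
- **orientational cross-correlations** C_ij = G_ij/√(G_ii G_jj) with G the
  pseudo-inverse restricted to a mode subset (default: slowest three);
- **collectivity** κ_k = N⁻¹ exp(−Σ_i u_{k,i}² ln u_{k,i}²) ∈ [1/N, 1],
  reported for the softest modes that account for one tenth of the total
  Σ λ_k⁻¹; exact zeros contribute nothing (x ln x → 0 limit);
- **domain separation**: the sign of u_{k,i} splits nodes into two
  anticorrelated blocks; sign changes between sequence-adjacent nodes of
  one chain mark crossover (hinge) nodes, and components below
  1e-6 × max|u_k| are treated as sign-0 hinge members;
- **hinges and hot spots**: strict local minima of soft-mode shapes within
  a 5-node window per chain; nodes above the 0.95 quantile of the summed
  10 stiffest mode shapes;
- **shape statistic**: axial ratio a = largest/smallest principal axis of
  the node cloud, where axis lengths are standard deviations along the PCA
  directions (so a is a length ratio); a near-zero smallest axis is
  flagged degenerate (a = +inf) rather than reported as a huge number.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff_rc` | 7.3 Å | spring cutoff, middle of the 7.0–7.5 Å first-coordination-shell range for folded proteins; applied uniformly to protein, nucleic and mixed pairs |
| `min_nodes` / `max_nodes` | 12 / 20000 | admission window; the upper cap is soft and configurable |
| `calpha_only_filter` | off | opt-in rejection of models that carry only Cα atoms (a database-curation rule; a Cα trace is a valid GNM input, so the toolkit default admits it) |
| `store_fraction` | 0.40 | fraction of the nonzero spectrum persisted, counted from the soft end; ceil rounding, never exceeding N − 1 |
| `n_fast` | 10 | stiff modes summed for energy-localization peaks |
| `soft_subset` | 1,2,3 | modes of the persisted cross-correlation map |
| `zero_tol` | 1e-8 | relative threshold classifying zero modes; the count is cross-checked against the graph component count and a mismatch is an error, never silently patched |

Distance comparison is boundary-inclusive (d = r_c is a contact). Contacts
are found with a k-d tree for N ≥ 500 and a brute-force distance matrix
below; the two are exactly equivalent. Eigendecomposition is dense
(`scipy.linalg.eigh`) up to N = 5000; above that a shift-invert Lanczos
partial decomposition returns the softest modes covering the stored 40%
plus the stiffest `n_fast`. A profile computed from a partial spectrum is
the soft-mode truncation of the msf and is flagged as such
(`ModeSpectrum.is_full`). Eigenvector signs are normalized (largest-|u|
component positive, ties to the lowest index) so repeated runs are
byte-identical; within degenerate eigenvalue blocks individual eigenvectors
remain solver-dependent, and only block-invariant observables (msf, summed
shapes, full-block correlations) should be compared across solvers.

Alternate locations keep the highest-occupancy conformer (ties: smallest
label). NMR-style multi-model files contribute their first model by
default. Biological assemblies are built by applying each REMARK 350
operator to its target chains, operator-major, each copy receiving a fresh
chain id from the cycle A–Z, a–z, 0–9, then two-character ids. A file whose
whole temperature-factor column is zero is treated as carrying no
experimental B-factors; such structures are analysed normally but excluded
from B-factor comparisons, with a logged warning.

## Synthetic fixtures: what they emulate and what they do not

The fixtures generator writes small, exactly reproducible PDB files:
collinear Cα chains (whose contact graph at the defaults is the path graph,
making the spectrum known in closed form: λ_k = 4 sin²(kπ/2N)), rings,
ideal α-helical traces (rise 1.5 Å, 100°/residue, radius 2.3 Å), two-lobed
dumbbells joined by a 3-node linker, a helix dimer whose second copy is
produced by a genuine REMARK 350 block (axis offset 8 Å, giving an
interface of spring contacts), a toy peptide + B-form-like duplex with
P/C4'/C2 nucleotide atoms, and ellipsoidal point clouds of stated axial
ratio. With a B-factor model, the generator runs the GNM on its own output
and writes B = c·msf + N(0, noise_sd²); c auto-scales the maximum B to
80 Å² so the fixed-width PDB column retains enough precision for exact
recovery checks. For the dimer, the B column is synthesized from the
*assembled* network — recreating in miniature the situation where only the
biological assembly explains the deposited B-factors.

Benchmark study conditions, fixed once: dumbbell n = 33 with 0.3 Å
coordinate jitter across 20 replicate geometries; dimer n = 30 with 0.25 Å
jitter and 4 Å² B-noise (≈5% of the B scale) across 50 replicates; noise
robustness on the 50-bead chain at σ ∈ {0, 0.5, 1, 2} × sd(B) with 200
replicates per level.

These fixtures exercise the full numerical pipeline, but they are not
proteins: they lack realistic packing density heterogeneity, crystal
contacts, missing residues, and the broad B-factor error structure of real
depositions. Passing the synthetic benchmarks demonstrates that the
machinery is correct and that planted signals are recovered; it does not by
itself certify the typical correlation levels achievable on experimental
structures.

## Numerical and degenerate-input choices

- Pseudo-inverse demands a connected network; disconnected inputs raise an
  error naming the components, with an explicit override for
  per-component analysis.
- The undefined-correlation guard (a node with no fluctuation in the chosen
  mode subset) triggers on diagonal entries below 1e-14 × the largest —
  analytically-zero eigenvector components reach floating point as ~1e-31
  residues, never exact zeros.
- Strict minima only: plateaus yield no minimum. A known consequence: when
  a geometry perturbation creates two "twin" nodes with identical
  neighbourhoods, their eigenvector components tie exactly (a graph
  automorphism forces it) and the window scan reports no minimum there.
  This is visible as an occasional miss in the dumbbell hinge benchmark and
  is accepted rather than special-cased.
- Colored-PDB output rescales values linearly to [0, 99.99]; a constant
  vector maps to all zeros (avoids 0/0 while keeping the file valid).
- Result bundles are rendered fully in memory before any file is written,
  so a failed run leaves a `failure.json` record and never a partial
  bundle.

## Known limitations

- Isotropic GNM only: no directional (3N-dimensional) modes, no mode
  animation vectors.
- PDB text only; mmCIF and accession download are out of scope.
- Serialization limits chain ids to the single PDB chain column; assemblies
  with more than 62 chains can be analysed in memory but not re-exported as
  PDB.
- Ligand/substrate heavy atoms are not network nodes (modified residues
  enter via the parent-residue map); the field has no consensus rule for
  ligand nodes in GNM.
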