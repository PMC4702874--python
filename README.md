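# gnmkit

Gaussian Network Model (GNM) analysis of biomolecular structures, from a
PDB coordinate file to mode spectra, fluctuation profiles, B-factor
comparisons, cross-correlation maps, collectivity measures and sign-based
domain/hinge decompositions. It handles proteins, DNA/RNA and their
complexes, for either the asymmetric unit or the biological assembly built
from REMARK 350 operators — the workflow behind per-entry structural
dynamics databases, packaged as a standalone library and command-line tool
for structural bioinformaticians who want the numbers locally.

## The model

The structure is coarse-grained to a network: one node per amino acid (Cα)
and three per nucleotide (P, C4', C2), with identical springs between all
node pairs within r_c = 7.3 Å. The topology is the Kirchhoff matrix **Γ**
(off-diagonal −1 per contact, diagonal = degree). Fluctuations follow from
its eigenmodes (λ_k, **u**_k):

    <ΔR_i · ΔR_j> = (3k_BT/γ) [Γ⁻¹]_ij ,    Γ⁻¹ = Σ_k λ_k⁻¹ u_k u_kᵀ

Low-λ (soft) modes are collective domain motions; high-λ (stiff) modes are
localized. Derived outputs: mean-square fluctuations and predicted
B-factors B_i = (8π²/3)·<(ΔR_i)²> with the Pearson correlation against the
deposited B column; per-mode shapes λ_k⁻¹u_{k,i}²; orientational
cross-correlations C_ij = [Γ⁻¹]_ij/([Γ⁻¹]_ii[Γ⁻¹]_jj)^½ over a mode subset;
collectivity κ_k = N⁻¹exp(−Σ u²ln u²); and the sign structure of each soft
mode, which splits the network into two anticorrelated blocks with hinge
(crossover) nodes at the sign changes. See `docs/methods.md` for the
assumptions, defaults and numerical conventions.

## Worked example

No downloads needed — the package generates its own valid toy PDB files.
Build a helix dimer whose second copy comes from a genuine REMARK 350
2-fold operator, with synthetic B-factors derived from the *assembled*
dimer (B = c·msf + noise):

```
$ gnmkit fixtures --kind dimer_biomt --n 30 --seed 1 --b-noise-sd 4.0 --out toy_dimer.pdb
$ gnmkit compute toy_dimer.pdb --assembly first --out dimer_out
{
  "axial_ratio": 7.884872,
  "n_chains": 2,
  "n_components": 1,
  "n_fast_modes_stored": 10,
  "n_nodes": 60,
  "n_soft_modes_stored": 24,
  "r_bfactor": 0.97529,
  ...
}
```

Reading: the assembly has 60 nodes in 2 chains forming one connected
network; the softest 24 modes (40% of the 59 nonzero modes) are stored;
the GNM-predicted fluctuation profile correlates at r = 0.975 with the
synthetic B column. Re-running on the asymmetric unit alone,

```
$ gnmkit compute toy_dimer.pdb --out mono_out     # asymmetric unit
...  "r_bfactor": 0.909362  ...
```

the correlation drops to 0.909 because the single-chain model misses the
interface springs that restrain the B-factors — the reason assembly-level
analysis matters for multimeric structures. The output bundle is plain
text: `eigenvalues.tsv`, `msf.tsv`, `modes_soft.tsv`, `modes_fast.tsv`,
`bfactor_compare.tsv`, `crosscorr.tsv` (slowest three modes by default),
`collectivity.tsv`, `domains_mode<k>.tsv`, color-coded PDBs
(`colored_msf.pdb`, `colored_mode<k>.pdb`, values scaled into the B
column), and `summary.json`.

Library use mirrors the CLI:

```python
import gnmkit as gk

st = gk.parse_pdb("toy_dimer.pdb")
asm = gk.build_assembly(st, "first_assembly")
nodes = gk.select_nodes(asm)
gamma = gk.build_kirchhoff(nodes, cutoff_rc=7.3)
spectrum = gk.decompose(gamma)
profile = gk.compute_fluctuations(spectrum)
hinges = gk.slow_mode_minima(profile, [1], chain_map=nodes.chain_ids)
```

Other fixture kinds: `linear_chain` (a path graph with a closed-form
spectrum), `ring`, `helix`, `dumbbell` (two lobes + 3-node linker, a
planted hinge), `protein_dna`, `ellipsoid_cloud`. `gnmkit batch
MANIFEST.txt` runs a list of files and writes a tsv/csv summary table.

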