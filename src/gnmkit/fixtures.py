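"""Deterministic synthetic structures written as valid PDB files.

Every pipeline stage is testable without touching a real deposition: the
generator emits coarse geometries (chains, rings, helices, dumbbells,
contact dimers with a REMARK 350 block, a toy protein–DNA complex, and
ellipsoidal point clouds) whose network properties are known by
construction. When a B-factor model is requested the generator runs the
GNM on its own output and writes B = c·msf + N(0, noise_sd²) into the
temperature-factor column, so parameter-recovery tests have a ground truth.

All geometry constants are idealized textbook values: a Cα virtual-bond
spacing of 3.8 Å, an α-helical Cα trace (rise 1.5 Å, 100°/residue, radius
2.3 Å) and B-form-like nucleotide spacing (rise 3.4 Å, twist 36°).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ContractError
from .structure import (
    AssemblyOperator,
    AtomRecord,
    MolecularStructure,
    build_assembly,
    format_pdb,
)

KINDS = (
    "linear_chain", "ring", "helix", "dumbbell", "dimer_biomt",
    "protein_dna", "ellipsoid_cloud",
)

CA_SPACING = 3.8          # Angstrom, Cα virtual bond
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3
DNA_RISE = 3.4
DNA_TWIST_DEG = 36.0
DIMER_OFFSET = 8.0        # Angstrom between helix axes in the contact dimer
LINKER_LENGTH = 3         # nodes joining the two dumbbell clusters

#: auto-scaled B-factor ceiling (Å²): chosen so the fixed-width PDB
#: temperature column (2 decimals) carries ~4 significant digits
B_SCALE_MAX = 80.0


@dataclass(frozen=True)
class BFactorModel:
    """B = c · msf + N(0, noise_sd²); c=None auto-scales max B to 80 Å²."""

    c: float | None = None
    noise_sd: float = 0.0
    seed: int | None = None      # defaults to the FixtureSpec seed


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n_residues: int
    spacing: float = CA_SPACING
    noise_sigma: float = 0.0     # Angstrom, isotropic coordinate jitter
    b_model: BFactorModel | None = None
    seed: int = 0
    n_nucleotides: int = 4       # protein_dna only (total over both strands)
    axis_ratio: float = 10.0     # ellipsoid_cloud only
    cutoff_rc: float = 7.3       # used when b_model runs the internal GNM


def _protein_atoms(coords: np.ndarray, chain: str = "A",
                   first_resnum: int = 1) -> list[AtomRecord]:
    atoms = []
    for i, p in enumerate(coords):
        atoms.append(AtomRecord(
            atom_name="CA", element="C", position=np.asarray(p, float),
            b_factor=0.0, occupancy=1.0, alt_loc="", chain_id=chain,
            residue_number=first_resnum + i, insertion_code="",
            residue_name="ALA", is_hetero=False,
        ))
    return atoms


def _linear_chain(n: int, s: float) -> np.ndarray:
    return np.column_stack([np.arange(n) * s, np.zeros(n), np.zeros(n)])


def _ring(n: int, s: float) -> np.ndarray:
    radius = s / (2.0 * np.sin(np.pi / n))
    th = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(th), radius * np.sin(th),
                            np.zeros(n)])


def _helix(n: int) -> np.ndarray:
    th = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n)
    return np.column_stack([
        HELIX_RADIUS * np.cos(th), HELIX_RADIUS * np.sin(th),
        HELIX_RISE * np.arange(n),
    ])


def _cluster_lattice(n_points: int, a: float) -> np.ndarray:
    """First n_points of a cubic lattice ordered by distance from origin."""
    r = 1
    while (2 * r + 1) ** 3 < n_points * 2:
        r += 1
    g = np.arange(-r, r + 1)
    pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T * a
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0],
                        np.linalg.norm(pts, axis=1)))
    return pts[order[:n_points]]


def _dumbbell(n: int, s: float) -> np.ndarray:
    """Two compact lattice clusters joined by a 3-node collinear linker."""
    if n < LINKER_LENGTH + 4:
        raise ContractError("dumbbell needs at least 7 residues")
    nc1 = (n - LINKER_LENGTH + 1) // 2
    nc2 = n - LINKER_LENGTH - nc1
    c1 = _cluster_lattice(nc1, s)
    attach = c1[np.argmax(c1[:, 0])]
    linker = np.array([attach + (j + 1) * np.array([s, 0.0, 0.0])
                       for j in range(LINKER_LENGTH)])
    far_x = 2.0 * attach[0] + (LINKER_LENGTH + 1) * s
    c2 = _cluster_lattice(nc2, s)
    c2 = np.column_stack([far_x - c2[:, 0], c2[:, 1], c2[:, 2]])
    return np.vstack([c1, linker, c2])


def _ellipsoid(n: int, axis_ratio: float, rng: np.random.Generator) -> np.ndarray:
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    semi = np.array([5.0 * axis_ratio, 5.0 * np.sqrt(axis_ratio), 5.0])
    return dirs * semi


def _nucleotide_atoms(chain: str, resnum: int, resname: str, theta: float,
                      z: float) -> list[AtomRecord]:
    geom = [("P", "P", 9.0, 0.0), ("C4'", "C", 7.0, 0.35), ("C2", "C", 3.5, 0.9)]
    atoms = []
    for name, el, radius, dth in geom:
        atoms.append(AtomRecord(
            atom_name=name, element=el,
            position=np.array([radius * np.cos(theta + dth),
                               radius * np.sin(theta + dth), z]),
            b_factor=0.0, occupancy=1.0, alt_loc="", chain_id=chain,
            residue_number=resnum, insertion_code="", residue_name=resname,
            is_hetero=False,
        ))
    return atoms


def _protein_dna(n_aa: int, n_nt: int, s: float) -> list[AtomRecord]:
    atoms = _protein_atoms(_linear_chain(n_aa, s) + np.array([16.0, 0.0, 0.0]))
    n1 = (n_nt + 1) // 2
    n2 = n_nt - n1
    twist = np.deg2rad(DNA_TWIST_DEG)
    for i in range(n1):
        atoms.extend(_nucleotide_atoms("B", i + 1, "DA", twist * i,
                                       DNA_RISE * i))
    for i in range(n2):
        atoms.extend(_nucleotide_atoms("C", i + 1, "DT",
                                       twist * i + np.pi + 0.6, DNA_RISE * i))
    return atoms


#: 2-fold rotation about the line (x=0, y=DIMER_OFFSET/2) parallel to z:
#: a proper C2 dimer, so the two copies are exact graph symmetry mates
_C2_ROTATION = np.diag([-1.0, -1.0, 1.0])


def _dimer_remark_lines() -> list[str]:
    rows = []
    mats = [
        (np.eye(3), np.zeros(3)),
        (_C2_ROTATION, np.array([0.0, DIMER_OFFSET, 0.0])),
    ]
    rows.append("REMARK 350 BIOMOLECULE: 1")
    rows.append("REMARK 350 APPLY THE FOLLOWING TO CHAINS: A")
    for idx, (rot, tr) in enumerate(mats, start=1):
        for r in range(3):
            rows.append(
                f"REMARK 350   BIOMT{r + 1}   {idx}"
                f"{rot[r, 0]:10.6f}{rot[r, 1]:10.6f}{rot[r, 2]:10.6f}"
                f"{tr[r]:15.5f}"
            )
    return rows


def dimer_operators() -> list[AssemblyOperator]:
    """The two rigid-body operators of the dimer_biomt fixture."""
    return [
        AssemblyOperator(np.eye(3), np.zeros(3), frozenset({"A"}), 1),
        AssemblyOperator(_C2_ROTATION, np.array([0.0, DIMER_OFFSET, 0.0]),
                         frozenset({"A"}), 2),
    ]


def _apply_b_model(structure: MolecularStructure, spec: FixtureSpec
                   ) -> MolecularStructure:
    """Synthesize experimental-like B-factors from the structure's own GNM.

    For the contact dimer the network is the *assembled* dimer, and the
    asymmetric unit inherits the msf of its copy within the assembly — the
    situation where only the full assembly reproduces the deposited
    B-factors.
    """
    from .network import build_kirchhoff, select_nodes
    from .spectral import compute_fluctuations, decompose

    bm = spec.b_model
    assert bm is not None
    if spec.kind == "dimer_biomt":
        target = build_assembly(structure, "first_assembly")
    else:
        target = structure
    nodes = select_nodes(target)
    gamma = build_kirchhoff(nodes, spec.cutoff_rc)
    profile = compute_fluctuations(decompose(gamma))
    asym_nodes = select_nodes(structure)
    msf = profile.msf[: len(asym_nodes)]

    c = bm.c if bm.c is not None else B_SCALE_MAX / float(msf.max())
    rng = np.random.default_rng(bm.seed if bm.seed is not None else spec.seed)
    b = np.clip(c * msf + rng.normal(0.0, bm.noise_sd, size=len(msf)), 0.0, None)

    node_b = {lab: float(v) for lab, v in zip(asym_nodes.labels, b)}
    residue_b: dict[tuple, list[float]] = {}
    for (ch, num, ic, _an), v in node_b.items():
        residue_b.setdefault((ch, num, ic), []).append(v)

    from dataclasses import replace
    new_atoms = []
    for a in structure.atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
        if key in node_b:
            val = node_b[key]
        else:
            vs = residue_b.get(a.residue_key())
            val = float(np.mean(vs)) if vs else 0.0
        new_atoms.append(replace(a, b_factor=val))
    return MolecularStructure(atoms=new_atoms,
                              assembly_ops=structure.assembly_ops,
                              all_assemblies=structure.all_assemblies,
                              metadata=structure.metadata)


def build_fixture(spec: FixtureSpec) -> tuple[MolecularStructure, list[str]]:
    """Construct the fixture in memory; returns (structure, header lines)."""
    if spec.kind not in KINDS:
        raise ContractError(f"unknown fixture kind {spec.kind!r}")
    if spec.n_residues < 1:
        raise ContractError("n_residues must be positive")
    rng = np.random.default_rng(spec.seed)
    header = [
        f"REMARK   6 GNMKIT SYNTHETIC FIXTURE KIND={spec.kind.upper()} "
        f"N={spec.n_residues} SEED={spec.seed}"
    ]
    n, s = spec.n_residues, spec.spacing

    if spec.kind == "linear_chain":
        atoms = _protein_atoms(_linear_chain(n, s))
    elif spec.kind == "ring":
        atoms = _protein_atoms(_ring(n, s))
    elif spec.kind in ("helix", "dimer_biomt"):
        atoms = _protein_atoms(_helix(n))
        if spec.kind == "dimer_biomt":
            header += _dimer_remark_lines()
    elif spec.kind == "dumbbell":
        atoms = _protein_atoms(_dumbbell(n, s))
    elif spec.kind == "protein_dna":
        atoms = _protein_dna(n, spec.n_nucleotides, s)
    elif spec.kind == "ellipsoid_cloud":
        atoms = _protein_atoms(_ellipsoid(n, spec.axis_ratio, rng))

    if spec.noise_sigma > 0:
        from dataclasses import replace
        jitter = rng.normal(0.0, spec.noise_sigma, size=(len(atoms), 3))
        atoms = [replace(a, position=a.position + d)
                 for a, d in zip(atoms, jitter)]

    structure = MolecularStructure(
        atoms=atoms,
        assembly_ops=dimer_operators() if spec.kind == "dimer_biomt" else [],
        metadata={"title": f"gnmkit fixture {spec.kind}"},
    )
    if structure.assembly_ops:
        structure.all_assemblies = [structure.assembly_ops]
    if spec.b_model is not None:
        structure = _apply_b_model(structure, spec)
    return structure, header


def generate(spec: FixtureSpec, path: str | Path) -> Path:
    """Write the fixture as a PDB file; identical specs yield identical bytes."""
    structure, header = build_fixture(spec)
    path = Path(path)
    path.write_text(format_pdb(structure, header))
    return path
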