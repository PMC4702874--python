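"""PDB reading/writing, biological-assembly construction and admission filters.

The parser is a thin layer over :mod:`gemmi`; what it adds is the policy the
pipeline needs: a single-model view (NMR depositions contribute only their
first model by default), alternate-location resolution by highest occupancy,
and extraction of the REMARK 350 (BIOMT) operators into plain rotation /
translation pairs so that biological assemblies can be built explicitly.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import (
    AssemblyError,
    ContractError,
    EmptyStructureError,
    ParseError,
)

log = logging.getLogger(__name__)

#: tolerance for |R^T R - I| when validating assembly rotations
_ROTATION_ORTHO_TOL = 1e-4


@dataclass(frozen=True)
class AtomRecord:
    """One coordinate record (ATOM or HETATM) after alt-loc resolution."""

    atom_name: str
    element: str
    position: np.ndarray          # shape (3,), Angstrom
    b_factor: float | None        # Angstrom^2; None if the file carries none
    occupancy: float
    alt_loc: str                  # '' if blank
    chain_id: str
    residue_number: int
    insertion_code: str           # '' if blank
    residue_name: str
    is_hetero: bool

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass(frozen=True)
class AssemblyOperator:
    """One BIOMT rigid-body operator of a biological-assembly block."""

    rotation: np.ndarray          # 3x3
    translation: np.ndarray       # (3,), Angstrom
    applies_to_chains: frozenset[str]
    operator_index: int

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        dev = np.abs(r.T @ r - np.eye(3)).max()
        if dev > _ROTATION_ORTHO_TOL:
            raise ContractError(
                f"assembly operator {self.operator_index}: rotation is not "
                f"orthogonal (|R^T R - I| max = {dev:.2e})"
            )

    def is_identity(self, tol: float = 1e-6) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ np.asarray(self.rotation, float).T + np.asarray(
            self.translation, float
        )


@dataclass
class MolecularStructure:
    """A single-model atomic structure with optional assembly operators."""

    atoms: list[AtomRecord]
    assembly_ops: list[AssemblyOperator] = field(default_factory=list)
    all_assemblies: list[list[AssemblyOperator]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[tuple[str, int, str], str, list[AtomRecord]]]:
        """Group atoms into residues preserving file order.

        Returns (residue_key, residue_name, atoms) triples.
        """
        out: list[tuple[tuple[str, int, str], str, list[AtomRecord]]] = []
        index: dict[tuple[str, int, str], int] = {}
        for a in self.atoms:
            key = a.residue_key()
            if key not in index:
                index[key] = len(out)
                out.append((key, a.residue_name, []))
            out[index[key]][2].append(a)
        return out

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass(frozen=True)
class AdmissionVerdict:
    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


def _resolve_altlocs(residue_atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    """Keep one location per atom name: highest occupancy, then smallest label."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in residue_atoms:
        if a.atom_name not in by_name:
            order.append(a.atom_name)
        by_name.setdefault(a.atom_name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            kept.append(group[0])
        else:
            best = min(group, key=lambda a: (-a.occupancy, a.alt_loc))
            kept.append(best)
    return kept


def _operators_from_gemmi(assembly: gemmi.Assembly) -> list[AssemblyOperator]:
    ops: list[AssemblyOperator] = []
    idx = 0
    for gen in assembly.generators:
        chains = frozenset(gen.chains)
        for op in gen.operators:
            idx += 1
            ops.append(
                AssemblyOperator(
                    rotation=np.array(op.transform.mat.tolist(), dtype=float),
                    translation=np.array(op.transform.vec.tolist(), dtype=float),
                    applies_to_chains=chains,
                    operator_index=idx,
                )
            )
    return ops


def parse_pdb(path: str | Path, model_policy: int | str = "first") -> MolecularStructure:
    """Parse a PDB file into a single-model :class:`MolecularStructure`.

    Parameters
    ----------
    path
        PDB-format file (ATOM/HETATM, MODEL/ENDMDL, REMARK 350 supported).
    model_policy
        ``"first"`` (default) keeps the first MODEL; an integer ``k`` keeps
        the k-th model (1-based, matching MODEL card numbering order).

    Alternate locations are resolved per atom name: the highest-occupancy
    conformer wins, ties go to the lexicographically smallest alt-loc label.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    if model_policy == "first":
        model_index = 0
    else:
        model_index = int(model_policy) - 1
        if not 0 <= model_index < len(st):
            raise ParseError(
                f"{path}: model {model_policy} requested but file has {len(st)} model(s)"
            )
    model = st[model_index]

    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            raw: list[AtomRecord] = []
            for at in res:
                alt = at.altloc if at.altloc not in ("\x00", " ") else ""
                b = float(at.b_iso)
                raw.append(
                    AtomRecord(
                        atom_name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        b_factor=b,
                        occupancy=float(at.occ),
                        alt_loc=alt,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name,
                        is_hetero=(res.het_flag == "H"),
                    )
                )
            atoms.extend(_resolve_altlocs(raw))

    if not atoms:
        raise EmptyStructureError(f"{path}: no coordinate records in selected model")

    for a in atoms:
        if not np.all(np.isfinite(a.position)):
            raise ParseError(f"{path}: non-finite coordinates for atom {a.atom_name}")

    all_assemblies = [_operators_from_gemmi(asm) for asm in st.assemblies]
    all_assemblies = [ops for ops in all_assemblies if ops]

    # A deposition with an all-zero temperature-factor column is treated as
    # having no experimental B-factors (common for NMR models).
    if atoms and all((a.b_factor or 0.0) == 0.0 for a in atoms):
        atoms = [replace(a, b_factor=None) for a in atoms]
        log.warning("%s: no temperature factors; B-dependent comparisons disabled", path)

    meta = {
        "title": st.name,
        "resolution": float(st.resolution) if st.resolution else None,
        "n_models": len(st),
        "model_used": model.num,
        "source_path": str(path),
    }
    return MolecularStructure(
        atoms=atoms,
        assembly_ops=all_assemblies[0] if all_assemblies else [],
        all_assemblies=all_assemblies,
        metadata=meta,
    )


def _chain_id_cycle():
    singles = string.ascii_uppercase + string.ascii_lowercase + string.digits
    yield from singles
    for a in singles:
        for b in singles:
            yield a + b


def build_assembly(
    structure: MolecularStructure,
    which: str = "first_assembly",
    assembly_index: int = 0,
) -> MolecularStructure:
    """Apply BIOMT operators to produce the biological assembly.

    ``which="asymmetric"`` returns the input unchanged. Otherwise each
    operator of the selected assembly block is applied to its target chains
    and every generated chain copy receives a fresh unique id, assigned
    operator-major in the order A-Z, a-z, 0-9, then two-character ids.
    """
    if which == "asymmetric":
        return structure
    if which not in ("first_assembly", "index"):
        raise ContractError(f"unknown assembly choice {which!r}")

    if assembly_index == 0:
        ops = structure.assembly_ops
    else:
        if assembly_index >= len(structure.all_assemblies):
            raise AssemblyError(
                f"assembly index {assembly_index} out of range "
                f"({len(structure.all_assemblies)} assemblies present)"
            )
        ops = structure.all_assemblies[assembly_index]
    if not ops:
        raise AssemblyError("structure has no assembly operators")

    present = set(structure.chain_ids)
    for op in ops:
        missing = op.applies_to_chains - present
        if missing:
            raise AssemblyError(
                f"operator {op.operator_index} targets absent chain(s) "
                f"{sorted(missing)}"
            )

    ids = _chain_id_cycle()
    new_atoms: list[AtomRecord] = []
    copies: list[tuple[str, int, np.ndarray]] = []  # (src chain, op idx, coords)
    chain_order = structure.chain_ids
    atoms_by_chain = {
        cid: [a for a in structure.atoms if a.chain_id == cid] for cid in chain_order
    }
    for op in ops:
        for cid in chain_order:
            if cid not in op.applies_to_chains:
                continue
            new_id = next(ids)
            src = atoms_by_chain[cid]
            xyz = op.apply(np.array([a.position for a in src]))
            for a, p in zip(src, xyz):
                new_atoms.append(replace(a, chain_id=new_id, position=p))
            copies.append((cid, op.operator_index, xyz))

    # degenerate-operator check: two copies of the same source chain landing
    # on identical coordinates almost certainly indicate a malformed BIOMT
    # block; both copies are kept, per the do-what-the-file-says policy.
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            ci, cj = copies[i], copies[j]
            if ci[0] == cj[0] and ci[2].shape == cj[2].shape:
                if np.abs(ci[2] - cj[2]).max() < 1e-6:
                    warnings.warn(
                        f"assembly operators {ci[1]} and {cj[1]} place chain "
                        f"{ci[0]} on identical coordinates; keeping both copies",
                        stacklevel=2,
                    )

    meta = dict(structure.metadata)
    meta["assembly"] = "built"
    return MolecularStructure(atoms=new_atoms, assembly_ops=[], all_assemblies=[],
                              metadata=meta)


def is_calpha_only(structure: MolecularStructure) -> bool:
    """True when every non-hetero atom of the model is a lone CA."""
    non_het = [a for a in structure.atoms if not a.is_hetero]
    return bool(non_het) and all(a.atom_name == "CA" for a in non_het)


def admit_structure(
    nodes,
    min_nodes: int = 12,
    max_nodes: int = 20000,
    structure: MolecularStructure | None = None,
    calpha_only_filter: bool = False,
) -> AdmissionVerdict:
    """Decide whether a node set is admitted to the GNM pipeline.

    Structures with fewer than ``min_nodes`` (default 12) or more than
    ``max_nodes`` (default 20000, a soft cap — raise it for the largest
    assemblies) are rejected. With ``calpha_only_filter`` on, models that
    carry only Cα atoms are rejected as well, mirroring the curation rule of
    large-scale database builds; it is off by default because a Cα trace is a
    perfectly valid GNM input.
    """
    n = len(nodes)
    if n < min_nodes:
        return AdmissionVerdict(False, f"too few nodes ({n} < {min_nodes})")
    if n > max_nodes:
        return AdmissionVerdict(False, f"too many nodes ({n} > {max_nodes})")
    if calpha_only_filter and structure is not None and is_calpha_only(structure):
        return AdmissionVerdict(False, "calpha-only")
    return AdmissionVerdict(True)


# --- PDB writing -----------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # standard alignment: 1/2-letter element names start in column 14
    if len(name) >= 4:
        return name[:4]
    return (" " + name).ljust(4)


def format_pdb(structure: MolecularStructure,
               header_lines: Sequence[str] = ()) -> str:
    """Render a single-model structure as fixed-width PDB text."""
    lines: list[str] = list(header_lines)
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if len(a.chain_id) != 1:
            raise ContractError(
                f"chain id {a.chain_id!r} does not fit the single-character "
                "PDB chain column"
            )
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        rec = "HETATM" if a.is_hetero else "ATOM  "
        x, y, z = a.position
        b = 0.0 if a.b_factor is None else a.b_factor
        lines.append(
            f"{rec}{serial:5d} {_format_atom_name(a.atom_name)}{a.alt_loc or ' '}"
            f"{a.residue_name:>3s} {a.chain_id}{a.residue_number:4d}"
            f"{a.insertion_code or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{b:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: MolecularStructure, path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write a single-model structure as fixed-width PDB text."""
    Path(path).write_text(format_pdb(structure, header_lines))


def colored_pdb_text(
    structure: MolecularStructure,
    per_node_values: np.ndarray,
    nodes=None,
) -> str:
    """PDB text whose B-factor column color-codes a per-node quantity.

    Values are rescaled linearly onto [0, 99.99] (a constant vector maps to
    all zeros). Non-node atoms of a residue inherit the mean of that
    residue's node values; residues without a node get 0.
    """
    from .network import select_nodes  # local import to avoid a cycle

    if nodes is None:
        nodes = select_nodes(structure)
    vals = np.asarray(per_node_values, dtype=float)
    if vals.shape != (len(nodes),):
        raise ContractError(
            f"per_node_values has length {vals.size}, expected {len(nodes)}"
        )
    if not np.all(np.isfinite(vals)):
        raise ContractError("per_node_values must be finite")

    lo, hi = vals.min(), vals.max()
    scaled = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo) * 99.99

    node_value: dict[tuple, float] = {}
    residue_values: dict[tuple[str, int, str], list[float]] = {}
    for (chain, resnum, icode, atom_name), v in zip(nodes.labels, scaled):
        node_value[(chain, resnum, icode, atom_name)] = v
        residue_values.setdefault((chain, resnum, icode), []).append(v)

    recolored = []
    for a in structure.atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
        if key in node_value:
            b = node_value[key]
        else:
            rv = residue_values.get(a.residue_key())
            b = float(np.mean(rv)) if rv else 0.0
        recolored.append(replace(a, b_factor=b))
    return format_pdb(
        MolecularStructure(atoms=recolored, metadata=structure.metadata)
    )


def write_colored_pdb(
    structure: MolecularStructure,
    per_node_values: np.ndarray,
    path: str | Path,
    nodes=None,
) -> None:
    """File-writing counterpart of :func:`colored_pdb_text`."""
    Path(path).write_text(colored_pdb_text(structure, per_node_values, nodes))
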