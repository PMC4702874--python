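"""Coarse-grained node selection and Kirchhoff (graph Laplacian) construction.

Proteins contribute one node per amino acid at the Cα position. Nucleic
acids use a three-node-per-nucleotide representation — phosphate (P), sugar
(C4') and base (C2) — which keeps the network density of double helices
comparable to folded protein. Springs of unit force constant connect every
node pair within a cutoff r_c (default 7.3 Å, inside the 7.0–7.5 Å
first-coordination-shell range established for folded proteins). The
connectivity is the Kirchhoff matrix Γ: off-diagonal Γ_ij = −1 for a
contact, diagonal Γ_ii = degree of node i, so every row sums to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _csgraph_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import ContractError, EmptyNetworkError
from .structure import MolecularStructure

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 7.3  # Angstrom

#: standard amino acids (node at CA)
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
#: standard nucleotides (nodes at P, C4', C2)
NUCLEOTIDES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
#: common modified residues mapped to a standard parent; extendable via the
#: hetero_residue_map config key
DEFAULT_HETERO_MAP = {"MSE": "MET", "SEC": "CYS", "PYL": "LYS", "PSU": "U"}

NUCLEOTIDE_NODE_ATOMS = ("P", "C4'", "C2")


@dataclass
class NodeSet:
    """The GNM nodes: coordinates plus provenance labels."""

    positions: np.ndarray                    # (N, 3), Angstrom
    labels: list[tuple[str, int, str, str]]  # (chain, resnum, icode, atom)
    node_class: list[str]                    # "protein" | "nucleotide"
    experimental_b: np.ndarray | None        # (N,), Angstrom^2, or None

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def chain_ids(self) -> list[str]:
        return [lab[0] for lab in self.labels]

    def label_strings(self) -> list[str]:
        return [f"{c}:{n}{i}:{a}" for c, n, i, a in self.labels]


@dataclass
class KirchhoffMatrix:
    """Γ with its cutoff metadata. Dense for small N, CSR above."""

    matrix: np.ndarray | sp.csr_array
    cutoff_rc: float
    node_ref: NodeSet | None = None
    isolated_nodes: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return self.matrix.toarray()
        return self.matrix

    def sparse(self) -> sp.csr_array:
        if sp.issparse(self.matrix):
            return self.matrix
        return sp.csr_array(self.matrix)


def select_nodes(
    structure: MolecularStructure,
    hetero_residue_map: dict[str, str] | None = None,
) -> NodeSet:
    """Pick GNM nodes from a parsed structure.

    One Cα node per amino acid; up to three nodes (P, C4', C2, in that
    order) per nucleotide. Residues missing a required atom simply
    contribute fewer nodes (logged). HETATM residues are eligible only via
    the modified-residue map; ligands and waters are excluded.
    """
    hetmap = dict(DEFAULT_HETERO_MAP)
    if hetero_residue_map:
        hetmap.update(hetero_residue_map)

    positions: list[np.ndarray] = []
    labels: list[tuple[str, int, str, str]] = []
    classes: list[str] = []
    bvals: list[float | None] = []

    for key, resname, atoms in structure.residues():
        name = hetmap.get(resname, resname)
        by_name = {a.atom_name: a for a in atoms}
        if name in AMINO_ACIDS:
            wanted = ("CA",)
            cls = "protein"
        elif name in NUCLEOTIDES:
            wanted = NUCLEOTIDE_NODE_ATOMS
            cls = "nucleotide"
        else:
            continue
        found_any = False
        for atom_name in wanted:
            a = by_name.get(atom_name)
            if a is None:
                continue
            found_any = True
            positions.append(a.position)
            labels.append((a.chain_id, a.residue_number, a.insertion_code,
                           a.atom_name))
            classes.append(cls)
            bvals.append(a.b_factor)
        if not found_any:
            log.info("residue %s %s contributes no node (missing %s)",
                     key, resname, "/".join(wanted))

    if not positions:
        raise EmptyNetworkError("no eligible GNM nodes in structure")

    if any(b is None for b in bvals):
        exp_b = None
    else:
        exp_b = np.array(bvals, dtype=float)
    return NodeSet(
        positions=np.array(positions, dtype=float),
        labels=labels,
        node_class=classes,
        experimental_b=exp_b,
    )


def _contact_pairs_brute(xyz: np.ndarray, rc: float) -> np.ndarray:
    d = squareform(pdist(xyz))
    iu, ju = np.triu_indices(len(xyz), k=1)
    mask = d[iu, ju] <= rc
    return np.column_stack([iu[mask], ju[mask]])


def _contact_pairs_tree(xyz: np.ndarray, rc: float) -> np.ndarray:
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=rc, output_type="ndarray")  # boundary inclusive
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    return pairs


def build_kirchhoff(
    nodes: NodeSet,
    cutoff_rc: float = DEFAULT_CUTOFF,
    force_dense: bool | None = None,
) -> KirchhoffMatrix:
    """Build Γ from node coordinates with an inclusive distance cutoff.

    Pairs at exactly r_c count as contacts. A k-d tree handles the neighbor
    search for large N; below N = 500 a brute-force distance matrix is used
    (the two agree exactly — the comparison d ≤ r_c is identical).
    """
    xyz = np.asarray(nodes.positions, dtype=float)
    n = len(xyz)
    if n < 2:
        raise ContractError("need at least 2 nodes to build a network")
    if cutoff_rc <= 0:
        raise ContractError("cutoff_rc must be positive")

    if n < 500:
        pairs = _contact_pairs_brute(xyz, cutoff_rc)
    else:
        pairs = _contact_pairs_tree(xyz, cutoff_rc)

    dense = force_dense if force_dense is not None else n <= 5000
    i, j = (pairs[:, 0], pairs[:, 1]) if len(pairs) else (np.array([], int),) * 2
    deg = np.bincount(i, minlength=n) + np.bincount(j, minlength=n)
    if dense:
        gamma = np.zeros((n, n), dtype=float)
        gamma[i, j] = -1.0
        gamma[j, i] = -1.0
        gamma[np.arange(n), np.arange(n)] = deg
        mat: np.ndarray | sp.csr_array = gamma
    else:
        rows = np.concatenate([i, j, np.arange(n)])
        cols = np.concatenate([j, i, np.arange(n)])
        vals = np.concatenate([-np.ones(2 * len(i)), deg.astype(float)])
        mat = sp.csr_array((vals, (rows, cols)), shape=(n, n))

    isolated = np.flatnonzero(deg == 0).tolist()
    if isolated:
        log.warning("network has %d isolated node(s): %s", len(isolated),
                    isolated[:10])
    return KirchhoffMatrix(matrix=mat, cutoff_rc=cutoff_rc, node_ref=nodes,
                           isolated_nodes=isolated)


def connected_components(gamma: KirchhoffMatrix) -> list[list[int]]:
    """Partition nodes into spring-graph components.

    Sorted by decreasing size, ties by smallest member index.
    """
    adj = -gamma.sparse().copy()
    adj.setdiag(0)
    n_comp, label = _csgraph_components(adj, directed=False)
    comps: list[list[int]] = [[] for _ in range(n_comp)]
    for idx, c in enumerate(label):
        comps[c].append(idx)
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def contact_map(gamma: KirchhoffMatrix) -> np.ndarray:
    """Binary adjacency: map_ij = 1 iff Γ_ij = −1. Symmetric, zero diagonal."""
    g = gamma.dense()
    m = (g == -1).astype(np.int8)
    np.fill_diagonal(m, 0)
    return m


def contact_edge_list(gamma: KirchhoffMatrix) -> list[tuple[int, int, int]]:
    """Upper-triangle contact edges as (i, j, 1) rows (0-based indices)."""
    m = contact_map(gamma)
    iu, ju = np.nonzero(np.triu(m, k=1))
    return [(int(a), int(b), 1) for a, b in zip(iu, ju)]


def write_contact_tsv(gamma: KirchhoffMatrix, edge_path=None, dense_path=None):
    """Export the contact map as an edge list and/or a dense matrix TSV."""
    if edge_path is not None:
        with open(edge_path, "w") as fh:
            fh.write("i\tj\tcontact\n")
            for i, j, v in contact_edge_list(gamma):
                fh.write(f"{i}\t{j}\t{v}\n")
    if dense_path is not None:
        np.savetxt(dense_path, contact_map(gamma), fmt="%d", delimiter="\t")
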