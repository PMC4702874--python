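"""Interpreted dynamics outputs: B-factor agreement, domain separation,
hinge/peak identification, shape statistics, and the persisted result bundle.

The sign structure of a soft-mode eigenvector splits the network into two
blocks of nodes moving in opposite directions along that mode axis;
sequence positions where the sign flips (crossover/hinge regions) are
low-mobility sites that mechanically couple the anticorrelated blocks.
Minima of soft-mode shapes flag the same mechanically constrained sites;
peaks of the summed stiffest-mode shapes flag energy-localization centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ContractError, UndefinedCorrelationError
from .network import NodeSet
from .spectral import (
    FluctuationProfile,
    ModeSpectrum,
    _FMT,
    collectivity_table,
    cross_correlation,
    theoretical_b_factors,
)
from .structure import MolecularStructure, colored_pdb_text


@dataclass
class DomainDecomposition:
    mode_index: int
    node_sign: np.ndarray          # per node: +1, -1 or 0
    crossover_nodes: list[int]     # ordered node indices


@dataclass
class ShapeStats:
    principal_axis_lengths: np.ndarray   # descending, Angstrom
    axial_ratio: float                   # >= 1, +inf when degenerate
    degenerate: bool = False


def bfactor_correlation(predicted: np.ndarray, experimental: np.ndarray) -> float:
    """Pearson correlation between predicted and experimental B-factors."""
    x = np.asarray(predicted, float)
    y = np.asarray(experimental, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ContractError("need two equal-length vectors of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input to correlation")
    return float(stats.pearsonr(x, y).statistic)


def domain_separation(
    spectrum: ModeSpectrum,
    k: int,
    chain_map: list[str] | None = None,
    sign_tol: float = 1e-6,
) -> DomainDecomposition:
    """Split nodes by the sign of eigenvector k; locate crossover nodes.

    Components with |u_i| below ``sign_tol`` · max|u| get sign 0 and are
    crossover members themselves; additionally, both endpoints of a strict
    +/− flip between sequence-adjacent nodes of the same chain are
    crossovers. Chain boundaries never produce crossovers.
    """
    _, u = spectrum.mode(k)
    tol = sign_tol * np.abs(u).max()
    sign = np.where(u > tol, 1, np.where(u < -tol, -1, 0))
    crossover: dict[int, None] = {}
    for i in np.flatnonzero(sign == 0):
        crossover[int(i)] = None
    if chain_map is None:
        chain_map = ["A"] * len(u)
    for i in range(len(u) - 1):
        if chain_map[i] != chain_map[i + 1]:
            continue
        if sign[i] * sign[i + 1] == -1:
            crossover[i] = None
            crossover[i + 1] = None
    return DomainDecomposition(
        mode_index=k,
        node_sign=sign,
        crossover_nodes=sorted(crossover),
    )


def _subset_shape(profile: FluctuationProfile, mode_subset) -> np.ndarray:
    shapes = profile.mode_shapes
    for k in mode_subset:
        if not 1 <= k <= shapes.shape[0]:
            raise ContractError(f"mode {k} outside stored shapes")
    return shapes[[k - 1 for k in mode_subset]].sum(axis=0)


def _chain_runs(chain_map: list[str] | None, n: int):
    if chain_map is None:
        yield 0, n
        return
    start = 0
    for i in range(1, n + 1):
        if i == n or chain_map[i] != chain_map[start]:
            yield start, i
            start = i


def slow_mode_minima(
    profile: FluctuationProfile,
    mode_subset: list[int] | None = None,
    window: int = 5,
    chain_map: list[str] | None = None,
) -> list[int]:
    """Local minima of the subset-summed soft-mode shape, per chain.

    A node is a minimum when it is strictly below every other node of its
    centered window (width ``window``, truncated at chain ends); plateaus
    yield none. Returned sorted by ascending shape value.
    """
    if mode_subset is None:
        mode_subset = [1]
    vals = _subset_shape(profile, mode_subset)
    half = window // 2
    minima: list[int] = []
    for lo, hi in _chain_runs(chain_map, len(vals)):
        for i in range(lo, hi):
            a, b = max(lo, i - half), min(hi, i + half + 1)
            others = np.delete(vals[a:b], i - a)
            if others.size and np.all(vals[i] < others):
                minima.append(i)
    minima.sort(key=lambda i: (vals[i], i))
    return minima


def fast_mode_peaks(
    profile: FluctuationProfile,
    n_fast: int = 10,
    top_q: float = 0.95,
) -> list[int]:
    """Nodes above the ``top_q`` quantile of the summed fastest-mode shape.

    The ``n_fast`` (default 10) highest-frequency modes are summed; peaks
    are returned sorted by descending value.
    """
    if n_fast < 1:
        raise ContractError("n_fast must be >= 1")
    shapes = profile.mode_shapes
    n_fast = min(n_fast, shapes.shape[0])
    vals = shapes[-n_fast:].sum(axis=0)
    thr = np.quantile(vals, top_q)
    idx = np.flatnonzero(vals >= thr)
    return sorted((int(i) for i in idx), key=lambda i: (-vals[i], i))


def axial_ratio(nodes: NodeSet) -> ShapeStats:
    """Shape anisotropy from PCA of the node coordinates.

    Principal axis lengths are the standard deviations along the principal
    directions (square roots of the covariance eigenvalues); the axial
    ratio a = largest/smallest is 1 for a sphere-like cloud and grows with
    elongation. Near-collinear/planar clouds are flagged degenerate with
    a = +inf.
    """
    xyz = np.asarray(nodes.positions, float)
    if len(xyz) < 3:
        raise ContractError("axial ratio needs at least 3 nodes")
    cov = np.cov(xyz.T)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    ev = np.clip(ev, 0.0, None)
    if ev[2] < 1e-10 * ev[0]:
        return ShapeStats(np.sqrt(ev), math.inf, degenerate=True)
    lengths = np.sqrt(ev)
    return ShapeStats(lengths, float(lengths[0] / lengths[2]))


# --- result bundle ---------------------------------------------------------

def stored_soft_mode_count(spectrum: ModeSpectrum, store_fraction: float) -> int:
    """ceil(fraction × n_nonzero), capped at n_nonzero ("up to 40%")."""
    return min(
        math.ceil(store_fraction * spectrum.n_nonzero), spectrum.n_nonzero
    )


def mode_report(
    spectrum: ModeSpectrum,
    profile: FluctuationProfile,
    store_fraction: float = 0.40,
    *,
    nodes: NodeSet,
    structure: MolecularStructure | None = None,
    out_dir: str | Path,
    soft_subset: tuple[int, ...] = (1, 2, 3),
    n_fast: int = 10,
    collectivity_fraction: float = 0.1,
    scale_policy: str = "fit",
) -> dict:
    """Persist the full result bundle for one structure as plain text.

    Stores the softest ceil(store_fraction × n_nonzero) modes (fraction
    default 0.40) plus the ``n_fast`` stiffest, the msf profile, the
    experimental/predicted B-factor comparison (when experimental values
    exist), the cross-correlation map over ``soft_subset`` (default the
    slowest three modes), collectivity for the softest modes covering a
    tenth of the dynamics, and a sign/domain map per stored soft mode.
    All file contents are rendered in memory first, so a failed run never
    leaves a partial bundle behind.
    """
    out_dir = Path(out_dir)
    labels = nodes.label_strings()
    n_soft = stored_soft_mode_count(spectrum, store_fraction)
    soft_modes = list(range(1, n_soft + 1))
    nf = min(n_fast, spectrum.n_nonzero)
    fast_modes = list(range(spectrum.n_nonzero - nf + 1, spectrum.n_nonzero + 1))
    subset = [k for k in soft_subset if 1 <= k <= spectrum.n_nonzero]

    files: dict[str, str] = {}

    def tsv(header: str, rows) -> str:
        return header + "\n" + "".join(rows)

    files["eigenvalues.tsv"] = tsv(
        "mode\tlambda",
        (f"{k}\t{_FMT % spectrum.mode(k)[0]}\n"
         for k in range(1, spectrum.n_nonzero + 1)),
    )

    def shapes_tsv(modes: list[int]) -> str:
        head = "node\t" + "\t".join(f"mode{k}" for k in modes)
        rows = (
            lab + "\t"
            + "\t".join(_FMT % profile.mode_shapes[k - 1, i] for k in modes)
            + "\n"
            for i, lab in enumerate(labels)
        )
        return tsv(head, rows)

    files["modes_soft.tsv"] = shapes_tsv(soft_modes)
    files["modes_fast.tsv"] = shapes_tsv(fast_modes)
    files["msf.tsv"] = tsv(
        "node\tmsf",
        (f"{lab}\t{_FMT % v}\n" for lab, v in zip(labels, profile.msf)),
    )

    r_b = None
    if nodes.experimental_b is not None:
        predicted = theoretical_b_factors(profile, scale_policy,
                                          nodes.experimental_b)
        r_b = bfactor_correlation(predicted, nodes.experimental_b)
        files["bfactor_compare.tsv"] = (
            f"# pearson_r = {_FMT % r_b}\n"
            + tsv(
                "node\texperimental_b\tpredicted_b",
                (f"{lab}\t{_FMT % e}\t{_FMT % p}\n"
                 for lab, e, p in zip(labels, nodes.experimental_b, predicted)),
            )
        )

    cc = cross_correlation(spectrum, subset) if subset else None
    if cc is not None:
        head = "# modes " + ",".join(map(str, cc.mode_subset))
        body = "\n".join(
            "\t".join(_FMT % v for v in row) for row in cc.values
        )
        files["crosscorr.tsv"] = head + "\n" + body + "\n"

    ctab = collectivity_table(spectrum, collectivity_fraction)
    files["collectivity.tsv"] = tsv(
        "mode\tkappa",
        (f"{k}\t{_FMT % v}\n" for k, v in zip(ctab.mode_indices, ctab.kappa)),
    )

    chain_map = nodes.chain_ids
    for k in soft_modes:
        dd = domain_separation(spectrum, k, chain_map)
        files[f"domains_mode{k}.tsv"] = tsv(
            "node\tsign\tcrossover",
            (
                f"{lab}\t{'+' if s > 0 else '-' if s < 0 else '0'}"
                f"\t{1 if i in set(dd.crossover_nodes) else 0}\n"
                for i, (lab, s) in enumerate(zip(labels, dd.node_sign))
            ),
        )

    if structure is not None:
        for k in subset:
            files[f"colored_mode{k}.pdb"] = colored_pdb_text(
                structure, profile.mode_shapes[k - 1], nodes
            )
        files["colored_msf.pdb"] = colored_pdb_text(structure, profile.msf, nodes)

    shape = axial_ratio(nodes)
    summary = {
        "n_nodes": spectrum.n_nodes,
        "n_components": spectrum.n_zero_modes,
        "n_chains": len(dict.fromkeys(chain_map)),
        "axial_ratio": None if shape.degenerate else round(shape.axial_ratio, 6),
        "r_bfactor": None if r_b is None else round(r_b, 6),
        "n_soft_modes_stored": n_soft,
        "n_fast_modes_stored": nf,
        "store_fraction": store_fraction,
        "soft_subset": subset,
        "collectivity_modes_reported": ctab.n_soft_reported,
    }
    files["summary.json"] = json.dumps(summary, indent=2, sort_keys=True) + "\n"

    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for name, text in files.items():
            p = out_dir / name
            p.write_text(text)
            written.append(p)
    except OSError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return summary
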