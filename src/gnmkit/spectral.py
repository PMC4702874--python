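"""Eigendecomposition of Γ and the GNM observables derived from it.

The central object is the mode spectrum: eigenvalues λ_k (ascending) and
orthonormal eigenvectors u_k of the Kirchhoff matrix. A connected network
has exactly one zero mode (the uniform translation of the scalar field);
every additional connected component adds one more. All fluctuation
quantities are computed in units where 3k_BT/γ = 1:

    <ΔR_i · ΔR_j>  =  [Γ⁻¹]_ij  =  Σ_k λ_k⁻¹ u_k u_kᵀ   (nonzero modes)

so the mean-square fluctuation of node i is the i-th diagonal element of
the pseudo-inverse, the per-mode contribution [C]_k = λ_k⁻¹ u_k u_kᵀ, and
orientational cross-correlations are the correlation-normalised
off-diagonals. Absolute Å² only enter through the B-factor conversion
B_i = (8π²/3)·<(ΔR_i)²>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    ContractError,
    DisconnectedNetworkError,
    MissingDataError,
    SpectralConsistencyError,
    UndefinedCorrelationError,
)
from .network import KirchhoffMatrix, connected_components

DEFAULT_ZERO_TOL = 1e-8
B_FACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class ModeSpectrum:
    """Eigenpairs of Γ, ascending; columns of ``eigenvectors`` are modes.

    ``is_full`` distinguishes a complete decomposition from a partial one
    (lowest + highest modes only) used for very large networks. Nonzero
    modes are addressed with 1-based indices: mode 1 is the softest.
    """

    eigenvalues: np.ndarray        # (M,)
    eigenvectors: np.ndarray       # (N, M)
    n_zero_modes: int
    n_nodes: int
    is_full: bool = True
    n_high_modes: int = 0          # for partial spectra: trailing stiff modes

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero_modes

    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero_modes:]

    def mode(self, k: int) -> tuple[float, np.ndarray]:
        """Return (λ_k, u_k) for nonzero mode k (1-based, 1 = softest)."""
        if not 1 <= k <= self.n_nonzero:
            raise IndexError(f"mode index {k} outside 1..{self.n_nonzero}")
        col = self.n_zero_modes + k - 1
        return float(self.eigenvalues[col]), self.eigenvectors[:, col]


@dataclass
class FluctuationProfile:
    """Per-node mean-square fluctuations and per-mode square displacements."""

    msf: np.ndarray                # (N,), units of 3k_BT/γ
    mode_shapes: np.ndarray        # (n_nonzero, N): λ_k⁻¹ u_{k,i}²
    mode_eigenvalues: np.ndarray   # (n_nonzero,)
    theoretical_b: np.ndarray | None = None  # Å², set by theoretical_b_factors


@dataclass
class CrossCorrelationMap:
    values: np.ndarray             # (N, N) in [−1, 1]
    mode_subset: list[int]


@dataclass
class CollectivityTable:
    mode_indices: list[int]
    kappa: np.ndarray
    n_soft_reported: int


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|·| element is positive.

    Ties resolve to the lowest index (argmax convention), making the output
    independent of the solver's arbitrary sign choice.
    """
    out = vecs.copy()
    for k in range(out.shape[1]):
        lead = np.argmax(np.abs(out[:, k]))
        if out[lead, k] < 0:
            out[:, k] = -out[:, k]
    return out


def decompose(
    gamma: KirchhoffMatrix,
    zero_tol: float = DEFAULT_ZERO_TOL,
    check_components: bool = True,
) -> ModeSpectrum:
    """Full symmetric eigendecomposition of Γ, ascending eigenvalues.

    Eigenvalues with λ ≤ zero_tol · λ_max are classified as zero modes; the
    count is validated against the graph component count — a mismatch means
    the numerical decomposition cannot be trusted and raises.
    """
    g = gamma.dense()
    vals, vecs = scipy.linalg.eigh(g)
    lam_max = float(vals[-1]) if vals[-1] > 0 else 1.0
    n_zero = int(np.sum(vals <= zero_tol * lam_max))
    n_zero = max(n_zero, 1)
    if check_components:
        n_comp = len(connected_components(gamma))
        if n_comp != n_zero:
            raise SpectralConsistencyError(
                f"{n_zero} numerical zero mode(s) but {n_comp} graph "
                f"component(s); decomposition unreliable"
            )
    vecs = _fix_eigenvector_signs(vecs)
    return ModeSpectrum(
        eigenvalues=vals,
        eigenvectors=vecs,
        n_zero_modes=n_zero,
        n_nodes=g.shape[0],
        is_full=True,
    )


def decompose_partial(
    gamma: KirchhoffMatrix,
    n_low: int,
    n_high: int = 0,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> ModeSpectrum:
    """Partial decomposition for large networks: softest plus stiffest modes.

    Computes the ``n_low`` lowest eigenpairs (zero modes included) via
    shift-invert Lanczos and optionally the ``n_high`` highest. Intended for
    N above the dense threshold; per-mode quantities agree with the dense
    path on the overlap, but pseudo-inverse/msf sums are truncated and the
    profile must be treated as a soft-mode approximation.
    """
    A = gamma.sparse().astype(float)
    n = A.shape[0]
    k_low = min(n_low, n - 1)
    vals_lo, vecs_lo = spla.eigsh(A.tocsc(), k=k_low, sigma=-0.1, which="LM")
    order = np.argsort(vals_lo)
    vals_lo, vecs_lo = vals_lo[order], vecs_lo[:, order]
    vals, vecs = vals_lo, vecs_lo
    nh = 0
    if n_high > 0:
        vals_hi, vecs_hi = spla.eigsh(A, k=min(n_high, n - 1), which="LA")
        order = np.argsort(vals_hi)
        vals = np.concatenate([vals_lo, vals_hi[order]])
        vecs = np.hstack([vecs_lo, vecs_hi[:, order]])
        nh = min(n_high, n - 1)
    lam_max = float(vals[-1]) if vals[-1] > 0 else 1.0
    n_zero = max(int(np.sum(vals_lo <= zero_tol * lam_max)), 1)
    return ModeSpectrum(
        eigenvalues=np.clip(vals, 0.0, None),
        eigenvectors=_fix_eigenvector_signs(vecs),
        n_zero_modes=n_zero,
        n_nodes=n,
        is_full=False,
        n_high_modes=nh,
    )


def _require_connected(spectrum: ModeSpectrum, allow_disconnected: bool,
                       gamma: KirchhoffMatrix | None = None):
    if spectrum.n_zero_modes > 1 and not allow_disconnected:
        comps = connected_components(gamma) if gamma is not None else []
        raise DisconnectedNetworkError(
            f"network has {spectrum.n_zero_modes} components; pass "
            "allow_disconnected=True to analyse per-component dynamics",
            components=comps,
        )


def pseudo_inverse(
    spectrum: ModeSpectrum,
    allow_disconnected: bool = False,
    gamma: KirchhoffMatrix | None = None,
) -> np.ndarray:
    """Γ⁻¹ = Σ_k λ_k⁻¹ u_k u_kᵀ over nonzero modes (units 3k_BT/γ = 1)."""
    if not spectrum.is_full:
        raise ContractError("pseudo_inverse requires a full decomposition")
    _require_connected(spectrum, allow_disconnected, gamma)
    lam = spectrum.nonzero_eigenvalues()
    U = spectrum.eigenvectors[:, spectrum.n_zero_modes:]
    return (U / lam) @ U.T


def mode_contribution(spectrum: ModeSpectrum, k: int) -> np.ndarray:
    """Rank-1 contribution [C]_k = λ_k⁻¹ u_k u_kᵀ of nonzero mode k."""
    lam, u = spectrum.mode(k)
    return np.outer(u, u) / lam


def compute_fluctuations(spectrum: ModeSpectrum) -> FluctuationProfile:
    """Mean-square fluctuations and per-mode shapes from the spectrum.

    For a partial spectrum the sum runs over the available soft modes only,
    which is the standard soft-mode approximation of the profile.
    """
    lam = spectrum.nonzero_eigenvalues()
    U = spectrum.eigenvectors[:, spectrum.n_zero_modes:]
    shapes = (U**2 / lam).T           # (n_nonzero, N)
    return FluctuationProfile(
        msf=shapes.sum(axis=0),
        mode_shapes=shapes,
        mode_eigenvalues=lam.copy(),
    )


def cross_correlation(
    spectrum: ModeSpectrum, mode_subset: list[int] | None = None
) -> CrossCorrelationMap:
    """Orientational cross-correlations over a subset of nonzero modes.

    C_ij = G_ij / sqrt(G_ii G_jj) with G the subset-restricted
    pseudo-inverse. The diagonal is exactly 1; off-diagonals are clamped to
    [−1, 1] only to absorb rounding at the 1e-12 level.
    """
    if mode_subset is None:
        mode_subset = list(range(1, spectrum.n_nonzero + 1))
    if not mode_subset:
        raise ContractError("mode_subset must be nonempty")
    G = np.zeros((spectrum.n_nodes, spectrum.n_nodes))
    for k in mode_subset:
        G += mode_contribution(spectrum, k)
    d = np.diag(G).copy()
    # an analytically-zero component reaches us as rounding noise (~1e-30
    # after squaring); anything this far below the largest diagonal entry
    # has no defined fluctuation direction in the subset
    bad = np.flatnonzero(d <= 1e-14 * d.max())
    if bad.size:
        raise UndefinedCorrelationError(
            f"nodes {bad.tolist()[:10]} have zero fluctuation in the "
            f"selected mode subset; correlation undefined",
            nodes=bad.tolist(),
        )
    denom = np.sqrt(np.outer(d, d))
    C = G / denom
    over = np.abs(C) - 1.0
    if over.max() > 1e-12:
        raise SpectralConsistencyError(
            f"cross-correlation exceeds unit magnitude by {over.max():.2e}"
        )
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CrossCorrelationMap(values=C, mode_subset=list(mode_subset))


def collectivity(spectrum: ModeSpectrum, k: int) -> float:
    """Entropy-based collectivity κ_k = exp(−Σ u² ln u²)/N ∈ [1/N, 1].

    κ = 1 for a uniformly distributed mode, 1/N for a mode localized on a
    single node. Exactly-zero components contribute nothing (x ln x → 0).
    """
    _, u = spectrum.mode(k)
    u2 = u**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u2 > 0.0, u2 * np.log(u2), 0.0)
    return float(np.exp(-terms.sum()) / spectrum.n_nodes)


def collectivity_table(
    spectrum: ModeSpectrum, fraction: float = 0.1
) -> CollectivityTable:
    """Collectivity for the soft modes covering ``fraction`` of the dynamics."""
    m = soft_mode_count(spectrum, fraction)
    idx = list(range(1, m + 1))
    kappa = np.array([collectivity(spectrum, k) for k in idx])
    return CollectivityTable(mode_indices=idx, kappa=kappa, n_soft_reported=m)


def soft_mode_count(spectrum: ModeSpectrum, fraction: float = 0.1) -> int:
    """Smallest m with Σ_{k≤m} λ_k⁻¹ ≥ fraction · Σ_k λ_k⁻¹.

    λ_k⁻¹ is each mode's share of the total mean-square fluctuation, so m
    counts the soft modes accounting for that fraction of overall dynamics.
    """
    if not 0 < fraction <= 1:
        raise ContractError("fraction must be in (0, 1]")
    inv = 1.0 / spectrum.nonzero_eigenvalues()
    cum = np.cumsum(inv)
    return int(np.searchsorted(cum, fraction * cum[-1] - 1e-15) + 1)


def theoretical_b_factors(
    profile: FluctuationProfile,
    scale_policy: str = "fit",
    experimental: np.ndarray | None = None,
) -> np.ndarray:
    """Convert msf to B-factors: B_i = (8π²/3) · c · msf_i.

    ``scale_policy="unit"`` uses c = 1 (pure model units); ``"fit"``
    chooses the least-squares scalar c mapping predicted onto experimental
    B-factors. Scaling is a presentation choice only — correlation with
    experiment is invariant under it.
    """
    raw = B_FACTOR_PREFACTOR * profile.msf
    if scale_policy == "unit":
        b = raw
    elif scale_policy == "fit":
        if experimental is None:
            raise MissingDataError("scale_policy='fit' needs experimental B-factors")
        exp = np.asarray(experimental, float)
        if exp.shape != raw.shape:
            raise ContractError("experimental vector length mismatch")
        c = float(raw @ exp) / float(raw @ raw)
        b = c * raw
    else:
        raise ContractError(f"unknown scale_policy {scale_policy!r}")
    profile.theoretical_b = b
    return b


# --- plain-text export -----------------------------------------------------

_FMT = "%.10g"


def write_eigenvalues_tsv(spectrum: ModeSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("mode\tlambda\n")
        for k in range(1, spectrum.n_nonzero + 1):
            lam, _ = spectrum.mode(k)
            fh.write(f"{k}\t{_FMT % lam}\n")


def write_eigenvectors_tsv(spectrum: ModeSpectrum, modes: list[int], path) -> None:
    with open(path, "w") as fh:
        fh.write("mode\tnode\tu\n")
        for k in modes:
            _, u = spectrum.mode(k)
            for i, v in enumerate(u):
                fh.write(f"{k}\t{i}\t{_FMT % v}\n")


def write_msf_tsv(profile: FluctuationProfile, labels: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("node\tmsf\n")
        for lab, v in zip(labels, profile.msf):
            fh.write(f"{lab}\t{_FMT % v}\n")


def write_mode_shapes_tsv(
    profile: FluctuationProfile, modes: list[int], labels: list[str], path
) -> None:
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(f"mode{k}" for k in modes) + "\n")
        for i, lab in enumerate(labels):
            row = "\t".join(_FMT % profile.mode_shapes[k - 1, i] for k in modes)
            fh.write(f"{lab}\t{row}\n")


def write_crosscorr_tsv(cc: CrossCorrelationMap, path) -> None:
    np.savetxt(path, cc.values, fmt=_FMT, delimiter="\t",
               header="modes " + ",".join(map(str, cc.mode_subset)))


def write_collectivity_tsv(table: CollectivityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("mode\tkappa\n")
        for k, v in zip(table.mode_indices, table.kappa):
            fh.write(f"{k}\t{_FMT % v}\n")
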