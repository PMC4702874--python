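"""Self-contained validation experiments on synthetic fixtures.

Each function sets up a known-truth scenario with the fixtures generator,
runs the regular pipeline on it, and returns the measured quantities. They
back both the test suite and the reproduction script, and double as usage
examples for the library API.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import fixtures as fx
from .analysis import bfactor_correlation, domain_separation, slow_mode_minima
from .network import build_kirchhoff, connected_components, select_nodes
from .spectral import (
    collectivity,
    compute_fluctuations,
    decompose,
    mode_contribution,
    pseudo_inverse,
)
from .structure import build_assembly, parse_pdb

_RC = 7.3

#: study conditions of the synthetic benchmarks (see docs/methods.md):
#: ~0.3 Å coordinate jitter emulates thermal/lattice heterogeneity between
#: replicate geometries; B-factor noise of 4 Å² is ~5% of the synthetic
#: 0–80 Å² temperature-factor scale.
DUMBBELL_N = 33
DUMBBELL_JITTER = 0.3
DIMER_N = 30
DIMER_JITTER = 0.25
DIMER_B_NOISE = 4.0
NOISE_CHAIN_N = 50


def _msf_of(nodes):
    return compute_fluctuations(decompose(build_kirchhoff(nodes, _RC))).msf


def path_spectrum_error(n: int) -> float:
    """Max |λ_k − 4 sin²(kπ/2N)| for the N-bead chain (a path graph)."""
    nodes = fx.build_fixture(fx.FixtureSpec("linear_chain", n))[0]
    sp = decompose(build_kirchhoff(select_nodes(nodes), _RC))
    k = np.arange(1, n)
    closed_form = np.sort(4.0 * np.sin(k * np.pi / (2 * n)) ** 2)
    return float(np.abs(sp.nonzero_eigenvalues() - closed_form).max())


def _sample_cloud(n: int, rng: np.random.Generator, spread: float = 4.0):
    from .network import NodeSet
    pts = rng.uniform(0, spread * n ** (1 / 3), size=(n, 3))
    return NodeSet(
        positions=pts,
        labels=[("A", i + 1, "", "CA") for i in range(n)],
        node_class=["protein"] * n,
        experimental_b=None,
    )


def _sample_connected(n: int, rng: np.random.Generator):
    for _ in range(200):
        nodes = _sample_cloud(n, rng)
        gamma = build_kirchhoff(nodes, _RC)
        if len(connected_components(gamma)) == 1:
            return nodes, gamma
    raise RuntimeError("failed to sample a connected geometric graph")


def pseudo_inverse_oracle_errors(
    n_graphs: int = 50, max_n: int = 200, seed: int = 0
) -> tuple[float, float]:
    """(max |G − pinv(Γ)|, max |Σ_k [C]_k − G|) over random connected graphs."""
    rng = np.random.default_rng(seed)
    worst_oracle = worst_sum = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(10, max_n + 1))
        nodes, gamma = _sample_connected(n, rng)
        sp = decompose(gamma)
        G = pseudo_inverse(sp)
        worst_oracle = max(
            worst_oracle, float(np.abs(G - np.linalg.pinv(gamma.dense(), rcond=1e-10)).max())
        )
        total = sum(mode_contribution(sp, k)
                    for k in range(1, sp.n_nonzero + 1))
        worst_sum = max(worst_sum, float(np.abs(total - G).max()))
    return worst_oracle, worst_sum


def collectivity_extremes(n: int = 16, n_graphs: int = 10, seed: int = 0):
    """κ of exact uniform/delta modes plus bound violations on random graphs.

    Returns (κ_uniform, κ_delta · N, worst bound violation).
    """
    from .spectral import ModeSpectrum
    uniform = np.full(n, 1.0 / np.sqrt(n))
    delta = np.zeros(n)
    delta[0] = 1.0
    zero = np.ones(n) / np.sqrt(n)
    sp_u = ModeSpectrum(np.array([0.0, 1.0]),
                        np.column_stack([zero, uniform]), 1, n)
    sp_d = ModeSpectrum(np.array([0.0, 1.0]),
                        np.column_stack([zero, delta]), 1, n)
    k_uniform = collectivity(sp_u, 1)
    k_delta = collectivity(sp_d, 1)

    rng = np.random.default_rng(seed)
    violation = 0.0
    for _ in range(n_graphs):
        m = int(rng.integers(8, 40))
        nodes = _sample_cloud(m, rng)
        sp = decompose(build_kirchhoff(nodes, _RC), check_components=True)
        for k in range(1, sp.n_nonzero + 1):
            kap = collectivity(sp, k)
            violation = max(violation, (1.0 / m) - kap, kap - 1.0)
    return k_uniform, k_delta * n, violation


def zero_mode_component_agreement(n_graphs: int = 100, seed: int = 0) -> float:
    """Fraction of random graphs where n_zero_modes equals the BFS count.

    Half the samples are deliberately fragmented by spreading the points
    far beyond the percolation density.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_graphs):
        n = int(rng.integers(8, 120))
        spread = 4.0 if i % 2 == 0 else 12.0   # dense vs fragmented
        nodes = _sample_cloud(n, rng, spread)
        gamma = build_kirchhoff(nodes, _RC)
        sp = decompose(gamma, check_components=False)
        hits += sp.n_zero_modes == len(connected_components(gamma))
    return hits / n_graphs


def noise_recovery_curve(
    seed: int = 0,
    sigma_mults: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    n_reps: int = 200,
) -> tuple[float, list[float]]:
    """(noiseless r, mean r per noise level) for B = c·msf + noise fixtures.

    Noise levels are multiples of the standard deviation of the synthetic
    B-factor profile itself; each replicate re-generates and re-parses the
    fixture file, so the fixed-width PDB quantization is included.
    """
    base = fx.build_fixture(fx.FixtureSpec("linear_chain", NOISE_CHAIN_N))[0]
    msf = _msf_of(select_nodes(base))
    sd_b = float((fx.B_SCALE_MAX / msf.max()) * msf.std())

    with tempfile.TemporaryDirectory() as td:
        p = Path(td) / "chain.pdb"
        fx.generate(
            fx.FixtureSpec("linear_chain", NOISE_CHAIN_N,
                           b_model=fx.BFactorModel(noise_sd=0.0)), p)
        noiseless_r = bfactor_correlation(
            msf, select_nodes(parse_pdb(p)).experimental_b)

        means = []
        for mult in sigma_mults:
            rs = []
            for rep in range(n_reps):
                fx.generate(
                    fx.FixtureSpec(
                        "linear_chain", NOISE_CHAIN_N,
                        b_model=fx.BFactorModel(noise_sd=mult * sd_b,
                                                seed=seed + 7919 * rep)), p)
                rs.append(bfactor_correlation(
                    msf, select_nodes(parse_pdb(p)).experimental_b))
            means.append(float(np.mean(rs)))
    return float(noiseless_r), means


def dimer_vs_monomer(n_seeds: int = 50, seed: int = 0):
    """Per-seed (r against dimer msf, r against monomer msf).

    B-factors are synthesized from the assembled dimer, so only the
    assembly model should explain them fully — the qualitative analogue of
    the gain observed when analysing biological assemblies instead of
    asymmetric units.
    """
    pairs = []
    with tempfile.TemporaryDirectory() as td:
        p = Path(td) / "dimer.pdb"
        for i in range(n_seeds):
            fx.generate(
                fx.FixtureSpec(
                    "dimer_biomt", DIMER_N, noise_sigma=DIMER_JITTER,
                    seed=seed + i,
                    b_model=fx.BFactorModel(noise_sd=DIMER_B_NOISE)), p)
            st = parse_pdb(p)
            nodes_m = select_nodes(st)
            b = nodes_m.experimental_b
            msf_mono = _msf_of(nodes_m)
            nodes_d = select_nodes(build_assembly(st, "first_assembly"))
            msf_dimer = _msf_of(nodes_d)[: len(nodes_m)]
            pairs.append((bfactor_correlation(msf_dimer, b),
                          bfactor_correlation(msf_mono, b)))
    return pairs


def dumbbell_hinge_recovery(n_seeds: int = 20, seed: int = 0):
    """(sign-uniform hits, minimum-in-linker hits) over jittered dumbbells."""
    nc1 = (DUMBBELL_N - fx.LINKER_LENGTH + 1) // 2
    linker = set(range(nc1, nc1 + fx.LINKER_LENGTH))
    sign_ok = min_ok = 0
    with tempfile.TemporaryDirectory() as td:
        p = Path(td) / "dumbbell.pdb"
        for i in range(n_seeds):
            fx.generate(
                fx.FixtureSpec("dumbbell", DUMBBELL_N,
                               noise_sigma=DUMBBELL_JITTER, seed=seed + i), p)
            nodes = select_nodes(parse_pdb(p))
            sp = decompose(build_kirchhoff(nodes, _RC))
            prof = compute_fluctuations(sp)
            dd = domain_separation(sp, 1, nodes.chain_ids)
            c1 = set(dd.node_sign[:nc1])
            c2 = set(dd.node_sign[nc1 + fx.LINKER_LENGTH:])
            if len(c1) == 1 and len(c2) == 1 and c1 != c2:
                sign_ok += 1
            minima = slow_mode_minima(prof, [1], chain_map=nodes.chain_ids)
            if minima and minima[0] in linker:
                min_ok += 1
    return sign_ok, min_ok
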