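import numpy as np
import pytest

from gnmkit.network import NodeSet, build_kirchhoff


def nodeset_from_points(points, chain="A", b=None):
    pts = np.asarray(points, float)
    return NodeSet(
        positions=pts,
        labels=[(chain, i + 1, "", "CA") for i in range(len(pts))],
        node_class=["protein"] * len(pts),
        experimental_b=None if b is None else np.asarray(b, float),
    )


def path_nodes(n, spacing=5.0):
    """Collinear nodes whose contact graph (r_c=7.3) is the N-path."""
    return nodeset_from_points(
        np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    )


def random_connected_nodes(n, rng, box=None):
    """Random geometric cloud dense enough to be connected at r_c = 7.3."""
    from gnmkit.network import connected_components

    box = box if box is not None else 4.0 * n ** (1 / 3)
    for _ in range(100):
        pts = rng.uniform(0, box, size=(n, 3))
        gamma = build_kirchhoff(nodeset_from_points(pts), 7.3)
        if len(connected_components(gamma)) == 1:
            return nodeset_from_points(pts)
    raise RuntimeError("could not sample a connected cloud")


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)
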