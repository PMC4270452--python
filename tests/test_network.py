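import numpy as np
import pytest

from astrofilter.culture import CellRecord, Culture, CultureSpec, generate_culture
from astrofilter.network import (AstrocyteNetwork, build_voronoi_network,
                                 network_stats, voronoi_adjacency)


def make_culture(entries, field=(200.0, 200.0)):
    spec = CultureSpec(field_width_um=field[0], field_height_um=field[1],
                       cell_density_mm2=100.0, hard_core_radius_um=0.0, seed=0)
    cells = tuple(
        CellRecord(i, x, y, cls, stim)
        for i, (x, y, cls, stim) in enumerate(entries)
    )
    return Culture(cells, spec)


def brute_force_adjacency(points, bounds, n_samples=20001):
    """Independent oracle: i, j share a positive-length Voronoi border iff
    some point of their perpendicular bisector inside the field is strictly
    closer to i and j than to every other site."""
    points = np.asarray(points, float)
    n = len(points)
    xmin, ymin, xmax, ymax = bounds
    adj = set()
    for i in range(n):
        for j in range(i + 1, n):
            mid = 0.5 * (points[i] + points[j])
            d = points[j] - points[i]
            t = np.array([-d[1], d[0]])
            t /= np.linalg.norm(t)
            span = 2 * max(xmax - xmin, ymax - ymin)
            lam = np.linspace(-span, span, n_samples)
            pts = mid + lam[:, None] * t
            inside = ((pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
                      & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax))
            if not inside.any():
                continue
            pts = pts[inside]
            dist = np.linalg.norm(pts[:, None, :] - points[None, :, :], axis=2)
            dij = dist[:, i]
            others = np.delete(dist, [i, j], axis=1)
            ok = (np.abs(dist[:, j] - dij) < 1e-9) & (others.min(axis=1) > dij + 1e-9)
            if ok.any():
                adj.add((i, j))
    return adj


def test_single_astrocyte_has_degree_zero():
    culture = make_culture([(50.0, 50.0, "astrocyte", True)])
    net = build_voronoi_network(culture)
    assert net.n_astrocytes == 1 and net.degrees().tolist() == [0]


def test_interposed_neuron_separates_astrocytes():
    culture = make_culture([
        (40.0, 100.0, "astrocyte", True),
        (160.0, 100.0, "astrocyte", False),
        (100.0, 101.0, "neuron", False),
        (100.0, 40.0, "unclassified", False),
    ])
    net = build_voronoi_network(culture)
    assert net.edges.size == 0


def test_unit_square_corners_couple_along_sides_only():
    """Four cocircular astrocytes: diagonal contact is a point, not a
    positive-length border, so each corner has exactly its two side
    neighbours."""
    pts = [(50.0, 50.0), (150.0, 50.0), (150.0, 150.0), (50.0, 150.0)]
    culture = make_culture([(x, y, "astrocyte", False) for x, y in pts])
    net = build_voronoi_network(culture)
    edges = {tuple(e) for e in net.edges}
    assert edges == {(0, 1), (1, 2), (2, 3), (0, 3)}


def test_path_of_three_astrocytes():
    culture = make_culture([
        (40.0, 40.0, "astrocyte", False),
        (100.0, 60.0, "astrocyte", False),
        (160.0, 40.0, "astrocyte", False),
    ])
    net = build_voronoi_network(culture)
    stats = network_stats(net)
    assert sorted(net.degrees()) == [1, 1, 2]
    assert stats["component_size_histogram"] == {3: 1}


def test_empty_network_stats():
    net = AstrocyteNetwork((), np.empty((0, 2)), np.empty((0, 2), int),
                           np.empty(0, bool))
    stats = network_stats(net)
    assert stats["degree_histogram"] == {} and stats["component_size_histogram"] == {}


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_adjacency_matches_bisector_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 20)
    pts = rng.uniform(20, 180, size=(n, 2))
    bounds = (0.0, 0.0, 200.0, 200.0)
    assert voronoi_adjacency(pts, bounds) == brute_force_adjacency(pts, bounds)


def test_adjacency_invariant_under_rotation_translation():
    rng = np.random.default_rng(42)
    pts = rng.uniform(-30, 30, size=(12, 2))
    big = (-1000.0, -1000.0, 1000.0, 1000.0)
    base = voronoi_adjacency(pts, big)
    theta = 0.53
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = pts @ R.T + np.array([17.0, -5.0])
    assert voronoi_adjacency(moved, big) == base


def test_removing_nonastrocytes_only_adds_edges():
    culture = generate_culture(CultureSpec(seed=13, cell_density_mm2=500.0))
    net_all = build_voronoi_network(culture)
    astro_only = Culture(culture.by_class("astrocyte"), culture.spec)
    net_astro = build_voronoi_network(astro_only)
    ids_all = {tuple(sorted((net_all.astrocyte_ids[a], net_all.astrocyte_ids[b])))
               for a, b in net_all.edges}
    ids_astro = {tuple(sorted((net_astro.astrocyte_ids[a], net_astro.astrocyte_ids[b])))
                 for a, b in net_astro.edges}
    assert ids_all <= ids_astro


def test_collinear_fallback_warns_and_chains():
    culture = make_culture([
        (40.0, 100.0, "astrocyte", False),
        (100.0, 100.0, "astrocyte", False),
        (160.0, 100.0, "astrocyte", False),
    ])
    with pytest.warns(UserWarning, match="collinear"):
        net = build_voronoi_network(culture)
    assert sorted(net.degrees()) == [1, 1, 2]


def test_calibrated_ensemble_degree_statistics():
    """Default synthetic cultures: modal astrocyte degree 0-1, with roughly
    a fifth of astrocytes isolated and a third singly coupled."""
    degs = []
    comps = []
    import networkx as nx
    for seed in range(10):
        net = build_voronoi_network(generate_culture(CultureSpec(seed=seed)))
        degs.extend(net.degrees().tolist())
        comps.extend(len(c) for c in nx.connected_components(net.graph()))
    degs = np.array(degs)
    frac0 = np.mean(degs == 0)
    frac1 = np.mean(degs == 1)
    assert frac0 + frac1 > 0.4           # modal degree is 0-1
    assert 0.10 <= frac0 <= 0.35         # ~1/5 isolated
    assert 0.20 <= frac1 <= 0.45         # ~1/3 degree-1
    assert max(comps) >= 5               # occasional larger clusters


def test_network_file_roundtrip(tmp_path):
    net = build_voronoi_network(generate_culture(CultureSpec(seed=2)))
    net.to_files(tmp_path / "e.tsv", tmp_path / "n.tsv")
    back = AstrocyteNetwork.from_files(tmp_path / "e.tsv", tmp_path / "n.tsv")
    assert back.astrocyte_ids == net.astrocyte_ids
    assert {tuple(e) for e in back.edges} == {tuple(e) for e in net.edges}
    assert (back.stimulated == net.stimulated).all()
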