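import numpy as np
import pytest

import spnmorph as sp
from spnmorph.core import SomaContour
from spnmorph.morphometry import FitError, aggregate_abs_z


def build_path_tree(paths, soma_radius=5.0):
    """Reconstruction from a list of polyline paths, each starting at a node
    id of an earlier path (or 0 for the soma)."""
    ids = [1]
    types = [1]
    xyz = [np.zeros(3)]
    radius = [soma_radius]
    parents = [-1]
    for attach, pts, r in paths:
        parent = attach
        for p in pts:
            ids.append(len(ids) + 1)
            types.append(3)
            xyz.append(np.asarray(p, dtype=float))
            radius.append(r)
            parents.append(parent)
            parent = ids[-1]
    return sp.Reconstruction(np.array(ids), np.array(types), np.array(xyz),
                             np.array(radius), np.array(parents),
                             provenance={"standardized": True})


# ---------------------------------------------------------------------------
# segment partition


def test_unbranched_primary_is_one_segment():
    recon = sp.straight_dendrite(50.0, 1.0, step=5.0)
    segs = sp.partition_segments(recon)
    assert len(segs) == 1
    s = segs[0]
    assert s.order == 1 and s.breadth == 1
    assert s.is_primary and s.is_terminal


def test_y_tree_orders_and_breadth(tiny_tree):
    segs = sp.partition_segments(tiny_tree)
    assert len(segs) == 3
    orders = sorted(s.order for s in segs)
    assert orders == [1, 2, 2]
    root = next(s for s in segs if s.order == 1)
    assert root.breadth == 2
    assert sum(s.is_terminal for s in segs) == 2


def test_full_binary_tree_depth3():
    # primary 10 μm, then two levels of bifurcation → 7 segments, breadth 4
    paths = [(1, [(0, 0, 10)], 1.0)]
    # level 2 from node id 2
    paths += [(2, [(-5, 0, 20)], 0.8), (2, [(5, 0, 20)], 0.8)]
    # level 3 from ids 3 and 4
    paths += [(3, [(-8, 0, 30)], 0.5), (3, [(-2, 0, 30)], 0.5),
              (4, [(2, 0, 30)], 0.5), (4, [(8, 0, 30)], 0.5)]
    recon = build_path_tree(paths)
    segs = sp.partition_segments(recon)
    assert len(segs) == 7
    root = next(s for s in segs if s.order == 1)
    assert root.breadth == 4
    assert max(s.order for s in segs) == 3


def test_segment_lengths_conserve_total(mouse_recon):
    segs = sp.partition_segments(mouse_recon)
    total = sum(s.length for s in segs)
    assert total == pytest.approx(mouse_recon.total_dendritic_length(),
                                  rel=1e-9)


def test_branch_root_breadth_equals_branch_terminals(mouse_recon):
    segs = sp.partition_segments(mouse_recon)
    for bsegs in sp.branches(segs).values():
        root = next(s for s in bsegs if s.is_primary)
        assert root.breadth == sum(s.is_terminal for s in bsegs)


# ---------------------------------------------------------------------------
# branch / neuron morphometry


def test_branch_morphometry_arithmetic():
    # 4 terminals of 100 μm, 3 internal segments of 20 μm
    paths = [(1, [(0, 0, 20)], 1.0)]
    paths += [(2, [(-10, 0, 40)], 0.8), (2, [(10, 0, 40)], 0.8)]
    for attach, x in ((3, -15), (3, -5), (4, 5), (4, 15)):
        paths.append((attach, [(x, 0, 140)], 0.6))
    recon = build_path_tree(paths)
    segs = sp.partition_segments(recon)
    bm = sp.branch_morphometry(segs)
    assert bm.n_terminals == 4
    total = sum(s.length for s in segs)
    term = sum(s.length for s in segs if s.is_terminal)
    assert term / total == pytest.approx(bm.terminal_length / bm.total_length)


def test_single_segment_branch_fraction_one():
    recon = sp.straight_dendrite(80.0, 1.0)
    segs = sp.partition_segments(recon)
    bm = sp.branch_morphometry(segs)
    assert bm.terminal_length == pytest.approx(bm.total_length)


def test_two_y_branches_counts():
    paths = [(1, [(0, 0, 10)], 1.0),
             (2, [(-5, 0, 20)], 0.6), (2, [(5, 0, 20)], 0.6),
             (1, [(0, 0, -10)], 1.0),
             (5, [(-5, 0, -20)], 0.6), (5, [(5, 0, -20)], 0.6)]
    recon = build_path_tree(paths)
    nm = sp.neuron_morphometry(recon)
    assert nm.n_primaries == 2
    assert nm.n_terminals == 4
    assert nm.n_bifurcations == 2


def test_bifurcation_identity_on_synthetic_cells():
    for seed in range(30):
        recon, _ = sp.sample_morphology(sp.MOUSE, seed=seed)
        nm = sp.neuron_morphometry(recon)
        assert nm.n_bifurcations == nm.n_terminals - nm.n_primaries


def test_terminal_segments_longest_per_order(human_recon):
    segs = sp.partition_segments(human_recon)
    term_mean = np.mean([s.length for s in segs if s.is_terminal])
    other = [s.length for s in segs if not s.is_terminal]
    assert term_mean > np.mean(other)


# ---------------------------------------------------------------------------
# Sholl


def test_sholl_straight_radial_dendrite():
    recon = sp.straight_dendrite(95.0, 1.0, step=1.0, soma_radius=0.5)
    radii, counts = sp.sholl(recon, step=10.0)
    for r, c in zip(radii, counts):
        assert c == (1 if r <= 90 else 0), (r, c)


def test_sholl_zero_beyond_max_extent(mouse_recon):
    radii, counts = sp.sholl(mouse_recon, step=10.0)
    rmax = np.linalg.norm(mouse_recon.xyz, axis=1).max()
    assert counts[radii > rmax].sum() == 0


def test_sholl_integral_tracks_total_length():
    totals, integrals = [], []
    for seed in range(12):
        recon, _ = sp.sample_morphology(sp.MOUSE, seed=seed)
        radii, counts = sp.sholl(recon, step=10.0)
        totals.append(recon.total_dendritic_length())
        integrals.append(counts.sum() * 10.0)
    r = np.corrcoef(totals, integrals)[0, 1]
    assert r > 0.8


# ---------------------------------------------------------------------------
# taper fits and the subtree law


def test_constant_taper_exact():
    arc = np.linspace(0, 80, 30)
    fit = sp.fit_taper(arc, np.full(30, 0.6), kind="constant")
    assert fit.d_base == pytest.approx(0.6)


def test_exponential_taper_generative_recovery():
    arc = np.linspace(0, 120, 60)
    diam = 0.5 + (2.5 - 0.5) * np.exp(-arc / 30.0)
    fit = sp.fit_taper(arc, diam, kind="exponential")
    assert fit.d_base == pytest.approx(2.5, rel=1e-6)
    assert fit.d_end == pytest.approx(0.5, rel=1e-6)
    assert fit.rate == pytest.approx(30.0, rel=1e-6)


def test_exponential_taper_underdetermined():
    with pytest.raises(FitError):
        sp.fit_taper(np.array([0.0, 5.0]), np.array([1.0, 0.9]),
                     kind="exponential")


def test_subtree_law_constructed_identity():
    rng = np.random.default_rng(0)

    class Stub:
        def __init__(self, L, d):
            self.subtree_length = L
            self.mean_diameter = d

    Ls = rng.uniform(50, 800, size=200)
    segs = [Stub(L, 0.002 * L) for L in Ls]
    law = sp.fit_subtree_law(segs)
    assert law.slope == pytest.approx(0.002, abs=1e-9)
    assert law.intercept == pytest.approx(0.0, abs=1e-9)
    assert law.r_squared == pytest.approx(1.0)

    noisy = [Stub(L, 0.002 * L + rng.normal(0, 0.05)) for L in Ls]
    law2 = sp.fit_subtree_law(noisy)
    assert abs(law2.slope - 0.002) / 0.002 < 0.10


def test_subtree_law_positive_on_generated_cell(mouse_recon):
    segs = sp.partition_segments(mouse_recon)
    law = sp.fit_subtree_law(segs)
    assert law.slope > 0
    assert law.r_squared > 0.5


# ---------------------------------------------------------------------------
# Feret diameters


def test_feret_circle():
    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    contour = SomaContour(np.c_[5 * np.cos(theta), 5 * np.sin(theta)])
    fmin, fmax, fmean = sp.feret_diameters(contour)
    assert fmin == pytest.approx(10.0, rel=1e-3)
    assert fmax == pytest.approx(10.0, rel=1e-3)
    assert fmean == pytest.approx(10.0, rel=1e-3)


def test_feret_unit_square():
    contour = SomaContour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
    fmin, fmax, _ = sp.feret_diameters(contour)
    assert fmin == pytest.approx(1.0, abs=1e-4)
    assert fmax == pytest.approx(np.sqrt(2), rel=1e-6)


def test_feret_ellipse_plausibility():
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    contour = SomaContour(np.c_[11 * np.cos(theta), 4.85 * np.sin(theta)])
    fmin, fmax, _ = sp.feret_diameters(contour)
    assert fmin == pytest.approx(9.7, rel=0.01)
    assert fmax == pytest.approx(22.0, rel=0.01)


def test_feret_ordering_invariant(mouse_recon):
    rng = np.random.default_rng(4)
    for _ in range(10):
        pts = rng.normal(size=(12, 2)) * rng.uniform(1, 8)
        fmin, fmax, fmean = sp.feret_diameters(SomaContour(pts))
        assert fmin <= fmean <= fmax


# ---------------------------------------------------------------------------
# statistics


def test_welch_identical_samples():
    x = np.arange(10.0)
    cmp = sp.compare_groups(x, x)
    assert cmp.t_statistic == pytest.approx(0.0, abs=1e-12)
    assert cmp.p_value == pytest.approx(1.0)


def test_spearman_perfect_monotone():
    x = np.arange(20.0)
    cmp = sp.compare_groups(x, x ** 3, paired=True)
    assert cmp.spearman_r == pytest.approx(1.0)


def test_welch_separated_normals():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 50)
    b = rng.normal(1, 1, 50)
    cmp = sp.compare_groups(a, b)
    assert cmp.p_value < 1e-3


def test_zscores():
    ref = [{"f": 1.0, "g": 10.0}, {"f": 3.0, "g": 10.0}]
    z = sp.zscore_features({"f": 2.0, "g": 11.0}, ref)
    assert z["f"] == pytest.approx(0.0)
    assert np.isnan(z["g"])  # zero SD flagged
    sd = np.std([1.0, 3.0], ddof=1)
    z2 = sp.zscore_features({"f": 2.0 + sd, "g": 0.0}, ref)
    assert z2["f"] == pytest.approx(1.0)
    assert aggregate_abs_z({"a": 1.5, "b": -2.0, "c": float("nan")}) \
        == pytest.approx(3.5)
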