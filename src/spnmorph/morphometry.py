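"""Segment decomposition and quantitative morphometry of dendritic trees.

Nomenclature follows the standard dendrogram conventions: a *branch* is the
subtree extending from one primary dendrite; a *segment* is the portion of a
dendrite between two structural points (soma/branch point/tip); *order* is the
centrifugal hierarchical level (primary = 1); *breadth* is the centripetal
level, i.e. the number of terminal tips distal to a segment (terminal = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import DENDRITE, SOMA, Reconstruction, SomaContour


class FitError(RuntimeError):
    """Raised when a regression cannot be performed or does not converge."""


# ---------------------------------------------------------------------------
# segments


@dataclass
class Segment:
    """One dendritic segment between two structural points.

    ``node_path`` lists node row indices; its first element is the geometric
    base (the parent structural point, or the soma-attached node for a primary
    segment) and its last element the segment's own structural end point.
    """

    index: int
    branch_id: int
    parent: int          # segment index of the parent segment, −1 for primary
    node_path: list[int]
    order: int
    length: float
    base_diameter: float
    end_diameter: float
    mean_diameter: float
    base_path_distance: float
    children: list[int] = field(default_factory=list)
    breadth: int = 0
    subtree_length: float = 0.0

    @property
    def is_primary(self) -> bool:
        return self.order == 1

    @property
    def is_terminal(self) -> bool:
        return not self.children


def partition_segments(recon: Reconstruction) -> list[Segment]:
    """Decompose a standardised reconstruction into dendritic segments.

    Every dendritic node belongs to exactly one segment (branch-point nodes
    belong to the segment they terminate); segment lengths sum to the total
    dendritic length.
    """
    if not recon.is_standardized:
        raise ValueError("partition_segments expects a standardised reconstruction")
    root = recon.root_index
    children = recon.children
    xyz, radius, types = recon.xyz, recon.radius, recon.types
    pd = recon.path_distances()

    segments: list[Segment] = []
    # stack entries: (first node of segment body, parent segment index, order,
    #                 geometric base row or None for primaries)
    stack: list[tuple[int, int, int, int | None]] = []
    for c in reversed(children[root]):
        if types[c] == DENDRITE:
            stack.append((c, -1, 1, None))
    branch_counter = -1
    while stack:
        first, parent_seg, order, base_row = stack.pop()
        if parent_seg == -1:
            branch_counter += 1
            branch_id = branch_counter
        else:
            branch_id = segments[parent_seg].branch_id
        path = [first]
        k = first
        while len(children[k]) == 1:
            k = children[k][0]
            path.append(k)
        full = path if base_row is None else [base_row] + path
        pts = xyz[full]
        dd = 2.0 * radius[full]
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        length = float(seglen.sum())
        if length > 0:
            mean_d = float(((dd[:-1] + dd[1:]) / 2 * seglen).sum() / length)
        else:
            mean_d = float(dd.mean())
        seg = Segment(
            index=len(segments), branch_id=branch_id, parent=parent_seg,
            node_path=full, order=order, length=length,
            base_diameter=float(dd[0]), end_diameter=float(dd[-1]),
            mean_diameter=mean_d,
            base_path_distance=float(pd[full[0]]),
        )
        segments.append(seg)
        if parent_seg >= 0:
            segments[parent_seg].children.append(seg.index)
        for g in reversed(children[k]):
            stack.append((g, seg.index, order + 1, k))

    # breadths and subtree lengths, leaves first
    for seg in sorted(segments, key=lambda s: s.order, reverse=True):
        if seg.is_terminal:
            seg.breadth = 1
            seg.subtree_length = seg.length
        else:
            seg.breadth = sum(segments[c].breadth for c in seg.children)
            seg.subtree_length = seg.length + sum(
                segments[c].subtree_length for c in seg.children)
    return segments


def segment_profile(recon: Reconstruction, seg: Segment
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(arc length from segment base, diameter) samples at the segment nodes."""
    pts = recon.xyz[seg.node_path]
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return arc, 2.0 * recon.radius[seg.node_path]


def classify_segments(segments: list[Segment]
                      ) -> dict[str, list[Segment]]:
    """Split segments into primary / intermediate / terminal taper classes.

    Non-bifurcating primary dendrites (order-1 terminals) are excluded, as is
    conventional for taper analysis.
    """
    out: dict[str, list[Segment]] = {"primary": [], "intermediate": [],
                                     "terminal": []}
    for s in segments:
        if s.is_primary and s.is_terminal:
            continue
        if s.is_primary:
            out["primary"].append(s)
        elif s.is_terminal:
            out["terminal"].append(s)
        else:
            out["intermediate"].append(s)
    return out


# ---------------------------------------------------------------------------
# aggregate morphometry


@dataclass
class BranchMorphometry:
    total_length: float
    n_terminals: int
    max_order: int
    mean_segment_length: float
    mean_terminal_length: float
    terminal_length: float
    terminal_length_fraction: float

    def features(self) -> dict[str, float]:
        return {
            "total_length_um": self.total_length,
            "terminal_length_um": self.terminal_length,
            "n_terminals": float(self.n_terminals),
            "max_order": float(self.max_order),
            "mean_segment_length_um": self.mean_segment_length,
            "mean_terminal_length_um": self.mean_terminal_length,
        }


def branch_morphometry(branch_segments: list[Segment]) -> BranchMorphometry:
    """Morphometry of one dendritic branch (a primary and its subtree)."""
    if not branch_segments:
        raise ValueError("branch has no segments")
    lengths = np.array([s.length for s in branch_segments])
    term = np.array([s.is_terminal for s in branch_segments])
    total = float(lengths.sum())
    terminal_total = float(lengths[term].sum())
    return BranchMorphometry(
        total_length=total,
        n_terminals=int(term.sum()),
        max_order=max(s.order for s in branch_segments),
        mean_segment_length=float(lengths.mean()),
        mean_terminal_length=float(lengths[term].mean()) if term.any() else 0.0,
        terminal_length=terminal_total,
        terminal_length_fraction=terminal_total / total if total > 0 else 1.0,
    )


def branches(segments: list[Segment]) -> dict[int, list[Segment]]:
    out: dict[int, list[Segment]] = {}
    for s in segments:
        out.setdefault(s.branch_id, []).append(s)
    return out


@dataclass
class NeuronMorphometry:
    n_primaries: int
    n_bifurcations: int
    n_terminals: int
    max_order: int
    max_breadth: int
    total_length: float
    mean_branching_ratio: float
    mean_terminal_length: float
    terminal_length_fraction: float
    sholl_radii: np.ndarray | None = None
    sholl_counts: np.ndarray | None = None

    def features(self) -> dict[str, float]:
        return {
            "total_length_um": self.total_length,
            "n_primaries": float(self.n_primaries),
            "n_bifurcations": float(self.n_bifurcations),
            "n_terminals": float(self.n_terminals),
            "max_order": float(self.max_order),
            "max_breadth": float(self.max_breadth),
            "mean_terminal_length_um": self.mean_terminal_length,
        }


def neuron_morphometry(recon: Reconstruction, sholl_step: float | None = None,
                       segments: list[Segment] | None = None
                       ) -> NeuronMorphometry:
    """Whole-neuron morphometry, optionally with a Sholl profile attached."""
    if segments is None:
        segments = partition_segments(recon)
    term = [s for s in segments if s.is_terminal]
    bifs = [s for s in segments if not s.is_terminal]
    total = sum(s.length for s in segments)
    tlen = sum(s.length for s in term)
    nm = NeuronMorphometry(
        n_primaries=sum(1 for s in segments if s.is_primary),
        n_bifurcations=len(bifs),
        n_terminals=len(term),
        max_order=max((s.order for s in segments), default=0),
        max_breadth=max((s.breadth for s in segments), default=0),
        total_length=float(total),
        mean_branching_ratio=(
            float(np.mean([len(s.children) for s in bifs])) if bifs else 0.0),
        mean_terminal_length=(
            float(np.mean([s.length for s in term])) if term else 0.0),
        terminal_length_fraction=float(tlen / total) if total > 0 else 1.0,
    )
    if sholl_step is not None:
        nm.sholl_radii, nm.sholl_counts = sholl(recon, sholl_step)
    return nm


def sholl(recon: Reconstruction, step: float = 10.0
          ) -> tuple[np.ndarray, np.ndarray]:
    """Sholl profile: dendrite crossings of concentric spheres about the soma.

    Crossings are detected as sign changes of ``|p| − r`` along each edge
    (Euclidean radial distance, linear interpolation within edges).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pidx = recon.parent_index
    child_is_dend = recon.types == DENDRITE
    r_node = np.linalg.norm(recon.xyz, axis=1)
    edges = [(pidx[k], k) for k in range(recon.n_nodes)
             if pidx[k] >= 0 and child_is_dend[k]]
    if not edges:
        return np.array([step]), np.array([0])
    rmax = float(r_node[child_is_dend].max()) if child_is_dend.any() else 0.0
    nr = max(1, int(np.ceil(rmax / step)))
    radii = step * np.arange(1, nr + 1)
    counts = np.zeros(nr, dtype=int)
    for p, k in edges:
        r0 = 0.0 if recon.types[p] == SOMA else r_node[p]
        r1 = r_node[k]
        lo, hi = (r0, r1) if r0 <= r1 else (r1, r0)
        # rings strictly inside (lo, hi]; a touch without crossing is ignored
        first = int(np.floor(lo / step)) + 1
        last = int(np.floor(hi / step))
        if last >= first:
            counts[first - 1: last] += 1
    return radii, counts


# ---------------------------------------------------------------------------
# taper fits and the diameter–subtree-length law


@dataclass
class TaperFit:
    kind: str               # exponential | linear | constant
    d_base: float
    d_end: float
    rate: float             # decay constant (μm) or slope (μm/μm); 0 for constant
    goodness: float         # RMS residual (μm)


def fit_taper(arc: np.ndarray, diam: np.ndarray, kind: str = "exponential"
              ) -> TaperFit:
    """Least-squares diameter taper fit for one segment class.

    ``arc`` are arc-length positions from each segment's base, pooled over the
    class; the exponential model is d(s) = d_end + (d_base − d_end)·e^(−s/rate).
    """
    arc = np.asarray(arc, dtype=float)
    diam = np.asarray(diam, dtype=float)
    if arc.shape != diam.shape:
        raise ValueError("arc and diam must have the same shape")
    n_par = {"constant": 1, "linear": 2, "exponential": 3}.get(kind)
    if n_par is None:
        raise ValueError(f"unknown taper kind {kind!r}")
    if len(arc) < n_par:
        raise FitError(f"{kind} fit needs at least {n_par} points")
    if kind == "constant":
        d0 = float(diam.mean())
        return TaperFit("constant", d0, d0, 0.0,
                        float(np.sqrt(np.mean((diam - d0) ** 2))))
    if kind == "linear":
        slope, intercept = np.polyfit(arc, diam, 1)
        resid = diam - (intercept + slope * arc)
        smax = float(arc.max())
        return TaperFit("linear", float(intercept),
                        float(intercept + slope * smax), float(slope),
                        float(np.sqrt(np.mean(resid ** 2))))

    def model(s, d_base, d_end, rate):
        return d_end + (d_base - d_end) * np.exp(-s / rate)

    span = max(float(arc.max() - arc.min()), 1.0)
    p0 = (float(diam[np.argmin(arc)]), float(diam[np.argmax(arc)]), span / 3)
    try:
        popt, _ = optimize.curve_fit(
            model, arc, diam, p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy detail
        raise FitError(f"exponential taper fit failed: {exc}") from exc
    resid = diam - model(arc, *popt)
    return TaperFit("exponential", float(popt[0]), float(popt[1]),
                    float(popt[2]), float(np.sqrt(np.mean(resid ** 2))))


def pooled_taper_samples(recon: Reconstruction, segments: list[Segment],
                         which: str) -> tuple[np.ndarray, np.ndarray]:
    """Pool (arc, diameter) node samples for one taper class of a neuron."""
    cls = classify_segments(segments)[which]
    arcs, dias = [], []
    for s in cls:
        a, d = segment_profile(recon, s)
        arcs.append(a)
        dias.append(d)
    if not arcs:
        return np.array([]), np.array([])
    return np.concatenate(arcs), np.concatenate(dias)


@dataclass
class SubtreeLaw:
    slope: float        # μm diameter per μm subtree length
    intercept: float    # μm
    r_squared: float


def fit_subtree_law(segments: list[Segment], inclusive: bool = True
                    ) -> SubtreeLaw:
    """Ordinary least squares of mean segment diameter vs subtree length L.

    L is the total dendritic length distal to the segment's base node; by
    default it includes the measuring segment itself (``inclusive``).
    """
    if len(segments) < 2:
        raise FitError("subtree-law fit needs at least 2 segments")
    L = np.array([s.subtree_length if inclusive
                  else s.subtree_length - s.length for s in segments])
    d = np.array([s.mean_diameter for s in segments])
    slope, intercept = np.polyfit(L, d, 1)
    pred = intercept + slope * L
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SubtreeLaw(float(slope), float(intercept), r2)


# ---------------------------------------------------------------------------
# soma Feret diameters


def feret_diameters(contour: SomaContour, angle_step_deg: float = 0.5
                    ) -> tuple[float, float, float]:
    """(min Feret, max Feret, mean caliper width) of a 2D outline.

    Max Feret is the largest point-pair distance; min Feret is the smallest
    projection width over a dense angular scan; the mean caliper is the
    angular average of the width.
    """
    pts = contour.points
    diff = pts[:, None, :] - pts[None, :, :]
    max_feret = float(np.sqrt((diff ** 2).sum(-1)).max())
    if max_feret == 0.0:
        raise ValueError("degenerate contour: all points coincide")
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T                      # (n_points, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    min_feret = float(widths.min())
    if min_feret < 1e-9 * max_feret:
        raise ValueError("degenerate (collinear) contour")
    return min_feret, max_feret, float(widths.mean())


# ---------------------------------------------------------------------------
# comparison statistics


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    spearman_r: float | None = None
    spearman_p: float | None = None


def compare_groups(sample_a, sample_b, paired: bool = False
                   ) -> GroupComparison:
    """Welch's two-sided t-test; optionally Spearman rank correlation.

    With ``paired=True`` the two samples are treated as (x, y) pairs and the
    Spearman correlation (mid-rank ties) is reported alongside the t-test.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    out = GroupComparison(float(t), float(p), len(a), len(b))
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        r, sp = stats.spearmanr(a, b)
        out.spearman_r = float(r) if np.isfinite(r) else 0.0
        out.spearman_p = float(sp) if np.isfinite(sp) else 1.0
    return out


def zscore_features(candidate: dict[str, float],
                    reference: list[dict[str, float]]
                    ) -> dict[str, float]:
    """Per-feature Z-score of a candidate against a reference population.

    Features whose reference SD is zero are flagged with ``nan`` and should be
    excluded from aggregates (see :func:`aggregate_abs_z`).
    """
    if not reference:
        raise ValueError("empty reference population")
    out: dict[str, float] = {}
    for feat, value in candidate.items():
        vals = np.array([ref[feat] for ref in reference], dtype=float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[feat] = (value - mu) / sd if sd > 0 else float("nan")
    return out


def aggregate_abs_z(zscores: dict[str, float]) -> float:
    """Sum of |Z| over features, ignoring flagged (nan) entries."""
    vals = [abs(v) for v in zscores.values() if np.isfinite(v)]
    return float(sum(vals))
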