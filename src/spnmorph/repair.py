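"""Detection and repair of slice-cut dendrites.

Slice-derived reconstructions lose the part of the arbour nearest the slice
face.  Cut points are terminal nodes near the maximal z of the cell.  Repair
grafts distal material from intact donor branches of the same centrifugal
order onto each cut point, scaling donor diameters to continue the cut
segment, and selects — among many randomised candidates — the repair whose
whole-neuron morphometry best matches a mirror-symmetry prediction built from
the intact (deep) half of the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DENDRITE, SOMA, Reconstruction
from .morphometry import (
    BranchMorphometry,
    NeuronMorphometry,
    Segment,
    branch_morphometry,
    branches,
    neuron_morphometry,
    partition_segments,
    segment_profile,
)

SCORE_FEATURES = ["total_length_um", "n_terminals", "max_order",
                  "n_bifurcations", "max_breadth", "mean_terminal_length_um"]


class GraftRejected(RuntimeError):
    """Scaled donor diameters fall outside the species bounds."""


class GraftNotApplicable(RuntimeError):
    """The donor offers no material of the required topological order."""


class RepairError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# cut detection


@dataclass
class CutReport:
    cut_node_ids: list[int]
    z_threshold: float
    z_max: float


def detect_cut_points(recon: Reconstruction, z_threshold: float) -> CutReport:
    """Flag terminal dendritic nodes within ``z_threshold`` of the maximal z."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    children = recon.children
    dend = recon.dendrite_mask
    z = recon.xyz[:, 2]
    z_max = float(z.max())
    cut = [int(recon.ids[k]) for k in range(recon.n_nodes)
           if dend[k] and not children[k] and z[k] >= z_max - z_threshold]
    return CutReport(cut, z_threshold, z_max)


# ---------------------------------------------------------------------------
# donor pool


@dataclass
class DonorBranch:
    recon: Reconstruction
    segments: list[Segment]                  # segments of this branch only
    orders: set[int]
    source: str = ""

    def segments_of_order(self, order: int) -> list[Segment]:
        return [s for s in self.segments if s.order == order]


@dataclass
class DonorPool:
    branches: list[DonorBranch]
    diameter_bounds: tuple[float, float]
    reference: list[dict[str, float]] = field(default_factory=list)
    # per-feature SDs of the intact cohort, used for candidate Z-scores
    feature_sd: dict[str, float] = field(default_factory=dict)

    def with_order(self, order: int) -> list[DonorBranch]:
        return [b for b in self.branches if order in b.orders]

    def nearest_order(self, order: int) -> int:
        """The available centrifugal order closest to ``order``.

        Deep cut points can exceed every donor's maximal order (intact donor
        branches are typically shallower); grafting then falls back to the
        closest order on offer (ties resolved toward the deeper order).
        """
        available = sorted({o for b in self.branches for o in b.orders})
        if not available:
            raise RepairError("donor pool has no segments at all")
        return min(available, key=lambda o: (abs(o - order), -o))


def build_donor_pool(recons: list[Reconstruction], z_threshold: float,
                     diameter_bounds: tuple[float, float]) -> DonorPool:
    """Collect intact dendritic branches (no cut points) across a cohort."""
    pool: list[DonorBranch] = []
    reference: list[dict[str, float]] = []
    for idx, recon in enumerate(recons):
        report = detect_cut_points(recon, z_threshold)
        cut_rows = {recon.index[i] for i in report.cut_node_ids}
        segs = partition_segments(recon)
        reference.append(neuron_morphometry(recon, segments=segs).features())
        for bid, bsegs in branches(segs).items():
            has_cut = any(s.node_path[-1] in cut_rows
                          for s in bsegs if s.is_terminal)
            if not has_cut:
                pool.append(DonorBranch(
                    recon=recon, segments=bsegs,
                    orders={s.order for s in bsegs},
                    source=f"recon{idx}/branch{bid}"))
    if not pool:
        raise RepairError(
            "donor pool is empty: every branch in the cohort contains a cut "
            "point; supply additional intact reconstructions")
    sds: dict[str, float] = {}
    if len(reference) > 1:
        for feat in reference[0]:
            vals = np.array([r[feat] for r in reference])
            sds[feat] = float(vals.std(ddof=1))
    return DonorPool(pool, diameter_bounds, reference, sds)


# ---------------------------------------------------------------------------
# mirror prediction


def _clip_above_plane(recon: Reconstruction, plane: float) -> Reconstruction:
    """Keep geometry with z ≤ plane; truncate crossing paths at the plane."""
    children = recon.children
    z = recon.xyz[:, 2]
    keep: list[int] = []
    extra: list[tuple[np.ndarray, float, int]] = []
    stack = [recon.root_index]
    while stack:
        k = stack.pop()
        keep.append(k)
        for c in children[k]:
            if z[c] <= plane:
                stack.append(c)
            else:
                t = (plane - z[k]) / (z[c] - z[k])
                if t > 1e-9:
                    pos = recon.xyz[k] + t * (recon.xyz[c] - recon.xyz[k])
                    r = recon.radius[k] + t * (recon.radius[c] - recon.radius[k])
                    extra.append((pos, float(r), k))
    keep_arr = np.array(sorted(keep))
    ids = list(recon.ids[keep_arr])
    types = list(recon.types[keep_arr])
    xyz = [p for p in recon.xyz[keep_arr]]
    radii = list(recon.radius[keep_arr])
    parents = list(recon.parent_ids[keep_arr])
    nid = int(recon.ids.max()) + 1
    for pos, r, prow in extra:
        ids.append(nid)
        types.append(DENDRITE)
        xyz.append(pos)
        radii.append(r)
        parents.append(int(recon.ids[prow]))
        nid += 1
    return Reconstruction(np.array(ids), np.array(types), np.array(xyz),
                          np.array(radii), np.array(parents),
                          provenance=dict(recon.provenance), validate=False)


def predict_morphometry(recon: Reconstruction,
                        sholl_step: float | None = None) -> NeuronMorphometry:
    """Mirror-symmetry morphometry prediction from the deep half of the cell.

    The geometry with z ≤ 0 (the half away from the slice face, soma at the
    origin) is kept, its z-mirror image is added, and the morphometry of the
    union is returned as the prediction for the intact cell.
    """
    if not recon.is_standardized:
        raise ValueError("predict_morphometry expects a standardised reconstruction")
    half = _clip_above_plane(recon, 0.0)
    if not np.any((half.types == DENDRITE)):
        raise ValueError("no dendrite below z = 0; cannot build a prediction")
    # union with the z-mirrored copy of the dendrites
    dend = half.types == DENDRITE
    n_d = int(dend.sum())
    if n_d == 0:
        raise ValueError("no dendrite below z = 0")
    offset = int(half.ids.max())
    soma_ids = set(int(i) for i in half.ids[half.types == SOMA])
    mirror_parent = np.array(
        [int(p) if int(p) in soma_ids else int(p) + offset
         for p in half.parent_ids[dend]])
    xyz_m = half.xyz[dend].copy()
    xyz_m[:, 2] *= -1.0
    union = Reconstruction(
        ids=np.concatenate([half.ids, half.ids[dend] + offset]),
        types=np.concatenate([half.types, half.types[dend]]),
        xyz=np.vstack([half.xyz, xyz_m]),
        radius=np.concatenate([half.radius, half.radius[dend]]),
        parent_ids=np.concatenate([half.parent_ids, mirror_parent]),
        provenance={"mirror_prediction": True, "standardized": True},
        validate=False)
    return neuron_morphometry(union, sholl_step=sholl_step)


# ---------------------------------------------------------------------------
# grafting


@dataclass
class _CutSite:
    node_id: int
    order: int
    mean_diameter: float
    position: np.ndarray
    tangent: np.ndarray


def _cut_site(recon: Reconstruction, segments: list[Segment],
              cut_node_id: int, tangent_window: float = 3.0) -> _CutSite:
    row = recon.index[cut_node_id]
    seg = next((s for s in segments if s.node_path[-1] == row), None)
    if seg is None or not seg.is_terminal:
        raise ValueError(f"node {cut_node_id} is not a terminal segment end")
    arc, _ = segment_profile(recon, seg)
    pts = recon.xyz[seg.node_path]
    end = pts[-1]
    s0 = max(0.0, float(arc[-1]) - tangent_window)
    base = np.array([np.interp(s0, arc, pts[:, i]) for i in range(3)])
    tangent = end - base
    norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        tangent = end - recon.xyz[seg.node_path[0]]
        norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        tangent = np.array([0.0, 0.0, 1.0])
        norm = 1.0
    return _CutSite(cut_node_id, seg.order, seg.mean_diameter, end,
                    tangent / norm)


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    c = float(a @ b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis perpendicular to a
        ref = np.array([1.0, 0.0, 0.0])
        if abs(a @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, ref)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


@dataclass
class GraftPlan:
    """Donor material expressed relative to the cut site, ready to append."""

    xyz: np.ndarray
    radius: np.ndarray
    parent_slot: np.ndarray        # −1 = attach to the cut node
    scale: float
    donor_source: str
    junction_diameter: float       # scaled donor base diameter


def _plan_graft(site: _CutSite, donor: DonorBranch, donor_seg: Segment,
                bounds: tuple[float, float]) -> GraftPlan:
    drecon = donor.recon
    base_row = donor_seg.node_path[0]
    base_pos = drecon.xyz[base_row]
    d_attach = 2.0 * float(drecon.radius[base_row])
    scale = site.mean_diameter / d_attach

    # distal material: the donor segment body plus its whole subtree
    seg_by_index = {s.index: s for s in donor.segments}
    rows: list[int] = []
    parent_slot: list[int] = []
    slot_of_row: dict[int, int] = {base_row: -1}

    def collect(seg: Segment) -> None:
        for r in seg.node_path[1:]:
            parent_row = drecon.parent_index[r]
            rows.append(r)
            parent_slot.append(slot_of_row[parent_row])
            slot_of_row[r] = len(rows) - 1
        for ci in seg.children:
            collect(seg_by_index[ci])

    collect(donor_seg)

    # bounds: every terminal segment of the grafted material, after scaling
    def check(seg: Segment) -> None:
        if seg.is_terminal:
            d = seg.mean_diameter * scale
            if not (bounds[0] <= d <= bounds[1]):
                raise GraftRejected(
                    f"scaled terminal diameter {d:.3f} μm outside "
                    f"[{bounds[0]}, {bounds[1]}]")
        for ci in seg.children:
            check(seg_by_index[ci])

    check(donor_seg)

    # orientation: align the donor base direction with the cut tangent
    arc, _ = segment_profile(drecon, donor_seg)
    pts = drecon.xyz[donor_seg.node_path]
    s1 = min(3.0, float(arc[-1])) if arc[-1] > 0 else 0.0
    ahead = np.array([np.interp(s1, arc, pts[:, i]) for i in range(3)])
    ddir = ahead - base_pos
    n = np.linalg.norm(ddir)
    ddir = ddir / n if n > 1e-12 else site.tangent
    rot = _rotation_to(ddir, site.tangent)

    rel = (drecon.xyz[rows] - base_pos) @ rot.T
    return GraftPlan(
        xyz=site.position + rel,
        radius=drecon.radius[rows] * scale,
        parent_slot=np.array(parent_slot, dtype=np.int64),
        scale=scale,
        donor_source=donor.source,
        junction_diameter=d_attach * scale,
    )


def graft(recon: Reconstruction, cut_node_id: int, donor: DonorBranch,
          bounds: tuple[float, float],
          rng: np.random.Generator | None = None,
          segments: list[Segment] | None = None
          ) -> tuple[Reconstruction, GraftPlan]:
    """Extend one cut terminal with same-order donor material.

    Raises :class:`GraftNotApplicable` when the donor has no segment of the
    cut node's order and :class:`GraftRejected` when scaled terminal diameters
    leave ``bounds``.
    """
    if segments is None:
        segments = partition_segments(recon)
    site = _cut_site(recon, segments, cut_node_id)
    candidates = donor.segments_of_order(site.order)
    if not candidates:
        raise GraftNotApplicable(
            f"donor {donor.source} has no order-{site.order} material")
    if rng is None:
        rng = np.random.default_rng()
    donor_seg = candidates[int(rng.integers(len(candidates)))]
    plan = _plan_graft(site, donor, donor_seg, bounds)
    return _apply_plans(recon, [(cut_node_id, plan)]), plan


def _apply_plans(recon: Reconstruction,
                 plans: list[tuple[int, GraftPlan]]) -> Reconstruction:
    ids = [recon.ids]
    types = [recon.types]
    xyz = [recon.xyz]
    radii = [recon.radius]
    parents = [recon.parent_ids]
    nid = int(recon.ids.max())
    for cut_id, plan in plans:
        n = len(plan.radius)
        new_ids = np.arange(nid + 1, nid + n + 1, dtype=np.int64)
        nid += n
        par = np.where(plan.parent_slot < 0, cut_id,
                       new_ids[np.maximum(plan.parent_slot, 0)])
        ids.append(new_ids)
        types.append(np.full(n, DENDRITE, dtype=np.int64))
        xyz.append(plan.xyz)
        radii.append(plan.radius)
        parents.append(par)
    prov = dict(recon.provenance)
    prov["repaired"] = True
    return Reconstruction(np.concatenate(ids), np.concatenate(types),
                          np.vstack(xyz), np.concatenate(radii),
                          np.concatenate(parents), provenance=prov,
                          validate=False)


# ---------------------------------------------------------------------------
# full repair


@dataclass
class RepairCandidate:
    recon: Reconstruction
    graft_log: list[dict]
    score: float


def repair_reconstruction(recon: Reconstruction, pool: DonorPool,
                          z_threshold: float, n_candidates: int = 100,
                          seed=None, resample_after: bool = True,
                          max_donor_tries: int = 50) -> RepairCandidate:
    """Generate randomised repairs and keep the best-matching candidate.

    Each candidate grafts a randomly chosen same-order donor onto every cut
    point; candidates are scored by the aggregate |Z| of their whole-neuron
    morphometry against the mirror-symmetry prediction, with per-feature SDs
    taken from the intact cohort behind the donor pool; the minimal-score
    candidate wins (ties broken by candidate index) and is resampled at 3 μm
    with the 1% length recovery.
    """
    from .swc import resample

    rng = np.random.default_rng(seed)
    report = detect_cut_points(recon, z_threshold)
    if not report.cut_node_ids:
        return RepairCandidate(recon, [], 0.0)
    segments = partition_segments(recon)
    sites = [_cut_site(recon, segments, cid) for cid in report.cut_node_ids]
    target = predict_morphometry(recon).features()
    sds = {f: pool.feature_sd.get(f, 0.0) for f in SCORE_FEATURES}

    best: RepairCandidate | None = None
    n_rejected = 0
    for ci in range(n_candidates):
        plans: list[tuple[int, GraftPlan]] = []
        log: list[dict] = []
        ok = True
        for site in sites:
            # same order first; if every same-order donor violates the
            # diameter bounds, widen to neighbouring orders by distance
            available = sorted({o for b in pool.branches for o in b.orders},
                               key=lambda o: (abs(o - site.order), -o))
            plan = None
            for order in available:
                usable = pool.with_order(order)
                for _ in range(max_donor_tries):
                    donor = usable[int(rng.integers(len(usable)))]
                    cands = donor.segments_of_order(order)
                    donor_seg = cands[int(rng.integers(len(cands)))]
                    try:
                        plan = _plan_graft(site, donor, donor_seg,
                                           pool.diameter_bounds)
                        break
                    except GraftRejected:
                        continue
                if plan is not None:
                    break
            if plan is None:
                ok = False
                break
            plans.append((site.node_id, plan))
            log.append({"cut_node": site.node_id, "donor": plan.donor_source,
                        "scale": plan.scale})
        if not ok:
            n_rejected += 1
            continue
        cand = _apply_plans(recon, plans)
        feats = neuron_morphometry(cand).features()
        score = 0.0
        for f in SCORE_FEATURES:
            sd = sds.get(f, 0.0)
            if sd > 0:
                score += abs(feats[f] - target[f]) / sd
        if best is None or score < best.score:
            best = RepairCandidate(cand, log, score)
    if best is None:
        raise RepairError(
            f"all {n_candidates} candidates rejected by the diameter bounds "
            f"({n_rejected} rejections); widen the pool or check the bounds")
    if resample_after:
        best = RepairCandidate(resample(best.recon, 3.0, 1.01),
                               best.graft_log, best.score)
    return best


def validate_repair(repaired_cohort: list[Reconstruction],
                    complete_branches: list[BranchMorphometry]
                    ) -> dict[str, float]:
    """Z of repaired-branch feature means against the complete-branch spread."""
    if not repaired_cohort or not complete_branches:
        raise ValueError("both cohorts must be non-empty")
    rep_feats: list[dict[str, float]] = []
    for recon in repaired_cohort:
        segs = partition_segments(recon)
        for bsegs in branches(segs).values():
            rep_feats.append(branch_morphometry(bsegs).features())
    comp = [b.features() for b in complete_branches]
    out: dict[str, float] = {}
    for feat in comp[0]:
        cvals = np.array([c[feat] for c in comp])
        rvals = np.array([r[feat] for r in rep_feats])
        sd = float(cvals.std(ddof=1))
        out[feat] = ((float(rvals.mean()) - float(cvals.mean())) / sd
                     if sd > 0 else float("nan"))
    return out
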