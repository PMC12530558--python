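"""Seeded synthetic SPN morphologies, spine inventories and slice artefacts.

The generator emulates the published cohort statistics of mouse and human
striatal projection neurons: 3–8 / 3–9 primary dendrites with medians 5 / 6,
the empirical branch-breadth (terminals per dendritic branch) frequency
tables, constant terminal diameters of 0.6 / 1.0 μm, terminal segments
carrying 84% / 92% of the dendritic length, sigmoid spine densities with
plateaus 1.6 / 0.7 spines/μm and mean spine areas 3.118 / 4.263 μm².  A
slice-cut operation truncates everything above a plane parallel to the slice
face, recording the ground-truth cut set so the repair pipeline can be tested
against known answers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DENDRITE, SOMA, Reconstruction
from .morphometry import BranchMorphometry, branch_morphometry, branches, partition_segments
from .spines import SpineDensityModel, spine_density


# ---------------------------------------------------------------------------
# presets


@dataclass(frozen=True)
class SpeciesPreset:
    """Generative parameter bundle for one species' SPN cohort."""

    name: str
    n_primary_probs: dict[int, float]
    breadth_counts: dict[int, int]       # empirical terminals-per-branch counts
    internal_length_mean: float          # μm, non-terminal segments
    internal_length_cv: float
    terminal_length_mean: float          # μm, calibrated to the terminal-length fraction
    terminal_length_cv: float
    terminal_length_fraction: float      # calibration target
    terminal_diameter: float             # μm
    terminal_diameter_sd: float          # per-segment jitter, μm
    subtree_slope: float                 # μm diameter per μm subtree length
    soma_radius: float                   # μm
    spine_model: SpineDensityModel
    f_spines: float
    spine_area_mean: float               # μm²
    spine_area_cv: float
    head_area_fraction: float
    neck_length_mean: float              # μm
    neck_diameter_mean: float            # μm
    cut_z_threshold: float               # μm, species cut-point search band
    diameter_bounds: tuple[float, float]  # μm, terminal-diameter repair bounds
    node_step: float = 4.0               # μm, polyline sampling
    direction_jitter: float = 0.25       # per-step direction noise (radians-ish)
    branch_angle_deg: float = 35.0

    @property
    def breadth_probs(self) -> dict[int, float]:
        total = sum(self.breadth_counts.values())
        return {k: v / total for k, v in self.breadth_counts.items()}

    @property
    def mean_breadth(self) -> float:
        total = sum(self.breadth_counts.values())
        return sum(k * v for k, v in self.breadth_counts.items()) / total

    @property
    def median_breadth(self) -> float:
        vals: list[int] = []
        for k, v in sorted(self.breadth_counts.items()):
            vals.extend([k] * v)
        return float(np.median(vals))


def _terminal_length_for_fraction(fraction: float, breadth_counts: dict[int, int],
                                  internal_mean: float) -> float:
    """Terminal-segment mean length that yields the target cohort
    terminal-length fraction under the branch-breadth distribution.

    A binary branch of breadth k has k terminal and k−1 internal segments, so
    fraction = E[k]·Lt / (E[k]·Lt + E[k−1]·Li).
    """
    total = sum(breadth_counts.values())
    ek = sum(k * v for k, v in breadth_counts.items()) / total
    ek1 = ek - 1.0
    return fraction * ek1 * internal_mean / ((1.0 - fraction) * ek)


_MOUSE_BREADTH = {1: 8, 2: 4, 3: 6, 4: 9, 5: 6, 6: 4, 7: 4, 8: 4, 13: 1}
_HUMAN_BREADTH = {1: 4, 2: 4, 3: 9, 4: 6, 5: 2, 6: 5, 7: 1, 8: 2, 15: 1, 21: 1}

MOUSE = SpeciesPreset(
    name="mouse",
    n_primary_probs={3: 0.10, 4: 0.20, 5: 0.30, 6: 0.20, 7: 0.12, 8: 0.08},
    breadth_counts=_MOUSE_BREADTH,
    internal_length_mean=20.0,
    internal_length_cv=0.30,
    terminal_length_mean=round(
        _terminal_length_for_fraction(0.84, _MOUSE_BREADTH, 20.0), 1),
    terminal_length_cv=0.35,
    terminal_length_fraction=0.84,
    terminal_diameter=0.6,
    terminal_diameter_sd=0.03,
    subtree_slope=0.0034,
    soma_radius=12.9 / 2,
    spine_model=SpineDensityModel(a=1.6, b=35.0, c=8.0),
    f_spines=2.23,
    spine_area_mean=3.118,
    spine_area_cv=0.6,
    head_area_fraction=0.7,
    neck_length_mean=1.0,
    neck_diameter_mean=0.2,
    cut_z_threshold=20.0,
    diameter_bounds=(0.376, 0.876),
)

HUMAN = SpeciesPreset(
    name="human",
    n_primary_probs={3: 0.06, 4: 0.12, 5: 0.22, 6: 0.28, 7: 0.16, 8: 0.10,
                     9: 0.06},
    breadth_counts=_HUMAN_BREADTH,
    internal_length_mean=20.0,
    internal_length_cv=0.30,
    terminal_length_mean=round(
        _terminal_length_for_fraction(0.92, _HUMAN_BREADTH, 20.0), 1),
    terminal_length_cv=0.35,
    terminal_length_fraction=0.92,
    terminal_diameter=1.0,
    terminal_diameter_sd=0.03,
    subtree_slope=0.0017,
    soma_radius=17.4 / 2,
    spine_model=SpineDensityModel(a=0.7, b=35.0, c=8.0),
    f_spines=1.71,
    spine_area_mean=4.263,
    spine_area_cv=0.6,
    head_area_fraction=0.7,
    neck_length_mean=1.2,
    neck_diameter_mean=0.25,
    cut_z_threshold=10.0,
    diameter_bounds=(0.59, 1.26),
)

PRESETS = {"mouse": MOUSE, "human": HUMAN}


@dataclass
class GroundTruth:
    """Per-cell ground truth recorded by the generator and the slicer."""

    recon: Reconstruction
    branch_morphometry: list[BranchMorphometry]
    cut_plane_z: float | None = None
    cut_node_ids: list[int] | None = None
    spines: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# random helpers


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * float(axis @ v) * (1 - np.cos(angle)))


def _deviate(direction: np.ndarray, angle: float, azimuth: float) -> np.ndarray:
    """Unit vector at ``angle`` from ``direction`` at the given azimuth."""
    d = _unit(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    perp = _unit(np.cross(d, ref))
    tilted = _rotate_about(d, perp, angle)
    return _unit(_rotate_about(tilted, d, azimuth))


# ---------------------------------------------------------------------------
# morphology sampling


@dataclass
class _SegSpec:
    length: float
    is_terminal: bool
    children: list["_SegSpec"] = field(default_factory=list)
    subtree_length: float = 0.0
    base_d: float = 0.0
    end_d: float = 0.0


def _sample_topology(k: int, preset: SpeciesPreset,
                     rng: np.random.Generator) -> _SegSpec:
    """Random binary topology realising k terminal tips, with lengths."""
    if k < 1:
        raise ValueError("branch breadth must be ≥ 1")
    if k == 1:
        return _SegSpec(
            length=_lognormal(rng, preset.terminal_length_mean,
                              preset.terminal_length_cv),
            is_terminal=True)
    j = int(rng.integers(1, k))
    node = _SegSpec(
        length=_lognormal(rng, preset.internal_length_mean,
                          preset.internal_length_cv),
        is_terminal=False,
        children=[_sample_topology(j, preset, rng),
                  _sample_topology(k - j, preset, rng)])
    return node


def _assign_diameters(spec: _SegSpec, preset: SpeciesPreset,
                      rng: np.random.Generator) -> None:
    _assign_subtree(spec)

    def law(L: float) -> float:
        return preset.terminal_diameter + preset.subtree_slope * max(
            0.0, L - preset.terminal_length_mean)

    def assign(s: _SegSpec) -> None:
        if s.is_terminal:
            d = preset.terminal_diameter + rng.normal(
                0.0, preset.terminal_diameter_sd)
            d = max(0.2, d)
            s.base_d = s.end_d = d
        else:
            s.base_d = law(s.subtree_length)
            s.end_d = law(s.subtree_length - s.length)
        for c in s.children:
            assign(c)

    assign(spec)


def _assign_subtree(s: _SegSpec) -> float:
    s.subtree_length = s.length + sum(_assign_subtree(c) for c in s.children)
    return s.subtree_length


def sample_morphology(preset: SpeciesPreset, seed=None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Reconstruction, GroundTruth]:
    """Generate one synthetic SPN as a standardised reconstruction.

    Tree growth: sample the number of primary dendrites, then per branch a
    breadth from the empirical table and a random binary topology realising
    it; per-order lognormal segment lengths; diameters from the subtree-length
    law with the species' constant terminal diameter; 3D embedding by a
    persistent random walk with radially spread primaries.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_prim = int(rng.choice(list(preset.n_primary_probs),
                            p=list(preset.n_primary_probs.values())))
    breadth_keys = sorted(preset.breadth_probs)
    breadth_p = [preset.breadth_probs[k] for k in breadth_keys]

    ids = [1]
    types = [SOMA]
    xyz = [np.zeros(3)]
    radii = [preset.soma_radius]
    parents = [-1]
    next_id = 2

    def emit(p: np.ndarray, r: float, parent: int) -> int:
        nonlocal next_id
        ids.append(next_id)
        types.append(DENDRITE)
        xyz.append(p.copy())
        radii.append(r)
        parents.append(parent)
        next_id += 1
        return ids[-1]

    def grow_segment(spec: _SegSpec, start: np.ndarray, direction: np.ndarray,
                     parent_id: int, emit_base: bool) -> tuple[np.ndarray, np.ndarray, int]:
        """Lay out one segment's polyline; returns (end point, end dir, end id)."""
        pos = start.copy()
        d = _unit(direction)
        pid = parent_id
        if emit_base:
            pid = emit(pos, spec.base_d / 2, pid)
        n_steps = max(1, int(round(spec.length / preset.node_step)))
        step = spec.length / n_steps
        for i in range(n_steps):
            d = _unit(d + preset.direction_jitter * rng.normal(size=3))
            pos = pos + step * d
            frac = (i + 1) / n_steps
            r = (spec.base_d + frac * (spec.end_d - spec.base_d)) / 2
            pid = emit(pos, r, pid)
        return pos, d, pid

    def grow(spec: _SegSpec, start: np.ndarray, direction: np.ndarray,
             parent_id: int, emit_base: bool) -> None:
        end, d, pid = grow_segment(spec, start, direction, parent_id, emit_base)
        if spec.children:
            theta = np.deg2rad(preset.branch_angle_deg) * (
                0.7 + 0.6 * rng.random(2))
            phi = rng.uniform(0, 2 * np.pi)
            dirs = [_deviate(d, theta[0], phi),
                    _deviate(d, theta[1], phi + np.pi)]
            for c, cd in zip(spec.children, dirs):
                grow(c, end, cd, pid, emit_base=False)

    for _ in range(n_prim):
        u = _random_unit(rng)
        k = int(rng.choice(breadth_keys, p=breadth_p))
        spec = _sample_topology(k, preset, rng)
        _assign_diameters(spec, preset, rng)
        grow(spec, u * preset.soma_radius, u, 1, emit_base=True)

    recon = Reconstruction(
        ids=np.array(ids), types=np.array(types), xyz=np.array(xyz),
        radius=np.array(radii), parent_ids=np.array(parents),
        provenance={"species": preset.name, "synthetic": True,
                    "standardized": True},
        validate=True)
    segs = partition_segments(recon)
    truth = GroundTruth(
        recon=recon,
        branch_morphometry=[branch_morphometry(b)
                            for b in branches(segs).values()])
    return recon, truth


# ---------------------------------------------------------------------------
# slicing


def slice_cut(recon: Reconstruction, slab_thickness: float = 300.0,
              soma_depth: float | None = 40.0, seed=None
              ) -> tuple[Reconstruction, list[int]]:
    """Truncate everything above the slice face at z = soma_depth.

    The soma sits ``soma_depth`` below the upper face of the slab; geometry
    crossing the face is cut at the plane by linear interpolation and the new
    terminal nodes are returned as the ground-truth cut set.  When
    ``soma_depth`` is None a depth is drawn uniformly from 30–50 μm (``seed``).
    """
    if soma_depth is None:
        soma_depth = float(np.random.default_rng(seed).uniform(30.0, 50.0))
    if not (slab_thickness > soma_depth > 0):
        raise ValueError("need slab_thickness > soma_depth > 0")
    plane = float(soma_depth)
    if recon.xyz[recon.root_index, 2] > plane:
        raise ValueError("the whole cell lies above the cut plane")

    children = recon.children
    z = recon.xyz[:, 2]
    keep_rows: list[int] = []
    cut_nodes: list[tuple[np.ndarray, float, int]] = []  # (pos, radius, parent row)
    stack = [recon.root_index]
    while stack:
        k = stack.pop()
        keep_rows.append(k)
        for c in children[k]:
            if z[c] <= plane:
                stack.append(c)
            else:
                t = (plane - z[k]) / (z[c] - z[k])
                if t <= 1e-9:
                    continue  # parent already on the plane: subtree removed
                pos = recon.xyz[k] + t * (recon.xyz[c] - recon.xyz[k])
                r = recon.radius[k] + t * (recon.radius[c] - recon.radius[k])
                cut_nodes.append((pos, float(r), k))
    if not any(recon.types[k] == DENDRITE for k in keep_rows):
        raise ValueError("no dendrite remains below the cut plane")

    keep_rows_arr = np.array(sorted(keep_rows))
    ids = recon.ids[keep_rows_arr]
    types = recon.types[keep_rows_arr]
    xyz = recon.xyz[keep_rows_arr]
    radii = recon.radius[keep_rows_arr]
    parents = recon.parent_ids[keep_rows_arr]
    nid = int(recon.ids.max()) + 1
    cut_ids = []
    extra = []
    for pos, r, prow in cut_nodes:
        extra.append((nid, DENDRITE, pos, r, int(recon.ids[prow])))
        cut_ids.append(nid)
        nid += 1
    if extra:
        ids = np.concatenate([ids, [e[0] for e in extra]])
        types = np.concatenate([types, [e[1] for e in extra]])
        xyz = np.vstack([xyz] + [e[2][None, :] for e in extra])
        radii = np.concatenate([radii, [e[3] for e in extra]])
        parents = np.concatenate([parents, [e[4] for e in extra]])
    prov = dict(recon.provenance)
    prov.update(sliced=True, cut_plane_z=plane)
    out = Reconstruction(ids, types, xyz, radii, parents,
                         provenance=prov, validate=True)
    return out, cut_ids


# ---------------------------------------------------------------------------
# spines


def sample_spines(recon: Reconstruction, preset: SpeciesPreset, seed=None,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place spines by an inhomogeneous Poisson process with rate S(x).

    Returns an inventory table with one row per spine: dendrite (primary
    branch) id, path distance, surface area, head area, neck length/diameter.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    segs = partition_segments(recon)
    pd_arr = recon.path_distances()
    model = preset.spine_model
    rows = []
    for seg in segs:
        path = seg.node_path
        x = pd_arr[path]
        for i in range(len(path) - 1):
            lo, hi = float(x[i]), float(x[i + 1])
            if hi <= lo:
                continue
            lam = float(spine_density((lo + hi) / 2, model)) * (hi - lo)
            n = rng.poisson(lam) if lam > 0 else 0
            for _ in range(n):
                area = _lognormal(rng, preset.spine_area_mean,
                                  preset.spine_area_cv)
                rows.append({
                    "dendrite_id": seg.branch_id,
                    "distance_um": rng.uniform(lo, hi),
                    "area_um2": area,
                    "head_area_um2": area * np.clip(
                        rng.normal(preset.head_area_fraction, 0.05), 0.3, 0.95),
                    "neck_length_um": _lognormal(
                        rng, preset.neck_length_mean, 0.4),
                    "neck_diameter_um": _lognormal(
                        rng, preset.neck_diameter_mean, 0.3),
                })
    cols = ["dendrite_id", "distance_um", "area_um2", "head_area_um2",
            "neck_length_um", "neck_diameter_um"]
    return pd.DataFrame(rows, columns=cols)


def sample_spine_areas(preset: SpeciesPreset, n: int, seed=None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n spine surface areas from the species' lognormal area model."""
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma2 = np.log(1.0 + preset.spine_area_cv ** 2)
    mu = np.log(preset.spine_area_mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def straight_dendrite(length: float, diameter: float, step: float = 2.0,
                      soma_radius: float = 6.0) -> Reconstruction:
    """A standardised single straight dendrite along +x (testing substrate)."""
    n = max(2, int(round(length / step)) + 1)
    s = np.linspace(0.0, length, n)
    ids = np.arange(1, n + 2)
    types = np.array([SOMA] + [DENDRITE] * n)
    xyz = np.zeros((n + 1, 3))
    xyz[1:, 0] = s + soma_radius
    radii = np.array([soma_radius] + [diameter / 2] * n)
    parents = np.array([-1] + list(ids[:-1]))
    return Reconstruction(ids, types, xyz, radii, parents,
                          provenance={"synthetic": True, "standardized": True})


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(preset: SpeciesPreset, n: int, seed,
                    out_dir: str | Path | None = None,
                    with_spines: bool = False
                    ) -> list[tuple[Reconstruction, GroundTruth]]:
    """n independent cells from one seeded stream; optionally written to disk.

    Each cell gets its own generator spawned from the master seed, so cohorts
    are bit-reproducible and cells are independent.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    master = np.random.SeedSequence(seed)
    cells = []
    manifest = {"species": preset.name, "n": n, "seed": int(seed),
                "cells": []}
    for i, child in enumerate(master.spawn(n)):
        rng = np.random.default_rng(child)
        recon, truth = sample_morphology(preset, rng=rng)
        if with_spines:
            truth.spines = sample_spines(recon, preset, rng=rng)
        cells.append((recon, truth))
        entry = {"cell": f"{preset.name}_{i:03d}",
                 "n_nodes": recon.n_nodes,
                 "total_length_um": round(recon.total_dendritic_length(), 3)}
        manifest["cells"].append(entry)
    if out_dir is not None:
        from .swc import write_swc

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (recon, truth), entry in zip(cells, manifest["cells"]):
            name = entry["cell"]
            write_swc(recon, out / f"{name}.swc")
            entry["swc"] = f"{name}.swc"
            if truth.spines is not None:
                truth.spines.to_csv(out / f"{name}_spines.csv", index=False)
                entry["spines"] = f"{name}_spines.csv"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cells


def cohort_digest(cells: list[tuple[Reconstruction, GroundTruth]]) -> str:
    """Stable hash of a cohort's node tables (reproducibility checks)."""
    h = hashlib.sha256()
    for recon, _ in cells:
        h.update(recon.ids.tobytes())
        h.update(np.round(recon.xyz, 9).tobytes())
        h.update(np.round(recon.radius, 9).tobytes())
        h.update(recon.parent_ids.tobytes())
    return h.hexdigest()
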