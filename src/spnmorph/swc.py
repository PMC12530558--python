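"""Reading, standardising, resampling and writing SWC reconstructions.

The processing chain mirrors the digital pre-processing used for slice-derived
striatal projection neuron (SPN) reconstructions: multi-point soma contours
are collapsed to a single sphere, the cell is centred at the origin, tissue
shrinkage is compensated along z only, and after repair the polylines are
resampled at a fixed 3 μm spatial resolution and upscaled by 1% to recover
the arc length lost by chord resampling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import AXON, DENDRITE, SOMA, Reconstruction, StructuralError, SwcNode


def read_swc(path_or_buffer, drop_axon: bool = False) -> Reconstruction:
    """Read a 7-column whitespace-delimited SWC file.

    Lines starting with ``#`` are comments.  The node table is validated
    (unique ids, single root, no cycles, positive radii).  Multi-point somata
    are kept as read; a ``multi_point_soma`` flag is recorded in the
    provenance and applied later by :func:`standardize`.
    """
    if isinstance(path_or_buffer, (str, Path)):
        text = Path(path_or_buffer).read_text()
        name = str(path_or_buffer)
    else:
        text = path_or_buffer.read()
        name = "<buffer>"
    nodes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise ValueError(
                f"{name}:{lineno}: expected 7 columns, got {len(cols)}")
        nid, tc = int(cols[0]), int(cols[1])
        x, y, z, r = (float(c) for c in cols[2:6])
        pid = int(cols[6])
        if pid == nid:
            raise StructuralError(f"node {nid} is its own parent")
        nodes.append(SwcNode(nid, tc, x, y, z, r, pid))
    if not nodes:
        raise ValueError(f"{name}: no nodes")
    recon = Reconstruction.from_nodes(
        nodes, provenance={"source": name}, validate=True)
    recon.provenance["multi_point_soma"] = int(recon.soma_mask.sum()) > 1
    if drop_axon and np.any(recon.types == AXON):
        recon = recon.drop_axon()
        recon.provenance["axon_dropped"] = True
    return recon


def write_swc(recon: Reconstruction, path) -> None:
    """Write standard 7-column SWC with ids renumbered 1..N depth-first."""
    Path(path).write_text(to_swc_string(recon))


def to_swc_string(recon: Reconstruction) -> str:
    order = _depth_first_rows(recon)
    new_id = {k: i + 1 for i, k in enumerate(order)}
    lines = ["# SWC written by spnmorph"]
    for key, val in sorted(recon.provenance.items()):
        lines.append(f"# {key}: {val}")
    pidx = recon.parent_index
    for k in order:
        p = pidx[k]
        pid = -1 if p < 0 else new_id[p]
        x, y, z = recon.xyz[k]
        lines.append(
            f"{new_id[k]} {int(recon.types[k])} {x:.6f} {y:.6f} {z:.6f} "
            f"{recon.radius[k]:.6f} {pid}")
    return "\n".join(lines) + "\n"


def _depth_first_rows(recon: Reconstruction) -> list[int]:
    out: list[int] = []
    stack = [recon.root_index]
    children = recon.children
    while stack:
        k = stack.pop()
        out.append(k)
        stack.extend(reversed(children[k]))
    return out


def correct_z_jumps(recon: Reconstruction) -> Reconstruction:
    """Pass-through hook for z-jump correction (no algorithm is prescribed)."""
    return recon


def standardize(recon: Reconstruction, shrink_z: float = 1.0,
                drop_axon: bool = True) -> Reconstruction:
    """Collapse the soma to a sphere, centre the cell, correct z shrinkage.

    The soma sphere takes the mean of the soma points as its centre and the
    mean point-to-centre distance as its radius (a single-point soma keeps
    its own radius).  All coordinates are translated so the soma centre is at
    the origin, then z is multiplied by ``shrink_z``; x and y are untouched.
    """
    if shrink_z <= 0:
        raise ValueError("shrink_z must be positive")
    if drop_axon and np.any(recon.types == AXON):
        recon = recon.drop_axon()
    soma = recon.soma_mask
    center = recon.xyz[soma].mean(axis=0)
    if soma.sum() > 1:
        radius = float(np.linalg.norm(recon.xyz[soma] - center, axis=1).mean())
    else:
        radius = float(recon.radius[soma][0])

    keep = ~soma
    soma_id = int(recon.ids.max()) + 1
    # reparent children of any soma node to the new sphere node
    soma_ids = set(int(i) for i in recon.ids[soma])
    new_parent = np.array(
        [soma_id if int(p) in soma_ids else int(p)
         for p in recon.parent_ids[keep]], dtype=np.int64)
    xyz = np.vstack([[center], recon.xyz[keep]]) - center
    xyz[:, 2] *= shrink_z
    ids = np.concatenate([[soma_id], recon.ids[keep]])
    types = np.concatenate([[SOMA], recon.types[keep]])
    radii = np.concatenate([[radius], recon.radius[keep]])
    parents = np.concatenate([[-1], new_parent])
    prov = dict(recon.provenance)
    prov.update(standardized=True, shrink_z=shrink_z)
    out = Reconstruction(ids, types, xyz, radii, parents,
                         provenance=prov, validate=True)
    return out


def resample(recon: Reconstruction, step: float = 3.0,
             upscale: float = 1.01) -> Reconstruction:
    """Resample every dendritic section at a fixed arc-length resolution.

    Branch points and terminals are preserved exactly; interior points are
    regenerated at an even spacing as close to ``step`` as divides the section
    length.  Afterwards all coordinates are scaled about the soma by
    ``upscale`` (length recovery); radii are interpolated along arc length and
    are *not* upscaled.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if upscale <= 0:
        raise ValueError("upscale must be positive")
    if not recon.is_standardized:
        raise ValueError("resample expects a standardised reconstruction")

    root = recon.root_index
    children = recon.children
    xyz, radius, types = recon.xyz, recon.radius, recon.types

    new_nodes: list[tuple[int, float, float, float, float, int]] = []
    # (type, x, y, z, r, parent_slot); slots are indices into new_nodes
    new_nodes.append((SOMA, *xyz[root], radius[root], -1))

    def structural(k: int) -> bool:
        return len(children[k]) != 1

    def add_path(path: list[int], parent_slot: int) -> int:
        """Resample a polyline (first point already emitted) and return the
        slot of its final node."""
        pts = xyz[path]
        rr = radius[path]
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        total = float(arc[-1])
        if total == 0.0:
            n = 1
        else:
            n = max(1, int(round(total / step)))
        s_new = np.linspace(0.0, total, n + 1)[1:]
        slot = parent_slot
        for i, s in enumerate(s_new):
            if i == len(s_new) - 1:
                p = pts[-1]
                r = rr[-1]
            else:
                p = np.array([np.interp(s, arc, pts[:, 0]),
                              np.interp(s, arc, pts[:, 1]),
                              np.interp(s, arc, pts[:, 2])])
                r = float(np.interp(s, arc, rr))
            new_nodes.append((int(types[path[-1]]), p[0], p[1], p[2], r, slot))
            slot = len(new_nodes) - 1
        return slot

    # walk sections: from soma to each structural point
    stack: list[tuple[int, int]] = []  # (first node of section, parent slot)
    for c in children[root]:
        # emit the section's base node exactly (soma-attached point)
        new_nodes.append((int(types[c]), *xyz[c], radius[c], 0))
        base_slot = len(new_nodes) - 1
        if structural(c):
            for g in children[c]:
                stack.append((g, base_slot))
        else:
            path = [c]
            k = c
            while not structural(k):
                k = children[k][0]
                path.append(k)
            end_slot = add_path(path, base_slot)
            for g in children[k]:
                stack.append((g, end_slot))
    while stack:
        first, parent_slot = stack.pop()
        path = [first]
        k = first
        while not structural(k):
            k = children[k][0]
            path.append(k)
        # prepend geometric base: the parent structural node
        base_row = recon.parent_index[first]
        path = [base_row] + path
        end_slot = add_path(path, parent_slot)
        for g in children[k]:
            stack.append((g, end_slot))

    arr = np.array([n[1:5] for n in new_nodes], dtype=float)
    coords = arr[:, :3] * upscale
    coords[0] = 0.0  # soma stays at the origin
    prov = dict(recon.provenance)
    prov.update(resample_step_um=step, resample_upscale=upscale)
    out = Reconstruction(
        ids=np.arange(1, len(new_nodes) + 1, dtype=np.int64),
        types=np.array([n[0] for n in new_nodes], dtype=np.int64),
        xyz=coords,
        radius=arr[:, 3],
        parent_ids=np.array(
            [-1 if n[5] < 0 else n[5] + 1 for n in new_nodes], dtype=np.int64),
        provenance=prov,
        validate=True,
    )
    return out
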