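"""TFCE kernels: a fast union-find implementation and an ndimage reference.

Both compute, per voxel v with statistic value s(v) >= 0,

    TFCE(v) = sum over h in {dh, 2dh, ...  <= s(v)} of e_v(h)^E * h^H * dh

where e_v(h) is the voxel count of the connected component containing v in
the supra-threshold set {s >= h}.  The union-find kernel adds voxels in
decreasing value order while lowering the threshold, so each component
merge is performed once; the ndimage version labels the supra-threshold
set independently at every step and serves as the independent cross-check.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage


def connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def neighbor_table(mask: np.ndarray, connectivity: int = 26):
    """Adjacency of in-mask voxels: (n_vox, max_nbr) index table + counts.

    Row i lists the flat in-mask indices of voxel i's neighbors.  Built once
    per mask and reused across every permutation.
    """
    mask = np.asarray(mask, dtype=bool)
    struct = connectivity_structure(connectivity)
    offsets = np.argwhere(struct) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]
    coords = np.argwhere(mask)
    n = coords.shape[0]
    vox_id = np.full(mask.shape, -1, dtype=np.int64)
    vox_id[mask] = np.arange(n)
    nbr = np.full((n, offsets.shape[0]), -1, dtype=np.int64)
    nnbr = np.zeros(n, dtype=np.int64)
    shape = np.asarray(mask.shape)
    for off in offsets:
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < shape), axis=1)
        ids = vox_id[tuple(shifted[ok].T)]
        src = np.flatnonzero(ok)[ids >= 0]
        ids = ids[ids >= 0]
        nbr[src, nnbr[src]] = ids
        nnbr[src] += 1
    return nbr, nnbr


@njit(cache=True)
def _find_with_offset(parent, off, v):
    """Root of v and the summed potential offset along the path; compresses."""
    r = v
    total = 0.0
    while parent[r] != r:
        total += off[r]
        r = parent[r]
    # path compression, keeping each node's offset-to-root correct
    w = v
    acc = total
    while parent[w] != r:
        nxt = parent[w]
        step = off[w]
        parent[w] = r
        off[w] = acc
        acc -= step
        w = nxt
    return r, total


@njit(cache=True)
def _tfce_union_find(vals, order, nbr, nnbr, dh, n_steps, E, H):
    # Voxels enter in decreasing value order as the threshold h sweeps down.
    # Each live component root r carries its size S[r] and a per-member
    # accumulator A[r]; a node's TFCE value is A[root] + (potential offsets
    # along its path), so late joiners are not credited with contributions
    # that predate their entry.  Per threshold step only the live roots are
    # touched, not every active voxel.
    n = vals.shape[0]
    parent = np.full(n, -1, np.int64)
    off = np.zeros(n)
    A = np.zeros(n)
    size = np.zeros(n, np.int64)
    roots = np.empty(n, np.int64)
    n_roots = 0
    ptr = 0
    for s in range(n_steps, 0, -1):
        h = dh * s
        while ptr < n and vals[order[ptr]] >= h:
            v = order[ptr]
            parent[v] = v
            size[v] = 1
            A[v] = 0.0
            off[v] = 0.0
            roots[n_roots] = v
            n_roots += 1
            for j in range(nnbr[v]):
                u = nbr[v, j]
                if parent[u] >= 0:
                    ru, _ = _find_with_offset(parent, off, u)
                    rv, _ = _find_with_offset(parent, off, v)
                    if ru != rv:
                        if size[ru] < size[rv]:
                            ru, rv = rv, ru
                        parent[rv] = ru
                        off[rv] = A[rv] - A[ru]
                        size[ru] += size[rv]
            ptr += 1
        # accumulate this threshold's contribution per live component
        hterm = h ** H * dh
        k = 0
        for i in range(n_roots):  # compact dead roots in place
            r = roots[i]
            if parent[r] == r:
                A[r] += size[r] ** E * hterm
                roots[k] = r
                k += 1
        n_roots = k
    out = np.zeros(n)
    for i in range(ptr):
        v = order[i]
        r, total = _find_with_offset(parent, off, v)
        out[v] = A[r] + total
    return out


def tfce_flat(vals: np.ndarray, nbr: np.ndarray, nnbr: np.ndarray,
              E: float, H: float, dh: float | None) -> np.ndarray:
    """TFCE of non-negative values on the in-mask voxel graph."""
    vals = np.ascontiguousarray(vals, dtype=np.float64)
    vmax = float(vals.max(initial=0.0))
    if vmax <= 0.0:
        return np.zeros_like(vals)
    if dh is None:
        dh = vmax / 100.0
    n_steps = int(np.floor(vmax / dh + 1e-12))
    if n_steps < 1:
        return np.zeros_like(vals)
    order = np.argsort(-vals, kind="stable")
    return _tfce_union_find(vals, order, nbr, nnbr, dh, n_steps, E, H)


def tfce_ndimage(stat_map: np.ndarray, E: float, H: float, dh: float | None,
                 connectivity: int = 26) -> np.ndarray:
    """Reference implementation via per-threshold connected-component labeling."""
    stat_map = np.asarray(stat_map, dtype=float)
    vmax = float(stat_map.max(initial=0.0))
    out = np.zeros_like(stat_map)
    if vmax <= 0.0:
        return out
    if dh is None:
        dh = vmax / 100.0
    struct = connectivity_structure(connectivity)
    n_steps = int(np.floor(vmax / dh + 1e-12))
    for s in range(1, n_steps + 1):
        h = dh * s
        labels, _ = ndimage.label(stat_map >= h, structure=struct)
        counts = np.bincount(labels.ravel())
        extent = counts[labels]
        out += np.where(labels > 0, extent.astype(float) ** E * h ** H * dh, 0.0)
    return out
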