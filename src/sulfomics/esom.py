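"""Emergent self-organizing map for compositional genome binning.

A large toroidal SOM is trained online on tetranucleotide window profiles:
each sample pulls its best-matching unit (BMU) and, with a Gaussian
neighborhood of exponentially shrinking radius and learning rate, the
surrounding nodes.  After training, the U-matrix (each node's mean
distance to its topological neighbors) shows genomes as basins separated
by high ridges.  Where the original workflow segmented that landscape by
hand, here the segmentation is a deterministic rule: discard nodes whose
U-value exceeds a threshold quantile, take toroidal connected components
of the remainder, let windows inherit their BMU's component, and assign a
contig to the majority bin of its windows (ties unassigned).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SomGrid", "BinAssignment", "grid_shape", "train", "bmu", "bmus", "umatrix", "extract_bins"]

_GOLDEN = (1 + 5**0.5) / 2


@dataclass
class SomGrid:
    """A trained toroidal SOM: node weights plus the training configuration."""

    rows: int
    cols: int
    weights: np.ndarray  # (rows, cols, dim)
    toroidal: bool = True
    epochs: int = 20
    radius_start: float = 0.0
    radius_end: float = 1.0
    rate_start: float = 0.5
    rate_end: float = 0.05
    seed: int = 0
    qe_history: list[float] = field(default_factory=list)  # per-epoch mean quantization error

    @property
    def dim(self) -> int:
        return self.weights.shape[2]


@dataclass
class BinAssignment:
    """Window- and contig-level bin membership; None marks unassigned."""

    window_bins: dict[str, int | None]
    contig_bins: dict[str, int | None]
    bins: dict[int, set[str]]  # bin_id -> contig ids


def grid_shape(n_samples: int, nodes_per_sample: float = 2.0, min_rows: int = 10, min_cols: int = 16) -> tuple[int, int]:
    """Emergent-map sizing: ~2 nodes per sample in a golden-ratio rectangle,
    never smaller than ``min_rows`` x ``min_cols``.

    Emergence needs more nodes than samples: clusters then settle as
    islands separated by wide interpolation zones whose U-values form the
    ridges the segmentation thresholds on.  Maps sized well below the
    sample count leave no room for ridges and the threshold rule degrades.
    """
    nodes = nodes_per_sample * max(n_samples, 1)
    cols = int(round(math.sqrt(nodes * _GOLDEN)))
    rows = int(round(nodes / max(cols, 1)))
    return max(rows, min_rows), max(cols, min_cols)


def _torus_sq_distances(rows: int, cols: int, toroidal: bool) -> tuple[np.ndarray, np.ndarray]:
    """Squared axial grid distances, (rows,rows) and (cols,cols)."""
    ri = np.arange(rows)
    ci = np.arange(cols)
    dr = np.abs(ri[:, None] - ri[None, :])
    dc = np.abs(ci[:, None] - ci[None, :])
    if toroidal:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    return (dr**2).astype(float), (dc**2).astype(float)


def _pca_init(matrix: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Deterministic initialization on the plane of the two leading PCs.

    Gives the map a coherent starting topology (faster, more reproducible
    organization than random init).  Component signs are fixed by making
    each PC's largest-magnitude loading positive.
    """
    mu = matrix.mean(axis=0)
    x = matrix - mu
    # economy SVD; right singular vectors are the principal axes
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    dim = matrix.shape[1]
    pcs = np.zeros((2, dim))
    scales = np.zeros(2)
    for i in range(min(2, vt.shape[0])):
        v = vt[i]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        pcs[i] = v
        scales[i] = s[i] / math.sqrt(max(len(matrix) - 1, 1))
    gr = np.linspace(-2, 2, rows)[:, None, None]
    gc = np.linspace(-2, 2, cols)[None, :, None]
    return mu + gr * (scales[0] * pcs[0]) + gc * (scales[1] * pcs[1])


def _quantization_error(weights: np.ndarray, matrix: np.ndarray) -> float:
    flat = weights.reshape(-1, weights.shape[2])
    # ||x - w||^2 = ||x||^2 - 2 x.w + ||w||^2
    d2 = (
        (matrix**2).sum(axis=1)[:, None]
        - 2 * matrix @ flat.T
        + (flat**2).sum(axis=1)[None, :]
    )
    return float(np.sqrt(np.maximum(d2.min(axis=1), 0.0)).mean())


def train(
    matrix: np.ndarray,
    rows: int | None = None,
    cols: int | None = None,
    *,
    epochs: int = 20,
    radius_start: float | None = None,
    radius_end: float = 1.0,
    rate_start: float = 0.5,
    rate_end: float = 0.05,
    toroidal: bool = True,
    seed: int = 0,
    presentation_orders=None,
) -> SomGrid:
    """Train an emergent SOM by the classical online rule.

    Radius and learning rate decay exponentially from their start to end
    values over all steps; sample presentation order is a fresh seeded
    shuffle every epoch (overridable via ``presentation_orders``, a list of
    index arrays, one per epoch — used to verify order invariance).  The
    mean quantization error at initialization and after each epoch is kept
    in ``qe_history``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("training matrix must be non-empty and 2-D")
    if not np.isfinite(matrix).all():
        raise ValueError("training matrix contains non-finite values")
    n, dim = matrix.shape
    if n == 1:
        warnings.warn("training on a single sample: map will be degenerate", stacklevel=2)
    if rows is None or cols is None:
        rows, cols = grid_shape(n)
    if radius_start is None:
        radius_start = min(rows, cols) / 2.0
    if not (radius_start >= radius_end > 0):
        raise ValueError("need radius_start >= radius_end > 0")
    if not (rate_start >= rate_end > 0):
        raise ValueError("need rate_start >= rate_end > 0")

    rng = np.random.default_rng(seed)
    weights = _pca_init(matrix, rows, cols).astype(float)
    dr2, dc2 = _torus_sq_distances(rows, cols, toroidal)
    qe_history = [_quantization_error(weights, matrix)]

    total_steps = epochs * n
    step = 0
    for epoch in range(epochs):
        if presentation_orders is not None:
            order = np.asarray(presentation_orders[epoch])
        else:
            order = rng.permutation(n)
        for idx in order:
            frac = step / max(total_steps - 1, 1)
            sigma = radius_start * (radius_end / radius_start) ** frac
            rate = rate_start * (rate_end / rate_start) ** frac
            x = matrix[idx]
            diff = x[None, None, :] - weights
            d2 = np.einsum("rcd,rcd->rc", diff, diff)
            bi = int(np.argmin(d2))  # first minimum = lexicographic (row, col)
            br, bc = divmod(bi, cols)
            h = rate * np.exp(-(dr2[br][:, None] + dc2[bc][None, :]) / (2.0 * sigma**2))
            weights += h[:, :, None] * diff
            step += 1
        qe_history.append(_quantization_error(weights, matrix))

    return SomGrid(
        rows=rows,
        cols=cols,
        weights=weights,
        toroidal=toroidal,
        epochs=epochs,
        radius_start=radius_start,
        radius_end=radius_end,
        rate_start=rate_start,
        rate_end=rate_end,
        seed=seed,
        qe_history=qe_history,
    )


def bmu(grid: SomGrid, vector: np.ndarray) -> tuple[int, int]:
    """Best-matching unit; ties go to the lexicographically smallest (row, col)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (grid.dim,):
        raise ValueError(f"vector dimension {vector.shape} does not match grid dim {grid.dim}")
    diff = grid.weights - vector[None, None, :]
    d2 = np.einsum("rcd,rcd->rc", diff, diff)
    bi = int(np.argmin(d2))
    return divmod(bi, grid.cols)


def bmus(grid: SomGrid, matrix: np.ndarray) -> np.ndarray:
    """BMU (row, col) for every row of ``matrix``; shape (n, 2)."""
    matrix = np.asarray(matrix, dtype=float)
    flat = grid.weights.reshape(-1, grid.dim)
    d2 = (
        (matrix**2).sum(axis=1)[:, None]
        - 2 * matrix @ flat.T
        + (flat**2).sum(axis=1)[None, :]
    )
    bi = np.argmin(d2, axis=1)
    return np.stack(divmod(bi, grid.cols), axis=1)


_NEIGH4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGH8 = _NEIGH4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def umatrix(grid: SomGrid, connectivity: int = 8) -> np.ndarray:
    """Per-node mean Euclidean distance to its topological neighbors."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    offsets = _NEIGH8 if connectivity == 8 else _NEIGH4
    w = grid.weights
    acc = np.zeros((grid.rows, grid.cols))
    count = 0
    for dr, dc in offsets:
        shifted = np.roll(np.roll(w, -dr, axis=0), -dc, axis=1)
        d = np.sqrt(((w - shifted) ** 2).sum(axis=2))
        if not grid.toroidal:
            # rolled-over rows/cols are not real neighbors on a plane
            mask = np.ones((grid.rows, grid.cols), bool)
            if dr == -1:
                mask[-1, :] = False
            elif dr == 1:
                mask[0, :] = False
            if dc == -1:
                mask[:, -1] = False
            elif dc == 1:
                mask[:, 0] = False
            d = np.where(mask, d, np.nan)
            acc += np.nan_to_num(d)
            count = None  # handled below
        else:
            acc += d
    if grid.toroidal:
        return acc / len(offsets)
    # planar: average over actual neighbor counts
    cnt = np.zeros((grid.rows, grid.cols))
    for dr, dc in offsets:
        mask = np.ones((grid.rows, grid.cols), bool)
        if dr == -1:
            mask[-1, :] = False
        elif dr == 1:
            mask[0, :] = False
        if dc == -1:
            mask[:, -1] = False
        elif dc == 1:
            mask[:, 0] = False
        cnt += mask
    return acc / cnt


def _connected_components(keep: np.ndarray, toroidal: bool, connectivity: int) -> np.ndarray:
    """Label connected components of a boolean grid (toroidal aware).

    Returns an int array, -1 outside ``keep``; labels are ordered by first
    raster-scan appearance.  A small union-find: scipy's labeller has no
    toroidal topology.
    """
    rows, cols = keep.shape
    parent = list(range(rows * cols))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    offsets = _NEIGH8 if connectivity == 8 else _NEIGH4
    for r in range(rows):
        for c in range(cols):
            if not keep[r, c]:
                continue
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if toroidal:
                    rr %= rows
                    cc %= cols
                elif not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                if keep[rr, cc]:
                    union(r * cols + c, rr * cols + cc)

    labels = np.full((rows, cols), -1, dtype=int)
    remap: dict[int, int] = {}
    for r in range(rows):
        for c in range(cols):
            if keep[r, c]:
                root = find(r * cols + c)
                if root not in remap:
                    remap[root] = len(remap)
                labels[r, c] = remap[root]
    return labels


def extract_bins(
    grid: SomGrid,
    bmu_table: np.ndarray,
    window_contigs,
    threshold_quantile: float = 0.6,
    connectivity: int = 8,
    window_ids=None,
) -> BinAssignment:
    """Segment the U-matrix into bins and assign windows and contigs.

    Nodes whose U-value exceeds the ``threshold_quantile`` of all node
    U-values are treated as ridge (removed); the remaining nodes split into
    toroidal connected components, each a bin.  A window inherits its BMU's
    component (None if the BMU was a ridge node); a contig takes the
    majority bin of its assigned windows, with ties left unassigned.
    """
    u = umatrix(grid, connectivity=connectivity)
    thr = np.quantile(u, threshold_quantile)
    keep = u <= thr
    labels = _connected_components(keep, grid.toroidal, connectivity)

    window_contigs = list(window_contigs)
    if window_ids is None:
        window_ids = [f"w{i:06d}" for i in range(len(window_contigs))]
    if not (len(bmu_table) == len(window_contigs) == len(window_ids)):
        raise ValueError("bmu_table, window_contigs and window_ids lengths differ")

    window_bins: dict[str, int | None] = {}
    per_contig: dict[str, dict[int, int]] = {}
    for (r, c), cid, wid in zip(bmu_table, window_contigs, window_ids):
        lab = int(labels[int(r), int(c)])
        b = lab if lab >= 0 else None
        window_bins[wid] = b
        if b is not None:
            per_contig.setdefault(cid, {})
            per_contig[cid][b] = per_contig[cid].get(b, 0) + 1
        else:
            per_contig.setdefault(cid, {})

    if not any(per_contig.values()) and len(window_contigs) > 0:
        warnings.warn("U-matrix threshold removed every data-bearing node; no bins", stacklevel=2)

    contig_bins: dict[str, int | None] = {}
    bins: dict[int, set[str]] = {}
    for cid, votes in per_contig.items():
        if not votes:
            contig_bins[cid] = None
            continue
        top = max(votes.values())
        winners = [b for b, v in votes.items() if v == top]
        if len(winners) != 1:
            contig_bins[cid] = None
            continue
        contig_bins[cid] = winners[0]
        bins.setdefault(winners[0], set()).add(cid)
    return BinAssignment(window_bins=window_bins, contig_bins=contig_bins, bins=bins)
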