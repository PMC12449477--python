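"""Grid construction, tumour-surface extraction, signed distance fields,
band stratification, and centroid-linkage clustering of band profiles.

The geometric pipeline: cell centroids are pooled onto a regular µm grid
(default 10 µm); a tumour mask is called per grid cell from the marker rule
(all positive markers present, negative marker absent); the mask is cleaned
with a 3×3 median filter followed by a 3×3 mean blur re-binarized at 0.5;
the outer boundary of the first (or largest) connected component is traced;
and a multi-source shortest-path distance over the 8-connected grid graph
(orthogonal steps weigh s, diagonal s·√2) gives every grid cell its signed
distance to the tumour surface — negative inside the tumour, zero on the
contour, positive outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.sparse.csgraph import dijkstra

from .model import CellTable, ConfigError, MarkerConfig, PanelGenes

SQRT2 = float(np.sqrt(2.0))


@dataclass
class GridField:
    """Regular lattice with per-grid-cell pooled gene counts.

    Arrays are indexed ``[iy, ix]``; the flat index is ``iy * nx + ix``.
    Grid cell (ix, iy) covers the half-open square
    ``[x0 + ix·s, x0 + (ix+1)·s) × [y0 + iy·s, y0 + (iy+1)·s)``.
    """

    origin: tuple[float, float]
    spacing: float
    nx: int
    ny: int
    counts: sp.csr_matrix          # (ny*nx) × n_genes
    genes: PanelGenes
    cell_flat_index: np.ndarray    # per input cell, its flat grid index

    @property
    def n_grid(self) -> int:
        return self.nx * self.ny

    def gene_image(self, gene: str) -> np.ndarray:
        j = self.genes.index_of(gene)
        return np.asarray(self.counts[:, j].todense()).ravel().reshape(self.ny, self.nx)

    def centres(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.spacing
        ys = y0 + (np.arange(self.ny) + 0.5) * self.spacing
        return xs, ys


def build_grid(table: CellTable, s: float = 10.0) -> GridField:
    """Pool cell counts onto an s-µm grid covering the centroid bounding box."""
    if s <= 0:
        raise ValueError("grid spacing must be positive")
    if table.n_cells == 0:
        raise ValueError("cannot grid an empty cell table")
    x0, y0 = float(table.x.min()), float(table.y.min())
    nx = int(np.floor((table.x.max() - x0) / s)) + 1
    ny = int(np.floor((table.y.max() - y0) / s)) + 1
    ix = np.floor((table.x - x0) / s).astype(np.int64)
    iy = np.floor((table.y - y0) / s).astype(np.int64)
    # a centroid exactly on the outer edge belongs to the last bin
    ix = np.minimum(ix, nx - 1)
    iy = np.minimum(iy, ny - 1)
    flat = iy * nx + ix
    pool = sp.csr_matrix(
        (np.ones(table.n_cells), (flat, np.arange(table.n_cells))),
        shape=(nx * ny, table.n_cells),
    )
    return GridField(
        origin=(x0, y0), spacing=float(s), nx=nx, ny=ny,
        counts=sp.csr_matrix(pool @ table.counts),
        genes=table.genes, cell_flat_index=flat,
    )


def tumour_mask(
    grid: GridField, rule: MarkerConfig, min_count: int = 1
) -> np.ndarray:
    """Marker-rule tumour mask: every positive marker pooled count >=
    ``min_count`` and every negative marker pooled count == 0.

    The per-cell positivity threshold (count >= 2) does not transfer to
    grids, which pool several cells; >= 1 is the minimal literal reading
    and ``min_count`` exposes the choice.
    """
    for g in rule.tumour_positive + rule.tumour_negative:
        if g not in grid.genes:
            raise ConfigError(f"tumour rule gene {g!r} not in panel")
    mask = np.ones((grid.ny, grid.nx), dtype=bool)
    for g in rule.tumour_positive:
        mask &= grid.gene_image(g) >= min_count
    for g in rule.tumour_negative:
        mask &= grid.gene_image(g) == 0
    return mask


def smooth_mask(mask: np.ndarray) -> np.ndarray:
    """3×3 median filter, then 3×3 mean blur re-binarized at >= 0.5.

    Borders are padded by replication (``mode='nearest'``).
    """
    med = scipy.ndimage.median_filter(mask.astype(np.uint8), size=3, mode="nearest")
    blur = scipy.ndimage.uniform_filter(med.astype(float), size=3, mode="nearest")
    return blur >= 0.5


@dataclass
class SurfaceContour:
    """Ordered outer boundary walk of one tumour component.

    ``walk`` is the closed Moore-trace order (may revisit cells on spurs);
    ``cells`` is the deduplicated (iy, ix) source set.
    """

    walk: list[tuple[int, int]]
    cells: np.ndarray = field(init=False)  # (k, 2) unique (iy, ix)

    def __post_init__(self) -> None:
        seen = dict.fromkeys(self.walk)
        self.cells = np.array(list(seen), dtype=np.int64).reshape(-1, 2)


_CLOCKWISE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _moore_trace(comp: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbour boundary tracing with Jacob's stopping criterion.

    ``start`` must be the first foreground pixel of the component in raster
    order, so the pixel to its west is background (or off-grid).
    """
    ny, nx = comp.shape

    def fg(p: tuple[int, int]) -> bool:
        y, x = p
        return 0 <= y < ny and 0 <= x < nx and bool(comp[y, x])

    backtrack = (start[0], start[1] - 1)
    walk = [start]
    p, b = start, backtrack
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    while True:
        # clockwise scan of p's Moore neighbourhood starting just after b
        rel = (b[0] - p[0], b[1] - p[1])
        k0 = _CLOCKWISE.index(rel)
        nxt = None
        for step in range(1, 9):
            dy, dx = _CLOCKWISE[(k0 + step) % 8]
            cand = (p[0] + dy, p[1] + dx)
            if fg(cand):
                nxt = cand
                prev_dy, prev_dx = _CLOCKWISE[(k0 + step - 1) % 8]
                b = (p[0] + prev_dy, p[1] + prev_dx)
                break
        if nxt is None:            # isolated single pixel
            break
        move = (p, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break                   # stopped: same pixel entered the same way
        p = nxt
        walk.append(p)
        if len(walk) > 8 * comp.sum() + 8:   # defensive; cannot trigger on valid masks
            break
    if walk[-1] == start and len(walk) > 1:
        walk = walk[:-1]
    return walk


def extract_contour(mask: np.ndarray, which: str = "first") -> SurfaceContour:
    """Outer boundary of one 8-connected component of the mask.

    ``which='first'`` keeps the component whose first pixel appears
    earliest in raster order (the first outer contour of a border-following
    hierarchy); ``which='largest'`` keeps the maximal-area component, which
    is invariant to the grid origin.
    """
    if not mask.any():
        raise ValueError("cannot extract a contour from an empty mask")
    labels, n_comp = scipy.ndimage.label(mask, structure=np.ones((3, 3)))
    if which == "first":
        first_flat = int(np.flatnonzero(labels.ravel())[0])
        target = int(labels.ravel()[first_flat])
    elif which == "largest":
        sizes = np.bincount(labels.ravel())[1:]
        target = int(np.argmax(sizes)) + 1
    else:
        raise ValueError("which must be 'first' or 'largest'")
    comp = labels == target
    start_flat = int(np.flatnonzero(comp.ravel())[0])
    start = (start_flat // mask.shape[1], start_flat % mask.shape[1])
    return SurfaceContour(walk=_moore_trace(comp, start))


@dataclass
class DistanceField:
    """Signed shortest-path distance (µm) from the tumour surface."""

    signed: np.ndarray             # (ny, nx); ±inf-free except unreachable
    spacing: float
    origin: tuple[float, float]
    unreachable: np.ndarray        # bool (ny, nx)

    def flat(self) -> np.ndarray:
        return self.signed.ravel()


def _grid_graph(ny: int, nx: int, s: float, connectivity: int) -> sp.csr_matrix:
    """Sparse undirected grid graph; orthogonal edges weigh s, diagonal s·√2."""
    idx = np.arange(ny * nx).reshape(ny, nx)
    rows, cols, w = [], [], []

    def add(a: np.ndarray, b: np.ndarray, weight: float) -> None:
        rows.append(a.ravel())
        cols.append(b.ravel())
        w.append(np.full(a.size, weight))

    add(idx[:, :-1], idx[:, 1:], s)            # east
    add(idx[:-1, :], idx[1:, :], s)            # south
    if connectivity == 8:
        add(idx[:-1, :-1], idx[1:, 1:], s * SQRT2)   # south-east
        add(idx[:-1, 1:], idx[1:, :-1], s * SQRT2)   # south-west
    elif connectivity != 4:
        raise ValueError("connectivity must be 4 or 8")
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    ww = np.concatenate(w)
    return sp.csr_matrix((ww, (r, c)), shape=(ny * nx, ny * nx))


def distance_field(
    mask: np.ndarray,
    contour: SurfaceContour,
    spacing: float = 10.0,
    connectivity: int = 8,
    origin: tuple[float, float] = (0.0, 0.0),
) -> DistanceField:
    """Multi-source shortest paths from the contour cells over the grid graph.

    The magnitude is the graph-shortest-path length to the nearest contour
    cell; the sign is negative iff the grid cell is mask-true and not on
    the contour.  Cells disconnected from every source are flagged
    unreachable (cannot occur on a full rectangular grid, but the flag is
    kept for masked/partial graphs).
    """
    if len(contour.cells) == 0:
        raise ValueError("contour has no cells")
    ny, nx = mask.shape
    graph = _grid_graph(ny, nx, spacing, connectivity)
    sources = contour.cells[:, 0] * nx + contour.cells[:, 1]
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    dist = np.asarray(dist, float).reshape(ny, nx)
    unreachable = np.isinf(dist)
    on_contour = np.zeros((ny, nx), dtype=bool)
    on_contour[contour.cells[:, 0], contour.cells[:, 1]] = True
    sign = np.where(mask & ~on_contour, -1.0, 1.0)
    return DistanceField(
        signed=sign * dist, spacing=spacing, origin=origin, unreachable=unreachable
    )


@dataclass(frozen=True)
class Band:
    name: str
    lo: float      # inclusive, µm
    hi: float      # exclusive


@dataclass
class BandPartition:
    """Disjoint half-open signed-distance intervals [lo, hi)."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo < a.hi:
                raise ConfigError(f"bands {a.name!r} and {b.name!r} overlap")
        for b in self.bands:
            if not b.lo < b.hi:
                raise ConfigError(f"band {b.name!r} has empty interval")

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Band name per distance; 'beyond' when in no band, 'unassigned'
        when the distance is not finite."""
        d = np.asarray(distances, float)
        out = np.full(d.shape, "beyond", dtype=object)
        for b in self.bands:
            out[(d >= b.lo) & (d < b.hi)] = b.name
        out[~np.isfinite(d)] = "unassigned"
        return out

    @classmethod
    def outside_default(cls) -> "BandPartition":
        """peri [0,20), mid [20,70), distal [70,120) µm outside the surface."""
        return cls(
            (Band("peri", 0.0, 20.0), Band("mid", 20.0, 70.0),
             Band("distal", 70.0, 120.0))
        )

    @classmethod
    def uniform(cls, lo: float = -60.0, hi: float = 150.0, width: float = 30.0
                ) -> "BandPartition":
        edges = np.arange(lo, hi + width / 2, width)
        return cls(
            tuple(
                Band(f"[{int(a)},{int(b)})", float(a), float(b))
                for a, b in zip(edges[:-1], edges[1:])
            )
        )


@dataclass
class BandProfile:
    """Band-level gene densities and (optional) cell-class proportions."""

    densities: pd.DataFrame        # columns: band, gene, density
    band_areas: dict[str, float]   # µm² of grid area per band
    proportions: pd.DataFrame | None = None


def assign_bands(
    table: CellTable,
    grid: GridField,
    dfield: DistanceField,
    bands: BandPartition,
    cell_classes: np.ndarray | None = None,
) -> tuple[np.ndarray, BandProfile]:
    """Band label per cell plus the band-level profile.

    A cell inherits the band of the grid cell containing its centroid.
    Band gene densities pool the grid counts of the band's grid cells over
    the band's grid area (cell count × s²).  When ``cell_classes`` is
    given (one label per cell, '' to ignore), per-band class proportions
    over the labelled classes are included.
    """
    flat_dist = dfield.flat()
    grid_band = bands.assign(flat_dist)
    cell_band = grid_band[grid.cell_flat_index]

    s2 = grid.spacing**2
    rows = []
    areas: dict[str, float] = {}
    dense_genes = grid.genes.names
    for b in bands.bands:
        sel = grid_band == b.name
        n_sel = int(sel.sum())
        areas[b.name] = n_sel * s2
        if n_sel == 0:
            continue
        pooled = np.asarray(grid.counts[np.flatnonzero(sel)].sum(axis=0)).ravel()
        dens = pooled / (n_sel * s2)
        rows.extend(
            {"band": b.name, "gene": g, "density": float(v)}
            for g, v in zip(dense_genes, dens)
        )
    densities = pd.DataFrame(rows, columns=["band", "gene", "density"])

    proportions = None
    if cell_classes is not None:
        cls = np.asarray(cell_classes, dtype=object)
        prop_rows = []
        class_names = [c for c in pd.unique(cls) if c != ""]
        for b in bands.bands:
            in_band = cell_band == b.name
            counts = {c: int(np.sum(in_band & (cls == c))) for c in class_names}
            total = sum(counts.values())
            for c in class_names:
                prop_rows.append(
                    {"band": b.name, "cell_class": c, "n_cells": counts[c],
                     "proportion": counts[c] / total if total else np.nan}
                )
        proportions = pd.DataFrame(prop_rows)

    return cell_band, BandProfile(densities=densities, band_areas=areas,
                                  proportions=proportions)


# ---------------------------------------------------------------------------
# UPGMC clustering of band profiles

@dataclass
class Dendrogram:
    """Centroid-linkage merge tree over profiles."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def walk(node) -> tuple[str, float]:
            if node.is_leaf():
                return self.labels[node.id], 0.0
            l_str, l_h = walk(node.left)
            r_str, r_h = walk(node.right)
            h = node.dist
            return f"({l_str}:{h - l_h:.10g},{r_str}:{h - r_h:.10g})", h

        s, _ = walk(tree)
        return s + ";"


def upgmc_cluster(
    profiles: np.ndarray | pd.DataFrame, labels: list[str] | None = None
) -> Dendrogram:
    """Centroid-linkage (UPGMC) agglomerative clustering on Euclidean
    distances between profile vectors (rows)."""
    if isinstance(profiles, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in profiles.index]
        X = profiles.to_numpy(float)
    else:
        X = np.asarray(profiles, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("UPGMC needs >= 2 profiles")
    if labels is None:
        labels = [f"profile_{i}" for i in range(X.shape[0])]
    Z = linkage(X, method="centroid", metric="euclidean")
    return Dendrogram(linkage_matrix=Z, labels=list(labels))


def band_profile_matrix(profile: BandProfile) -> pd.DataFrame:
    """Pivot a BandProfile's densities to a band × gene matrix."""
    return profile.densities.pivot(index="band", columns="gene", values="density")
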