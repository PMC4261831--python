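"""Lines-of-evidence integration: normalization, clustering, IDW surfaces.

Site-level endpoints from the three lines of evidence (SQG-Q risk
indices from sediment chemistry, EC50-derived genotoxic potencies from
the in-vitro assays, and the IBR from field biomarkers) are placed on a
common 0-1 scale by min-max normalization, then explored two ways:

* hierarchical clustering (complete linkage) of sites with Euclidean
  distances and of endpoints with Spearman rank-correlation distance
  d = 1 - R, exported as merge lists and Newick strings for heatmap
  dendrograms;
* inverse-distance-weighted (IDW) interpolation of each normalized
  endpoint onto a planar grid for mapping.

EC50s enter as potencies: 1 - minmax(EC50) over the estimable entries,
so the most potent extract (lowest EC50) scores 1; a non-estimable EC50
means no measurable effect at the tested doses and scores 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def minmax_normalize(values) -> np.ndarray:
    """(x - min)/(max - min) ignoring NaN; a constant vector maps to all zeros."""
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size == 0:
        raise ValueError("min-max normalization needs at least one non-missing value")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        out = np.zeros_like(x)
        out[np.isnan(x)] = np.nan
        return out
    return (x - lo) / (hi - lo)


def ec50_to_potency(ec50_values) -> np.ndarray:
    """Potency in [0, 1] from EC50s: 1 - minmax over estimable entries.

    NaN entries (non-estimable, "-" in the source tables: no measurable
    damage at the tested doses) become potency 0.  A single estimable
    EC50 degenerates to potency 0.
    """
    x = np.asarray(ec50_values, dtype=float)
    pot = np.zeros_like(x)
    mask = ~np.isnan(x)
    if mask.sum() == 1:
        return pot  # degenerate normalization: a lone estimate carries no contrast
    if mask.any():
        pot[mask] = 1.0 - minmax_normalize(x[mask])
    return pot


def spearman_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance 1 - Spearman R between endpoint profiles over sites.

    ``profiles``: endpoints x sites.  Distances lie in [0, 2]; identical
    rankings give 0, exactly reversed rankings give 2.  A constant
    profile has undefined rank correlation; its distances are set to 1
    with a warning.
    """
    names = list(profiles.index)
    mat = profiles.to_numpy(dtype=float)
    k = len(names)
    d = np.zeros((k, k))
    constant = [np.unique(row).size == 1 for row in mat]
    if any(constant):
        warnings.warn("constant endpoint profile: Spearman undefined, distance set to 1",
                      stacklevel=2)
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                dij = 1.0
            else:
                rho = stats.spearmanr(mat[i], mat[j]).statistic
                dij = 1.0 - float(rho)
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=names, columns=names)


def hcluster(dist: pd.DataFrame | np.ndarray, method: str = "complete") -> np.ndarray:
    """Agglomerative clustering of a symmetric distance matrix.

    Returns a scipy linkage matrix (merge list with heights).  Ties are
    resolved deterministically by scipy's ordering, which favours the
    lowest leaf indices.
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else \
        np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return hierarchy.linkage(squareform(d, checks=False), method=method)


def linkage_to_newick(linkage: np.ndarray, labels: list) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cut_clusters(linkage: np.ndarray, n_clusters: int, labels: list) -> dict:
    """Flat cluster membership (label -> cluster id) at a given cluster count."""
    assignment = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return dict(zip(labels, (int(a) for a in assignment)))


@dataclass
class ClusterPipelineResult:
    """Both dendrograms plus the normalized matrix behind the heatmap."""

    normalized: pd.DataFrame            # sites x endpoints in [0, 1]
    site_linkage: np.ndarray            # Euclidean, complete
    endpoint_linkage: np.ndarray        # Spearman distance, complete
    site_newick: str
    endpoint_newick: str


def site_cluster_pipeline(matrix: pd.DataFrame) -> ClusterPipelineResult:
    """Normalize a sites-x-endpoints matrix and cluster both margins.

    Missing values become 0 after normalization (no measurable signal,
    logged), mirroring the "-" convention of the potency tables.  Sites
    are clustered on Euclidean distances, endpoints on Spearman
    rank-correlation distance, both with complete linkage.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 sites and 2 endpoints")
    norm = matrix.apply(lambda col: pd.Series(minmax_normalize(col), index=col.index),
                        axis=0)
    n_missing = int(norm.isna().sum().sum())
    if n_missing:
        logger.info("%d missing cells set to 0 after normalization", n_missing)
        norm = norm.fillna(0.0)

    site_d = squareform(pdist(norm.to_numpy(), metric="euclidean"), checks=False)
    site_link = hcluster(site_d)
    endo_d = spearman_distance(norm.T)
    endo_link = hcluster(endo_d)
    return ClusterPipelineResult(
        normalized=norm,
        site_linkage=site_link,
        endpoint_linkage=endo_link,
        site_newick=linkage_to_newick(site_link, list(norm.index)),
        endpoint_newick=linkage_to_newick(endo_link, list(norm.columns)),
    )


@dataclass
class SpatialField:
    """Point values plus the grid they are interpolated onto."""

    points: pd.DataFrame        # columns site, x, y
    values: pd.Series           # indexed by site
    bbox: tuple                 # (xmin, xmax, ymin, ymax)
    resolution: tuple           # (nx, ny)


def idw_interpolate(field: SpatialField, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted surface over the field's grid.

    value(g) = sum(w_i v_i) / sum(w_i), w_i = d(g, p_i)^-power.  A grid
    node coinciding with a data point returns that point's value exactly;
    the surface is bounded by the input value range.  Returns an (ny, nx)
    array with row 0 at ymin.
    """
    pts = field.points.set_index("site").loc[field.values.index]
    xy = pts[["x", "y"]].to_numpy(dtype=float)
    v = field.values.to_numpy(dtype=float)
    # duplicate coordinates with conflicting values are ill-posed for IDW
    uniq, inv = np.unique(xy, axis=0, return_inverse=True)
    if uniq.shape[0] < xy.shape[0]:
        for k in range(uniq.shape[0]):
            vals = v[inv == k]
            if np.unique(vals).size > 1:
                raise ValueError(f"duplicate point {tuple(uniq[k])} with conflicting values")
    xmin, xmax, ymin, ymax = field.bbox
    nx, ny = field.resolution
    gx = np.linspace(xmin, xmax, nx)
    gy = np.linspace(ymin, ymax, ny)
    gridx, gridy = np.meshgrid(gx, gy)
    surface = np.empty((ny, nx))
    for iy in range(ny):
        dx = gridx[iy][:, None] - xy[None, :, 0]
        dy = gridy[iy][:, None] - xy[None, :, 1]
        dist = np.hypot(dx, dy)
        exact = dist < 1e-12
        w = np.where(exact, 1.0, dist) ** (-power)  # placeholder where exact
        weighted = (w * v[None, :]).sum(axis=1) / w.sum(axis=1)
        hit = exact.any(axis=1)
        exact_vals = v[np.argmax(exact, axis=1)]
        surface[iy] = np.where(hit, exact_vals, weighted)
    return surface


def surface_to_ascii_grid(surface: np.ndarray, bbox: tuple, nodata: float = -9999.0) -> str:
    """Serialize a surface as an ESRI ASCII grid (text raster)."""
    ny, nx = surface.shape
    xmin, xmax, ymin, ymax = bbox
    cell = (xmax - xmin) / (nx - 1) if nx > 1 else 1.0
    header = (f"ncols {nx}\nnrows {ny}\nxllcorner {xmin}\nyllcorner {ymin}\n"
              f"cellsize {cell}\nNODATA_value {nodata}\n")
    # ASCII grids store the top row first
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in surface[::-1])
    return header + body + "\n"
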