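"""Point-pattern statistics for germinal-center cell maps.

The module answers four spatial questions about a GC:

* do two cell populations segregate or aggregate?  A randomization test
  compares observed nearest-neighbor (NN) distances against a null built by
  shuffling phenotype labels over the fixed cell positions — the natural
  exchangeable null when the tissue's overall cell density must be
  preserved;
* where is the DZ/LZ interface?  The outward-facing edge of the concave
  hull (alpha shape) of the DZ cell cloud, with a band of configurable
  total width centered on it;
* how does cell density change across the interface?  Signed-distance bins
  (negative = DZ side) with areas measured by buffering and polygon
  clipping;
* how do continuous quantities co-vary?  Permutation-p correlations
  (Pearson or Kendall) with percentile-bootstrap confidence intervals.

All distances are Euclidean and in μm; bins are half-open ``[lo, hi)``;
rank statistics use the midrank convention for ties.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import Delaunay, cKDTree

from .containers import CellMap

__all__ = [
    "RandomizationTestResult",
    "InterfaceModel",
    "DensityProfile",
    "CorrelationResult",
    "ProximityComparison",
    "nn_distances",
    "nn_randomization_test",
    "delineate_interface",
    "density_profile",
    "range_normalized_distance",
    "correlate",
    "nn_proximity_comparison",
]


# ---------------------------------------------------------------------------
# nearest-neighbor distances and the segregation/aggregation test
# ---------------------------------------------------------------------------

def nn_distances(query_points: np.ndarray, reference_points: np.ndarray) -> np.ndarray:
    """Distance from each query point to its nearest reference point (μm)."""
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    r = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if r.size == 0:
        raise ValueError("reference point set is empty")
    d, _ = cKDTree(r).query(q)
    return np.asarray(d, dtype=float)


@dataclass
class RandomizationTestResult:
    observed: np.ndarray            # A -> B NN distances
    null_pooled: np.ndarray         # pooled across permutations
    direction: str                  # segregation | aggregation | none
    p: float                        # calibrated permutation rank-sum p (two-sided)
    p_pooled_ranksum: float         # asymptotic rank-sum vs pooled null (descriptive)
    median_observed: float
    median_null: float
    n_perm: int
    seed: int
    type_a: str = ""
    type_b: str = ""


def nn_randomization_test(
    cellmap: CellMap,
    type_a: str,
    type_b: str,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> RandomizationTestResult:
    """Label-randomization test for segregation/aggregation of two cell types.

    The observed statistic is the set of A→B NN distances.  The null keeps
    every cell position fixed and reassigns the A/B labels at random over
    the union of positions, ``n_perm`` times; null distances are pooled
    across permutations.

    Two p-values are computed.  The primary ``p`` is a calibrated
    permutation p: each labeling (observed and permuted) is summarized by
    the mean rank of its distances within the pooled set, and the observed
    summary is ranked among the permuted ones (two-sided, add-one
    estimator) — exact under label exchangeability.  ``p_pooled_ranksum``
    is the descriptive two-sided rank-sum test of the observed distances
    against the pooled null, the form in which such comparisons are usually
    reported; it treats pooled distances as independent and should not be
    used for calibration.

    Direction is ``segregation`` if the observed median exceeds the pooled
    null median with ``p < alpha``, ``aggregation`` for the reverse,
    ``none`` otherwise.
    """
    pts_a = cellmap.points(phenotype=type_a)
    pts_b = cellmap.points(phenotype=type_b)
    if len(pts_a) < 5 or len(pts_b) < 5:
        raise ValueError("need at least 5 cells of each type")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a coarse permutation p", stacklevel=2)

    union = np.vstack([pts_a, pts_b])
    n_a = len(pts_a)
    rng = np.random.default_rng(seed)

    observed = nn_distances(pts_a, pts_b)
    null_sets = []
    for _ in range(n_perm):
        order = rng.permutation(len(union))
        a_star = union[order[:n_a]]
        b_star = union[order[n_a:]]
        null_sets.append(nn_distances(a_star, b_star))

    pooled_all = np.concatenate([observed] + null_sets)
    ranks = stats.rankdata(pooled_all)
    t_obs = ranks[:n_a].mean()
    t_null = np.array(
        [ranks[n_a + i * n_a : n_a + (i + 1) * n_a].mean() for i in range(n_perm)]
    )
    n_ge = int((t_null >= t_obs).sum())
    n_le = int((t_null <= t_obs).sum())
    p = min(1.0, 2.0 * min(1 + n_ge, 1 + n_le) / (n_perm + 1))

    null_pooled = np.concatenate(null_sets)
    p_pooled = float(
        stats.mannwhitneyu(observed, null_pooled, alternative="two-sided").pvalue
    )

    med_obs = float(np.median(observed))
    med_null = float(np.median(null_pooled))
    if p < alpha and med_obs > med_null:
        direction = "segregation"
    elif p < alpha and med_obs < med_null:
        direction = "aggregation"
    else:
        direction = "none"
    return RandomizationTestResult(
        observed=observed,
        null_pooled=null_pooled,
        direction=direction,
        p=float(p),
        p_pooled_ranksum=p_pooled,
        median_observed=med_obs,
        median_null=med_null,
        n_perm=n_perm,
        seed=seed,
        type_a=type_a,
        type_b=type_b,
    )


# ---------------------------------------------------------------------------
# DZ/LZ interface delineation
# ---------------------------------------------------------------------------

@dataclass
class InterfaceModel:
    """DZ/LZ boundary with a distance band centered on it.

    ``boundary`` is the outward-facing edge of the DZ point cloud's concave
    hull; ``dz_region`` the hull itself (clipped to the GC).  The signed
    distance to the boundary is negative on the DZ side.
    """

    boundary: shapely.Geometry
    dz_region: shapely.Geometry
    gc_polygon: shapely.Polygon
    band_width: float
    alpha: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        geoms = shapely.points(pts[:, 0], pts[:, 1])
        d = shapely.distance(geoms, self.boundary)
        inside = shapely.contains_xy(self.dz_region, pts[:, 0], pts[:, 1])
        sign = np.where(inside, -1.0, 1.0)
        return sign * d

    def in_band(self, points: np.ndarray) -> np.ndarray:
        return np.abs(self.signed_distance(points)) <= self.band_width / 2.0


def _alpha_shape(points: np.ndarray, alpha: float) -> shapely.Geometry:
    """Union of Delaunay triangles with circumradius ≤ alpha."""
    tri = Delaunay(points)
    keep = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        la, lb, lc = (
            np.linalg.norm(b - c),
            np.linalg.norm(a - c),
            np.linalg.norm(a - b),
        )
        u, w = b - a, c - a
        area2 = abs(u[0] * w[1] - u[1] * w[0])
        if area2 <= 0:
            continue
        circum_r = la * lb * lc / (2.0 * area2)
        if circum_r <= alpha:
            keep.append(shapely.Polygon([a, b, c]))
    if not keep:
        raise ValueError("alpha too small: no triangle kept; increase alpha")
    return _fill_holes(shapely.unary_union(keep))


def _fill_holes(geom: shapely.Geometry) -> shapely.Geometry:
    """Drop interior rings: local density dips inside the DZ cloud are not
    part of its outward-facing edge."""
    if geom.geom_type == "Polygon":
        return shapely.Polygon(geom.exterior)
    if geom.geom_type == "MultiPolygon":
        return shapely.unary_union([shapely.Polygon(p.exterior) for p in geom.geoms])
    return geom


def delineate_interface(
    dz_points: np.ndarray,
    gc_polygon: shapely.Polygon,
    band_width: float = 100.0,
    alpha: float | None = None,
    edge_tol: float | None = None,
    closing_factor: float = 3.0,
) -> InterfaceModel:
    """Delineate the DZ/LZ interface from the DZ cell cell point cloud.

    The DZ region is the alpha-shape (concave hull) of the DZ points —
    largest component, holes filled, smoothed by a morphological closing of
    radius ``closing_factor·alpha`` so sampling-noise dents do not masquerade
    as interface structure — clipped to the GC polygon.  The interface is
    the part of its boundary that does not hug the GC boundary: the
    outward-facing edge toward the LZ.  The band of total width
    ``band_width`` (default 100 μm: inner and outer layers 50 μm each) is
    centered on it.

    ``alpha`` defaults to four times the median DZ nearest-neighbor
    spacing; boundary segments within ``edge_tol`` (default ``2·alpha``) of
    the GC boundary are discarded as GC-edge artifacts.
    """
    pts = np.atleast_2d(np.asarray(dz_points, dtype=float))
    if len(pts) < 3:
        raise ValueError("need at least 3 DZ points")
    v = pts - pts[0]
    nz = np.flatnonzero((v != 0).any(axis=1))
    if len(nz) == 0:
        raise ValueError("DZ points are collinear")
    ref = v[nz[0]]
    cross_z = ref[0] * v[:, 1] - ref[1] * v[:, 0]
    if np.allclose(cross_z, 0.0):
        raise ValueError("DZ points are collinear")

    if alpha is None:
        d, _ = cKDTree(pts).query(pts, k=2)
        alpha = 4.0 * float(np.median(d[:, 1]))
    if edge_tol is None:
        edge_tol = 2.0 * alpha

    try:
        region = _alpha_shape(pts, alpha)
    except Exception as err:  # qhull degeneracy
        raise ValueError(f"cannot triangulate DZ points: {err}") from err
    if region.geom_type == "MultiPolygon":
        region = max(region.geoms, key=lambda p: p.area)
    if closing_factor > 0:
        c = closing_factor * alpha
        region = _fill_holes(region.buffer(c).buffer(-c))
    region = region.intersection(gc_polygon)
    if region.is_empty:
        raise ValueError("DZ hull does not intersect the GC polygon")

    boundary = region.boundary
    gc_edge = gc_polygon.exterior.buffer(edge_tol)
    interface = boundary.difference(gc_edge)
    if interface.is_empty:
        interface = boundary
    return InterfaceModel(
        boundary=interface,
        dz_region=region,
        gc_polygon=gc_polygon,
        band_width=float(band_width),
        alpha=float(alpha),
    )


# ---------------------------------------------------------------------------
# density profiles across the interface
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    edges: np.ndarray                       # signed-distance bin edges, μm
    densities: pd.DataFrame                 # bins × phenotypes, cells/μm²
    counts: pd.DataFrame
    areas: np.ndarray                       # μm² per bin
    area_method: str = "buffer_clip"


def _band_area(model: InterfaceModel, lo: float, hi: float) -> float:
    """Area of the signed-distance slab [lo, hi) inside the GC."""

    def one_side(a: float, b: float, dz_side: bool) -> float:
        # 0 <= a < b are absolute distances on one side of the boundary
        outer = model.boundary.buffer(b)
        ring = outer if a == 0 else outer.difference(model.boundary.buffer(a))
        piece = ring.intersection(model.gc_polygon)
        side = (
            piece.intersection(model.dz_region)
            if dz_side
            else piece.difference(model.dz_region)
        )
        return float(side.area)

    if hi <= 0:
        return one_side(abs(hi), abs(lo), dz_side=True)
    if lo >= 0:
        return one_side(lo, hi, dz_side=False)
    return one_side(0.0, abs(lo), dz_side=True) + one_side(0.0, hi, dz_side=False)


def density_profile(
    cellmap: CellMap,
    interface: InterfaceModel,
    bin_width: float = 10.0,
    phenotypes: list[str] | None = None,
) -> DensityProfile:
    """Per-phenotype cell density in signed-distance bins across the band.

    Bins are half-open ``[lo, hi)`` tiling ``[-band/2, band/2]``; negative
    distances are the DZ side.  Densities divide bin counts by bin areas
    obtained by buffering the boundary and clipping to the GC polygon and
    to the DZ/LZ side.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    half = interface.band_width / 2.0
    n_bins = max(1, int(round(2.0 * half / bin_width)))
    edges = -half + bin_width * np.arange(n_bins + 1)
    edges[-1] = half

    phenos = phenotypes if phenotypes is not None else cellmap.phenotypes
    counts = pd.DataFrame(0, index=range(n_bins), columns=phenos, dtype=int)
    for ph in phenos:
        pts = cellmap.points(phenotype=ph)
        if not len(pts):
            continue
        d = interface.signed_distance(pts)
        idx = np.floor((d - edges[0]) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        for i in idx[ok]:
            counts.loc[i, ph] += 1

    areas = np.array([_band_area(interface, edges[i], edges[i + 1]) for i in range(n_bins)])
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = counts.to_numpy(dtype=float) / areas[:, None]
    densities = pd.DataFrame(dens, index=counts.index, columns=phenos)
    return DensityProfile(edges=edges, densities=densities, counts=counts, areas=areas)


def range_normalized_distance(
    points: np.ndarray,
    interface: InterfaceModel,
    compartments: np.ndarray | pd.Series | None = None,
    per_compartment: bool = True,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Range-normalized distance of cells to the interface, in [0, 1].

    Each cell's |signed distance| is divided by the maximum |signed
    distance| within its compartment (or over all cells when
    ``per_compartment`` is false), so 0 is the boundary and 1 the deepest
    cell.  Cells are labeled ``close`` when the value falls below
    ``threshold`` (default 0.4).  Compartments with a single cell have an
    undefined normalization and are flagged.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = interface.signed_distance(pts)
    out = pd.DataFrame({"signed_d_um": d})
    out["flagged"] = False
    if per_compartment:
        if compartments is None:
            raise ValueError("per-compartment normalization needs compartment labels")
        comp = np.asarray(compartments)
        out["compartment"] = comp
        norm = np.full(len(d), np.nan)
        for c in pd.unique(comp):
            m = comp == c
            if m.sum() < 2:
                out.loc[m, "flagged"] = True
                continue
            norm[m] = np.abs(d[m]).max()
    else:
        norm = np.full(len(d), np.abs(d).max())
    with np.errstate(divide="ignore", invalid="ignore"):
        out["norm_d"] = np.where(norm > 0, np.abs(d) / norm, 0.0)
    out.loc[out["flagged"], "norm_d"] = np.nan
    out["close"] = out["norm_d"] < threshold
    return out


# ---------------------------------------------------------------------------
# permutation/bootstrap correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    method: str
    r: float
    p: float
    ci_low: float
    ci_high: float
    ci_level: float
    n: int
    n_perm: int
    b_boot: int
    seed: int
    exhaustive: bool = False


def _corr_stat(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    n_perm: int = 999,
    b_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> CorrelationResult:
    """Correlation with a permutation p-value and a bootstrap CI.

    The p-value shuffles ``y`` ``n_perm`` times (two-sided on |r|, add-one
    estimator ``(1 + #{|r*| ≥ |r|}) / (1 + n_perm)``); when ``n!`` does not
    exceed ``n_perm`` all permutations are enumerated instead and the p is
    the exact fraction.  The CI is the percentile bootstrap over paired
    resamples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")

    n = len(x)
    r_obs = _corr_stat(x, y, method)
    rng = np.random.default_rng(seed)
    eps = 1e-12

    exhaustive = math.factorial(n) <= n_perm
    if exhaustive:
        count = 0
        total = 0
        for perm in _iter_permutations(range(n)):
            r_star = _corr_stat(x, y[list(perm)], method)
            if abs(r_star) >= abs(r_obs) - eps:
                count += 1
            total += 1
        p = count / total
    else:
        count = 0
        for _ in range(n_perm):
            r_star = _corr_stat(x, y[rng.permutation(n)], method)
            if abs(r_star) >= abs(r_obs) - eps:
                count += 1
        p = (1 + count) / (1 + n_perm)

    boots = []
    for _ in range(b_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if xb.std() == 0 or yb.std() == 0:
            continue
        boots.append(_corr_stat(xb, yb, method))
    lo_q = (1.0 - ci_level) / 2.0
    if boots:
        ci_low, ci_high = np.quantile(boots, [lo_q, 1.0 - lo_q])
    else:
        ci_low = ci_high = r_obs
    return CorrelationResult(
        method=method,
        r=r_obs,
        p=float(p),
        ci_low=float(min(ci_low, r_obs)),
        ci_high=float(max(ci_high, r_obs)),
        ci_level=ci_level,
        n=n,
        n_perm=n_perm,
        b_boot=b_boot,
        seed=seed,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# multi-type proximity comparison
# ---------------------------------------------------------------------------

@dataclass
class ProximityComparison:
    medians: pd.DataFrame                   # query, reference, n, median_um
    pairwise: pd.DataFrame                  # query, ref_1, ref_2, rank-sum p
    distances: dict = field(default_factory=dict)


def nn_proximity_comparison(
    cellmap: CellMap,
    query_types: list[str],
    reference_types: list[str],
) -> ProximityComparison:
    """Median NN distance of each query type to each reference type.

    For every query phenotype the NN-distance sets toward the different
    reference phenotypes are compared pairwise by a two-sided rank-sum
    test, asking e.g. whether CD4 cells sit closer to DZ than to LZ B
    cells.
    """
    present = set(cellmap.phenotypes)
    for t in list(query_types) + list(reference_types):
        if t not in present:
            raise ValueError(f"phenotype {t!r} not present in the cell map")

    dist: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    for q in query_types:
        pts_q = cellmap.points(phenotype=q)
        for r in reference_types:
            pts_r = cellmap.points(phenotype=r)
            d = nn_distances(pts_q, pts_r)
            dist[(q, r)] = d
            rows.append(
                {"query": q, "reference": r, "n": len(d), "median_um": float(np.median(d))}
            )
    pw = []
    for q in query_types:
        for i, r1 in enumerate(reference_types):
            for r2 in reference_types[i + 1 :]:
                d1, d2 = dist[(q, r1)], dist[(q, r2)]
                if len(d1) > 1 and len(d2) > 1:
                    p = float(stats.mannwhitneyu(d1, d2, alternative="two-sided").pvalue)
                else:
                    p = float("nan")
                pw.append({"query": q, "ref_1": r1, "ref_2": r2, "p": p})
    return ProximityComparison(
        medians=pd.DataFrame(rows),
        pairwise=pd.DataFrame(pw),
        distances=dist,
    )
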