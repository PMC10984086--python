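"""Synthetic germinal-center data with planted, recorded ground truth.

Four generators emulate the data types of the study design so that every
downstream statistic can be exercised against a known answer:

* :func:`simulate_gc_map` — a GC point pattern in which T cells are repelled
  from the dark zone (DZ) by independent thinning of a homogeneous Poisson
  process, while B cells fill the whole GC uniformly;
* :func:`simulate_nuclei_image` — a DNA-stain image in which each nucleus is
  a disc of euchromatin carrying non-overlapping heterochromatin foci whose
  area fraction differs between DZ and LZ nuclei.  Total DNA content per
  nucleus is conserved, so a higher heterochromatin fraction dims the
  euchromatin baseline — the physical reason compacted (DZ) nuclei show a
  lower minimum DNA intensity and a wider intensity spread;
* :func:`simulate_paired_roi_expression` — matched DZ/LZ region-of-interest
  expression with planted log-fold-changes on a random gene subset;
* :func:`simulate_cohort` — tumor cohorts in which a latent DZ-signature
  activity drives signature genes and, through a logistic link, an
  anti-correlated latent T-cell fraction driving a T-cell gene block.

Every generator is deterministic given its config seed; randomness flows
through named sub-streams (:func:`gcniche.containers.substream`) so stages
can be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.special import expit

from .containers import CellMap, ExpressionMatrix, GeneSignature, substream

__all__ = [
    "TissueSimConfig",
    "NucleiSimConfig",
    "ExpressionSimConfig",
    "GroundTruth",
    "simulate_gc_map",
    "grid_cell_map",
    "simulate_nuclei_image",
    "simulate_paired_roi_expression",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TissueSimConfig:
    """Geometry and intensities of the simulated GC point pattern.

    The GC is a disc of radius ``gc_radius`` (μm); the DZ is the half-plane
    cut ``x < x_cut`` with ``x_cut`` chosen so the DZ covers ``dz_fraction``
    of the disc area.  T cells are a homogeneous Poisson process of
    intensity ``t_intensity`` (points/μm²) thinned inside the DZ with
    retention probability ``dz_t_retention`` (1 = no repulsion, 0 = complete
    exclusion).  γδT-like cells are Poisson with base intensity
    ``gdt_intensity`` multiplied by ``gdt_dz_enrichment`` inside the DZ.
    """

    gc_radius: float = 250.0
    dz_fraction: float = 0.5
    n_b_cells: int = 1500
    t_intensity: float = 0.002
    dz_t_retention: float = 0.2
    gdt_dz_enrichment: float = 3.0
    gdt_intensity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gc_radius <= 0:
            raise ValueError("gc_radius must be positive")
        if not (0.0 < self.dz_fraction < 1.0):
            raise ValueError("dz_fraction must lie in (0, 1)")
        if not (0.0 <= self.dz_t_retention <= 1.0):
            raise ValueError("dz_t_retention must lie in [0, 1]")
        if self.n_b_cells < 0 or self.t_intensity < 0 or self.gdt_dz_enrichment < 0:
            raise ValueError("counts and intensities must be non-negative")
        if self.gdt_intensity is None:
            self.gdt_intensity = 0.15 * self.t_intensity


@dataclass
class NucleiSimConfig:
    """Rendering parameters for synthetic DNA-stain nuclei.

    ``f_hc_dz`` / ``f_hc_lz`` are the heterochromatin area fractions planted
    in DZ and LZ nuclei (each nucleus draws its own fraction from a normal
    with sd ``f_hc_sd``, clipped to [0, 0.55]).  Heterochromatin foci are
    ``hc_intensity_ratio`` times brighter than euchromatin; total intensity
    per nucleus is conserved, with per-nucleus lognormal brightness jitter
    of scale ``brightness_sd``.  Intensities live on a [0, 1] scale before
    16-bit quantization; ``noise_sd`` is additive Gaussian noise on that
    scale.
    """

    pixel_size: float = 0.15          # μm per pixel
    nucleus_radius: float = 3.5       # μm
    f_hc_dz: float = 0.35
    f_hc_lz: float = 0.15
    f_hc_sd: float = 0.05
    hc_intensity_ratio: float = 3.0
    noise_sd: float = 0.01
    brightness_sd: float = 0.05
    base_mean: float = 0.5
    focus_radius: float | None = None  # μm; default nucleus_radius / 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0.0 <= self.f_hc_dz < 1.0 and 0.0 <= self.f_hc_lz < 1.0):
            raise ValueError("heterochromatin fractions must lie in [0, 1)")
        if self.hc_intensity_ratio <= 1.0:
            raise ValueError("hc_intensity_ratio must exceed 1")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if self.focus_radius is None:
            self.focus_radius = self.nucleus_radius / 6.0


@dataclass
class ExpressionSimConfig:
    """Planted-effect design for paired-ROI and cohort expression.

    Paired design: gene ``g`` in pair ``i`` has value
    ``mu_g + b_i ± logfc/2·[g planted] + eps`` with ``eps ~ N(0, gene_sd)``
    and a shared per-pair offset ``b_i ~ N(0, pair_effect_sd)`` common to
    both members of the pair (so within-pair differences cancel it).

    Cohort design: a latent per-sample DZ activity ``a ~ N(0, 1)`` loads on
    the signature genes with weight ``sig_loading``; the latent T-cell
    fraction is ``logistic(cohort_beta·a + eta)``, ``eta ~ N(0, tfrac_noise_sd)``,
    and drives a dedicated T-cell gene block.
    """

    n_genes: int = 1800
    n_pairs: int = 10
    n_samples: int = 300
    n_de: int = 150
    logfc: float = 1.0
    gene_sd: float = 0.5
    pair_effect_sd: float = 1.0
    cohort_beta: float = -2.0
    sig_loading: float = 1.0
    tcell_loading: float = 1.0
    n_tcell_genes: int = 30
    tfrac_noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.gene_sd <= 0:
            raise ValueError("gene_sd must be positive")
        if min(self.n_genes, self.n_pairs, self.n_samples, self.n_de) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class GroundTruth:
    """Planted truths recorded by the generators (filled per generator)."""

    compartment: pd.Series | None = None          # per-cell DZ/LZ label
    dz_cut_x: float | None = None                 # half-plane cut, μm
    f_hc: pd.Series | None = None                 # realized HC fraction per nucleus
    de_genes: dict[str, int] = field(default_factory=dict)   # gene -> ±1
    activity: pd.Series | None = None             # per-sample DZ activity
    t_fraction: pd.Series | None = None           # per-sample latent T fraction
    tcell_genes: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tissue point patterns
# ---------------------------------------------------------------------------

def _halfplane_cut(radius: float, dz_fraction: float) -> float:
    """x such that the disc area left of ``x`` is ``dz_fraction`` of the total."""

    def frac(c: float) -> float:
        u = c / radius
        return 0.5 + (u * math.sqrt(max(1 - u * u, 0.0)) + math.asin(u)) / math.pi

    return brentq(lambda c: frac(c) - dz_fraction, -radius, radius, xtol=1e-9 * radius)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * math.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_gc_map(cfg: TissueSimConfig) -> tuple[CellMap, GroundTruth]:
    """Simulate a GC cell map with T-cell repulsion from the DZ.

    B cells are uniform over the GC disc.  T cells are a homogeneous Poisson
    process over the disc, then independently thinned inside the DZ with
    retention probability ``cfg.dz_t_retention``, so the expected DZ T-cell
    count is ``retention · t_intensity · DZ area``.  γδT-like cells use
    ``gdt_dz_enrichment`` as a DZ intensity multiplier (values > 1 enrich
    the DZ, mirroring their aggregation with DZ B cells).

    Returns the :class:`CellMap` (phenotypes ``B``, ``T``, ``gdT``; each
    cell carries its true compartment) and a :class:`GroundTruth`.
    """
    R = cfg.gc_radius
    cut = _halfplane_cut(R, cfg.dz_fraction)
    area = math.pi * R * R

    rng_b = substream(cfg.seed, "tissue.b_cells")
    rng_t = substream(cfg.seed, "tissue.t_cells")
    rng_g = substream(cfg.seed, "tissue.gdt_cells")

    b_xy = _uniform_disc(rng_b, cfg.n_b_cells, R)

    n_t = rng_t.poisson(cfg.t_intensity * area)
    t_xy = _uniform_disc(rng_t, n_t, R)
    in_dz = t_xy[:, 0] < cut
    keep = ~in_dz | (rng_t.random(n_t) < cfg.dz_t_retention)
    t_xy = t_xy[keep]

    lam_max = cfg.gdt_intensity * max(1.0, cfg.gdt_dz_enrichment)
    n_g = rng_g.poisson(lam_max * area)
    g_xy = _uniform_disc(rng_g, n_g, R)
    lam = np.where(g_xy[:, 0] < cut, cfg.gdt_intensity * cfg.gdt_dz_enrichment, cfg.gdt_intensity)
    g_xy = g_xy[rng_g.random(n_g) * lam_max < lam]

    xy = np.vstack([b_xy, t_xy, g_xy])
    phen = ["B"] * len(b_xy) + ["T"] * len(t_xy) + ["gdT"] * len(g_xy)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(len(xy))],
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "phenotype": phen,
            "compartment_true": np.where(xy[:, 0] < cut, "DZ", "LZ"),
        }
    )
    theta = np.linspace(0.0, 2.0 * math.pi, 257)[:-1]
    polygon = shapely.Polygon(np.column_stack([R * np.cos(theta), R * np.sin(theta)]))
    cellmap = CellMap(cells, polygon)
    gt = GroundTruth(
        compartment=cells.set_index("cell_id")["compartment_true"],
        dz_cut_x=cut,
        params=asdict(cfg),
    )
    return cellmap, gt


def with_aid_labels(cellmap: CellMap) -> CellMap:
    """Relabel DZ B cells as ``AID`` (the DZ marker phenotype).

    Imaging maps identify DZ B cells by AID positivity; tests of T-cell
    exclusion from the DZ compare CD3-like T cells against this AID+
    reference rather than against all B cells.
    """
    cells = cellmap.cells.copy()
    mask = (cells["phenotype"] == "B") & (cells.get("compartment_true") == "DZ")
    cells.loc[mask, "phenotype"] = "AID"
    return CellMap(cells, cellmap.polygon)


def grid_cell_map(
    n_dz: int,
    n_lz: int,
    spacing_um: float = 9.0,
    phenotype: str = "B",
) -> CellMap:
    """Lay DZ and LZ cells on a regular grid (DZ block left, LZ block right).

    A convenience layout for rendering nuclei without collisions; the grid
    spacing must exceed the nucleus diameter used downstream.
    """
    n = n_dz + n_lz
    ncol = max(1, math.ceil(math.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), ncol)
    x = cols * spacing_um
    y = rows * spacing_um
    comp = np.array(["DZ"] * n_dz + ["LZ"] * n_lz)
    cells = pd.DataFrame(
        {
            "cell_id": [f"n{i:05d}" for i in range(n)],
            "x_um": x.astype(float),
            "y_um": y.astype(float),
            "phenotype": phenotype,
            "compartment_true": comp,
        }
    )
    pad = spacing_um
    poly = shapely.box(-pad, -pad, x.max() + pad, y.max() + pad)
    return CellMap(cells, poly)


# ---------------------------------------------------------------------------
# nuclei images
# ---------------------------------------------------------------------------

def _place_foci(
    rng: np.random.Generator, R_px: float, target_area_px: float, r_focus_px: float
) -> list[tuple[float, float, float]]:
    """Dart-throw non-overlapping foci (cx, cy, r) inside a disc of radius R.

    Foci lie fully inside the nucleus.  When the remaining target area is
    smaller than a full focus, the last focus shrinks to match; when dart
    throwing jams, the focus radius is reduced and packing continues, so the
    realized area tracks the target within rasterization error.
    """
    foci: list[tuple[float, float, float]] = []
    remaining = target_area_px
    r = r_focus_px
    fails = 0
    while remaining > 1.0 and r >= 1.0:
        r_use = min(r, math.sqrt(remaining / math.pi))
        if R_px - r_use <= 0:
            break
        cx, cy = _uniform_disc(rng, 1, R_px - r_use)[0]
        ok = all((cx - fx) ** 2 + (cy - fy) ** 2 >= (r_use + fr) ** 2 for fx, fy, fr in foci)
        if ok:
            foci.append((cx, cy, r_use))
            remaining -= math.pi * r_use * r_use
            fails = 0
        else:
            fails += 1
            if fails >= 400:
                r /= 1.5
                fails = 0
    return foci


def simulate_nuclei_image(
    cellmap: CellMap, cfg: NucleiSimConfig
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a 16-bit DNA-stain image and label mask for a cell map.

    Each nucleus is a disc of euchromatin carrying non-overlapping
    heterochromatin foci at ``hc_intensity_ratio`` times the euchromatin
    level.  The integrated intensity of a nucleus is independent of its
    heterochromatin fraction f (DNA content is conserved): the euchromatin
    level is ``base_mean / (1 + f·(ratio − 1))``, so compacted nuclei have a
    dimmer euchromatin floor and a wider intensity spread.

    Returns ``(image, label_mask, ground_truth)``; the mask assigns one
    positive integer per nucleus (row order of the cell table, starting at
    1) with 0 background.  Raises ``ValueError`` naming the first colliding
    pair if nuclei would overlap at the requested radius.
    """
    px = cfg.pixel_size
    R_um = cfg.nucleus_radius
    xy = cellmap.cells[["x_um", "y_um"]].to_numpy(dtype=float)
    ids = cellmap.cells["cell_id"].to_numpy()

    if len(xy) > 1:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(2.0 * R_um)
        if pairs:
            i, j = sorted(pairs)[0]
            raise ValueError(
                f"nuclei {ids[i]!r} and {ids[j]!r} overlap at radius {R_um} μm"
            )

    margin = R_um + 3 * px
    x0, y0 = xy.min(axis=0) - margin
    w = int(math.ceil((xy[:, 0].max() + margin - x0) / px)) + 1
    h = int(math.ceil((xy[:, 1].max() + margin - y0) / px)) + 1

    image = np.zeros((h, w), dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.uint16)

    comp = (
        cellmap.cells["compartment_true"].to_numpy()
        if "compartment_true" in cellmap.cells.columns
        else np.array(["DZ"] * len(xy))
    )
    rng = substream(cfg.seed, "nuclei.render")
    noise_rng = substream(cfg.seed, "nuclei.noise")

    R_px = R_um / px
    rf_px = cfg.focus_radius / px
    f_real = np.zeros(len(xy))

    for k in range(len(xy)):
        f_target = cfg.f_hc_dz if comp[k] == "DZ" else cfg.f_hc_lz
        f_k = float(np.clip(rng.normal(f_target, cfg.f_hc_sd), 0.0, 0.55)) if cfg.f_hc_sd > 0 else f_target
        cx = (xy[k, 0] - x0) / px
        cy = (xy[k, 1] - y0) / px

        r0, r1 = int(cy - R_px) - 1, int(cy + R_px) + 2
        c0, c1 = int(cx - R_px) - 1, int(cx + R_px) + 2
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= R_px**2
        n_disc = int(disc.sum())
        if n_disc == 0:
            continue

        hc = np.zeros_like(disc)
        if f_k > 0:
            foci = _place_foci(rng, R_px, f_k * math.pi * R_px**2, rf_px)
            for fx, fy, fr in foci:
                hc |= (xx - (cx + fx)) ** 2 + (yy - (cy + fy)) ** 2 <= fr**2
            hc &= disc
        f_real[k] = hc.sum() / n_disc

        # conserve integrated intensity: e·(n_ec + ratio·n_hc) = base_mean·n
        e_level = cfg.base_mean / (1.0 + f_real[k] * (cfg.hc_intensity_ratio - 1.0))
        bright = math.exp(rng.normal(0.0, cfg.brightness_sd)) if cfg.brightness_sd > 0 else 1.0
        patch = np.where(hc, cfg.hc_intensity_ratio * e_level, e_level) * bright

        img_view = image[r0:r1, c0:c1]
        lab_view = labels[r0:r1, c0:c1]
        img_view[disc] = patch[disc]
        lab_view[disc] = k + 1

    if cfg.noise_sd > 0:
        image = image + noise_rng.normal(0.0, cfg.noise_sd, size=image.shape)
    image16 = np.clip(np.round(image * 65535.0), 0, 65535).astype(np.uint16)

    gt = GroundTruth(
        compartment=pd.Series(comp, index=ids, name="compartment_true"),
        f_hc=pd.Series(f_real, index=ids, name="f_hc"),
        params=asdict(cfg),
    )
    return image16, labels, gt


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_paired_roi_expression(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Matched DZ/LZ ROI expression with planted log2 fold-changes.

    A random subset of ``n_de`` genes receives a symmetric ``±logfc/2``
    shift between the DZ and LZ member of every pair (half up in DZ, half
    down).  The per-pair offset ``b_i`` is shared by both members, so it
    cancels in within-pair differences.
    """
    rng = substream(cfg.seed, "expression.paired")
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    b = rng.normal(0.0, cfg.pair_effect_sd, cfg.n_pairs)

    de_idx = rng.choice(cfg.n_genes, size=cfg.n_de, replace=False)
    signs = np.zeros(cfg.n_genes)
    half = cfg.n_de // 2
    signs[de_idx[:half]] = 1.0
    signs[de_idx[half:]] = -1.0

    cols, data, zone, pair = [], [], [], []
    for i in range(cfg.n_pairs):
        for z, s in (("DZ", +1.0), ("LZ", -1.0)):
            x = mu + b[i] + s * signs * cfg.logfc / 2.0
            x = x + rng.normal(0.0, cfg.gene_sd, cfg.n_genes)
            cols.append(f"P{i + 1:02d}_{z}")
            data.append(x)
            zone.append(z)
            pair.append(f"P{i + 1:02d}")

    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    design = pd.DataFrame({"pair": pair, "zone": zone}, index=cols)
    gt = GroundTruth(
        de_genes={genes[i]: int(signs[i]) for i in de_idx},
        params=asdict(cfg),
    )
    return ExpressionMatrix(values, design), gt


def simulate_cohort(
    cfg: ExpressionSimConfig,
    signature: GeneSignature,
    cohort_id: str = "cohort1",
) -> tuple[ExpressionMatrix, GroundTruth]:
    """A tumor cohort whose DZ-signature activity is linked to T-cell content.

    Per sample, a latent DZ activity ``a ~ N(0,1)`` loads (positively, or by
    the signature's per-gene direction) on the signature genes.  The latent
    T-cell fraction is ``logistic(cohort_beta·a + eta)`` and drives a block
    of ``n_tcell_genes`` dedicated T-cell genes (ids ``TC####``), so a
    negative ``cohort_beta`` plants the anti-correlation between DZ score
    and T-cell content.  All latents are recorded in the ground truth.
    """
    if len(signature) == 0:
        raise ValueError("signature must be non-empty")
    rng = substream(cfg.seed, f"expression.cohort.{cohort_id}")

    sig_genes = list(signature.genes)
    tc_genes = [f"TC{i:04d}" for i in range(cfg.n_tcell_genes)]
    n_bg = cfg.n_genes - len(sig_genes) - len(tc_genes)
    if n_bg < 0:
        raise ValueError("n_genes too small for signature plus T-cell block")
    bg_genes = [f"BG{i:04d}" for i in range(n_bg)]
    genes = sig_genes + tc_genes + bg_genes

    n = cfg.n_samples
    a = rng.normal(0.0, 1.0, n)
    eta = rng.normal(0.0, cfg.tfrac_noise_sd, n)
    tfrac = expit(cfg.cohort_beta * a + eta)
    t_std = (tfrac - tfrac.mean()) / tfrac.std()

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(genes))
    dirs = np.ones(len(sig_genes))
    if signature.directions:
        dirs = np.array([signature.directions.get(g, 1) for g in sig_genes], dtype=float)

    X = mu[:, None] + rng.normal(0.0, cfg.gene_sd, (len(genes), n))
    X[: len(sig_genes)] += cfg.sig_loading * dirs[:, None] * a[None, :]
    X[len(sig_genes) : len(sig_genes) + len(tc_genes)] += cfg.tcell_loading * t_std[None, :]

    samples = [f"{cohort_id}_s{i:03d}" for i in range(n)]
    values = pd.DataFrame(X, index=genes, columns=samples)
    design = pd.DataFrame({"cohort": cohort_id}, index=samples)
    gt = GroundTruth(
        activity=pd.Series(a, index=samples, name="dz_activity"),
        t_fraction=pd.Series(tfrac, index=samples, name="t_fraction"),
        tcell_genes=tc_genes,
        params={**asdict(cfg), "cohort_id": cohort_id},
    )
    return ExpressionMatrix(values, design), gt
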