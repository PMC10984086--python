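"""Nuclear segmentation and chrometric feature extraction.

"Chrometric" features are per-nucleus summaries of the DNA-stain intensity
distribution and nuclear morphology, used as proxies for chromatin state:
compacted (heterochromatin-rich) nuclei show a dimmer euchromatin floor
(lower minimum intensity) and a wider spread (higher 80th/20th-percentile
ratio, higher HC/EC ratio).

Conventions (declared once, used everywhere):

* percentiles use linear interpolation on the sorted pixel values;
* the heterochromatin/euchromatin (HC/EC) ratio thresholds each nucleus at
  its own ``mean + k_sd·sd`` (population sd), which keeps the estimator
  robust to per-image illumination differences;
* intensities may be min–max normalized per image before extraction
  (``normalize=True``, the pipeline default) — percentile ratios and the
  HC/EC ratio are invariant to this affine rescaling, absolute intensities
  are not;
* pixel coordinates are 0-based, x right / y down; physical units enter via
  ``pixel_size`` (μm per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "FEATURE_NAMES",
    "NucleusRecord",
    "WelchResult",
    "segment_nuclei",
    "extract_chrometric_features",
    "hc_ec_ratio",
    "feature_group_test",
]

#: The fixed 14-feature chrometric inventory, in stable output order.
FEATURE_NAMES = [
    "min_intensity",
    "max_intensity",
    "mean_intensity",
    "sd_intensity",
    "entropy",
    "p20",
    "p50",
    "p80",
    "ratio_p80_p20",
    "hc_ec_ratio",
    "area_um2",
    "perimeter_um",
    "eccentricity",
    "solidity",
]

MIN_PIXELS = 10  # labels below this are flagged and left unmeasured


@dataclass
class NucleusRecord:
    nucleus_id: int
    x_um: float
    y_um: float
    area_um2: float


@dataclass
class WelchResult:
    """Unequal-variance two-sample t comparison of one feature."""

    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def _as_float_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {image.shape}")
    if np.nanmin(image) < 0:
        raise ValueError("image intensities must be non-negative")
    return image.astype(np.float64)


def segment_nuclei(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_area: int = 50,
    watershed_on: bool = False,
    pixel_size: float = 1.0,
    min_peak_distance: int | None = None,
) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Segment nuclei from a single-channel DNA-stain image.

    Foreground is thresholded (``"otsu"``, ``"mean"``, or a numeric cutoff),
    components below ``min_area`` pixels are dropped, and — when
    ``watershed_on`` — touching nuclei are split by a distance-transform
    watershed seeded at distance-map peaks.  Deterministic.

    Returns the label mask (0 = background) and one :class:`NucleusRecord`
    per nucleus with centroid and area in physical units.
    """
    img = _as_float_image(image)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32), []

    if isinstance(threshold_method, str):
        if threshold_method == "otsu":
            t = threshold_otsu(img)
        elif threshold_method == "mean":
            t = float(img.mean())
        else:
            raise ValueError(f"unknown threshold_method {threshold_method!r}")
    else:
        t = float(threshold_method)

    fg = img > t
    fg = remove_small_objects(fg, max_size=int(min_area) - 1)
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32), []

    if watershed_on:
        dist = ndi.distance_transform_edt(fg)
        if min_peak_distance is None:
            # half the typical object radius keeps one peak per convex lobe
            min_peak_distance = max(3, int(dist.max() * 0.7))
        peaks = peak_local_max(dist, min_distance=min_peak_distance, labels=fg)
        markers = np.zeros(img.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        lab = watershed(-dist, markers, mask=fg)
        lab = remove_small_objects(lab, max_size=int(min_area) - 1)
        # relabel consecutively
        lab, _, _ = _relabel(lab)
    else:
        lab, _ = ndi.label(fg)
        lab = lab.astype(np.int32)

    records = [
        NucleusRecord(
            nucleus_id=int(p.label),
            x_um=float(p.centroid[1]) * pixel_size,
            y_um=float(p.centroid[0]) * pixel_size,
            area_um2=float(p.area) * pixel_size**2,
        )
        for p in regionprops(lab)
    ]
    return lab, records


def _relabel(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    old = np.unique(lab)
    old = old[old > 0]
    new = np.zeros(lab.max() + 1, dtype=np.int32)
    new[old] = np.arange(1, len(old) + 1)
    return new[lab], old, new


def _shannon_entropy(pixels: np.ndarray, bins: int = 32) -> float:
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return 0.0
    hist, _ = np.histogram(pixels, bins=bins, range=(lo, hi))
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def hc_ec_ratio(
    image: np.ndarray, label_mask: np.ndarray, k_sd: float = 1.0
) -> pd.Series:
    """Per-nucleus heterochromatin-to-euchromatin pixel ratio.

    Within each nucleus, heterochromatin pixels are those brighter than the
    nucleus's own ``mean + k_sd·sd`` (population sd); the ratio is
    ``|HC| / |EC|`` with EC the remaining nucleus pixels.  A nucleus with no
    pixel above threshold (including a constant nucleus) gets ratio 0 by
    convention.
    """
    img = _as_float_image(image)
    lab = np.asarray(label_mask)
    if lab.shape != img.shape:
        raise ValueError("label mask shape does not match image")
    out = {}
    objects = ndi.find_objects(lab.astype(np.int64))
    for lbl, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        px = img[sl][lab[sl] == lbl]
        thr = px.mean() + k_sd * px.std()
        n_hc = int((px > thr).sum())
        n_ec = px.size - n_hc
        out[int(lbl)] = n_hc / n_ec if n_hc > 0 and n_ec > 0 else 0.0
    return pd.Series(out, name="hc_ec_ratio", dtype=float)


def extract_chrometric_features(
    image: np.ndarray,
    label_mask: np.ndarray,
    pixel_size: float = 1.0,
    normalize: bool = True,
    k_sd: float = 1.0,
) -> pd.DataFrame:
    """One row of chrometric features per labeled nucleus.

    Columns: ``nucleus_id`` (index), centroid ``x_um``/``y_um``, a
    ``flagged`` marker, and the 14 features of :data:`FEATURE_NAMES`.
    Labels with fewer than 10 pixels are flagged and their features set to
    missing.  With ``normalize=True`` the image is min–max rescaled to
    [0, 1] before intensity features are measured.
    """
    img = _as_float_image(image)
    lab = np.asarray(label_mask)
    if lab.shape != img.shape:
        raise ValueError("label mask shape does not match image")
    if normalize:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

    hc = hc_ec_ratio(img, lab, k_sd=k_sd)

    rows = []
    for p in regionprops(lab.astype(np.int32), intensity_image=img):
        px = img[p.slice][p.image]
        row = {
            "nucleus_id": int(p.label),
            "x_um": float(p.centroid[1]) * pixel_size,
            "y_um": float(p.centroid[0]) * pixel_size,
            "flagged": px.size < MIN_PIXELS,
        }
        if px.size < MIN_PIXELS:
            row.update({f: np.nan for f in FEATURE_NAMES})
        else:
            p20, p50, p80 = np.percentile(px, [20, 50, 80])  # linear interpolation
            row.update(
                {
                    "min_intensity": float(px.min()),
                    "max_intensity": float(px.max()),
                    "mean_intensity": float(px.mean()),
                    "sd_intensity": float(px.std()),
                    "entropy": _shannon_entropy(px),
                    "p20": float(p20),
                    "p50": float(p50),
                    "p80": float(p80),
                    "ratio_p80_p20": float(p80 / p20) if p20 > 0 else np.nan,
                    "hc_ec_ratio": float(hc.get(int(p.label), 0.0)),
                    "area_um2": float(p.area) * pixel_size**2,
                    "perimeter_um": float(p.perimeter) * pixel_size,
                    "eccentricity": float(p.eccentricity),
                    "solidity": float(p.solidity),
                }
            )
        rows.append(row)
    cols = ["x_um", "y_um", "flagged"] + FEATURE_NAMES
    if not rows:
        return pd.DataFrame(columns=cols).rename_axis("nucleus_id")
    return pd.DataFrame(rows).set_index("nucleus_id")[cols]


def feature_group_test(
    values_a: np.ndarray | pd.Series, values_b: np.ndarray | pd.Series
) -> WelchResult:
    """Welch's unequal-variance t-test between two feature distributions."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values only")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        statistic=float(t),
        pvalue=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=a.size,
        n_b=b.size,
    )
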