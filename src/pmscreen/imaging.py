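"""Fluorescence internal-over-PM ratio quantification.

The endocytosis readout is computed per cell from two concentric ellipses:
the outer one surrounds the whole cell, the inner one delimits the
cytoplasmic interior while excluding the plasma membrane. The PM signal is
the mean pixel intensity over the elliptical annulus (outer minus inner),
the internal signal the mean over the inner ellipse, and the statistic is
their ratio internal/PM — low when a GFP-tagged transporter sits at the PM,
rising as it is internalized toward the vacuole. Per condition the median
ratio with a bootstrap 95% confidence interval is reported, conditions are
compared with two-sided Wilcoxon rank-sum tests, and p-values from a shared
family of comparisons are Holm-adjusted. A synthetic field generator
renders cells with known interior/ring levels for ground-truth testing,
and a convenience detector fits ellipses to thresholded components for
users without hand-drawn ROIs.

Pixel membership is decided by the pixel-center test on a 0-based grid:
pixel (row, col) belongs to an ellipse when the point (x=col, y=row)
satisfies the ellipse inequality. The ratio is invariant under a
multiplicative intensity gain but not under an additive offset (camera
pedestal); images should be dark-level corrected upstream.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Ellipse",
    "EllipsePair",
    "synthesize_field",
    "measure_cell",
    "measure_field",
    "detect_cells",
    "summarize_condition",
    "normalize_to_baseline",
    "wilcoxon_rank_sum",
    "holm_adjust",
    "compare_conditions",
    "read_image",
    "write_image",
    "read_rois",
]


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in image coordinates: center (cx, cy) in pixels with
    x = column and y = row, semi-axes a, b in pixels, rotation theta in
    radians measured from the +x axis toward +y."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"semi-axes must be > 0, got a={self.a}, b={self.b}")

    def quadratic_form(self, x, y):
        """Value of the ellipse inequality at (x, y); <= 1 means inside."""
        dx = np.asarray(x, dtype=float) - self.cx
        dy = np.asarray(y, dtype=float) - self.cy
        c, s = math.cos(self.theta), math.sin(self.theta)
        u = (dx * c + dy * s) / self.a
        v = (-dx * s + dy * c) / self.b
        return u * u + v * v

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
        return self.quadratic_form(cols, rows) <= 1.0

    def boundary(self, n: int = 256) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        c, s = math.cos(self.theta), math.sin(self.theta)
        bx = self.cx + self.a * np.cos(t) * c - self.b * np.sin(t) * s
        by = self.cy + self.a * np.cos(t) * s + self.b * np.sin(t) * c
        return bx, by


@dataclass(frozen=True)
class EllipsePair:
    """Outer (whole-cell) and inner (interior, PM-excluding) ellipses for
    one cell; the inner ellipse must lie strictly inside the outer."""

    cell_id: str
    outer: Ellipse
    inner: Ellipse

    def __post_init__(self) -> None:
        bx, by = self.inner.boundary()
        if not np.all(self.outer.quadratic_form(bx, by) < 1.0):
            raise ValueError(
                f"cell {self.cell_id}: inner ellipse is not strictly contained "
                "in the outer ellipse"
            )


def synthesize_field(cells, noise_sd: float = 0.0, background: float = 0.0,
                     seed: int = 0, shape: tuple[int, int] | None = None):
    """Render a synthetic grayscale field of non-overlapping cells.

    *cells* is a list of ``(EllipsePair, interior_level, ring_level)``.
    Ring pixels (outer∖inner annulus) are set to ``ring_level``, interior
    pixels to ``interior_level``, the rest to ``background``; independent
    Gaussian noise of sd *noise_sd* is added everywhere. Deterministic for
    a fixed seed. Returns ``(image, truth)`` where *truth* is a DataFrame
    with the per-cell ground-truth ratio ``interior_level / ring_level``.
    """
    if not cells:
        raise ValueError("no cells to render")
    for pair, interior, ring in cells:
        if not (interior > background and ring > background):
            raise ValueError(
                f"cell {pair.cell_id}: levels must exceed background "
                f"(interior={interior}, ring={ring}, background={background})"
            )
        if background < 0:
            raise ValueError("background must be >= 0")
    if shape is None:
        pad = 3
        h = max(int(math.ceil(p.outer.cy + max(p.outer.a, p.outer.b))) + pad
                for p, _, _ in cells)
        w = max(int(math.ceil(p.outer.cx + max(p.outer.a, p.outer.b))) + pad
                for p, _, _ in cells)
        shape = (h, w)

    image = np.full(shape, float(background))
    occupied = np.zeros(shape, dtype=bool)
    truth = []
    for pair, interior, ring in cells:
        outer_mask = pair.outer.mask(shape)
        if (outer_mask & occupied).any():
            raise ValueError(f"cell {pair.cell_id} overlaps a previously placed cell")
        occupied |= outer_mask
        inner_mask = pair.inner.mask(shape)
        image[outer_mask & ~inner_mask] = float(ring)
        image[inner_mask] = float(interior)
        truth.append({"cell_id": pair.cell_id,
                      "true_ratio": float(interior) / float(ring)})
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=shape)
    return image, pd.DataFrame(truth)


def measure_cell(image: np.ndarray, pair: EllipsePair,
                 condition: str | None = None, time=None) -> dict:
    """Measure one cell's internal and PM-annulus mean intensities.

    Returns a dict with ``cell_id, condition, time, internal_intensity,
    pm_intensity, ratio``. Errors: ellipses out of the image bounds, an
    empty annulus (inner too close to the outer at pixel resolution), or a
    non-positive PM intensity.
    """
    image = np.asarray(image, dtype=float)
    bx, by = pair.outer.boundary()
    if bx.min() < -0.5 or by.min() < -0.5 or \
            bx.max() > image.shape[1] - 0.5 or by.max() > image.shape[0] - 0.5:
        raise ValueError(f"cell {pair.cell_id}: outer ellipse exceeds image bounds")
    outer_mask = pair.outer.mask(image.shape)
    inner_mask = pair.inner.mask(image.shape)
    annulus = outer_mask & ~inner_mask
    if not inner_mask.any():
        raise ValueError(f"cell {pair.cell_id}: inner ellipse covers no pixel centers")
    if not annulus.any():
        raise ValueError(
            f"cell {pair.cell_id}: annulus contains no pixel centers "
            "(inner ellipse too close to the outer)"
        )
    internal = float(image[inner_mask].mean())
    pm = float(image[annulus].mean())
    if pm <= 0:
        raise ValueError(f"cell {pair.cell_id}: PM intensity must be > 0, got {pm}")
    return {
        "cell_id": pair.cell_id,
        "condition": condition,
        "time": time,
        "internal_intensity": internal,
        "pm_intensity": pm,
        "ratio": internal / pm,
    }


def measure_field(image: np.ndarray, pairs, condition: str | None = None,
                  time=None) -> pd.DataFrame:
    """Measure every cell of a field; returns one row per cell."""
    return pd.DataFrame([measure_cell(image, p, condition, time) for p in pairs])


def detect_cells(image: np.ndarray, threshold_quantile: float = 0.5,
                 min_area: int = 25, pm_margin: float = 2.0) -> list[EllipsePair]:
    """Fit ellipse pairs to bright connected components.

    A convenience stand-in for hand-drawn ROIs: the image is thresholded at
    the given intensity quantile, connected components of at least
    *min_area* pixels are reduced to their second-order-moment ellipses
    (outer), and the inner ellipse is the outer shrunk by *pm_margin*
    pixels on each semi-axis. Deterministic; a blank field yields an empty
    list.
    """
    from skimage import measure as skmeasure

    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        return []
    threshold = float(np.quantile(image, threshold_quantile))
    labels = skmeasure.label(image > threshold)
    pairs: list[EllipsePair] = []
    for region in skmeasure.regionprops(labels):
        if region.area < min_area:
            continue
        cy, cx = region.centroid
        a = region.axis_major_length / 2.0
        b = region.axis_minor_length / 2.0
        if b <= pm_margin + 0.5:
            continue
        # skimage orientation is measured from the row axis; convert to the
        # x-axis convention used by Ellipse.
        theta = math.pi / 2.0 - region.orientation
        outer = Ellipse(cx, cy, a, b, theta)
        inner = Ellipse(cx, cy, a - pm_margin, b - pm_margin, theta)
        pairs.append(EllipsePair(f"cell{len(pairs) + 1}", outer, inner))
    return pairs


def summarize_condition(measurements, n_bootstrap: int = 2000, seed: int = 0,
                        condition: str | None = None) -> dict:
    """Median internal-over-PM ratio with a bootstrap percentile 95% CI.

    *measurements* is a DataFrame with a ``ratio`` column or a plain
    sequence of ratios. The CI is the 2.5–97.5 percentile range of the
    median over *n_bootstrap* seeded resamples.
    """
    if isinstance(measurements, pd.DataFrame):
        ratios = measurements["ratio"].to_numpy(dtype=float)
        if condition is None and "condition" in measurements.columns \
                and measurements["condition"].nunique() == 1:
            condition = measurements["condition"].iloc[0]
    else:
        ratios = np.asarray(measurements, dtype=float)
    if ratios.size == 0:
        raise ValueError("cannot summarize a condition with no cells")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ratios.size, size=(n_bootstrap, ratios.size))
    boot_medians = np.median(ratios[idx], axis=1)
    low, high = np.percentile(boot_medians, [2.5, 97.5])
    return {
        "condition": condition,
        "n_cells": int(ratios.size),
        "median": float(np.median(ratios)),
        "ci_low": float(low),
        "ci_high": float(high),
    }


def normalize_to_baseline(measurements: pd.DataFrame, variant_col: str = "condition",
                          time_col: str = "time", baseline=0) -> pd.DataFrame:
    """Normalize ratios within each variant by its baseline-time median.

    Every ratio is divided by the median ratio of its variant's group at
    ``time == baseline``; a variant without a baseline group is an error.
    Returns a copy with the ``ratio`` column rescaled (the baseline group's
    normalized median is exactly 1).
    """
    out = measurements.copy()
    for variant, grp in out.groupby(variant_col, sort=False):
        base = grp.loc[grp[time_col] == baseline, "ratio"]
        if base.empty:
            raise ValueError(f"variant {variant!r} has no baseline (time={baseline!r}) group")
        out.loc[grp.index, "ratio"] = grp["ratio"] / float(base.median())
    return out


# ---------------------------------------------------------------------------
# Inference: Wilcoxon rank-sum with an exact small-sample path, Holm family
# adjustment.
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 10


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    For both sample sizes <= 10 the permutation null of the rank sum is
    enumerated exhaustively (midranks, so ties are exact); the two-sided
    p-value is ``min(1, 2 * min(P(W <= w), P(W >= w)))``. Larger samples
    use the normal approximation with the tie-corrected variance and no
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = x.size, pooled.size
    w_obs = ranks[:n1].sum()

    if x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N:
        sums = np.fromiter(
            (ranks[list(c)].sum() for c in itertools.combinations(range(n), n1)),
            dtype=float,
        )
        eps = 1e-9
        p_low = np.mean(sums <= w_obs + eps)
        p_high = np.mean(sums >= w_obs - eps)
        return float(min(1.0, 2.0 * min(p_low, p_high)))

    n2 = y.size
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w == 0:
        return 1.0
    z = (w_obs - mean_w) / math.sqrt(var_w)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def compare_conditions(groups: dict, pairs=None) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum comparisons with Holm adjustment.

    *groups* maps a condition label to its ratios; *pairs* restricts the
    family to the requested label pairs (default: all unordered pairs).
    Returns a DataFrame with ``group1, group2, p, p_holm``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for label, values in groups.items():
        if len(np.atleast_1d(values)) == 0:
            raise ValueError(f"group {label!r} is empty")
    if pairs is None:
        pairs = list(itertools.combinations(groups.keys(), 2))
    raw = [wilcoxon_rank_sum(groups[a], groups[b]) for a, b in pairs]
    adj = holm_adjust(raw)
    return pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "p": raw,
        "p_holm": adj,
    })


# ---------------------------------------------------------------------------
# File I/O: 16-bit grayscale images (PNG or TIFF) and ROI tables.
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a grayscale image (PNG via imageio, TIFF via tifffile)."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {img.shape}")
    return img.astype(float)


def write_image(image: np.ndarray, path) -> None:
    """Write an image as 16-bit grayscale, clipping to the uint16 range."""
    data = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 65535).astype(np.uint16)
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def read_rois(path) -> pd.DataFrame:
    """Read an ellipse-pair table (TSV).

    Required columns: ``cell_id, condition, time, outer_cx, outer_cy,
    outer_a, outer_b, outer_theta, inner_cx, inner_cy, inner_a, inner_b,
    inner_theta``. Returns the frame with an ``EllipsePair`` attached per
    row under the ``pair`` column.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["cell_id", "condition", "time"] + [
        f"{which}_{p}" for which in ("outer", "inner")
        for p in ("cx", "cy", "a", "b", "theta")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    df["pair"] = [
        EllipsePair(
            str(row.cell_id),
            Ellipse(row.outer_cx, row.outer_cy, row.outer_a, row.outer_b, row.outer_theta),
            Ellipse(row.inner_cx, row.inner_cy, row.inner_a, row.inner_b, row.inner_theta),
        )
        for row in df.itertuples()
    ]
    return df
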