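"""Embryo-image measurements: orientation, profile extraction, staging.

Mirrors the study's image-processing conventions: embryos are oriented
anterior-left / dorsal-up; embryo length comes from the segmented bounds of
the combined nuclear + FISH background; expression profiles are taken in a
band below the smoothed lower border of the dorsal nuclear layer (robust
local regression), averaged over 100 equal AP regions, self-background
subtracted per embryo, and aggregated to 50 bins; time classes are read
from nuclear length, internuclear distance and the membrane invagination
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import StagingConfig
from .registry import TIME_CLASSES
from .render import EmbryoImage


class SegmentationError(ValueError):
    pass


class ExtractionError(ValueError):
    pass


@dataclass
class OrientedEmbryo:
    """Segmented, anterior-left / dorsal-up embryo with its channels."""

    mask: np.ndarray
    nuclear: np.ndarray
    fish: np.ndarray
    dic: np.ndarray
    pixel_size_um: float
    x0: int
    x1: int  # inclusive AP bounds of the mask, pixels

    @property
    def length_px(self) -> int:
        return self.x1 - self.x0 + 1

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_size_um


@dataclass
class StagingFeatures:
    """Morphological staging features, micrometres / dimensionless."""

    nuclear_length_um: float
    internuclear_um: float
    invagination_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.invagination_ratio < 1.0:
            raise ValueError("invagination_ratio must lie in [0, 1)")


def _segment(image: EmbryoImage) -> np.ndarray:
    combined = image.nuclear_channel + image.fish_channel
    if combined.max() <= 0:
        raise SegmentationError("blank image: no embryo signal")
    mask = combined > 0.05 * combined.max()
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("no embryo component found")
    sizes = ndimage.sum(mask, labels, range(1, n + 1))
    big = sizes > 0.01 * mask.size
    if big.sum() == 0:
        raise SegmentationError("no embryo-sized component found")
    if big.sum() > 1:
        raise SegmentationError(f"{int(big.sum())} embryo-sized components found")
    return labels == (int(np.flatnonzero(big)[0]) + 1)


def orient_embryo(image: EmbryoImage) -> OrientedEmbryo:
    """Segment and orient an embryo image anterior-left, dorsal-up.

    The AP axis is taken horizontal (images are transposed if taller than
    wide); the anterior is the blunter mask end (larger near-tip height), a
    heuristic matching the renderer's geometry; the dorsal side is the one
    holding the nuclear layer.  Idempotent on already-oriented input.
    """
    nuc, fish, dic = (
        image.nuclear_channel, image.fish_channel, image.dic_proxy_channel,
    )
    mask = _segment(image)
    ys, xs = np.nonzero(mask)
    if (ys.max() - ys.min()) > (xs.max() - xs.min()):
        nuc, fish, dic = nuc.T, fish.T, dic.T
        mask = mask.T
        ys, xs = xs, ys
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    heights = np.bincount(xs - x0, minlength=x1 - x0 + 1)
    d = max(3, (x1 - x0 + 1) // 10)
    left_h = heights[:d].mean()
    right_h = heights[-d:].mean()
    if right_h > left_h:  # blunter end on the right -> flip
        nuc, fish, dic = nuc[:, ::-1], fish[:, ::-1], dic[:, ::-1]
        mask = mask[:, ::-1]
        W = mask.shape[1]
        x0, x1 = W - 1 - x1, W - 1 - x0
    cy = (y0 + y1) / 2.0
    ys2, _ = np.nonzero(mask)
    upper = nuc[mask & (np.arange(mask.shape[0])[:, None] < cy)].sum()
    lower = nuc[mask & (np.arange(mask.shape[0])[:, None] >= cy)].sum()
    if lower > upper:  # nuclei ventral -> flip dorsoventrally
        nuc, fish, dic = nuc[::-1], fish[::-1], dic[::-1]
        mask = mask[::-1]
    return OrientedEmbryo(
        mask=np.ascontiguousarray(mask),
        nuclear=np.ascontiguousarray(nuc),
        fish=np.ascontiguousarray(fish),
        dic=np.ascontiguousarray(dic),
        pixel_size_um=image.pixel_size_um,
        x0=x0,
        x1=x1,
    )


def _nuclear_band(oriented: OrientedEmbryo):
    """Per-column lower border of the dorsal nuclear layer (pixel y), raw."""
    nuc = oriented.nuclear
    base = np.median(nuc[oriented.mask])  # cytoplasmic background level
    thresh = base + 0.4 * (nuc.max() - base)
    H = nuc.shape[0]
    cols = np.arange(oriented.x0, oriented.x1 + 1)
    border = np.full(cols.shape, np.nan)
    top_half = H // 2
    for i, x in enumerate(cols):
        col = nuc[:top_half, x]
        idx = np.nonzero(col > thresh)[0]
        if idx.size:
            border[i] = idx.max()
    return cols, border


def dorsal_border(oriented: OrientedEmbryo, frac: float = 0.1) -> np.ndarray:
    """Smoothed lower border of the dorsal nuclear layer, one y per column.

    Robust local regression (lowess with robustifying iterations) over the
    columns where nuclei are seen; missing columns (between nuclei, poles)
    are filled from the fit.
    """
    cols, border = _nuclear_band(oriented)
    ok = ~np.isnan(border)
    if ok.sum() < 10:
        raise ExtractionError("dorsal nuclear layer not found")
    fitted = lowess(
        border[ok], cols[ok].astype(float), frac=frac, it=2,
        return_sorted=False,
    )
    return np.interp(cols.astype(float), cols[ok].astype(float), fitted)


def nuclear_length_px(oriented: OrientedEmbryo) -> float:
    """Median apical-basal nuclear extent: full width at half maximum of
    nuclear blobs above the cytoplasmic base, per blob column."""
    nuc = oriented.nuclear
    base = np.median(nuc[oriented.mask])
    cols, border = _nuclear_band(oriented)
    peaks = _blob_columns(oriented)
    if peaks.size == 0:
        raise ExtractionError("no nuclear blobs found")
    lengths = []
    top_half = nuc.shape[0] // 2
    for x in peaks:
        col = nuc[:top_half, x] - base
        half = 0.5 * col.max()
        lengths.append(int((col > half).sum()))
    return float(np.median(lengths))


def _blob_columns(oriented: OrientedEmbryo) -> np.ndarray:
    """x positions of nuclear blob centres along the dorsal band."""
    from scipy.signal import find_peaks

    nuc = oriented.nuclear
    top_half = nuc.shape[0] // 2
    band = nuc[:top_half, oriented.x0 : oriented.x1 + 1].max(axis=0)
    base = np.median(nuc[oriented.mask])
    peaks, _ = find_peaks(band, height=base + 0.5 * (band.max() - base),
                          distance=3)
    return peaks + oriented.x0


def staging_features(
    oriented: OrientedEmbryo, staging: StagingConfig | None = None
) -> StagingFeatures:
    """Measure nuclear length, internuclear distance and invagination ratio."""
    px = oriented.pixel_size_um
    nl = nuclear_length_px(oriented) * px
    peaks = _blob_columns(oriented)
    if peaks.size < 3:
        raise ExtractionError("too few nuclei for internuclear distance")
    ind = float(np.median(np.diff(peaks))) * px

    # invagination: deepest vertical ridge run in the DIC proxy, relative to
    # the mask half-height at that column
    dic = oriented.dic
    ratio = 0.0
    if dic.max() > 0:
        on = dic > 0.5 * dic.max()
        depths = on.sum(axis=0)
        x_best = int(np.argmax(depths))
        depth = int(depths[x_best])
        col_mask = oriented.mask[:, x_best]
        half_height = col_mask.sum() / 2.0
        if half_height > 0 and depth > 1:
            ratio = min(depth / half_height, 0.999)
    return StagingFeatures(nl, ind, ratio)


def classify_time(
    features: StagingFeatures, staging: StagingConfig | None = None
) -> str:
    """Deterministic time class from staging features.

    nc13 is recognised by short nuclei with large internuclear distance;
    within nc14, T1/T2 are split on nuclear length while invagination is
    absent, and T3..T9 follow the monotone invagination-ratio bins.  Values
    at range edges clamp to the nearest class.
    """
    stg = staging or StagingConfig()
    if (
        features.internuclear_um >= stg.nc13_internuclear_min
        and features.nuclear_length_um <= stg.nc13_nuclear_length_max
    ):
        return "nc13"
    r = features.invagination_ratio
    if r < stg.invagination_onset:
        return "T1" if features.nuclear_length_um < stg.t1_t2_nuclear_length_cut else "T2"
    k = int(np.searchsorted(np.asarray(stg.invagination_bins), r, side="right"))
    return TIME_CLASSES[2 + k]  # bins map to T3..T9


def extract_profile(
    oriented: OrientedEmbryo,
    fish_channel: np.ndarray | None = None,
    n_regions: int = 100,
    n_bins: int = 50,
    lowess_frac: float = 0.1,
) -> np.ndarray:
    """Extract a 50-bin AP expression profile.

    The band from the smoothed dorsal nuclear border to half a nuclear
    length below it is split into ``n_regions`` equal AP regions; region
    means of the FISH channel are background-subtracted by the per-embryo
    minimum region mean, clipped at 0 and aggregated pairwise to
    ``n_bins`` bins.

    Raises
    ------
    ExtractionError
        If the measurement band falls outside the embryo mask over most of
        the AP axis.
    """
    fish = oriented.fish if fish_channel is None else fish_channel
    border = dorsal_border(oriented, frac=lowess_frac)
    nl = nuclear_length_px(oriented)
    H, W = fish.shape
    yy = np.arange(H)[:, None]
    cols = np.arange(oriented.x0, oriented.x1 + 1)
    sub_mask = oriented.mask[:, oriented.x0 : oriented.x1 + 1]
    # near the poles the fitted border extrapolates beyond the curved
    # dorsal edge; clamp the band onto the mask's own dorsal cortex there
    has_col = sub_mask.any(axis=0)
    mask_top = np.where(has_col, sub_mask.argmax(axis=0), np.nan)
    band_top = np.fmax(border, mask_top)
    band = (yy >= band_top[None, :]) & (yy <= band_top[None, :] + 0.5 * nl)
    valid = band & sub_mask
    sub = fish[:, oriented.x0 : oriented.x1 + 1]

    edges = np.linspace(0, cols.size, n_regions + 1).astype(int)
    del cols  # only the per-region edges are used below
    means = np.full(n_regions, np.nan)
    for r in range(n_regions):
        m = valid[:, edges[r] : edges[r + 1]]
        if m.any():
            means[r] = sub[:, edges[r] : edges[r + 1]][m].mean()
    bad = np.isnan(means)
    if bad.mean() > 0.2:
        raise ExtractionError(
            "measurement band lies outside the embryo mask for "
            f"{int(bad.sum())} of {n_regions} AP regions"
        )
    if bad.any():
        idx = np.arange(n_regions)
        means[bad] = np.interp(idx[bad], idx[~bad], means[~bad])
    means = np.clip(means - means.min(), 0.0, None)
    if n_regions % n_bins:
        raise ValueError("n_regions must be a multiple of n_bins")
    k = n_regions // n_bins
    return means.reshape(n_bins, k).mean(axis=1)
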