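"""Percent-mosaicism quantification for one DAB-stained core image.

Pipeline: RGB -> brown (DAB) intensity by color deconvolution -> one global
2-class Otsu cut on the non-background histogram -> a ladder of binary masks
at threshold correction factors 1.5..2.75 (the candidate "strongly positive"
masks) plus one mask at factor 0.5 (all myocytes, any shade of brown) ->
50-px minimum object size filter -> percent positive = 100 * area(selected
positive mask) / area(myocyte mask).

The correction factors multiply the Otsu cut, the threshold-correction
convention of CellProfiler-style pipelines; which factor best isolates the
dark-brown population varies from core to core, so selection is either a
manual per-core index or an automatic separation rule (see
:func:`score_mosaicism`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateImageError,
    ImageFormatError,
    SpecValidationError,
    UnevaluableCoreError,
)
from .stains import rgb_to_concentrations

DEFAULT_FACTORS = tuple(1.5 + 0.125 * k for k in range(11))
MYOCYTE_FACTOR = 0.5


@dataclass(frozen=True)
class QuantConfig:
    """Tunable settings of the quantifier.

    ``background_od_epsilon`` drops near-white pixels (optical density below
    the cut) from the Otsu histogram so empty background cannot dominate the
    class statistics.  ``connectivity`` is 4 or 8 (8 by default, the
    CellProfiler-like choice).  ``brown_mode`` selects the brown-intensity
    definition: ``"deconvolution"`` (two-stain unmixing, default) or
    ``"blue_norm"`` (simple channel arithmetic, for sensitivity analysis).
    """

    factors: Sequence[float] = DEFAULT_FACTORS
    myocyte_factor: float = MYOCYTE_FACTOR
    min_object_size_px: int = 50
    connectivity: int = 8
    background_od_epsilon: float = 0.10
    n_bins: int = 256
    smooth_sigma: float = 0.0
    brown_mode: str = "deconvolution"
    selection: Union[str, int] = "auto"

    def validate(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if f.ndim != 1 or len(f) == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise SpecValidationError(
                "factors must be a strictly increasing positive sequence"
            )
        if self.myocyte_factor <= 0:
            raise SpecValidationError("myocyte_factor must be positive")
        if self.connectivity not in (4, 8):
            raise SpecValidationError("connectivity must be 4 or 8")
        if self.min_object_size_px < 0:
            raise SpecValidationError("min_object_size_px must be nonnegative")
        if self.brown_mode not in ("deconvolution", "blue_norm"):
            raise SpecValidationError("brown_mode must be deconvolution or blue_norm")


@dataclass
class BinaryMask:
    values: np.ndarray  # bool
    correction_factor: float
    base_threshold: float
    min_object_size_px: int = 0  # 0 until the size filter has been applied

    @property
    def area_px(self) -> int:
        return int(self.values.sum())


@dataclass
class MaskSeries:
    myl4_masks: list  # 11 size-filtered BinaryMask, factors 1.5..2.75
    myocyte_mask: BinaryMask  # size-filtered, factor 0.5
    base_threshold: float
    factors: tuple


@dataclass
class MosaicismScore:
    percent_positive: float
    positive_area_px: int
    myocyte_area_px: int
    selected_factor: float
    selection_mode: str  # "manual_index" or "auto_rule"
    base_threshold: float = float("nan")
    qc_flags: list = field(default_factory=list)


def _skimage_connectivity(connectivity: int) -> int:
    return 2 if connectivity == 8 else 1


def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"expected an RGB image (H, W, 3); got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ImageFormatError("expected an 8-bit RGB image")
    return arr


def compute_brown_intensity(rgb: np.ndarray, config: QuantConfig = QuantConfig()) -> np.ndarray:
    """Per-pixel DAB (brown) intensity map, nonnegative floats.

    Pure white maps to ~0; an all-black image is rejected as degenerate.
    """
    arr = _check_rgb(rgb)
    if arr.max() == 0:
        raise DegenerateImageError("all-black image carries no stain information")
    if config.brown_mode == "deconvolution":
        dab = rgb_to_concentrations(arr)[..., 1]
    else:  # blue-normalized brown: DAB absorbs blue, hematoxylin absorbs red
        a = arr.astype(float)
        dab = (a[..., 0] - a[..., 2]) / 255.0
    intensity = np.clip(dab, 0.0, None)
    if config.smooth_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, config.smooth_sigma)
    return intensity


def apply_manual_exclusion(rgb: np.ndarray, exclusion_mask: Optional[np.ndarray]) -> np.ndarray:
    """Paint manually excluded regions white so they are ignored downstream.

    Mirrors manual erasure of non-myocyte regions (vessels, adipose,
    fibrosis): white pixels carry zero optical density, so they drop out of
    the histogram, every mask, and every area count.
    """
    arr = _check_rgb(rgb)
    if exclusion_mask is None:
        return arr
    excl = np.asarray(exclusion_mask)
    if excl.shape != arr.shape[:2]:
        raise ImageFormatError(
            f"exclusion mask shape {excl.shape} does not match image {arr.shape[:2]}"
        )
    out = arr.copy()
    out[excl.astype(bool)] = 255
    return out


def _as_bool_exclusion(exclusion_mask, shape):
    if exclusion_mask is None:
        return np.zeros(shape, dtype=bool)
    excl = np.asarray(exclusion_mask)
    if excl.shape != shape:
        raise ImageFormatError(
            f"exclusion mask shape {excl.shape} does not match map {shape}"
        )
    return excl.astype(bool)


def otsu_base_threshold(
    intensity_map: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
    config: QuantConfig = QuantConfig(),
) -> float:
    """Global 2-class Otsu cut over a 256-bin histogram of candidate pixels.

    Candidates are non-excluded pixels with intensity at or above the
    background epsilon.  The returned threshold is the lower edge of the
    first bin of the upper class; among equally good cuts the lowest wins.
    """
    imap = np.asarray(intensity_map, dtype=float)
    excl = _as_bool_exclusion(exclusion_mask, imap.shape)
    vals = imap[~excl & np.isfinite(imap) & (imap >= config.background_od_epsilon)]
    if vals.size < 2 or np.ptp(vals) == 0.0:
        raise DegenerateImageError(
            "intensity histogram is degenerate (constant or empty); core unevaluable"
        )
    counts, edges = np.histogram(vals, bins=config.n_bins, range=(vals.min(), vals.max()))
    counts = counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    s0 = np.cumsum(counts * centers)[:-1]
    s1 = (counts * centers).sum() - s0
    # one canonical cut per partition: the cut must close a non-empty bin,
    # otherwise sliding across empty bins yields duplicate partitions whose
    # float scores differ only by rounding noise
    valid = (w0 > 0) & (w1 > 0) & (counts[:-1] > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        between = np.where(valid, w0 * w1 * (s0 / w0 - s1 / w1) ** 2, -np.inf)
    k = int(np.argmax(between))  # first (lowest) maximizing cut
    if not np.isfinite(between[k]):
        raise DegenerateImageError("histogram collapsed into a single bin")
    return float(edges[k + 1])


def build_mask(
    intensity_map: np.ndarray,
    base_threshold: float,
    correction_factor: float,
    exclusion_mask: Optional[np.ndarray] = None,
) -> BinaryMask:
    """Threshold at ``correction_factor * base_threshold`` (no size filter)."""
    if correction_factor <= 0:
        raise SpecValidationError("correction_factor must be positive")
    if base_threshold <= 0:
        raise SpecValidationError("base_threshold must be positive")
    imap = np.asarray(intensity_map, dtype=float)
    excl = _as_bool_exclusion(exclusion_mask, imap.shape)
    values = (imap >= correction_factor * base_threshold) & ~excl
    return BinaryMask(values=values, correction_factor=float(correction_factor),
                      base_threshold=float(base_threshold))


def filter_small_objects(mask: BinaryMask, min_size_px: int = 50,
                         connectivity: int = 8) -> BinaryMask:
    """Drop connected components smaller than ``min_size_px`` pixels.

    Components with exactly ``min_size_px`` pixels are kept.
    """
    if min_size_px <= 1:
        filtered = mask.values.copy()
    else:
        structure = ndimage.generate_binary_structure(2, _skimage_connectivity(connectivity))
        labels, _ = ndimage.label(mask.values.astype(bool), structure=structure)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size_px
        keep[0] = False
        filtered = keep[labels]
    return BinaryMask(values=filtered, correction_factor=mask.correction_factor,
                      base_threshold=mask.base_threshold,
                      min_object_size_px=min_size_px)


def generate_mask_series(
    intensity_map: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
    config: QuantConfig = QuantConfig(),
) -> MaskSeries:
    """All 11 size-filtered positive masks plus the all-myocyte mask."""
    config.validate()
    base = otsu_base_threshold(intensity_map, exclusion_mask, config)
    myl4 = [
        filter_small_objects(
            build_mask(intensity_map, base, f, exclusion_mask),
            config.min_object_size_px, config.connectivity,
        )
        for f in config.factors
    ]
    myocyte = filter_small_objects(
        build_mask(intensity_map, base, config.myocyte_factor, exclusion_mask),
        config.min_object_size_px, config.connectivity,
    )
    return MaskSeries(myl4_masks=myl4, myocyte_mask=myocyte,
                      base_threshold=base, factors=tuple(config.factors))


def _auto_select(series: MaskSeries, intensity_map: np.ndarray,
                 connectivity: int) -> tuple:
    """Pick the factor whose mask best separates dark objects from the rest.

    The myocyte mask is labelled into objects; a factor "captures" an object
    when it covers at least half of its area.  The factor maximizing the gap
    between the dimmest captured object mean and the brightest uncaptured
    object mean wins; ties go to the lowest factor.
    """
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n_obj = ndimage.label(series.myocyte_mask.values, structure=structure)
    if n_obj == 0:
        return 0, ["no_myocyte_objects"]
    idx = np.arange(1, n_obj + 1)
    obj_means = ndimage.mean(np.asarray(intensity_map, float), labels, idx)
    best_gap, best_i = -np.inf, None
    for i, mask in enumerate(series.myl4_masks):
        coverage = ndimage.mean(mask.values.astype(float), labels, idx)
        captured = coverage >= 0.5
        if not captured.any():
            continue
        inside = obj_means[captured].min()
        outside = obj_means[~captured].max() if (~captured).any() else 0.0
        gap = inside - outside
        if gap > best_gap:
            best_gap, best_i = gap, i
    if best_i is None:
        return 0, ["all_positive_masks_empty"]
    return best_i, []


def score_mosaicism(
    series: MaskSeries,
    selection: Union[str, int] = "auto",
    intensity_map: Optional[np.ndarray] = None,
    connectivity: int = 8,
) -> MosaicismScore:
    """Area-ratio mosaicism statistic from a mask series.

    ``selection`` is either ``"auto"`` (automatic separation rule; requires
    the intensity map) or an integer index into the factor ladder,
    reproducing the manual blinded choice of the original workflow.
    """
    myo_area = series.myocyte_mask.area_px
    if myo_area == 0:
        raise UnevaluableCoreError("zero myocyte area; core unevaluable")
    qc: list = []
    if isinstance(selection, int):
        if not (0 <= selection < len(series.myl4_masks)):
            raise SpecValidationError(
                f"manual index {selection} outside 0..{len(series.myl4_masks) - 1}"
            )
        i, mode = selection, "manual_index"
    elif selection == "auto":
        if intensity_map is None:
            raise SpecValidationError("auto selection requires the intensity map")
        i, qc = _auto_select(series, intensity_map, connectivity)
        mode = "auto_rule"
    else:
        raise SpecValidationError("selection must be 'auto' or an integer index")
    pos_area = series.myl4_masks[i].area_px
    return MosaicismScore(
        percent_positive=100.0 * pos_area / myo_area,
        positive_area_px=pos_area,
        myocyte_area_px=myo_area,
        selected_factor=series.factors[i],
        selection_mode=mode,
        base_threshold=series.base_threshold,
        qc_flags=qc,
    )


def quantify_core(
    rgb: np.ndarray,
    exclusion_mask: Optional[np.ndarray] = None,
    config: QuantConfig = QuantConfig(),
) -> MosaicismScore:
    """Full single-core pipeline: image (+ optional exclusions) to score."""
    config.validate()
    cleaned = apply_manual_exclusion(rgb, exclusion_mask)
    intensity = compute_brown_intensity(cleaned, config)
    excl = exclusion_mask if exclusion_mask is None else np.asarray(exclusion_mask).astype(bool)
    series = generate_mask_series(intensity, excl, config)
    return score_mosaicism(series, config.selection, intensity, config.connectivity)
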