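"""Ground-truthed synthetic IHC cores and multi-TMA cohorts.

The image generator emulates the phenomenology of mosaic DAB staining in
ventricular myocardium: a minority of cell-sized blobs render with dark
brown (high DAB optical density), the remainder with faint "blush" DAB on a
hematoxylin background; small dark debris specks and unstained vessel-shaped
holes are added.  Every rendered pixel is bookkept, so the ground truth is
the exact pixel count of what was drawn, not the requested fraction.

The cohort generator emulates a multi-TMA autopsy study with repeated cores
per subject: a square-root-scale linear model with crossed subject and TMA
random intercepts produces a per-core positive fraction, which is squared
back to a percent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CapacityError, SpecValidationError
from .stains import concentrations_to_rgb

# pixel-level DAB texture noise (OD units), truncated at +/- 3 SD so the
# blush / dark-brown intensity populations stay separated
PIXEL_NOISE_SD = 0.01
# per-myocyte intensity draws truncated at +/- 2 SD (same reason)
CELL_TRUNC_SD = 2.0
# debris rendered at this DAB OD (as dark as positive cells)
DEBRIS_DAB_OD = 0.90
# fraction of replicated subjects contributing three cores instead of two
TRIPLE_REPLICATE_SHARE = 4.0 / 82.0


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic TMA-core image."""

    width_px: int = 384
    height_px: int = 384
    n_myocytes: int = 90
    true_mosaic_fraction: float = 0.15
    myocyte_area_px_mean: float = 700.0
    myocyte_area_px_sd: float = 180.0
    dab_pos_intensity_mean: float = 0.95
    dab_neg_intensity_mean: float = 0.32
    dab_intensity_sd: float = 0.025
    hematoxylin_intensity_mean: float = 0.45
    n_debris: int = 12
    debris_area_px_max: int = 20
    n_vessels: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.true_mosaic_fraction <= 1.0):
            raise SpecValidationError("true_mosaic_fraction must be in [0, 1]")
        if self.dab_pos_intensity_mean <= self.dab_neg_intensity_mean:
            raise SpecValidationError(
                "dab_pos_intensity_mean must exceed dab_neg_intensity_mean"
            )
        if not (0.0 < self.dab_pos_intensity_mean):
            raise SpecValidationError("dab_pos_intensity_mean must be positive")
        if self.dab_neg_intensity_mean < 0.0:
            raise SpecValidationError("dab_neg_intensity_mean must be nonnegative")
        if self.dab_intensity_sd < 0.0:
            raise SpecValidationError("dab_intensity_sd must be nonnegative")
        if self.myocyte_area_px_mean <= 0.0:
            raise SpecValidationError("myocyte_area_px_mean must be positive")
        if self.myocyte_area_px_sd < 0.0:
            raise SpecValidationError("myocyte_area_px_sd must be nonnegative")
        if not (0.0 <= self.hematoxylin_intensity_mean <= 1.0):
            raise SpecValidationError("hematoxylin_intensity_mean must be in [0, 1]")
        for name in ("width_px", "height_px"):
            if getattr(self, name) < 32:
                raise SpecValidationError(f"{name} must be at least 32")
        for name in ("n_myocytes", "n_debris", "n_vessels", "debris_area_px_max"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be nonnegative")


@dataclass
class CoreGroundTruth:
    """Exact pixel bookkeeping of one rendered core."""

    true_mosaic_percent: float
    true_positive_area_px: int
    true_myocyte_area_px: int
    myocyte_labels: np.ndarray  # int32, 0 = no myocyte, 1..n myocyte ids
    positive_flags: np.ndarray  # bool per myocyte (index = label - 1)
    per_myocyte_area_px: np.ndarray  # int per myocyte


def _truncnorm(rng: np.random.Generator, mean, sd, trunc, size=None):
    draw = rng.normal(0.0, 1.0, size=size)
    return mean + sd * np.clip(draw, -trunc, trunc)


def _choose_positive(areas: np.ndarray, fraction: float, rng: np.random.Generator):
    """Pick a myocyte subset whose total area best matches the target fraction.

    Greedy fill in random order, then a single-swap / single-add refinement
    pass; with cell areas far below the total this lands within one small
    cell of the target.
    """
    total = int(areas.sum())
    target = fraction * total
    order = rng.permutation(len(areas))
    chosen = np.zeros(len(areas), dtype=bool)
    s = 0
    for i in order:
        if s + areas[i] <= target:
            chosen[i] = True
            s += areas[i]
    improved = True
    while improved:
        improved = False
        err = abs(s - target)
        # try single additions
        for i in np.flatnonzero(~chosen):
            if abs(s + areas[i] - target) < err:
                chosen[i] = True
                s += areas[i]
                err = abs(s - target)
                improved = True
        # try single swaps
        for i in np.flatnonzero(chosen):
            for j in np.flatnonzero(~chosen):
                if abs(s - areas[i] + areas[j] - target) < err:
                    chosen[i] = False
                    chosen[j] = True
                    s = s - areas[i] + areas[j]
                    err = abs(s - target)
                    improved = True
                    break
    if fraction >= 1.0:
        chosen[:] = True
    if fraction <= 0.0:
        chosen[:] = False
    return chosen


def _window(cy, cx, half, H, W):
    """Clamped raster window around (cy, cx); the ellipse placement logic
    guarantees the shape itself stays inside the image."""
    y0 = max(0, int(cy - half))
    y1 = min(H, int(cy + half) + 1)
    x0 = max(0, int(cx - half))
    x1 = min(W, int(cx + half) + 1)
    return y0, y1, x0, x1


def _ellipse_mask(h, w, cy, cx, a, b, theta):
    """Boolean raster of a rotated ellipse inside an (h, w) window."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_core_image(spec: ImageSpec):
    """Render one synthetic core.

    Returns ``(rgb_image, ground_truth, exclusion_mask)`` where the RGB image
    is 8-bit, the exclusion mask is uint8 (0 = keep, 255 = exclude, marking
    vessel regions) and the ground truth counts exactly the rendered pixels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px

    inset = 4
    n_slots_needed = spec.n_myocytes + spec.n_vessels
    if n_slots_needed == 0:
        pitch = min(H, W) - 2 * inset
    else:
        pitch = int(np.floor(np.sqrt((W - 2 * inset) * (H - 2 * inset) / n_slots_needed)))
    # floor division can leave too few whole grid cells; shrink until it fits
    while pitch >= 8:
        cols = (W - 2 * inset) // pitch
        rows = (H - 2 * inset) // pitch
        if rows * cols >= n_slots_needed:
            break
        pitch -= 1
    if pitch < 8:
        raise CapacityError(
            f"image {W}x{H} too small to place {spec.n_myocytes} myocytes "
            f"and {spec.n_vessels} vessels"
        )
    axis_cap = pitch / 2.0 - 2.0

    slots = [(r, c) for r in range(rows) for c in range(cols)]
    slot_order = rng.permutation(len(slots))

    labels = np.zeros((H, W), dtype=np.int32)
    vessel_mask = np.zeros((H, W), dtype=bool)

    # vessels first: thin elongated unstained holes
    for k in range(spec.n_vessels):
        r, c = slots[slot_order[k]]
        cy0 = inset + r * pitch + pitch / 2 + rng.uniform(-1, 1)
        cx0 = inset + c * pitch + pitch / 2 + rng.uniform(-1, 1)
        a = axis_cap
        b = max(2.0, axis_cap / rng.uniform(3.0, 5.0))
        theta = rng.uniform(0, np.pi)
        y0, y1, x0, x1 = _window(cy0, cx0, pitch / 2, H, W)
        m = _ellipse_mask(y1 - y0, x1 - x0, cy0 - y0, cx0 - x0, a, b, theta)
        vessel_mask[y0:y1, x0:x1] |= m

    # myocytes: convex elliptical blobs, one per grid slot, no overlap
    areas_req = np.clip(
        rng.normal(spec.myocyte_area_px_mean, spec.myocyte_area_px_sd, spec.n_myocytes),
        300.0,
        3000.0,
    )
    for k in range(spec.n_myocytes):
        r, c = slots[slot_order[spec.n_vessels + k]]
        e = rng.uniform(1.0, 1.6)
        a0 = np.sqrt(areas_req[k] * e / np.pi)
        b0 = np.sqrt(areas_req[k] / (e * np.pi))
        scale = min(1.0, axis_cap / a0)
        a, b = a0 * scale, b0 * scale
        theta = rng.uniform(0, np.pi)
        slack = max(0.0, pitch / 2.0 - a - 1.0)
        cy0 = inset + r * pitch + pitch / 2 + rng.uniform(-slack, slack)
        cx0 = inset + c * pitch + pitch / 2 + rng.uniform(-slack, slack)
        y0, y1, x0, x1 = _window(cy0, cx0, pitch / 2, H, W)
        m = _ellipse_mask(y1 - y0, x1 - x0, cy0 - y0, cx0 - x0, a, b, theta)
        block = labels[y0:y1, x0:x1]
        block[m] = k + 1

    areas = np.bincount(labels.ravel(), minlength=spec.n_myocytes + 1)[1:].astype(np.int64)
    if spec.n_myocytes and areas.min() == 0:  # pragma: no cover - defensive
        raise CapacityError("a myocyte rasterized to zero pixels; enlarge the image")

    flags = _choose_positive(areas, spec.true_mosaic_fraction, rng)

    # debris: dark specks strictly below the size filter by default, placed
    # with 1-px clearance from myocytes so components never merge
    debris_mask = np.zeros((H, W), dtype=bool)
    if spec.n_debris > 0 and spec.debris_area_px_max >= 1:
        occupied = labels > 0
        # 8-neighborhood dilation by one pixel
        dil = occupied.copy()
        dil[1:, :] |= occupied[:-1, :]
        dil[:-1, :] |= occupied[1:, :]
        dil[:, 1:] |= occupied[:, :-1]
        dil[:, :-1] |= occupied[:, 1:]
        dil[1:, 1:] |= occupied[:-1, :-1]
        dil[:-1, :-1] |= occupied[1:, 1:]
        dil[1:, :-1] |= occupied[:-1, 1:]
        dil[:-1, 1:] |= occupied[1:, :-1]
        placed = 0
        attempts = 0
        while placed < spec.n_debris and attempts < 50 * max(1, spec.n_debris):
            attempts += 1
            area = rng.integers(3, spec.debris_area_px_max + 1)
            rad = max(1.0, np.sqrt(area / np.pi))
            cy0 = rng.uniform(rad + 1, H - rad - 2)
            cx0 = rng.uniform(rad + 1, W - rad - 2)
            y0, y1 = int(cy0 - rad) - 1, int(cy0 + rad) + 2
            x0, x1 = int(cx0 - rad) - 1, int(cx0 + rad) + 2
            m = _ellipse_mask(y1 - y0, x1 - x0, cy0 - y0, cx0 - x0, rad, rad, 0.0)
            if m.sum() > spec.debris_area_px_max:
                continue
            window_clear = ~(dil[y0:y1, x0:x1] | vessel_mask[y0:y1, x0:x1])
            if np.all(window_clear[m]):
                debris_mask[y0:y1, x0:x1] |= m
                placed += 1

    # stain amounts
    h_conc = np.full((H, W), spec.hematoxylin_intensity_mean, dtype=float)
    h_conc += np.clip(rng.normal(0.0, 0.03, (H, W)), -0.09, 0.09)
    h_conc = np.clip(h_conc, 0.0, None)

    cell_dab = np.where(
        flags,
        _truncnorm(rng, spec.dab_pos_intensity_mean, spec.dab_intensity_sd,
                   CELL_TRUNC_SD, spec.n_myocytes),
        _truncnorm(rng, spec.dab_neg_intensity_mean, spec.dab_intensity_sd,
                   CELL_TRUNC_SD, spec.n_myocytes),
    )
    d_conc = np.zeros((H, W), dtype=float)
    if spec.n_myocytes:
        d_conc[labels > 0] = cell_dab[labels[labels > 0] - 1]
    d_conc[debris_mask] = DEBRIS_DAB_OD
    d_conc += np.clip(rng.normal(0.0, PIXEL_NOISE_SD, (H, W)), -3 * PIXEL_NOISE_SD,
                      3 * PIXEL_NOISE_SD)
    d_conc = np.clip(d_conc, 0.0, None)

    # vessels are unstained holes
    h_conc[vessel_mask] = 0.0
    d_conc[vessel_mask] = 0.0
    labels[vessel_mask] = 0

    # recount after vessel carving (vessels were placed first and never
    # overlap myocyte slots, but keep the bookkeeping authoritative)
    areas = np.bincount(labels.ravel(), minlength=spec.n_myocytes + 1)[1:].astype(np.int64)
    total_area = int(areas.sum())
    pos_area = int(areas[flags].sum())

    conc = np.stack([h_conc, d_conc, np.zeros_like(h_conc)], axis=-1)
    rgb = concentrations_to_rgb(conc)

    exclusion = np.where(vessel_mask, 255, 0).astype(np.uint8)
    percent = 100.0 * pos_area / total_area if total_area else 0.0
    gt = CoreGroundTruth(
        true_mosaic_percent=percent,
        true_positive_area_px=pos_area,
        true_myocyte_area_px=total_area,
        myocyte_labels=labels,
        positive_flags=flags,
        per_myocyte_area_px=areas,
    )
    return rgb, gt, exclusion


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: disease strata and cohort shares, pediatric stratum excluded (ages >= 18)
DISEASE_PREVALENCE = {
    "Control": 245,
    "SCD + CAD - Thrombosis": 118,
    "SCD - CAD": 85,
    "SCD + CAD + Thrombosis": 70,
    "HCM": 55,
    "DCM": 41,
    "IHD": 34,
    "ACM": 9,
    "Other": 14,
}

#: square-root-scale disease shifts used as generator defaults
DEFAULT_DISEASE_EFFECTS = {
    "SCD + CAD - Thrombosis": 0.011,
    "SCD - CAD": -0.049,
    "SCD + CAD + Thrombosis": -0.031,
    "HCM": 0.21,
    "ACM": -0.028,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic multi-TMA cohort."""

    n_subjects: int = 668
    n_tmas: int = 5
    replicate_core_probability: float = 82.0 / 668.0
    sex_effect_sqrt_scale: float = 0.097
    age_effect_sqrt_scale: float = -0.00013
    disease_effects_sqrt_scale: dict = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_EFFECTS)
    )
    intercept_sqrt_scale: float = 0.29
    subject_sd: float = 0.08
    tma_sd: float = 0.02
    residual_sd: float = 0.045
    sex_ratio_male: float = 0.692
    age_mean_sd: tuple = (54.7, 16.4)
    seed: int = 0

    def validate(self) -> None:
        for name in ("subject_sd", "tma_sd", "residual_sd"):
            if getattr(self, name) < 0.0:
                raise SpecValidationError(f"{name} must be nonnegative")
        for name in ("replicate_core_probability", "sex_ratio_male"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise SpecValidationError(f"{name} must be in [0, 1]")
        if self.n_subjects < 1:
            raise SpecValidationError("n_subjects must be at least 1")
        if self.n_tmas < 1:
            raise SpecValidationError("n_tmas must be at least 1")


def generate_cohort(spec: CohortSpec, noise_sign: int = 1) -> pd.DataFrame:
    """Simulate one cohort table, one row per core.

    ``noise_sign`` = -1 negates every random-effect and residual draw while
    keeping all covariates identical — antithetic pairing for Monte-Carlo
    variance reduction in recovery studies; +1 is a plain draw.
    """
    spec.validate()
    if noise_sign not in (-1, 1):
        raise SpecValidationError("noise_sign must be +1 or -1")
    rng_cov = np.random.default_rng(spec.seed)
    rng_noise = np.random.default_rng((spec.seed + 987_654_321) % 2**31)

    n = spec.n_subjects
    diseases = np.array(list(DISEASE_PREVALENCE))
    probs = np.array(list(DISEASE_PREVALENCE.values()), dtype=float)
    probs /= probs.sum()

    male = rng_cov.random(n) < spec.sex_ratio_male
    age = np.clip(rng_cov.normal(*spec.age_mean_sd, n), 18.0, 95.0)
    disease = rng_cov.choice(diseases, size=n, p=probs)
    ethnicity = np.where(rng_cov.random(n) < 0.608, "Caucasian", "Other")
    heart_weight = np.exp(rng_cov.normal(6.0, 0.25, n))
    hw_missing = rng_cov.random(n) < 308.0 / 756.0
    bmi = np.exp(rng_cov.normal(3.28, 0.18, n))
    bmi_missing = rng_cov.random(n) < 0.10
    home_tma = rng_cov.integers(1, spec.n_tmas + 1, n)
    replicated = rng_cov.random(n) < spec.replicate_core_probability
    triple = replicated & (rng_cov.random(n) < TRIPLE_REPLICATE_SHARE)
    n_cores = np.where(triple, 3, np.where(replicated, 2, 1))

    u_subject = noise_sign * rng_noise.normal(0.0, spec.subject_sd, n)
    v_tma = noise_sign * rng_noise.normal(0.0, spec.tma_sd, spec.n_tmas)
    d_eff = np.array(
        [spec.disease_effects_sqrt_scale.get(d, 0.0) for d in disease]
    )

    rows = []
    for i in range(n):
        subj_mean = (
            spec.intercept_sqrt_scale
            + spec.sex_effect_sqrt_scale * male[i]
            + spec.age_effect_sqrt_scale * age[i]
            + d_eff[i]
            + u_subject[i]
        )
        for j in range(n_cores[i]):
            if j == 0 or rng_cov.random() < 0.5:
                tma = home_tma[i]
            else:
                tma = int(rng_cov.integers(1, spec.n_tmas + 1))
            eps = noise_sign * rng_noise.normal(0.0, spec.residual_sd)
            s = np.clip(subj_mean + v_tma[tma - 1] + eps, 0.0, 1.0)
            rows.append(
                {
                    "core_id": f"S{i:04d}C{j}",
                    "subject_id": f"S{i:04d}",
                    "tma_id": int(tma),
                    "sex": "male" if male[i] else "female",
                    "age": float(age[i]),
                    "ethnicity": ethnicity[i],
                    "disease": disease[i],
                    "site": "septum" if rng_cov.random() < 0.15 else "left_ventricle",
                    "heart_weight": np.nan if hw_missing[i] else float(heart_weight[i]),
                    "bmi": np.nan if bmi_missing[i] else float(bmi[i]),
                    "unevaluable": False,
                    "true_percent": float(100.0 * s**2),
                }
            )
    return pd.DataFrame(rows)


def core_seed(master_seed: int, core_id: str) -> int:
    """Deterministic per-core seed: CRC-32 of ``"{master_seed}:{core_id}"``."""
    return zlib.crc32(f"{master_seed}:{core_id}".encode()) & 0x7FFFFFFF


def render_cohort_images(cohort: pd.DataFrame, base_spec: ImageSpec):
    """Render each cohort core with its table percent as the target fraction.

    Returns ``{core_id: (rgb, ground_truth, exclusion_mask)}``.  Per-core
    seeds derive from ``(base_spec.seed, core_id)`` so the set is fully
    reproducible and insensitive to row order.
    """
    if cohort["core_id"].duplicated().any():
        dupes = cohort.loc[cohort["core_id"].duplicated(), "core_id"].tolist()
        raise SpecValidationError(f"duplicate core ids: {dupes}")
    out = {}
    for _, row in cohort.iterrows():
        spec = replace(
            base_spec,
            true_mosaic_fraction=float(row["true_percent"]) / 100.0,
            seed=core_seed(base_spec.seed, str(row["core_id"])),
        )
        out[str(row["core_id"])] = generate_core_image(spec)
    return out


def plant_exclusions(
    cohort: pd.DataFrame,
    n_minor_subjects: int = 8,
    n_problem_rows: int = 23,
    seed: int = 0,
) -> pd.DataFrame:
    """Inject exclusion-rule targets into a cohort copy.

    ``n_minor_subjects`` whole subjects are aged below 18; among the
    remaining rows, ``n_problem_rows`` are made unusable (missing sex,
    missing age, or flagged unevaluable, cycling through the three reasons).
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    subjects = out["subject_id"].unique()
    if len(subjects) < n_minor_subjects:
        raise SpecValidationError("not enough subjects to plant minors")
    minors = rng.choice(subjects, size=n_minor_subjects, replace=False)
    out.loc[out["subject_id"].isin(minors), "age"] = rng.uniform(
        1.0, 17.0, size=int(out["subject_id"].isin(minors).sum())
    )
    eligible = out.index[~out["subject_id"].isin(minors)]
    if len(eligible) < n_problem_rows:
        raise SpecValidationError("not enough rows to plant problems")
    out["sex"] = out["sex"].astype(object)
    problem = rng.choice(eligible, size=n_problem_rows, replace=False)
    for k, idx in enumerate(problem):
        reason = k % 3
        if reason == 0:
            out.loc[idx, "sex"] = np.nan
        elif reason == 1:
            out.loc[idx, "age"] = np.nan
        else:
            out.loc[idx, "unevaluable"] = True
    return out
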