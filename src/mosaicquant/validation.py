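"""Concordance and reproducibility checks for the area-based score.

Three analyses mirror the original QC workflow: (1) Pearson correlation of
the area-based percent against blinded manual cell counting on a handful of
cores; (2) average variation between replicate cores taken from the same
heart; (3) a paired comparison of positive vs negative cell areas, testing
whether strongly stained myocytes are simply larger (they should not be, or
the area ratio would be a biased estimate of the cell-count fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, SpecValidationError, UndefinedCorrelationError


@dataclass(frozen=True)
class ManualCount:
    """Blinded per-core cell count (the comparator method)."""

    core_id: str
    n_positive_cells: int
    n_total_cells: int

    def __post_init__(self):
        if self.n_total_cells <= 0:
            raise SpecValidationError("n_total_cells must be positive")
        if not (0 <= self.n_positive_cells <= self.n_total_cells):
            raise SpecValidationError(
                "n_positive_cells must be between 0 and n_total_cells"
            )

    @property
    def percent_positive_cells(self) -> float:
        return 100.0 * self.n_positive_cells / self.n_total_cells


@dataclass(frozen=True)
class ReplicateSet:
    """Two or three per-core scores from the same subject."""

    subject_id: str
    core_scores: tuple

    def __post_init__(self):
        if len(self.core_scores) not in (2, 3):
            raise SpecValidationError(
                f"subject {self.subject_id}: replicate sets need 2 or 3 cores, "
                f"got {len(self.core_scores)}"
            )


@dataclass(frozen=True)
class PairedAreas:
    """Cell areas of positive vs negative myocytes within one core."""

    core_id: str
    areas_positive: tuple
    areas_negative: tuple

    def __post_init__(self):
        if len(self.areas_positive) == 0 or len(self.areas_negative) == 0:
            raise SpecValidationError(
                f"core {self.core_id}: both area groups must be non-empty"
            )


@dataclass
class CellAreaResult:
    t_statistic: float
    p_value: float
    df: int
    mean_difference: float
    per_core_difference: Dict[str, float]
    mode: str


def manual_vs_area_correlation(manual: Sequence[ManualCount], scores) -> dict:
    """Pearson r between manual percent-positive cells and area percent.

    ``scores`` maps core_id -> area percent (a dict, or any iterable of
    objects with ``core_id``-keyed access handled by the caller).  Cores are
    matched by id; unmatched ids on either side are reported, not an error.
    """
    by_id = dict(scores)
    matched = [(m.percent_positive_cells, by_id[m.core_id]) for m in manual
               if m.core_id in by_id]
    unmatched_manual = [m.core_id for m in manual if m.core_id not in by_id]
    manual_ids = {m.core_id for m in manual}
    unmatched_scores = [k for k in by_id if k not in manual_ids]
    if len(matched) < 3:
        raise InsufficientDataError(
            f"need at least 3 matched cores, got {len(matched)}"
        )
    x = np.array([m[0] for m in matched])
    y = np.array([m[1] for m in matched])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the score vectors")
    r = float(stats.pearsonr(x, y).statistic)
    return {
        "r": r,
        "n": len(matched),
        "unmatched_manual": unmatched_manual,
        "unmatched_scores": unmatched_scores,
    }


def replicate_variation(replicates: Sequence[ReplicateSet], mode: str = "pairwise") -> dict:
    """Average variation in percent staining between replicate cores.

    ``mode='pairwise'`` (default): per subject, the mean absolute difference
    over all core pairs; ``mode='range'``: max minus min.  Returns the
    across-subject mean plus the per-subject values.
    """
    if mode not in ("pairwise", "range"):
        raise SpecValidationError("mode must be 'pairwise' or 'range'")
    if len(replicates) == 0:
        raise InsufficientDataError("no replicate sets supplied")
    per_subject = {}
    for rep in replicates:
        scores = np.asarray(rep.core_scores, dtype=float)
        if mode == "pairwise":
            diffs = [abs(a - b) for a, b in combinations(scores, 2)]
            per_subject[rep.subject_id] = float(np.mean(diffs))
        else:
            per_subject[rep.subject_id] = float(scores.max() - scores.min())
    return {
        "mean_variation": float(np.mean(list(per_subject.values()))),
        "per_subject": per_subject,
        "mode": mode,
    }


def compare_cell_areas(paired: Sequence[PairedAreas], mode: str = "paired_core_means") -> CellAreaResult:
    """Do positive cells differ in size from negative cells?

    Default pairs at the core level: per-core mean positive area vs per-core
    mean negative area, then a paired t-test on the differences.  A pooled
    Welch comparison across all cells (``mode='pooled_welch'``) is offered
    since core-level pairing is one of several defensible designs.
    """
    if mode == "pooled_welch":
        pos = np.concatenate([np.asarray(p.areas_positive, float) for p in paired])
        neg = np.concatenate([np.asarray(p.areas_negative, float) for p in paired])
        if len(pos) < 2 or len(neg) < 2:
            raise InsufficientDataError("need at least 2 cells per group")
        res = stats.ttest_ind(pos, neg, equal_var=False)
        return CellAreaResult(
            t_statistic=float(res.statistic), p_value=float(res.pvalue),
            df=int(np.floor(res.df)), mean_difference=float(pos.mean() - neg.mean()),
            per_core_difference={}, mode=mode,
        )
    if mode != "paired_core_means":
        raise SpecValidationError("mode must be 'paired_core_means' or 'pooled_welch'")
    if len(paired) < 2:
        raise InsufficientDataError(
            f"need at least 2 cores with both groups, got {len(paired)}"
        )
    diffs = {}
    for p in paired:
        diffs[p.core_id] = float(
            np.mean(p.areas_positive) - np.mean(p.areas_negative)
        )
    d = np.array(list(diffs.values()))
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
        p_value = 1.0 if d.mean() == 0.0 else 0.0
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p_value = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return CellAreaResult(
        t_statistic=float(t), p_value=float(p_value), df=n - 1,
        mean_difference=float(d.mean()), per_core_difference=diffs, mode=mode,
    )


# ---------------------------------------------------------------------------
# adapters from synthetic ground truth
# ---------------------------------------------------------------------------

def counts_from_ground_truth(core_id: str, gt) -> ManualCount:
    """Manual count equivalent taken from a rendered core's ground truth."""
    return ManualCount(
        core_id=core_id,
        n_positive_cells=int(np.asarray(gt.positive_flags).sum()),
        n_total_cells=int(len(gt.positive_flags)),
    )


def areas_from_ground_truth(core_id: str, gt):
    """Positive/negative per-cell areas from ground truth, or None if a core
    lacks one of the two groups."""
    flags = np.asarray(gt.positive_flags, dtype=bool)
    areas = np.asarray(gt.per_myocyte_area_px, dtype=float)
    if flags.all() or (~flags).all():
        return None
    return PairedAreas(
        core_id=core_id,
        areas_positive=tuple(areas[flags]),
        areas_negative=tuple(areas[~flags]),
    )


def replicates_from_table(scores) -> List[ReplicateSet]:
    """Group a (subject_id, percent) table into 2-3 core replicate sets.

    ``scores`` is a DataFrame with ``subject_id`` and a percent column
    (first non-id numeric column or 'percent_positive').  Subjects with a
    single core are skipped; subjects with more than three cores use the
    first three.
    """
    col = "percent_positive" if "percent_positive" in scores.columns else "true_percent"
    out = []
    for sid, grp in scores.groupby("subject_id"):
        vals = grp[col].dropna().tolist()[:3]
        if len(vals) >= 2:
            out.append(ReplicateSet(subject_id=str(sid), core_scores=tuple(vals)))
    return out
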