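"""Abstracted sequencing QC: quality-threshold calibration from a
Sanger-validated variant subset, and case/control differential
missingness screening.

The original study validated ~10% of called variants by capillary
sequencing and used the outcome to tune its quality filters.  The exact
filter variables (depth, strand balance, mapping quality, ...) are not
recoverable, so this module exposes a single scalar site-quality axis:
given (quality, confirmed/refuted) records, it finds the lowest quality
cutoff whose retained set meets a target false-call rate.  A pluggable
multi-axis grid search over arbitrary per-site feature columns covers
richer filter spaces.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .core import CohortSheet, GenotypeMatrix

__all__ = [
    "ValidationRecord",
    "CalibrationResult",
    "CalibrationInfeasibleError",
    "calibrate_quality_threshold",
    "calibrate_grid",
    "differential_missingness_test",
]


@dataclass
class ValidationRecord:
    variant_id: str
    site_quality: float
    outcome: str  # "confirmed" | "refuted"

    def __post_init__(self) -> None:
        if self.site_quality < 0:
            raise ValueError("site_quality must be non-negative")
        if self.outcome not in ("confirmed", "refuted"):
            raise ValueError("outcome must be 'confirmed' or 'refuted'")


@dataclass
class CalibrationResult:
    q_star: float
    retained_fraction: float
    achieved_false_rate: float


class CalibrationInfeasibleError(ValueError):
    def __init__(self, best_rate: float):
        self.best_rate = best_rate
        super().__init__(
            f"no quality threshold attains the target false rate; "
            f"best achievable is {best_rate:.4g}"
        )


def calibrate_quality_threshold(
    records, max_false_rate: float
) -> CalibrationResult:
    """Smallest observed quality q* whose retained set (quality >= q*)
    has refuted/(confirmed+refuted) <= ``max_false_rate``.

    Scanning candidate thresholds in ascending order maximises the
    retained fraction among thresholds meeting the target.  Raises
    :class:`CalibrationInfeasibleError` (carrying the best achievable
    rate) when no observed threshold works.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one validation record")
    if not 0 <= max_false_rate < 1:
        raise ValueError("max_false_rate must be in [0, 1)")
    q = np.array([r.site_quality for r in records])
    refuted = np.array([r.outcome == "refuted" for r in records])
    best_rate = np.inf
    for cand in np.unique(q):
        keep = q >= cand
        rate = refuted[keep].sum() / keep.sum()
        best_rate = min(best_rate, rate)
        if rate <= max_false_rate:
            return CalibrationResult(
                q_star=float(cand),
                retained_fraction=keep.sum() / len(records),
                achieved_false_rate=float(rate),
            )
    raise CalibrationInfeasibleError(float(best_rate))


def calibrate_grid(frame: pd.DataFrame, axes, max_false_rate: float):
    """Multi-axis filter search: ``frame`` has an ``outcome`` column plus
    one column per quality axis; every combination of observed axis
    values is scanned (all-axes >= cutoffs), and the combination meeting
    the target false rate with maximal retention is returned as a dict
    ``axis -> cutoff`` plus its :class:`CalibrationResult`."""
    if "outcome" not in frame.columns:
        raise ValueError("frame needs an 'outcome' column")
    refuted = (frame["outcome"] == "refuted").to_numpy()
    grids = [np.unique(frame[a].to_numpy(dtype=float)) for a in axes]
    best = None
    best_rate = np.inf
    for cuts in product(*grids):
        keep = np.ones(len(frame), dtype=bool)
        for a, c in zip(axes, cuts):
            keep &= frame[a].to_numpy(dtype=float) >= c
        if not keep.any():
            continue
        rate = refuted[keep].sum() / keep.sum()
        best_rate = min(best_rate, rate)
        if rate <= max_false_rate:
            retained = keep.sum() / len(frame)
            if best is None or retained > best[1].retained_fraction:
                best = (
                    dict(zip(axes, (float(c) for c in cuts))),
                    CalibrationResult(np.nan, retained, float(rate)),
                )
    if best is None:
        raise CalibrationInfeasibleError(float(best_rate))
    return best


def differential_missingness_test(
    matrix: GenotypeMatrix, sheet: CohortSheet, alpha: float = 0.05
):
    """Per-variant Fisher exact test of (called, missing) x (case,
    control); cases are all non-control samples pooled.

    Returns ``(frame, flagged_ids)``: a DataFrame with per-variant
    missing counts and p-values, and the IDs flagged at the Bonferroni
    threshold ``alpha / n_variants``.
    """
    if matrix.samples != sheet.sample_ids:
        raise ValueError("matrix samples and sample sheet must match in order")
    case = sheet.group != "control"
    if not case.any() or case.all():
        raise ValueError("need both case and control samples")
    miss = matrix.missing_mask()
    n_case, n_ctrl = int(case.sum()), int((~case).sum())
    miss_case = miss[case, :].sum(axis=0)
    miss_ctrl = miss[~case, :].sum(axis=0)
    pvals = np.array(
        [
            stats.fisher_exact(
                [
                    [n_case - mc, mc],
                    [n_ctrl - mr, mr],
                ]
            )[1]
            for mc, mr in zip(miss_case, miss_ctrl)
        ]
    )
    cutoff = alpha / matrix.n_variants
    flagged = pvals < cutoff
    frame = pd.DataFrame(
        {
            "variant_id": matrix.variant_ids(),
            "missing_cases": miss_case,
            "missing_controls": miss_ctrl,
            "p": pvals,
            "flagged": flagged,
        }
    )
    return frame, frame.loc[flagged, "variant_id"].tolist()
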