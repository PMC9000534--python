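"""Stage II: blank filtering, pairwise group comparison, and marker export.

The blank filter aligns each group compound against the blank group (same
RT + spectral-similarity criteria as stage I) and flags it as background when
its mean detected area is not more than ``ratio_min`` (default 5) times the
blank's mean area.  Flagged compounds stay in the table so comparisons can
report them as disqualified rather than silently losing them.

Group comparisons are directional: the focal group must carry the compound in
more than ``fraction_focal_min`` (default 0.6) of its samples and have the
larger mean.  The t statistic is computed on full-length area vectors with
zeros for samples where the compound was not detected — absence is evidence of
a low level, and padding keeps the test defined when the compound is missing
from the reference group entirely.  Default test: two-sided pooled-variance
Student's t; Welch is available via ``equal_var=False``.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import (
    DEFAULT_MZ_TOL,
    DEFAULT_RT_TOL,
    DEFAULT_SCORE_MIN,
    GroupTable,
    UnifiedCompound,
)
from .spectra import similarity_score

__all__ = [
    "MarkerResult",
    "ComparisonReport",
    "blank_filter",
    "compare_groups",
    "export_report",
    "DEFAULT_BLANK_RATIO",
    "DEFAULT_FRACTION_MARKER",
    "DEFAULT_P_SIGNIFICANT",
    "DEFAULT_P_POSSIBLE",
]

DEFAULT_BLANK_RATIO = 5.0
DEFAULT_FRACTION_MARKER = 0.6
DEFAULT_FRACTION_REFERENCE = 0.3
DEFAULT_P_SIGNIFICANT = 0.05
DEFAULT_P_POSSIBLE = 0.1

Status = Literal[
    "significant",
    "possibly_significant",
    "not_significant",
    "disqualified_blank",
    "disqualified_fraction",
]


@dataclass
class MarkerResult:
    """Outcome of one compound in one directional group comparison."""

    name: str
    rt_mean: float
    top_ions: tuple[tuple[float, float], ...]
    focal_group: str
    reference_group: str
    mean_focal: float
    mean_reference: float
    fold: float  # mean_focal / mean_reference; inf when reference mean is 0
    p_value: float | None
    fraction_focal: float
    fraction_reference: float
    status: Status
    areas_focal: dict[str, float] = field(default_factory=dict)
    areas_reference: dict[str, float] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    focal_group: str
    reference_group: str
    results: list[MarkerResult]
    metadata: dict = field(default_factory=dict)

    def count(self, status: Status) -> int:
        return sum(1 for r in self.results if r.status == status)


def _best_alignment(
    compound: UnifiedCompound,
    table: GroupTable,
    rt_tol: float,
    mz_tol: float,
    score_min: float,
    claimed: set[int],
) -> int | None:
    """Index of the best-matching unclaimed compound in ``table``, or None.

    ``table.compounds`` is RT-sorted after finalization, so only the RT window
    around the query compound is scored.
    """
    rts = [c.rt_mean for c in table.compounds]
    lo = bisect_left(rts, compound.rt_mean - rt_tol)
    hi = bisect_right(rts, compound.rt_mean + rt_tol)
    best: tuple[float, float, int] | None = None
    for idx in range(lo, hi):
        other = table.compounds[idx]
        if idx in claimed:
            continue
        drt = abs(compound.rt_mean - other.rt_mean)
        if drt >= rt_tol:
            continue
        score = similarity_score(compound.combined_spectrum, other.combined_spectrum, mz_tol)
        if score <= score_min:
            continue
        key = (-score, drt, idx)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def blank_filter(
    sample_table: GroupTable,
    blank_table: GroupTable,
    ratio_min: float = DEFAULT_BLANK_RATIO,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    score_min: float = DEFAULT_SCORE_MIN,
) -> GroupTable:
    """Flag background compounds by comparison with the blank group (in place).

    A compound is disqualified when it aligns to a blank compound and its mean
    detected area is <= ``ratio_min`` times the blank's mean detected area;
    compounds with no blank counterpart are always kept.  Raising
    ``ratio_min`` can only disqualify more compounds, never fewer.
    """
    if not (sample_table.finalized and blank_table.finalized):
        raise ValueError("both tables must be finalized before blank filtering")
    claimed: set[int] = set()
    for compound in sample_table.compounds:
        idx = _best_alignment(compound, blank_table, rt_tol, mz_tol, score_min, claimed)
        if idx is None:
            compound.blank_disqualified = False
            continue
        claimed.add(idx)
        blank_mean = blank_table.compounds[idx].mean_area()
        compound.blank_disqualified = compound.mean_area() <= ratio_min * blank_mean
    return sample_table


def _padded_areas(areas: dict[str, float], sample_ids: Sequence[str]) -> np.ndarray:
    return np.array([areas.get(sid, 0.0) for sid in sample_ids], dtype=float)


def compare_groups(
    focal: GroupTable,
    reference: GroupTable,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    score_min: float = DEFAULT_SCORE_MIN,
    fraction_focal_min: float = DEFAULT_FRACTION_MARKER,
    fraction_ref_min: float = DEFAULT_FRACTION_REFERENCE,
    p_significant: float = DEFAULT_P_SIGNIFICANT,
    p_possible: float = DEFAULT_P_POSSIBLE,
    equal_var: bool = True,
    log_transform: bool = False,
) -> ComparisonReport:
    """Directional comparison of the focal group against a reference group.

    Every focal compound yields a :class:`MarkerResult`.  Blank-disqualified
    focal compounds are reported as ``disqualified_blank``; compounds below
    the focal fraction threshold as ``disqualified_fraction``.  The reference
    areas come from the best-aligned reference compound; an unaligned or
    blank-disqualified reference counts as all zeros.  With fewer than two
    focal detections the p-value is undefined and the compound is reported
    ``not_significant``.
    """
    if not (focal.finalized and reference.finalized):
        raise ValueError("both tables must be finalized before comparison")
    results: list[MarkerResult] = []
    claimed: set[int] = set()
    for compound in sorted(focal.compounds, key=lambda c: c.rt_mean):
        ref_idx = _best_alignment(compound, reference, rt_tol, mz_tol, score_min, claimed)
        ref_compound: UnifiedCompound | None = None
        if ref_idx is not None:
            claimed.add(ref_idx)
            ref_compound = reference.compounds[ref_idx]

        usable_ref = (
            ref_compound is not None
            and not ref_compound.blank_disqualified
            and ref_compound.fraction >= fraction_ref_min
        )
        mean_focal = compound.mean_area()
        mean_reference = ref_compound.mean_area() if usable_ref else 0.0
        fold = mean_focal / mean_reference if mean_reference > 0 else math.inf
        fraction_reference = ref_compound.fraction if usable_ref else 0.0

        x = _padded_areas(compound.areas, focal.sample_ids)
        y = (
            _padded_areas(ref_compound.areas, reference.sample_ids)
            if usable_ref
            else np.zeros(reference.n_group)
        )
        if log_transform:
            x = np.log10(x + 1.0)
            y = np.log10(y + 1.0)

        p_value: float | None
        if len(compound.areas) < 2:
            p_value = None
        else:
            p_value = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
            if math.isnan(p_value):
                p_value = None

        if compound.blank_disqualified:
            status: Status = "disqualified_blank"
        elif compound.fraction <= fraction_focal_min:
            status = "disqualified_fraction"
        elif p_value is None or mean_focal <= mean_reference:
            status = "not_significant"
        elif p_value <= p_significant:
            status = "significant"
        elif p_value < p_possible:
            status = "possibly_significant"
        else:
            status = "not_significant"

        results.append(
            MarkerResult(
                name=compound.representative_name,
                rt_mean=compound.rt_mean,
                top_ions=compound.combined_spectrum.ions,
                focal_group=focal.group,
                reference_group=reference.group,
                mean_focal=mean_focal,
                mean_reference=mean_reference,
                fold=fold,
                p_value=p_value,
                fraction_focal=compound.fraction,
                fraction_reference=fraction_reference,
                status=status,
                areas_focal=dict(compound.areas),
                areas_reference=dict(ref_compound.areas) if usable_ref else {},
            )
        )

    results.sort(key=lambda r: (r.p_value if r.p_value is not None else 2.0, -r.fold))
    return ComparisonReport(
        focal_group=focal.group,
        reference_group=reference.group,
        results=results,
        metadata={
            "rt_tol": rt_tol,
            "mz_tol": mz_tol,
            "score_min": score_min,
            "fraction_focal_min": fraction_focal_min,
            "fraction_ref_min": fraction_ref_min,
            "p_significant": p_significant,
            "p_possible": p_possible,
            "equal_var": equal_var,
            "log_transform": log_transform,
        },
    )


def _report_frame(report: ComparisonReport) -> pd.DataFrame:
    """Tabular view of a report, including the raw per-sample areas."""
    focal_samples = sorted({sid for r in report.results for sid in r.areas_focal})
    ref_samples = sorted({sid for r in report.results for sid in r.areas_reference})
    # BH-adjusted p-values as supplementary information only; classification
    # uses the unadjusted p-values.
    defined = [(i, r.p_value) for i, r in enumerate(report.results) if r.p_value is not None]
    bh = {}
    if defined:
        order = sorted(defined, key=lambda t: t[1])
        m = len(order)
        prev = 1.0
        for rank in range(m, 0, -1):
            i, p = order[rank - 1]
            prev = min(prev, p * m / rank)
            bh[i] = prev
    rows = []
    for i, r in enumerate(report.results):
        row = {
            "name": r.name,
            "rt_mean": round(r.rt_mean, 3),
            "top_ions": ";".join(f"{mz:.4f}:{rel:.3f}" for mz, rel in r.top_ions),
            "mean_focal": r.mean_focal,
            "mean_reference": r.mean_reference,
            "fold": "inf" if math.isinf(r.fold) else r.fold,
            "p_value": r.p_value,
            "p_bh": bh.get(i),
            "fraction_focal": r.fraction_focal,
            "fraction_reference": r.fraction_reference,
            "status": r.status,
        }
        for sid in focal_samples:
            row[f"area_{report.focal_group}_{sid}"] = r.areas_focal.get(sid, 0.0)
        for sid in ref_samples:
            row[f"area_{report.reference_group}_{sid}"] = r.areas_reference.get(sid, 0.0)
        rows.append(row)
    columns = [
        "name", "rt_mean", "top_ions", "mean_focal", "mean_reference", "fold",
        "p_value", "p_bh", "fraction_focal", "fraction_reference", "status",
    ]
    columns += [f"area_{report.focal_group}_{sid}" for sid in focal_samples]
    columns += [f"area_{report.reference_group}_{sid}" for sid in ref_samples]
    return pd.DataFrame(rows, columns=columns)


def export_report(
    report: ComparisonReport, path: str | Path, format: Literal["tsv", "xlsx"] = "tsv"
) -> None:
    """Write a report as TSV (canonical) or XLSX (convenience)."""
    frame = _report_frame(report)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "xlsx":
        frame.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValueError(f"unknown format {format!r}")
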