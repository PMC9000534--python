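"""Stage I: merge per-sample peak lists into a unified compound table per group.

Two records from different samples are the same compound when their retention
times differ by less than ``rt_tol`` (default 0.12 min) and their spectra score
above ``score_min`` (default 0.5) with ions matched within ``mz_tol`` (default
1.1 mDa).  Samples are merged sequentially in manifest order; each incoming
record aligns to the best-scoring open compound (ties broken by the smaller RT
difference) or starts a new one.  Two records from the same sample never merge
with each other.  On alignment the compound's RT becomes a running average,
the peak area is appended under the sample id, and the spectra are combined
into an occurrence-weighted consensus spectrum.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .msp_io import PeakRecord
from .spectra import MAX_IONS, Spectrum, match_ions, similarity_score

__all__ = [
    "UnifiedCompound",
    "GroupTable",
    "merge_sample",
    "combine_spectra",
    "finalize_group",
    "DEFAULT_RT_TOL",
    "DEFAULT_MZ_TOL",
    "DEFAULT_SCORE_MIN",
    "DEFAULT_FRACTION_MIN",
]

DEFAULT_RT_TOL = 0.12  # minutes
DEFAULT_MZ_TOL = 0.0011  # Da
DEFAULT_SCORE_MIN = 0.5
DEFAULT_FRACTION_MIN = 0.3


@dataclass
class UnifiedCompound:
    """One compound aligned across the samples of a group."""

    name: str
    rt_mean: float
    combined_spectrum: Spectrum
    areas: dict[str, float] = field(default_factory=dict)
    n_merged: int = 1  # aligned occurrences, used as running-average weight
    names: dict[str, int] = field(default_factory=dict)
    fraction: float = 0.0  # set by finalize_group
    blank_disqualified: bool = False  # set by the blank filter

    @property
    def representative_name(self) -> str:
        """Most frequent record name, ties broken alphabetically."""
        return min(self.names, key=lambda n: (-self.names[n], n))

    def mean_area(self) -> float:
        """Mean peak area over the samples where the compound was detected."""
        return sum(self.areas.values()) / len(self.areas)


@dataclass
class GroupTable:
    """Unified compound list for one sample group."""

    group: str
    compounds: list[UnifiedCompound] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    finalized: bool = False

    @property
    def n_group(self) -> int:
        return len(self.sample_ids)


def combine_spectra(
    existing: Spectrum,
    incoming: Spectrum,
    weight_existing: int,
    mz_tol: float = DEFAULT_MZ_TOL,
    weight_incoming: int = 1,
) -> Spectrum:
    """Occurrence-weighted consensus of two spectra.

    Matched ions get the count-weighted mean m/z and relative intensity;
    unmatched ions from either side are retained at count-weighted intensity
    (so an ion seen once in ``weight_existing + 1`` spectra is down-weighted
    accordingly, rather than letting one saturated sample dominate).  The
    result is renormalized to its new base peak and truncated to the top 7.
    """
    if weight_existing < 1 or weight_incoming < 1:
        raise ValueError("occurrence weights must be >= 1")
    w = float(weight_existing)
    wi = float(weight_incoming)
    total = w + wi
    pairs = match_ions(existing, incoming, mz_tol)
    matched_e = {i for i, _ in pairs}
    matched_i = {j for _, j in pairs}
    merged: list[tuple[float, float]] = []
    for i, j in pairs:
        mz_e, rel_e = existing.ions[i]
        mz_i, rel_i = incoming.ions[j]
        merged.append(((mz_e * w + mz_i * wi) / total, (rel_e * w + rel_i * wi) / total))
    for i, (mz, rel) in enumerate(existing.ions):
        if i not in matched_e:
            merged.append((mz, rel * w / total))
    for j, (mz, rel) in enumerate(incoming.ions):
        if j not in matched_i:
            merged.append((mz, rel * wi / total))
    merged.sort(key=lambda ion: (-ion[1], ion[0]))
    merged = merged[:MAX_IONS]
    base = merged[0][1]
    return Spectrum(tuple((mz, rel / base) for mz, rel in merged))


def merge_sample(
    table: GroupTable,
    records: Sequence[PeakRecord],
    sample_id: str,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    score_min: float = DEFAULT_SCORE_MIN,
) -> GroupTable:
    """Merge one sample's peak list into the group table (in place).

    Candidates for an incoming record are compounds with |dRT| < rt_tol not
    yet claimed by this sample; the best candidate is the highest similarity
    score above ``score_min``, ties broken by the smaller |dRT|.  Records that
    align to nothing start a new compound.
    """
    if sample_id in table.sample_ids:
        raise ValueError(f"sample {sample_id!r} already merged into group {table.group!r}")
    table.sample_ids.append(sample_id)

    # compounds sorted by rt_mean for windowed candidate lookup
    table.compounds.sort(key=lambda c: c.rt_mean)
    rts = [c.rt_mean for c in table.compounds]
    claimed: set[int] = set()
    new_compounds: list[UnifiedCompound] = []

    for record in sorted(records, key=lambda r: r.rt):
        lo = bisect_left(rts, record.rt - rt_tol)
        hi = bisect_right(rts, record.rt + rt_tol)
        best: tuple[float, float, int] | None = None  # (-score, |dRT|, index)
        for idx in range(lo, hi):
            if idx in claimed:
                continue
            compound = table.compounds[idx]
            drt = abs(record.rt - compound.rt_mean)
            if drt >= rt_tol:
                continue
            score = similarity_score(record.spectrum, compound.combined_spectrum, mz_tol)
            if score <= score_min:
                continue
            key = (-score, drt, idx)
            if best is None or key < best:
                best = key
        if best is None:
            new_compounds.append(
                UnifiedCompound(
                    name=record.name,
                    rt_mean=record.rt,
                    combined_spectrum=record.spectrum,
                    areas={sample_id: record.area},
                    n_merged=1,
                    names={record.name: 1},
                )
            )
        else:
            idx = best[2]
            claimed.add(idx)
            compound = table.compounds[idx]
            compound.combined_spectrum = combine_spectra(
                compound.combined_spectrum, record.spectrum, compound.n_merged, mz_tol
            )
            compound.rt_mean = (compound.rt_mean * compound.n_merged + record.rt) / (
                compound.n_merged + 1
            )
            compound.n_merged += 1
            compound.areas[sample_id] = record.area
            compound.names[record.name] = compound.names.get(record.name, 0) + 1

    table.compounds.extend(new_compounds)
    table.compounds.sort(key=lambda c: c.rt_mean)
    return table


def _consolidate(table: GroupTable, rt_tol: float, mz_tol: float, score_min: float) -> None:
    """Re-merge split twins left behind by sequential merging.

    Sequential merging is order-dependent: a single out-of-tolerance mass
    reading in the first encounter of two samples can split one compound into
    two, after which later samples attach to either twin.  Because each record
    joins exactly one compound, such twins have disjoint sample sets, and
    their consensus spectra (occurrence-averaged m/z) score highly against
    each other.  Pairs meeting the alignment criteria with disjoint sample
    sets are therefore merged until no such pair remains.  Compounds detected
    in overlapping samples are never touched, so distinct co-eluting compounds
    (present together in at least one sample) cannot be collapsed.
    """
    merged = True
    while merged:
        merged = False
        table.compounds.sort(key=lambda c: c.rt_mean)
        for i in range(len(table.compounds) - 1):
            a = table.compounds[i]
            for j in range(i + 1, len(table.compounds)):
                b = table.compounds[j]
                if b.rt_mean - a.rt_mean >= rt_tol:
                    break
                if a.areas.keys() & b.areas.keys():
                    continue
                score = similarity_score(a.combined_spectrum, b.combined_spectrum, mz_tol)
                if score <= score_min:
                    continue
                a.combined_spectrum = combine_spectra(
                    a.combined_spectrum, b.combined_spectrum, a.n_merged, mz_tol,
                    weight_incoming=b.n_merged,
                )
                a.rt_mean = (a.rt_mean * a.n_merged + b.rt_mean * b.n_merged) / (
                    a.n_merged + b.n_merged
                )
                a.n_merged += b.n_merged
                a.areas.update(b.areas)
                for name, count in b.names.items():
                    a.names[name] = a.names.get(name, 0) + count
                del table.compounds[j]
                merged = True
                break
            if merged:
                break


def finalize_group(
    table: GroupTable,
    fraction_min: float = DEFAULT_FRACTION_MIN,
    rt_tol: float = DEFAULT_RT_TOL,
    mz_tol: float = DEFAULT_MZ_TOL,
    score_min: float = DEFAULT_SCORE_MIN,
) -> GroupTable:
    """Consolidate split compounds, compute detection fractions, filter.

    A compound detected in fewer than ``fraction_min`` of the group's samples
    is removed (fraction >= fraction_min is kept).  Idempotent.
    """
    if table.n_group == 0:
        raise ValueError("cannot finalize a group with no merged samples")
    _consolidate(table, rt_tol, mz_tol, score_min)
    n = table.n_group
    kept: list[UnifiedCompound] = []
    for compound in table.compounds:
        compound.fraction = len(compound.areas) / n
        if compound.fraction >= fraction_min:
            kept.append(compound)
    table.compounds = sorted(kept, key=lambda c: c.rt_mean)
    table.finalized = True
    return table
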