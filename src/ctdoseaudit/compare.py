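"""Region/scanner-stratified fitting and slope comparison.

The audit's headline quantity is the absolute percentage difference between
a fitted metric-vs-SSDE slope and the matching published reference slope,
summarized per region/scanner cell and averaged across cells.  Slope
magnitudes are compared, so a sign flip in either slope does not change the
result.  Integer percentages are rounded half-away-from-zero; means are
taken over the unrounded values and reported to one decimal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateDesignError
from .metrics import MartinRegion, MartinSegment


# ---------------------------------------------------------------------------
# Rounding (centralized; round-half-away-from-zero)
# ---------------------------------------------------------------------------

def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding)."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


# ---------------------------------------------------------------------------
# OLS fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares fit of ``y = slope*x + intercept``."""

    slope: float
    intercept: float
    r2: float
    n: int
    x_metric: str = "x"
    y_metric: str = "y"
    scanner_id: str = ""
    region: str = ""


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    *,
    x_metric: str = "x",
    y_metric: str = "y",
    scanner_id: str = "",
    region: str = "",
) -> FitResult:
    """OLS with intercept; ``r2 = 1 - SS_res/SS_tot``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError(f"need at least 2 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant x: slope is not identifiable")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FitResult(
        slope=slope, intercept=intercept, r2=r2, n=int(x.size),
        x_metric=x_metric, y_metric=y_metric, scanner_id=scanner_id,
        region=region,
    )


# ---------------------------------------------------------------------------
# Slope percent differences
# ---------------------------------------------------------------------------

def abs_slope_pct_diff(observed: float, reference: float) -> float:
    """Unrounded ``||observed| - |reference|| / |reference| * 100``."""
    if reference == 0:
        raise ZeroDivisionError("reference slope must be non-zero")
    return abs(abs(observed) - abs(reference)) / abs(reference) * 100.0


def slope_pct_diff(observed: float, reference: float) -> int:
    """Integer percent difference (round half away from zero)."""
    return int(round_half_away(abs_slope_pct_diff(observed, reference)))


@dataclass(frozen=True)
class SlopeComparison:
    observed_slope: float
    reference_slope: float
    pct_diff: int

    @classmethod
    def of(cls, observed: float, reference: float) -> "SlopeComparison":
        return cls(observed, reference, slope_pct_diff(observed, reference))

    @property
    def pct_diff_raw(self) -> float:
        return abs_slope_pct_diff(self.observed_slope, self.reference_slope)


@dataclass(frozen=True)
class MeanPctDiff:
    """Mean of unrounded percent differences, reported to one decimal."""

    mean: float
    min: float
    max: float
    n: int


def mean_abs_pct_diff(diffs: Sequence[float]) -> MeanPctDiff:
    """Arithmetic mean (1 decimal) and range of percent differences."""
    if len(diffs) == 0:
        raise ValueError("empty list of percent differences")
    diffs = [float(d) for d in diffs]
    return MeanPctDiff(
        mean=round_half_away(sum(diffs) / len(diffs), 1),
        min=min(diffs),
        max=max(diffs),
        n=len(diffs),
    )


# ---------------------------------------------------------------------------
# Slope table (per-region, per-scanner cells vs reference segments)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellData:
    """Per (region, scanner) point sets; metric values per series/study."""

    ssde: Sequence[float]
    sed: Sequence[float] | None = None
    ed: Sequence[float] | None = None


@dataclass
class SlopeTableCell:
    region: str
    scanner: str
    sed_fit: FitResult | None = None
    ed_fit: FitResult | None = None
    sed_cmp: SlopeComparison | None = None
    ed_cmp: SlopeComparison | None = None


@dataclass
class SlopeTable:
    cells: list[SlopeTableCell]
    reference: dict[str, float]          # region -> reference slope
    sed_summary: MeanPctDiff | None
    ed_summary: MeanPctDiff | None
    unreferenced_regions: list[str] = field(default_factory=list)

    def cell(self, region: str, scanner: str) -> SlopeTableCell | None:
        for c in self.cells:
            if c.region == region and c.scanner == scanner:
                return c
        return None

    # -- serialization (deterministic: cells sorted, fixed float repr) -----

    def to_records(self) -> list[dict]:
        rows = []
        for c in sorted(self.cells, key=lambda c: (c.region, c.scanner)):
            rows.append({
                "region": c.region,
                "scanner": c.scanner,
                "sed_slope": None if c.sed_fit is None else c.sed_fit.slope,
                "sed_intercept": None if c.sed_fit is None else c.sed_fit.intercept,
                "sed_r2": None if c.sed_fit is None else c.sed_fit.r2,
                "sed_n": None if c.sed_fit is None else c.sed_fit.n,
                "sed_pct_diff": None if c.sed_cmp is None else c.sed_cmp.pct_diff,
                "ed_slope": None if c.ed_fit is None else c.ed_fit.slope,
                "ed_intercept": None if c.ed_fit is None else c.ed_fit.intercept,
                "ed_r2": None if c.ed_fit is None else c.ed_fit.r2,
                "ed_n": None if c.ed_fit is None else c.ed_fit.n,
                "ed_pct_diff": None if c.ed_cmp is None else c.ed_cmp.pct_diff,
                "reference_slope": self.reference.get(c.region),
            })
        return rows

    def to_json(self) -> str:
        payload = {
            "cells": self.to_records(),
            "reference_slopes": dict(sorted(self.reference.items())),
            "sed_summary": None if self.sed_summary is None else vars(self.sed_summary),
            "ed_summary": None if self.ed_summary is None else vars(self.ed_summary),
            "unreferenced_regions": sorted(self.unreferenced_regions),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv(self) -> str:
        rows = self.to_records()
        cols = list(rows[0].keys()) if rows else ["region", "scanner"]
        lines = [",".join(cols)]
        for row in rows:
            lines.append(",".join(
                "" if row[c] is None else
                (repr(row[c]) if isinstance(row[c], float) else str(row[c]))
                for c in cols
            ))
        return "\n".join(lines) + "\n"


def reference_slopes(segments: Iterable[MartinSegment]) -> dict[str, float]:
    """Region -> reference slope magnitude from the calibration segments."""
    return {seg.scanned_region.value: abs(seg.a) for seg in segments}


def build_slope_table(
    data: Mapping[tuple[str | MartinRegion, str], CellData],
    segments: Sequence[MartinSegment],
) -> SlopeTable:
    """Fit SED~SSDE and ED~SSDE per (region, scanner) cell and compare slopes.

    Cells with fewer than 2 points are emitted empty.  Regions without a
    reference segment are flagged and excluded from the two summary means.
    """
    refs = reference_slopes(segments)
    cells: list[SlopeTableCell] = []
    sed_diffs: list[float] = []
    ed_diffs: list[float] = []
    unreferenced: set[str] = set()
    for (region, scanner), cell_data in data.items():
        region_key = getattr(region, "value", region)
        cell = SlopeTableCell(region=region_key, scanner=str(scanner))
        ref = refs.get(region_key)
        if ref is None:
            unreferenced.add(region_key)
        for metric in ("sed", "ed"):
            y = getattr(cell_data, metric)
            if y is None or len(y) < 2 or len(cell_data.ssde) < 2:
                continue
            fit = fit_linear(
                cell_data.ssde, y,
                x_metric="ssde", y_metric=metric,
                scanner_id=str(scanner), region=region_key,
            )
            setattr(cell, f"{metric}_fit", fit)
            if ref is not None:
                cmp = SlopeComparison.of(fit.slope, ref)
                setattr(cell, f"{metric}_cmp", cmp)
                (sed_diffs if metric == "sed" else ed_diffs).append(cmp.pct_diff_raw)
        cells.append(cell)
    return SlopeTable(
        cells=cells,
        reference=refs,
        sed_summary=mean_abs_pct_diff(sed_diffs) if sed_diffs else None,
        ed_summary=mean_abs_pct_diff(ed_diffs) if ed_diffs else None,
        unreferenced_regions=sorted(unreferenced),
    )


def compare_slope_cells(
    slopes: Mapping[tuple[str, str], Mapping[str, float]],
    segments: Sequence[MartinSegment],
) -> tuple[dict[tuple[str, str, str], SlopeComparison], MeanPctDiff | None, MeanPctDiff | None]:
    """Compare externally supplied per-cell slopes against the segments.

    ``slopes`` maps (region, scanner) to {"sed": slope, "ed": slope}
    (either metric optional).  Returns per-(region, scanner, metric)
    comparisons plus the SED and ED summary means over unrounded values.
    """
    refs = reference_slopes(segments)
    out: dict[tuple[str, str, str], SlopeComparison] = {}
    sed_diffs: list[float] = []
    ed_diffs: list[float] = []
    for (region, scanner), metrics in slopes.items():
        ref = refs.get(region)
        if ref is None:
            continue
        for metric, slope in metrics.items():
            if slope is None:
                continue
            cmp = SlopeComparison.of(float(slope), ref)
            out[(region, scanner, metric)] = cmp
            (sed_diffs if metric == "sed" else ed_diffs).append(cmp.pct_diff_raw)
    return (
        out,
        mean_abs_pct_diff(sed_diffs) if sed_diffs else None,
        mean_abs_pct_diff(ed_diffs) if ed_diffs else None,
    )


# ---------------------------------------------------------------------------
# Box-plot statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxStats:
    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float


def summarize_box(values: Sequence[float]) -> BoxStats:
    """Quartiles by linear interpolation; whiskers = most extreme data
    points within 1.5*IQR of the box edges."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    # the box edges are data quantiles, so at least one point is inside
    return BoxStats(
        n=int(arr.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
    )
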