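"""End-to-end audit orchestration: ingest/generate -> filter -> classify ->
metrics -> slope comparison -> report bundle.

The report bundle is deterministic: identical configurations produce
byte-identical artifacts (floats are serialized with ``repr``, rows and
keys are sorted, and all randomness flows through the cohort seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import constants
from .compare import BoxStats, CellData, SlopeTable, build_slope_table, summarize_box
from .errors import (
    CalibrationRangeError,
    ConfigError,
    DiameterRangeError,
    NegativeDoseWarning,
)
from .metrics import (
    ConversionFactorTable,
    DwaterMap,
    MartinSegment,
    SsdeModel,
    WeightCorrectionModel,
    compute_ed,
    compute_sed,
    sed_from_ssde,
    ssde_from_deff,
    study_ed_total,
)
from .records import (
    FilterRules,
    SeriesRegion,
    StudyAlias,
    StudyRecord,
    filter_cohort,
    read_series_table,
    summarize_alias_counts,
    write_series_table,
)
from .regions import (
    AliasRuleSet,
    DEFAULT_ALIAS_RULES,
    classify_protocol,
    derive_study_alias,
)
from .synthetic import SERIES_TO_MARTIN_REGION, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "study_metrics.csv",
    "series_export.csv",
    "slope_table.csv",
    "slope_table.json",
    "box_stats.json",
    "exclusions.csv",
    "summary.json",
)


@dataclass
class RunConfig:
    """One audit run; exactly one of ``input_path`` / ``cohort`` is set."""

    out_dir: Path
    input_path: Path | None = None
    cohort: CohortConfig | None = None
    rules: FilterRules = field(default_factory=FilterRules)
    alias_rules: AliasRuleSet = DEFAULT_ALIAS_RULES
    factors_dms: ConversionFactorTable | None = None
    factors_dw: ConversionFactorTable | None = None
    segments: Sequence[MartinSegment] | None = None
    ssde_model: SsdeModel | None = None
    dwater_map: DwaterMap | None = None
    wmodel: WeightCorrectionModel = field(default_factory=WeightCorrectionModel)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.cohort is None):
            raise ConfigError(
                "exactly one of input_path or cohort must be supplied"
            )
        self.out_dir = Path(self.out_dir)
        if self.factors_dms is None:
            self.factors_dms = constants.default_factor_table("aapm_rpt96")
        if self.factors_dw is None:
            self.factors_dw = constants.default_factor_table("deak2010")
        if self.segments is None:
            self.segments = constants.default_segments()
        if self.ssde_model is None:
            self.ssde_model = SsdeModel()


@dataclass
class AuditReport:
    paths: dict[str, Path]
    slope_table: SlopeTable
    box_stats: dict[str, BoxStats]
    alias_counts: dict[str, int]
    n_studies: int
    n_kept: int
    n_excluded: int


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _classify_missing_regions(
    studies: Sequence[StudyRecord], rules: AliasRuleSet
) -> list[StudyRecord]:
    """Fill undefined series regions from protocol names; then derive any
    undefined study alias from the series."""
    out = []
    for study in studies:
        series = []
        for s in study.series:
            if s.series_region is SeriesRegion.UNDEFINED and s.protocol_name:
                region = classify_protocol(s.protocol_name, rules)
                s = dataclasses.replace(s, series_region=region)
            series.append(s)
        study = study.replace_series(series)
        if study.study_alias is StudyAlias.UNDEFINED and study.diagnostic_series():
            alias, _multi = derive_study_alias(study)
            study = dataclasses.replace(study, study_alias=alias)
        out.append(study)
    return out


def _series_metrics(
    study: StudyRecord,
    factors: ConversionFactorTable,
    ssde_model: SsdeModel,
    segments: Sequence[MartinSegment],
    wmodel: WeightCorrectionModel,
) -> list[dict]:
    """Per-diagnostic-series SSDE / ED / SED / SED-from-SSDE rows."""
    rows = []
    for s in study.diagnostic_series():
        row: dict = {
            "study_id": study.study_id,
            "series_uid": s.series_uid,
            "scanner": s.scanner_id.value,
            "region": s.series_region.value,
            "scan_length": s.scan_length,
            "dlp": s.dlp,
            "ssde": None,
            "ed": None,
            "sed": None,
            "sed_from_ssde": None,
        }
        try:
            row["ed"] = compute_ed(s.dlp, s.series_region, factors)
            if study.patient_weight is not None:
                row["sed"] = compute_sed(
                    s.dlp, s.series_region, factors, study.patient_weight, wmodel
                )
        except Exception:
            logger.warning("metric failure for series %s", s.series_uid)
        if s.d_eff is not None:
            try:
                row["ssde"] = ssde_from_deff(
                    s.ctdi_vol, s.d_eff, s.phantom, ssde_model
                )
            except DiameterRangeError:
                logger.warning("implausible d_eff for series %s", s.series_uid)
        martin = SERIES_TO_MARTIN_REGION.get(s.series_region)
        if martin is not None and row["ssde"] is not None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", NegativeDoseWarning)
                    row["sed_from_ssde"] = sed_from_ssde(
                        row["ssde"], martin, s.scan_length, segments
                    )
            except CalibrationRangeError:
                pass  # scan length outside every calibrated window
        rows.append(row)
    return rows


def _collect_cells(series_rows: Sequence[dict]) -> dict[tuple[str, str], CellData]:
    """Group per-series (ssde, sed, ed) points into slope-table cells.

    Series without SSDE or ED are skipped; a cell's SED column is dropped
    whenever any of its series lacks weight (keeps x/y aligned).
    """
    grouped: dict[tuple[str, str], dict] = {}
    for row in series_rows:
        martin = SERIES_TO_MARTIN_REGION.get(SeriesRegion(row["region"]))
        if martin is None or row["ssde"] is None or row["ed"] is None:
            continue
        key = (martin.value, row["scanner"])
        g = grouped.setdefault(key, {"ssde": [], "sed": [], "ed": [],
                                     "sed_complete": True})
        g["ssde"].append(row["ssde"])
        g["ed"].append(row["ed"])
        if row["sed"] is None:
            g["sed_complete"] = False
        else:
            g["sed"].append(row["sed"])
    return {
        key: CellData(
            ssde=g["ssde"], ed=g["ed"],
            sed=g["sed"] if g["sed_complete"] else None,
        )
        for key, g in sorted(grouped.items())
    }


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_csv(path: Path, columns: Sequence[str], rows: Sequence[Mapping]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(row.get(c)) for c in columns) + "\n")


# ---------------------------------------------------------------------------
# The audit
# ---------------------------------------------------------------------------

def run_audit(config: RunConfig) -> AuditReport:
    """Execute the full audit and write the report bundle.

    The slope table is fitted on the *audited* view: the commercial-style
    view with fixed-region misassignment when the cohort is synthetic and
    misassignment is enabled, otherwise the ingested records themselves.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort is not None:
        dms_view, dw_view, _truth = generate_cohort(config.cohort)
    else:
        dms_view = read_series_table(config.input_path)
        dw_view = dms_view
    dms_view = _classify_missing_regions(dms_view, config.alias_rules)
    dw_by_id = {st.study_id: st for st in dw_view}

    kept, excluded = filter_cohort(dms_view, config.rules)
    alias_counts = summarize_alias_counts(dms_view)
    assert sum(alias_counts.values()) == len(dms_view)

    # --- per-study metrics -------------------------------------------------
    study_rows: list[dict] = []
    series_rows: list[dict] = []
    audited: list[StudyRecord] = []
    for study in kept:
        dw_study = dw_by_id.get(study.study_id, study)
        audited.append(dw_study)
        sed_total = None
        if study.patient_weight is not None:
            sed_total = study_ed_total(
                study, config.factors_dms, weight_corrected=True,
                wmodel=config.wmodel,
            )
        srows = _series_metrics(
            dw_study, config.factors_dms, config.ssde_model,
            config.segments, config.wmodel,
        )
        series_rows.extend(srows)
        ssde_vals = [r["ssde"] for r in srows if r["ssde"] is not None]
        sfs_vals = [r["sed_from_ssde"] for r in srows if r["sed_from_ssde"] is not None]
        study_rows.append({
            "study_id": study.study_id,
            "study_alias": study.study_alias.value,
            "n_series": len(study.series),
            "dlp_total": sum(s.dlp for s in study.series),
            "ed_dms": study_ed_total(study, config.factors_dms),
            "ed_dw": study_ed_total(dw_study, config.factors_dw),
            "sed_dms": sed_total,
            "ssde_mean": (sum(ssde_vals) / len(ssde_vals)) if ssde_vals else None,
            "sed_from_ssde_total": sum(sfs_vals) if sfs_vals else None,
        })

    # --- slope table on the audited view -----------------------------------
    cells = _collect_cells(series_rows)
    slope_table = build_slope_table(cells, config.segments)

    # --- box statistics ----------------------------------------------------
    box_stats: dict[str, BoxStats] = {}
    for metric in ("ed_dms", "ed_dw", "sed_dms", "dlp_total"):
        values = [r[metric] for r in study_rows if r[metric] is not None]
        if values:
            box_stats[metric] = summarize_box(values)

    # --- artifacts ---------------------------------------------------------
    paths = {name: out / name for name in ARTIFACTS}
    _write_csv(
        paths["study_metrics.csv"],
        ["study_id", "study_alias", "n_series", "dlp_total", "ed_dms",
         "ed_dw", "sed_dms", "ssde_mean", "sed_from_ssde_total"],
        study_rows,
    )
    write_series_table(audited, paths["series_export.csv"])
    with open(paths["slope_table.csv"], "w", encoding="utf-8") as fh:
        fh.write(slope_table.to_csv())
    with open(paths["slope_table.json"], "w", encoding="utf-8") as fh:
        fh.write(slope_table.to_json())
    with open(paths["box_stats.json"], "w", encoding="utf-8") as fh:
        json.dump(
            {k: vars(v) for k, v in sorted(box_stats.items())},
            fh, indent=2, sort_keys=True,
        )
    _write_csv(
        paths["exclusions.csv"], ["study_id", "reason"],
        [{"study_id": e.study.study_id, "reason": e.reason} for e in excluded],
    )
    summary = {
        "n_studies": len(dms_view),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "alias_counts": dict(sorted(alias_counts.items())),
        "alias_counts_total": sum(alias_counts.values()),
        "sed_summary": None if slope_table.sed_summary is None
        else vars(slope_table.sed_summary),
        "ed_summary": None if slope_table.ed_summary is None
        else vars(slope_table.ed_summary),
    }
    with open(paths["summary.json"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    return AuditReport(
        paths=paths,
        slope_table=slope_table,
        box_stats=box_stats,
        alias_counts=alias_counts,
        n_studies=len(dms_view),
        n_kept=len(kept),
        n_excluded=len(excluded),
    )
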