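"""Seeded synthetic two-scanner cohort with a DMS view and a DW view.

The generator produces the statistical structure the audit pipeline
assumes: an adult age distribution, a region mix dominated by chest and
head studies, weight-dependent body diameters, per-region scan-length
windows, DLP consistent with CTDIvol by construction, and -- when enabled --
a "commercial view" copy of every study with the fixed-region
misassignment applied.  Each study draws from its own RNG stream keyed by
``(seed, study index)`` so cohorts are extensible without re-drawing
earlier studies.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .metrics import MartinRegion, SsdeModel, ssde_from_deff
from .records import (
    AcquisitionType,
    Phantom,
    Scanner,
    SeriesRecord,
    SeriesRegion,
    Sex,
    StudyAlias,
    StudyRecord,
)
from .regions import derive_study_alias, emulate_fixed_region

# study alias -> primary series-level region
_ALIAS_TO_SERIES_REGION = {
    StudyAlias.HEAD: SeriesRegion.HEAD,
    StudyAlias.NECK: SeriesRegion.NECK,
    StudyAlias.CHEST: SeriesRegion.CHEST,
    StudyAlias.ABDOMEN: SeriesRegion.ABDOMEN_PELVIS,
    StudyAlias.PELVIS: SeriesRegion.ABDOMEN_PELVIS,
}

#: series region -> calibration (scanned) region used for SED-from-SSDE
SERIES_TO_MARTIN_REGION = {
    SeriesRegion.CHEST: MartinRegion.CHEST,
    SeriesRegion.ABDOMEN_PELVIS: MartinRegion.ABDOMEN_PELVIS,
    SeriesRegion.TRUNK: MartinRegion.CAP,
}


@dataclass(frozen=True)
class CohortConfig:
    """Fully seeded description of a synthetic cohort."""

    n_studies: int = 200
    seed: int = 0
    scanner_mix: Mapping[str, float] = field(
        default_factory=lambda: {"CT1": 0.5, "CT2": 0.5}
    )
    # default mix mirrors a hospital case mix dominated by chest and head
    study_alias_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "head": 0.278, "chest": 0.514, "abdomen": 0.183,
            "neck": 0.017, "pelvis": 0.008,
        }
    )
    age_mean: float = 63.3
    age_sd: float = 15.3
    age_bounds: tuple[float, float] = (16.0, 104.0)
    weight_mean: float = 75.0
    weight_sd: float = 15.0
    weight_bounds: tuple[float, float] = (40.0, 150.0)
    # effective diameter: affine in weight for body regions, constant-mean
    # for head
    deff_weight_slope: float = 0.2     # cm per kg
    deff_intercept: float = 14.0       # cm
    deff_noise_sd: float = 1.5         # cm
    head_deff_mean: float = 17.0       # cm
    head_deff_sd: float = 1.0          # cm
    ctdi_medians: Mapping[str, float] = field(
        default_factory=lambda: {
            "head": 40.0, "neck": 10.0, "chest": 8.0,
            "abdomen_pelvis": 12.0, "trunk": 12.0,
        }
    )
    ctdi_sigma: float = 0.35           # lognormal shape
    scan_length_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "head": (12.0, 18.0), "neck": (20.0, 30.0), "chest": (30.0, 37.0),
            "abdomen_pelvis": (40.0, 50.0), "trunk": (62.0, 70.0),
        }
    )
    multi_region_prob: float = 0.1
    scout_prob: float = 0.8
    misassignment: bool = True

    def __post_init__(self) -> None:
        for name, mix in (("scanner_mix", self.scanner_mix),
                          ("study_alias_mix", self.study_alias_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} proportions sum to {total}, expected 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"{name} has a negative proportion")
        if self.n_studies < 0:
            raise ConfigError("n_studies must be >= 0")
        if not (0 <= self.multi_region_prob <= 1):
            raise ConfigError("multi_region_prob must be in [0, 1]")
        for scale in (self.age_sd, self.weight_sd, self.ctdi_sigma):
            if scale <= 0:
                raise ConfigError("scale parameters must be > 0")


def _choice(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix.keys())
    u = rng.random()
    acc = 0.0
    for k in keys:
        acc += mix[k]
        if u < acc:
            return k
    return keys[-1]


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float,
    bounds: tuple[float, float],
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if bounds[0] <= v <= bounds[1]:
            return v
    return min(max(mean, bounds[0]), bounds[1])  # pathological config


def _draw_series(
    rng: np.random.Generator,
    config: CohortConfig,
    study_id: str,
    index: int,
    scanner: Scanner,
    region: SeriesRegion,
    weight: float,
    acquisition: AcquisitionType,
) -> tuple[SeriesRecord, dict]:
    key = region.value
    lo, hi = config.scan_length_windows[key]
    scan_length = rng.uniform(lo, hi)
    median = config.ctdi_medians[key]
    ctdi = median * math.exp(rng.normal(0.0, config.ctdi_sigma))
    if acquisition is AcquisitionType.SCOUT:
        ctdi *= 0.02  # localizers deposit a tiny fraction of the dose
    if region is SeriesRegion.HEAD:
        d_eff = config.head_deff_mean + rng.normal(0.0, config.head_deff_sd)
        phantom = Phantom.HEAD16
    else:
        d_eff = (config.deff_weight_slope * weight + config.deff_intercept
                 + rng.normal(0.0, config.deff_noise_sd))
        phantom = Phantom.BODY32
    d_eff = min(max(d_eff, 7.0), 59.0)
    series = SeriesRecord(
        study_id=study_id,
        series_uid=f"{study_id}.{index}",
        scanner_id=scanner,
        protocol_name=f"{key.upper()} ROUTINE",
        series_region=region,
        acquisition_type=acquisition,
        ctdi_vol=ctdi,
        phantom=phantom,
        dlp=ctdi * scan_length,   # exact by construction
        scan_length=scan_length,
        d_eff=d_eff,
    )
    latent = {
        "region": key, "ctdi_vol": ctdi, "scan_length": scan_length,
        "d_eff": d_eff, "scout": acquisition is AcquisitionType.SCOUT,
    }
    return series, latent


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[StudyRecord], list[StudyRecord], dict]:
    """Generate ``(dms_view, dw_view, truth)``.

    Both views share study and series UIDs.  The DW view is a deep copy of
    the DMS view with :func:`emulate_fixed_region` applied to every study
    when ``config.misassignment`` is enabled.  The truth ledger records
    every latent draw keyed by study id.
    """
    dms_view: list[StudyRecord] = []
    truth: dict = {"config_seed": config.seed, "studies": {}}
    for i in range(config.n_studies):
        rng = np.random.default_rng((config.seed, i))
        study_id = f"S{i:05d}"
        scanner = Scanner(_choice(rng, dict(config.scanner_mix)))
        alias = StudyAlias(_choice(rng, dict(config.study_alias_mix)))
        primary = _ALIAS_TO_SERIES_REGION[alias]
        multi = rng.random() < config.multi_region_prob
        secondary: SeriesRegion | None = None
        if multi:
            pool = [r for r in (SeriesRegion.HEAD, SeriesRegion.CHEST,
                                SeriesRegion.ABDOMEN_PELVIS) if r != primary]
            secondary = pool[int(rng.integers(len(pool)))]
        age = _truncated_normal(rng, config.age_mean, config.age_sd,
                                config.age_bounds)
        weight = _truncated_normal(rng, config.weight_mean, config.weight_sd,
                                   config.weight_bounds)
        sex = Sex.F if rng.random() < 0.52 else Sex.M
        with_scout = rng.random() < config.scout_prob

        series: list[SeriesRecord] = []
        latents: list[dict] = []
        idx = 1
        if with_scout:
            s, l = _draw_series(rng, config, study_id, idx, scanner, primary,
                                weight, AcquisitionType.SCOUT)
            series.append(s); latents.append(l); idx += 1
        regions = [primary] + ([secondary] if secondary is not None else [])
        for region in regions:
            s, l = _draw_series(rng, config, study_id, idx, scanner, region,
                                weight, AcquisitionType.HELICAL)
            series.append(s); latents.append(l); idx += 1

        study = StudyRecord(
            study_id=study_id, patient_age=age, patient_sex=sex,
            patient_weight=weight, study_alias=alias, series=series,
        )
        derived_alias, multi_flag = derive_study_alias(study)
        study.study_alias = derived_alias
        dms_view.append(study)
        truth["studies"][study_id] = {
            "scanner": scanner.value, "alias": derived_alias.value,
            "multi_region": bool(multi_flag), "age": age, "weight": weight,
            "series": latents,
        }

    if config.misassignment:
        dw_view = [emulate_fixed_region(st) for st in dms_view]
    else:
        dw_view = [copy.deepcopy(st) for st in dms_view]
    return dms_view, dw_view, truth


# ---------------------------------------------------------------------------
# Injected linear SED structure (for parameter-recovery tests)
# ---------------------------------------------------------------------------

@dataclass
class SedStructureCohort:
    dms_view: list[StudyRecord]
    dw_view: list[StudyRecord]
    truth: dict
    frame: pd.DataFrame   # study_id, series_uid, region, scanner, ssde, sed


def inject_linear_sed_structure(
    config: CohortConfig,
    region_slopes: Mapping[str, tuple[float, float]],
    noise_sd: float,
    ssde_model: SsdeModel | None = None,
) -> SedStructureCohort:
    """Generate a cohort whose per-series SED follows a known line.

    ``region_slopes`` maps a calibration-region key (``chest``,
    ``abdomen_pelvis``, ``cap``, ...) to ``(a, b)``; for every diagnostic
    series whose region maps into that vocabulary, SED is drawn as
    ``a*SSDE - b + Normal(0, noise_sd)`` with SSDE computed from the
    generated CTDIvol and diameter.  Downstream fits must recover the
    injected parameters.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    valid = {r.value for r in MartinRegion}
    slopes: dict[str, tuple[float, float]] = {}
    for key, ab in region_slopes.items():
        key = getattr(key, "value", key)
        if key not in valid:
            raise ConfigError(f"unknown region key {key!r}")
        a, b = float(ab[0]), float(ab[1])
        if not (math.isfinite(a) and math.isfinite(b)):
            raise ConfigError(f"slopes for {key!r} must be finite")
        slopes[key] = (a, b)

    dms_view, dw_view, truth = generate_cohort(config)
    ssde_model = ssde_model or SsdeModel()
    noise_rng = np.random.default_rng((config.seed, 999_983))
    rows = []
    for study in dms_view:
        for s in study.diagnostic_series():
            martin = SERIES_TO_MARTIN_REGION.get(s.series_region)
            if martin is None or martin.value not in slopes:
                continue
            ssde = ssde_from_deff(s.ctdi_vol, s.d_eff, s.phantom, ssde_model)
            a, b = slopes[martin.value]
            sed = a * ssde - b + noise_rng.normal(0.0, noise_sd)
            rows.append({
                "study_id": study.study_id,
                "series_uid": s.series_uid,
                "region": martin.value,
                "scanner": s.scanner_id.value,
                "ssde": ssde,
                "sed": sed,
            })
    frame = pd.DataFrame(
        rows, columns=["study_id", "series_uid", "region", "scanner",
                       "ssde", "sed"],
    )
    return SedStructureCohort(dms_view=dms_view, dw_view=dw_view,
                              truth=truth, frame=frame)
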