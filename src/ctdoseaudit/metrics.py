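"""The dose-metric engine.

Implements the metric definitions used throughout the audit:

* ``ED = f(region) * DLP`` with a region-specific DLP-to-ED factor,
* ``wkg(w) = c0 + c1*w + c2*w**2``, a dimensionless weight correction,
* ``SED = wkg(w) * ED`` (weight-corrected, size-specific effective dose),
* ``SSDE = CTDIvol * a_e * exp(-b_e * D_eff)`` per phantom,
* an optional linear re-basing of SSDE from effective-diameter to
  water-equivalent-diameter basis (chest-type regions only),
* ``SED = a * SSDE - b`` from published region/scan-length regression
  segments.

Units are fixed repo-wide: mGy, mGy.cm, mSv, cm, kg.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import (
    CalibrationRangeError,
    DiameterRangeError,
    MapNotConfiguredError,
    NegativeDoseWarning,
    RegionLookupError,
    WeightMissingError,
    WeightRangeError,
)
from .records import Phantom, SeriesRegion, StudyRecord


# ---------------------------------------------------------------------------
# Conversion-factor table (DLP -> ED)
# ---------------------------------------------------------------------------

class FactorSource(str, enum.Enum):
    DEAK2010 = "deak2010"
    AAPM_RPT96 = "aapm_rpt96"
    CUSTOM = "custom"


@dataclass(frozen=True)
class ConversionFactorTable:
    """Region -> f in mSv/(mGy.cm), under a named source."""

    source: FactorSource
    factors: Mapping[SeriesRegion, float]

    def __post_init__(self) -> None:
        for region, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {region.value} must be > 0, got {f}")

    def factor(self, region: SeriesRegion) -> float:
        try:
            return self.factors[region]
        except KeyError:
            raise RegionLookupError(
                f"no conversion factor for region {region.value!r} "
                f"(source {self.source.value})"
            ) from None

    @classmethod
    def from_file(cls, path: str | Path) -> "ConversionFactorTable":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "ConversionFactorTable":
        try:
            source = FactorSource(raw.get("source", "custom"))
        except ValueError:
            source = FactorSource.CUSTOM
        factors = {
            SeriesRegion(k): float(v) for k, v in raw["factors"].items()
        }
        return cls(source=source, factors=factors)

    def to_mapping(self) -> dict:
        return {
            "source": self.source.value,
            "factors": {r.value: f for r, f in sorted(
                self.factors.items(), key=lambda kv: kv[0].value)},
        }


# ---------------------------------------------------------------------------
# Weight correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightCorrectionModel:
    """Quadratic weight factor; ~1 near 70 kg, decreasing with weight."""

    c0: float = 1.73
    c1: float = -1.33e-2   # per kg
    c2: float = 4.04e-5    # per kg^2
    valid_weight_range: tuple[float, float] = (20.0, 200.0)


def compute_wkg(
    w: float,
    model: WeightCorrectionModel | None = None,
    *,
    check_range: bool = True,
) -> float:
    """Dimensionless weight-correction factor ``c0 + c1*w + c2*w**2``."""
    model = model or WeightCorrectionModel()
    lo, hi = model.valid_weight_range
    if check_range and not (lo <= w <= hi):
        raise WeightRangeError(
            f"weight {w} kg outside valid range [{lo}, {hi}] kg"
        )
    return model.c0 + model.c1 * w + model.c2 * w * w


# ---------------------------------------------------------------------------
# ED and SED
# ---------------------------------------------------------------------------

def compute_ed(
    dlp: float, region: SeriesRegion, table: ConversionFactorTable
) -> float:
    """Effective dose in mSv: ``f(region) * DLP``."""
    if dlp < 0:
        raise ValueError(f"dlp must be >= 0, got {dlp}")
    return table.factor(region) * dlp


def compute_sed(
    dlp: float,
    region: SeriesRegion,
    table: ConversionFactorTable,
    w: float | None,
    wmodel: WeightCorrectionModel | None = None,
) -> float:
    """Size-specific effective dose in mSv: ``wkg(w) * f(region) * DLP``.

    A missing weight raises :class:`WeightMissingError` (distinct from the
    out-of-range error) rather than silently defaulting.
    """
    if w is None:
        raise WeightMissingError("patient weight required for SED")
    return compute_wkg(w, wmodel) * compute_ed(dlp, region, table)


# ---------------------------------------------------------------------------
# SSDE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SsdeModel:
    """Per-phantom exponential conversion factor ``a_e * exp(-b_e * D)``."""

    coefficients: Mapping[Phantom, tuple[float, float]] = field(
        default_factory=lambda: {
            Phantom.BODY32: (3.704369, 0.03671937),
            Phantom.HEAD16: (1.874799, 0.03871313),
        }
    )

    def __post_init__(self) -> None:
        for phantom, (a_e, b_e) in self.coefficients.items():
            if a_e <= 0 or b_e <= 0:
                raise ValueError(
                    f"SSDE coefficients for {phantom.value} must be > 0"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "SsdeModel":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        coeff = {
            Phantom(k): (float(v["a_e"]), float(v["b_e"]))
            for k, v in raw["phantoms"].items()
        }
        return cls(coefficients=coeff)

    def unity_diameter(self, phantom: Phantom) -> float:
        """Diameter (cm) at which the conversion factor is exactly 1."""
        a_e, b_e = self.coefficients[phantom]
        return math.log(a_e) / b_e


DEFF_PLAUSIBLE_CM = (6.0, 60.0)  # guards mm-vs-cm unit mix-ups


def ssde_from_deff(
    ctdi_vol: float,
    d_eff: float,
    phantom: Phantom = Phantom.BODY32,
    model: SsdeModel | None = None,
) -> float:
    """Size-specific dose estimate: ``CTDIvol * a_e * exp(-b_e * D_eff)``."""
    model = model or SsdeModel()
    lo, hi = DEFF_PLAUSIBLE_CM
    if not (lo < d_eff < hi):
        raise DiameterRangeError(
            f"effective diameter {d_eff} cm outside plausible range "
            f"({lo}, {hi}) cm -- check units (cm expected)"
        )
    if ctdi_vol < 0:
        raise ValueError(f"ctdi_vol must be >= 0, got {ctdi_vol}")
    if phantom not in model.coefficients:
        raise RegionLookupError(f"no SSDE coefficients for phantom {phantom.value}")
    a_e, b_e = model.coefficients[phantom]
    return ctdi_vol * a_e * math.exp(-b_e * d_eff)


# ---------------------------------------------------------------------------
# Diameter-basis re-mapping (effective -> water-equivalent)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DwaterMap:
    """Linear map from SSDE(D_eff) to SSDE(D_water) for chest-type regions.

    No default coefficients ship: the map must be configured explicitly,
    otherwise re-basing raises rather than applying a silent identity.
    """

    slope: float
    intercept: float
    applicable_regions: frozenset[str] = frozenset({"chest", "chest_abdomen"})

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


def ssde_to_dwater_basis(
    ssde_deff: float, map: DwaterMap | None, region: str
) -> float:
    """Re-base an effective-diameter SSDE onto the water-equivalent basis."""
    if map is None:
        raise MapNotConfiguredError(
            "D_water basis map coefficients required; configure DwaterMap "
            "explicitly (no silent identity)"
        )
    region_key = getattr(region, "value", region)
    if region_key not in map.applicable_regions:
        raise RegionLookupError(
            f"D_water map not applicable to region {region_key!r}"
        )
    return map.slope * ssde_deff + map.intercept


# ---------------------------------------------------------------------------
# SED from SSDE via calibrated segments
# ---------------------------------------------------------------------------

class MartinRegion(str, enum.Enum):
    """Scanned-region vocabulary of the SED-SSDE calibration segments."""

    CHEST = "chest"
    ABDOMEN_PELVIS = "abdomen_pelvis"
    CAP = "cap"
    ABDOMEN = "abdomen"
    CHEST_ABDOMEN = "chest_abdomen"


class SignConvention(str, enum.Enum):
    A_X_MINUS_B = "a_x_minus_b"
    A_X_PLUS_B = "a_x_plus_b"


@dataclass(frozen=True)
class MartinSegment:
    """One calibrated linear segment SED = a*SSDE -/+ b on a length window."""

    scanned_region: MartinRegion
    scan_length_window: tuple[float, float]   # cm
    a: float                                   # mSv/mGy
    b: float                                   # mSv
    sign_convention: SignConvention = SignConvention.A_X_MINUS_B
    slope_sign_flipped: bool = False  # source printed -a; magnitude used

    def __post_init__(self) -> None:
        lo, hi = self.scan_length_window
        if not lo < hi:
            raise ValueError(f"scan-length window must have lo < hi, got ({lo}, {hi})")
        if not math.isfinite(self.a):
            raise ValueError("slope a must be finite")

    def covers(self, region: MartinRegion, scan_length: float) -> bool:
        lo, hi = self.scan_length_window
        return region is self.scanned_region and lo <= scan_length <= hi

    def evaluate(self, ssde: float) -> float:
        if self.sign_convention is SignConvention.A_X_MINUS_B:
            return self.a * ssde - self.b
        return self.a * ssde + self.b


def load_segments(path: str | Path) -> list[MartinSegment]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    convention = SignConvention(raw.get("sign_convention", "a_x_minus_b"))
    segments = []
    for seg in raw["segments"]:
        lo, hi = seg["scan_length_cm"]
        segments.append(
            MartinSegment(
                scanned_region=MartinRegion(seg["region"]),
                scan_length_window=(float(lo), float(hi)),
                a=float(seg["a"]),
                b=float(seg["b"]),
                sign_convention=SignConvention(
                    seg.get("sign_convention", convention.value)
                ),
                slope_sign_flipped=bool(seg.get("slope_sign_flipped", False)),
            )
        )
    return segments


def sed_from_ssde(
    ssde: float,
    scanned_region: MartinRegion,
    scan_length: float,
    segments: Sequence[MartinSegment],
) -> float:
    """Evaluate the unique segment covering (region, scan length).

    A negative result (possible at small SSDE) is returned as-is with a
    :class:`NegativeDoseWarning` -- clamping would bias comparison slopes.
    """
    matches = [s for s in segments if s.covers(scanned_region, scan_length)]
    if not matches:
        raise CalibrationRangeError(
            f"scan length {scan_length} cm out of calibrated range for "
            f"region {scanned_region.value!r}"
        )
    if len(matches) > 1:
        raise CalibrationRangeError(
            f"ambiguous calibration: {len(matches)} segments cover "
            f"({scanned_region.value}, {scan_length} cm)"
        )
    value = matches[0].evaluate(ssde)
    if value < 0:
        warnings.warn(
            f"negative SED {value:.4g} mSv from linear map at SSDE {ssde:.4g}",
            NegativeDoseWarning,
            stacklevel=2,
        )
    return value


# ---------------------------------------------------------------------------
# Study-level totals
# ---------------------------------------------------------------------------

def study_ed_total(
    study: StudyRecord,
    table: ConversionFactorTable,
    *,
    weight_corrected: bool = False,
    wmodel: WeightCorrectionModel | None = None,
) -> float:
    """Sum per-series ED (or SED) using each series' own region label."""
    total = 0.0
    for s in study.series:
        try:
            if weight_corrected:
                total += compute_sed(s.dlp, s.series_region, table,
                                     study.patient_weight, wmodel)
            else:
                total += compute_ed(s.dlp, s.series_region, table)
        except (RegionLookupError, WeightMissingError, WeightRangeError) as exc:
            raise type(exc)(f"series {s.series_uid}: {exc}") from exc
    return total
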