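"""Loaders for the versioned constant tables shipped with the package.

Every table carries a ``source`` provenance string and can be replaced by a
user-supplied YAML file of the same shape; nothing downstream hard-codes
the numbers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .metrics import ConversionFactorTable, MartinSegment, SsdeModel, load_segments

_DATA = resources.files("ctdoseaudit") / "data"


def _data_path(name: str) -> Path:
    with resources.as_file(_DATA / name) as p:
        return Path(p)


def default_factor_table(source: str = "aapm_rpt96") -> ConversionFactorTable:
    """Shipped DLP->ED factor table; ``source`` in {aapm_rpt96, deak2010}."""
    names = {
        "aapm_rpt96": "conversion_factors_aapm_rpt96.yaml",
        "deak2010": "conversion_factors_deak2010.yaml",
    }
    if source not in names:
        raise KeyError(f"unknown factor-table source {source!r}")
    return ConversionFactorTable.from_file(_data_path(names[source]))


def default_ssde_model() -> SsdeModel:
    return SsdeModel.from_file(_data_path("ssde_coefficients.yaml"))


def default_segments() -> list[MartinSegment]:
    """Shipped SED-from-SSDE calibration segments."""
    return load_segments(_data_path("sed_ssde_segments.yaml"))


def published_audit_fits() -> dict:
    """Published region/scanner slope cells + alias counts (worked-example input)."""
    with open(_data_path("published_audit_fits.yaml"), "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)
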