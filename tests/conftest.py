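from __future__ import annotations

import pytest

from ctdoseaudit import constants
from ctdoseaudit.metrics import ConversionFactorTable, FactorSource
from ctdoseaudit.records import (
    AcquisitionType,
    Phantom,
    Scanner,
    SeriesRecord,
    SeriesRegion,
    Sex,
    StudyAlias,
    StudyRecord,
)


@pytest.fixture
def factor_table() -> ConversionFactorTable:
    """Explicit factor table used by the worked examples (never the shipped
    defaults, so default edits cannot silently change expected values)."""
    return ConversionFactorTable(
        source=FactorSource.CUSTOM,
        factors={
            SeriesRegion.HEAD: 0.0021,
            SeriesRegion.NECK: 0.0059,
            SeriesRegion.CHEST: 0.014,
            SeriesRegion.ABDOMEN_PELVIS: 0.015,
            SeriesRegion.TRUNK: 0.014666666666666666,
        },
    )


@pytest.fixture
def segments():
    return constants.default_segments()


@pytest.fixture
def make_series():
    def _make(
        study_id: str = "S1",
        series_uid: str = "S1.1",
        region: SeriesRegion = SeriesRegion.CHEST,
        dlp: float = 100.0,
        ctdi_vol: float = 5.0,
        scan_length: float = 33.0,
        acquisition: AcquisitionType = AcquisitionType.HELICAL,
        scanner: Scanner = Scanner.CT1,
        d_eff: float | None = 25.0,
        phantom: Phantom = Phantom.BODY32,
        protocol_name: str = "CHEST ROUTINE",
    ) -> SeriesRecord:
        return SeriesRecord(
            study_id=study_id,
            series_uid=series_uid,
            scanner_id=scanner,
            protocol_name=protocol_name,
            series_region=region,
            acquisition_type=acquisition,
            ctdi_vol=ctdi_vol,
            phantom=phantom,
            dlp=dlp,
            scan_length=scan_length,
            d_eff=d_eff,
        )

    return _make


@pytest.fixture
def make_study(make_series):
    def _make(
        study_id: str = "S1",
        regions=(SeriesRegion.CHEST,),
        dlps=None,
        age: float = 50.0,
        weight: float | None = 70.0,
        alias: StudyAlias = StudyAlias.CHEST,
        with_scout: bool = False,
    ) -> StudyRecord:
        series = []
        idx = 1
        if with_scout:
            series.append(make_series(
                study_id=study_id, series_uid=f"{study_id}.{idx}",
                region=regions[0], dlp=1.0, ctdi_vol=0.05,
                acquisition=AcquisitionType.SCOUT,
            ))
            idx += 1
        for j, region in enumerate(regions):
            dlp = 100.0 if dlps is None else dlps[j]
            series.append(make_series(
                study_id=study_id, series_uid=f"{study_id}.{idx}",
                region=region, dlp=dlp,
            ))
            idx += 1
        return StudyRecord(
            study_id=study_id, patient_age=age, patient_sex=Sex.F,
            patient_weight=weight, study_alias=alias, series=series,
        )

    return _make
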