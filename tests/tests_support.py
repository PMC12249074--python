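"""Plain (non-fixture) builders usable inside hypothesis @given bodies."""

from __future__ import annotations

from ctdoseaudit.records import (
    AcquisitionType,
    Phantom,
    Scanner,
    SeriesRecord,
    SeriesRegion,
    StudyAlias,
    StudyRecord,
)


def build_series(
    study_id: str,
    series_uid: str,
    region: SeriesRegion,
    dlp: float = 100.0,
    acquisition: AcquisitionType = AcquisitionType.HELICAL,
) -> SeriesRecord:
    return SeriesRecord(
        study_id=study_id,
        series_uid=series_uid,
        scanner_id=Scanner.CT1,
        protocol_name=f"{region.value} protocol",
        series_region=region,
        acquisition_type=acquisition,
        ctdi_vol=5.0,
        phantom=Phantom.HEAD16 if region is SeriesRegion.HEAD else Phantom.BODY32,
        dlp=dlp,
        scan_length=30.0,
        d_eff=20.0,
    )


def build_study(
    regions,
    dlps=None,
    study_id: str = "S1",
    age: float = 50.0,
    weight: float | None = 70.0,
) -> StudyRecord:
    series = [
        build_series(
            study_id, f"{study_id}.{i}", region,
            dlp=100.0 if dlps is None else dlps[i],
        )
        for i, region in enumerate(regions)
    ]
    return StudyRecord(
        study_id=study_id, patient_age=age, patient_weight=weight,
        study_alias=StudyAlias.CHEST, series=series,
    )
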