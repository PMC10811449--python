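"""Metadata extraction: depth-limited tag flattening and consolidation."""

import pandas as pd
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

import oculink as ol
from oculink.extraction import (ENCAPSULATED_PDF_SOP_CLASS, DicomFormatError,
                                RecordRejectedError, TagMap, TagEntry,
                                classify_image_type, parse_dicom_date)
from oculink.simulate import SyntheticConfig, emit_dicom_fixtures, generate_cohort


def _write_minimal(path, **extra):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.77.1.5.1"
    meta.MediaStorageSOPInstanceUID = "1.2.3.4"
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = "1.2.3.4"
    ds.PatientName = "DOE^JOHN^A"
    ds.Modality = "OP"
    for k, v in extra.items():
        setattr(ds, k, v)
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    return path


def test_depth_two_content_is_dropped(tmp_path):
    """Attributes inside a sub-sequence (depth 2) never reach the TagMap."""
    inner = Dataset()
    inner.CodeValue = "DEPTH2"
    mid = Dataset()
    mid.AnatomicRegionSequence = [inner]
    mid.ImageLaterality = "L"
    path = _write_minimal(tmp_path / "a.dcm", AnatomicRegionSequence=[mid])
    tm = ol.load_dicom_tags(path)
    values = [str(e.value) for e in tm.entries.values()]
    assert not any("DEPTH2" in v for v in values)
    # the depth-1 attribute inside the outer sequence IS retained
    assert tm.get_value("0020,0062") == "L"
    assert all(e.depth in (0, 1) for e in tm.entries.values())


def test_flat_file_retains_all_attributes(tmp_path):
    path = _write_minimal(tmp_path / "b.dcm", PatientSex="M")
    tm = ol.load_dicom_tags(path)
    assert tm.get_value("0010,0010") == "DOE^JOHN^A"
    assert tm.get_value("0010,0040") == "M"
    assert all(e.depth == 0 for e in tm.entries.values())


def test_non_dicom_file_raises_format_error(tmp_path):
    bad = tmp_path / "not.dcm"
    bad.write_bytes(b"definitely not dicom" * 10)
    with pytest.raises(DicomFormatError):
        ol.load_dicom_tags(bad)


def test_pixel_data_never_loaded(tmp_path):
    """A large pixel payload must not appear in the TagMap."""
    big = bytes(512 * 512)
    path = _write_minimal(tmp_path / "c.dcm", Rows=512, Columns=512,
                          BitsAllocated=8, BitsStored=8, HighBit=7,
                          PixelRepresentation=0, SamplesPerPixel=1,
                          PhotometricInterpretation="MONOCHROME2",
                          PixelData=big)
    tm = ol.load_dicom_tags(path)
    assert "7FE0,0010" not in tm


@pytest.mark.parametrize("pn,expected", [
    ("DOE^JOHN^A", {"family": "DOE", "given": "JOHN", "middle": "A",
                    "prefix": "", "suffix": ""}),
    ("", {"family": "", "given": "", "middle": "", "prefix": "", "suffix": ""}),
    ("DOE", {"family": "DOE", "given": "", "middle": "", "prefix": "",
             "suffix": ""}),
    ("A^B^C^D^E^F", {"family": "A", "given": "B", "middle": "C",
                     "prefix": "D", "suffix": "E"}),
])
def test_parse_person_name(pn, expected):
    parts = ol.parse_person_name(pn)
    assert parts == expected
    assert not any("^" in v for v in parts.values())


def test_extract_records_missing_sex_still_produces_record():
    tm = TagMap(entries={
        "0008,0018": TagEntry("SOPInstanceUID", "UI", "1.2.3", 0),
    })
    row = ol.extract_records(tm, "LOC01")
    assert row["patient_sex"] == ""
    assert row["sop_instance_uid"] == "1.2.3"


def test_extract_records_rejects_missing_sop_uid():
    tm = TagMap(entries={"0010,0010": TagEntry("PatientName", "PN", "X", 0)})
    with pytest.raises(RecordRejectedError):
        ol.extract_records(tm, "LOC01")


def test_encapsulated_pdf_is_measurement():
    tm = TagMap(entries={
        "0008,0018": TagEntry("SOPInstanceUID", "UI", "9.9.9", 0),
        "0008,0016": TagEntry("SOPClassUID", "UI", ENCAPSULATED_PDF_SOP_CLASS, 0),
        "0008,1155": TagEntry("ReferencedSOPInstanceUID", "UI", "1.2.3", 1),
    })
    row = ol.extract_records(tm, "LOC01")
    assert row["sop_class_uid"] == ENCAPSULATED_PDF_SOP_CLASS
    assert row["referenced_sop_uid"] == "1.2.3"
    patients, images = ol.consolidate_patients([row])
    assert bool(images["is_measurement"].iloc[0])


@pytest.mark.parametrize("modality,tokens,expected", [
    ("OPT", "ORIGINAL;PRIMARY", "OCT"),
    ("OP", "ORIGINAL;PRIMARY;AUTOFLUORESCENCE", "FAF"),
    ("OP", "ORIGINAL;PRIMARY;INFRARED", "IR"),
    ("OP", "ORIGINAL;PRIMARY;COLOR", "COLOR"),
    ("OP", "ORIGINAL;PRIMARY;FLUORESCEIN", "FA"),
    ("OP", "ORIGINAL;PRIMARY;ICG", "ICGA"),
    ("OP", "ORIGINAL;PRIMARY;BLUE", "BR"),
    ("MR", "", "OTHER"),
])
def test_image_type_mapping(modality, tokens, expected):
    assert classify_image_type(modality, tokens) == expected


def test_consolidate_counts_patients_visits_images():
    """Same identity in 3 files over 2 dates -> 1 patient, 2 visits, 3 images."""
    base = dict(location_id="L", patient_name="DOE^JO", patient_birthdate="19500101",
                patient_sex="F", patient_mrn="42", sop_class_uid="x",
                study_uid="s", series_uid="se", modality="OPT",
                image_type_tokens="", manufacturer="H", referenced_sop_uid="")
    rows = [dict(base, sop_instance_uid=f"1.{i}", acquisition_date=d)
            for i, d in enumerate(["20200101", "20200101", "20200301"])]
    patients, images = ol.consolidate_patients(rows)
    assert len(patients) == 1
    assert patients["n_visits"].iloc[0] == 2
    assert patients["n_images"].iloc[0] == 3
    assert patients["last_visit_date"].iloc[0] == "2020-03-01"


def test_consolidate_empty_input():
    patients, images = ol.consolidate_patients([])
    assert patients.empty and images.empty


def test_consolidate_matches_generator_ground_truth(clean_cohort):
    cfg, registry, metadata, truth = clean_cohort
    patients, images = ol.consolidate_patients(metadata)
    assert len(patients) == truth.counts["n_patients"]
    imgs = images[~images["is_measurement"]]
    assert len(imgs) == truth.counts["n_images"]
    assert imgs["visit_key"].nunique() == truth.counts["n_visits"]
    assert images["is_measurement"].sum() == truth.counts["n_measurements"]
    # per-patient image counts partition the archive
    assert patients["n_images"].sum() == len(images)
    assert set(patients["patient_key"]) == set(truth.true_links)


def test_consolidate_idempotent(clean_cohort):
    """Re-consolidating the image table of a consolidated run changes nothing."""
    _, _, metadata, _ = clean_cohort
    p1, i1 = ol.consolidate_patients(metadata)
    p2, i2 = ol.consolidate_patients(metadata)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(i1, i2)


def test_dicom_fixture_roundtrip(tmp_path, clean_cohort):
    """Fixture files re-read by the extractor reproduce the generated rows."""
    _, _, metadata, _ = clean_cohort
    sample = metadata.head(8)
    paths = emit_dicom_fixtures(sample, tmp_path)
    keys = ["patient_name", "patient_birthdate", "patient_sex", "patient_mrn",
            "sop_instance_uid", "sop_class_uid", "study_uid", "series_uid",
            "modality", "manufacturer", "acquisition_date",
            "referenced_sop_uid"]
    for path, (_, orig) in zip(paths, sample.iterrows()):
        row = ol.extract_records(ol.load_dicom_tags(path), orig["location_id"])
        for k in keys:
            assert row[k] == orig[k], k


@pytest.mark.parametrize("raw,expected", [
    ("20200315", "2020-03-15"),
    ("2020-03-15", "2020-03-15"),
    ("garbage", None),
    ("", None),
])
def test_parse_dicom_date(raw, expected):
    d = parse_dicom_date(raw)
    assert (d.isoformat() if d else None) == expected
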