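"""Synthetic multi-practice imaging archive + registry roster generator.

Emulates, at configurable scale, a two-practice ophthalmic imaging archive
and the EHR registry roster it is linked against: several modalities,
multiple images per visit, per-patient last-visit dates, OCT key-measurement
documents referencing their parent scan, a shared true patient mapping, and
the failure modes the linkage QC must catch (numeric/special-character
names, abnormal birthdates, device "test" patients, per-field missingness,
and imaging patients absent from the registry). Ground truth is returned
alongside the tables so linkage precision/recall are computable exactly.

Defaults mirror the study archive shape: ~4.6 visits per patient and ~9.1
images per visit (negative-binomial), an image-type mix proportional to the
archive's per-type image counts, contamination rates equal to the archive's
per-flag patient fractions, and an 11.8% registry-absent fraction (the
complement of the cleaned patient linkage rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import _names
from .extraction import ENCAPSULATED_PDF_SOP_CLASS, patient_key_for
from .harmonize import FLAG_DOB, FLAG_NAME, FLAG_TEST
from .linkage import LinkResult
from .report import load_icd_map

_TYPE_META = {
    # category -> (modality, image-type token, manufacturer)
    "OCT": ("OPT", "ORIGINAL;PRIMARY", "Heidelberg Engineering"),
    "FAF": ("OP", "ORIGINAL;PRIMARY;AUTOFLUORESCENCE", "Heidelberg Engineering"),
    "IR": ("OP", "ORIGINAL;PRIMARY;INFRARED", "Heidelberg Engineering"),
    "COLOR": ("OP", "ORIGINAL;PRIMARY;COLOR", "Optos"),
    "FA": ("OP", "ORIGINAL;PRIMARY;FLUORESCEIN", "Heidelberg Engineering"),
    "ICGA": ("OP", "ORIGINAL;PRIMARY;ICG", "Heidelberg Engineering"),
    "BR": ("OP", "ORIGINAL;PRIMARY;BLUE", "Heidelberg Engineering"),
}

# archive-shaped per-type image mix (proportions of per-type image counts)
_DEFAULT_TYPE_MIX = {
    "OCT": 0.20, "FAF": 0.05, "IR": 0.27, "COLOR": 0.12,
    "FA": 0.31, "ICGA": 0.03, "BR": 0.02,
}

# plausible per-diagnosis prevalence among registry patients
_DIAG_PREVALENCE = {
    "diabetic_retinopathy_with_dme": 0.14,
    "diabetic_retinopathy_without_dme": 0.17,
    "exudative_amd": 0.12,
    "nonexudative_amd": 0.21,
    "geographic_atrophy": 0.04,
    "glaucoma": 0.20,
    "retinal_vascular_occlusion": 0.09,
    "choroidal_disorders": 0.12,
    "hereditary_retinal_dystrophy": 0.04,
}

REGISTRY_COLUMNS = ["registry_id", "location_ids", "name_raw", "family",
                    "given", "middle", "birthdate", "gender", "mrn",
                    "icd_codes"]


class ConfigError(ValueError):
    """Synthetic configuration is infeasible."""


@dataclass
class SyntheticConfig:
    n_patients: int = 1000
    n_locations: int = 2
    visits_per_patient: tuple[float, float] = (4.6, 2.0)  # (mean, dispersion)
    images_per_visit: tuple[float, float] = (9.1, 3.0)
    image_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_MIX))
    p_missing: dict[str, float] = field(
        default_factory=lambda: {"mrn": 0.0, "gender": 0.0,
                                 "birthdate": 0.0, "name": 0.0})
    p_registry_absent: float = 0.118
    contamination: dict[str, float] = field(
        default_factory=lambda: {"p_numeric_name": 2365 / 54896,
                                 "p_abnormal_dob": 118 / 54896,
                                 "p_test_name": 17 / 54896})
    measurement_fraction: float = 0.10
    date_range: tuple[date, date] = (date(2014, 1, 1), date(2020, 6, 1))
    seed: int = 0

    def validate(self):
        probs = ([self.p_registry_absent, self.measurement_fraction]
                 + list(self.p_missing.values())
                 + list(self.contamination.values())
                 + list(self.image_type_mix.values()))
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if abs(sum(self.image_type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("image_type_mix must sum to 1")
        if self.n_patients < 1 or self.n_locations < 1:
            raise ConfigError("need at least one patient and one location")
        if self.date_range[0] >= self.date_range[1]:
            raise ConfigError("date_range start must precede end")


@dataclass
class GroundTruth:
    """Generator bookkeeping for exact evaluation of a pipeline run."""

    true_links: dict[str, str | None] = field(default_factory=dict)
    planted_flags: dict[str, str] = field(default_factory=dict)
    planted_diagnoses: dict[str, set] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def _nb_counts(rng, mean, dispersion, size, minimum=1):
    """Negative-binomial counts with a floor (every patient visits once)."""
    mu = max(mean - minimum, 1e-9)
    r = dispersion
    p = r / (r + mu)
    return minimum + rng.negative_binomial(r, p, size=size)


def _sample_date(rng, start: date, end: date) -> date:
    return start + timedelta(days=int(rng.integers(0, (end - start).days + 1)))


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (registry roster, per-instance imaging metadata, ground truth).

    Reproducible for a fixed seed. Every imaging patient either maps to a
    registry patient sharing its practice location (identifiers equal up to
    injected missingness) or is registry-absent; contaminated patients carry
    the configured abnormality and are registry-absent by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    locations = [f"LOC{i + 1:02d}" for i in range(config.n_locations)]
    types = sorted(config.image_type_mix)
    type_p = np.array([config.image_type_mix[t] for t in types])
    type_p = type_p / type_p.sum()
    icd_map = load_icd_map()

    seen_identities: set[tuple] = set()
    truth = GroundTruth()
    registry_rows, meta_rows = [], []
    n_visits_total = n_images_total = n_meas_total = 0
    start, end = config.date_range

    for idx in range(config.n_patients):
        loc = locations[int(rng.integers(len(locations)))]
        # unique clean identity per location
        for _ in range(100):
            family = _names.SURNAMES[int(rng.integers(len(_names.SURNAMES)))]
            given = _names.GIVEN_NAMES[int(rng.integers(len(_names.GIVEN_NAMES)))]
            middle = (_names.MIDDLE_INITIALS[int(rng.integers(
                len(_names.MIDDLE_INITIALS)))] if rng.random() < 0.6 else "")
            dob = _sample_date(rng, date(1920, 1, 1), date(2005, 12, 31))
            ident = (loc, family, given, middle, dob)
            if ident not in seen_identities:
                seen_identities.add(ident)
                break
        else:  # pragma: no cover - name pool large enough in practice
            raise ConfigError("could not draw a unique identity")
        if middle == "" and rng.random() < 0.08:
            middle = _names.SUFFIXES[int(rng.integers(len(_names.SUFFIXES)))]
        gender = ["M", "F", "O"][int(rng.choice(3, p=[0.47, 0.51, 0.02]))]
        mrn = f"{idx + 1:06d}"
        if rng.random() < 0.3:
            mrn = "00" + mrn  # leading zeros: harmonization must strip them

        # contamination draw (segments are disjoint -> at most one abnormality)
        u = rng.random()
        c = config.contamination
        flag = None
        img_family, img_given, img_dob = family, given, dob
        if u < c.get("p_numeric_name", 0.0):
            flag = FLAG_NAME
            img_family = (family + str(1 + int(rng.integers(9)))
                          if rng.random() < 0.7 else family + "#")
        elif u < c.get("p_numeric_name", 0.0) + c.get("p_abnormal_dob", 0.0):
            flag = FLAG_DOB
            img_dob = (_sample_date(rng, date(1850, 1, 1), date(1899, 12, 31))
                       if rng.random() < 0.7
                       else _sample_date(rng, end + timedelta(days=30),
                                         end + timedelta(days=400)))
        elif u < (c.get("p_numeric_name", 0.0) + c.get("p_abnormal_dob", 0.0)
                  + c.get("p_test_name", 0.0)):
            flag = FLAG_TEST
            img_given = "TEST"

        registry_absent = flag is not None or rng.random() < config.p_registry_absent
        registry_id = None
        if not registry_absent:
            registry_id = f"REG{idx + 1:07d}"
            locs = [loc]
            if config.n_locations > 1 and rng.random() < 0.05:
                extra = locations[int(rng.integers(len(locations)))]
                if extra != loc:
                    locs.append(extra)
            diag_codes = set()
            for label, prev in _DIAG_PREVALENCE.items():
                if label in icd_map and icd_map[label] and rng.random() < prev:
                    codes = icd_map[label]
                    diag_codes.add(codes[int(rng.integers(len(codes)))])
            truth.planted_diagnoses[registry_id] = diag_codes
            registry_rows.append({
                "registry_id": registry_id,
                "location_ids": ";".join(locs),
                "name_raw": f"{family}^{given}^{middle}",
                "family": family, "given": given, "middle": middle,
                "birthdate": dob.isoformat(),
                "gender": {"M": "Male", "F": "Female", "O": "Other"}[gender],
                "mrn": mrn.lstrip("0") or "0",
                "icd_codes": ";".join(sorted(diag_codes)),
            })

        # imaging-side field values after missingness injection
        pm = config.p_missing
        name_pn = (f"{img_family}^{img_given}^{middle}"
                   if rng.random() >= pm.get("name", 0.0) else "")
        bd_str = (img_dob.strftime("%Y%m%d")
                  if rng.random() >= pm.get("birthdate", 0.0) else "")
        sex = gender if rng.random() >= pm.get("gender", 0.0) else ""
        mrn_img = mrn if rng.random() >= pm.get("mrn", 0.0) else ""

        n_visits = int(_nb_counts(rng, *config.visits_per_patient, size=1)[0])
        visit_dates = sorted({_sample_date(rng, start, end)
                              for _ in range(n_visits)})
        n_visits = len(visit_dates)
        n_visits_total += n_visits
        pk = patient_key_for(loc, name_pn, bd_str, mrn_img)
        if pk in truth.true_links:
            # dedup-key collision under heavy missingness: restore the MRN so
            # the two patients stay distinct imaging identities
            mrn_img = mrn
            pk = patient_key_for(loc, name_pn, bd_str, mrn_img)
        truth.true_links[pk] = registry_id
        if flag is not None:
            truth.planted_flags[pk] = flag

        for v, vdate in enumerate(visit_dates):
            study_uid = f"1.2.826.0.1.{config.seed}.{idx + 1}.{v + 1}"
            n_img = int(_nb_counts(rng, *config.images_per_visit, size=1)[0])
            img_types = rng.choice(len(types), size=n_img, p=type_p)
            for i, ti in enumerate(img_types):
                cat = types[int(ti)]
                modality, tokens, manu = _TYPE_META[cat]
                sop = f"{study_uid}.1.{i + 1}"
                meta_rows.append({
                    "location_id": loc,
                    "patient_name": name_pn,
                    "patient_birthdate": bd_str,
                    "patient_sex": sex,
                    "patient_mrn": mrn_img,
                    "sop_instance_uid": sop,
                    "sop_class_uid": "1.2.840.10008.5.1.4.1.1.77.1.5.4"
                    if cat == "OCT" else "1.2.840.10008.5.1.4.1.1.77.1.5.1",
                    "study_uid": study_uid,
                    "series_uid": f"{study_uid}.2.{ti + 1}",
                    "modality": modality,
                    "image_type_tokens": tokens,
                    "manufacturer": manu,
                    "acquisition_date": vdate.strftime("%Y%m%d"),
                    "referenced_sop_uid": "",
                })
                n_images_total += 1
                if cat == "OCT" and rng.random() < config.measurement_fraction:
                    meta_rows.append({
                        "location_id": loc,
                        "patient_name": name_pn,
                        "patient_birthdate": bd_str,
                        "patient_sex": sex,
                        "patient_mrn": mrn_img,
                        "sop_instance_uid": sop + ".99",
                        "sop_class_uid": ENCAPSULATED_PDF_SOP_CLASS,
                        "study_uid": study_uid,
                        "series_uid": f"{study_uid}.3",
                        "modality": "DOC",
                        "image_type_tokens": "",
                        "manufacturer": manu,
                        "acquisition_date": vdate.strftime("%Y%m%d"),
                        "referenced_sop_uid": sop,
                    })
                    n_meas_total += 1

    registry = pd.DataFrame(registry_rows, columns=REGISTRY_COLUMNS)
    metadata = pd.DataFrame(meta_rows)
    truth.counts = {
        "n_patients": config.n_patients,
        "n_registry_patients": len(registry),
        "n_visits": n_visits_total,
        "n_images": n_images_total,
        "n_measurements": n_meas_total,
        "n_linkable_patients": sum(v is not None
                                   for v in truth.true_links.values()),
        "n_flagged": len(truth.planted_flags),
    }
    return registry, metadata, truth


def evaluate_linkage(result: LinkResult, truth: GroundTruth) -> dict:
    """Precision/recall/F1 and confusion counts of a link result vs truth.

    Registry-absent imaging patients that stay unlinked count as true
    negatives; a true linkable pair recovered exactly is a true positive.
    """
    known = set(truth.true_links)
    got = set(result.links) | result.unlinked_patient_keys
    unknown = got - known
    if unknown:
        raise ValueError(f"result contains {len(unknown)} patient keys "
                         "absent from ground truth (mismatched cohorts?)")
    tp = fp = tn = 0
    n_linkable = sum(1 for rid in truth.true_links.values() if rid is not None)
    for pk, true_rid in truth.true_links.items():
        linked = result.links.get(pk)
        if linked is not None:
            rid = linked[0]
            if true_rid is not None and rid == true_rid:
                tp += 1
            else:
                fp += 1
        elif true_rid is None:
            tn += 1
    # a mislinked patient counts against both precision and recall
    fn = n_linkable - tp
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / n_linkable if n_linkable else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def emit_dicom_fixtures(metadata: pd.DataFrame, out_dir) -> list[str]:
    """Write minimal valid DICOM Part-10 files for a metadata table.

    Image rows get a tiny pixel payload; measurement rows get an encapsulated
    PDF stub with a reference to their parent scan. The first image file also
    carries a sequence containing a nested sub-sequence, to exercise the
    depth-2 drop rule of the extractor.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    first_image_done = False
    for n, row in enumerate(metadata.to_dict("records")):
        is_meas = row["sop_class_uid"] == ENCAPSULATED_PDF_SOP_CLASS
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = row["sop_class_uid"] or \
            "1.2.840.10008.5.1.4.1.1.77.1.5.1"
        meta.MediaStorageSOPInstanceUID = row["sop_instance_uid"]
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = row["sop_instance_uid"]
        ds.StudyInstanceUID = row["study_uid"]
        ds.SeriesInstanceUID = row["series_uid"]
        ds.PatientName = row["patient_name"]
        ds.PatientID = row["patient_mrn"]
        ds.PatientBirthDate = row["patient_birthdate"]
        ds.PatientSex = row["patient_sex"]
        ds.Modality = row["modality"]
        if row["image_type_tokens"]:
            ds.ImageType = row["image_type_tokens"].split(";")
        ds.Manufacturer = row["manufacturer"]
        ds.AcquisitionDate = row["acquisition_date"]
        ds.StudyDate = row["acquisition_date"]
        if is_meas:
            ref = Dataset()
            ref.ReferencedSOPClassUID = "1.2.840.10008.5.1.4.1.1.77.1.5.4"
            ref.ReferencedSOPInstanceUID = row["referenced_sop_uid"]
            ds.ReferencedImageSequence = [ref]
            ds.EncapsulatedDocument = b"%PDF-1.4 synthetic measurement stub\n%%EOF"
            ds.MIMETypeOfEncapsulatedDocument = "application/pdf"
        else:
            ds.Rows = 2
            ds.Columns = 2
            ds.BitsAllocated = 8
            ds.BitsStored = 8
            ds.HighBit = 7
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.PixelData = bytes([0, 64, 128, 255])
            if not first_image_done:
                # depth-1 sequence carrying a depth-2 sub-sequence: content of
                # the sub-sequence must be dropped by the extractor
                inner = Dataset()
                inner.CodeValue = "SECRET-DEPTH2"
                inner.CodeMeaning = "should never surface"
                mid = Dataset()
                mid.AnatomicRegionSequence = [inner]
                mid.ImageLaterality = "R"
                ds.AnatomicRegionSequence = [mid]
                first_image_done = True
        path = out_dir / f"img_{n:06d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(str(path))
    return paths


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["date_range"] = [config.date_range[0].isoformat(),
                       config.date_range[1].isoformat()]
    return d
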