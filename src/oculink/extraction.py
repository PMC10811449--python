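"""DICOM metadata extraction and per-archive consolidation.

Reads DICOM Part-10 files (never the pixel payload), flattens the first two
attribute levels (top-level attributes plus attributes directly inside one
level of sequence nesting) into a :class:`TagMap`, extracts the identifier
and image fields needed for record linkage, and consolidates per-instance
records into an imaging-side patient table and an image table.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pydicom
from pydicom.errors import InvalidDicomError

log = logging.getLogger(__name__)

ENCAPSULATED_PDF_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.104.1"

#: canonical column order of the flat per-instance metadata table
INSTANCE_COLUMNS = [
    "location_id",
    "patient_name",
    "patient_birthdate",
    "patient_sex",
    "patient_mrn",
    "sop_instance_uid",
    "sop_class_uid",
    "study_uid",
    "series_uid",
    "modality",
    "image_type_tokens",
    "manufacturer",
    "acquisition_date",
    "referenced_sop_uid",
]

IMAGE_CATEGORIES = ("OCT", "FAF", "IR", "COLOR", "FA", "ICGA", "BR", "OTHER")

# Manufacturer-metadata driven mapping from (Modality, ImageType tokens) to
# the seven ophthalmic image categories. First matching rule wins.
DEFAULT_IMAGE_TYPE_RULES = [
    {"modality": "OPT", "image_type": "OCT"},
    {"modality": "OP", "tokens_any": ["AUTOFLUORESCENCE", "FAF"], "image_type": "FAF"},
    {"modality": "OP", "tokens_any": ["INFRARED", "IR"], "image_type": "IR"},
    {"modality": "OP", "tokens_any": ["FLUORESCEIN", "FA"], "image_type": "FA"},
    {"modality": "OP", "tokens_any": ["ICG", "ICGA"], "image_type": "ICGA"},
    {"modality": "OP", "tokens_any": ["BLUE", "BR"], "image_type": "BR"},
    {"modality": "OP", "tokens_any": ["COLOR"], "image_type": "COLOR"},
    {"modality": "XC", "image_type": "COLOR"},
]


class DicomFormatError(ValueError):
    """File is not a DICOM Part-10 object."""


class DicomParseError(ValueError):
    """File looks like DICOM but could not be parsed."""


class RecordRejectedError(ValueError):
    """Instance lacks an attribute required for deduplication/linkage."""


@dataclass
class TagEntry:
    keyword: str
    vr: str
    value: object
    depth: int


@dataclass
class TagMap:
    """Flat view of the first two metadata levels of one DICOM object."""

    entries: dict[str, TagEntry] = field(default_factory=dict)

    def get_value(self, tag: str, default=None):
        entry = self.entries.get(tag)
        if entry is None or entry.value in (None, ""):
            return default
        return entry.value

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, tag: str) -> bool:
        return tag in self.entries


def _tag_key(tag) -> str:
    return f"{tag.group:04X},{tag.element:04X}"


def _element_value(elem):
    if elem.VR == "PN":
        return str(elem.value) if elem.value is not None else ""
    if isinstance(elem.value, (list, pydicom.multival.MultiValue)):
        return [str(v) for v in elem.value]
    if isinstance(elem.value, bytes):
        return elem.value
    if elem.value is None:
        return ""
    return str(elem.value) if not isinstance(elem.value, (int, float)) else elem.value


def load_dicom_tags(path) -> TagMap:
    """Read one DICOM file into a :class:`TagMap`.

    Top-level attributes (depth 0) and attributes directly inside sequence
    items (depth 1) are retained; anything nested deeper is dropped. The
    pixel payload is never read into the record.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True, force=False)
    except InvalidDicomError as exc:
        raise DicomFormatError(f"not a DICOM Part-10 file: {path}") from exc
    except Exception as exc:  # truncated / corrupt stream
        raise DicomParseError(f"failed to parse DICOM file {path}: {exc}") from exc

    tm = TagMap()
    for elem in ds:
        key = _tag_key(elem.tag)
        if elem.VR == "SQ":
            tm.entries[key] = TagEntry(elem.keyword or "", "SQ", None, 0)
            for item in elem.value:
                for sub in item:
                    if sub.VR == "SQ":
                        log.debug("dropping depth>=2 sequence %s in %s",
                                  _tag_key(sub.tag), path)
                        continue
                    sub_key = _tag_key(sub.tag)
                    if sub_key in tm.entries:
                        continue  # first occurrence wins; tag keys stay unique
                    tm.entries[sub_key] = TagEntry(
                        sub.keyword or "", sub.VR, _element_value(sub), 1)
        else:
            if key not in tm.entries:
                tm.entries[key] = TagEntry(
                    elem.keyword or "", elem.VR, _element_value(elem), 0)
    return tm


def parse_person_name(pn: str) -> dict[str, str]:
    """Split a caret-delimited DICOM PN string into its five components."""
    parts = ["", "", "", "", ""]
    if pn:
        tokens = str(pn).split("^")
        if len(tokens) > 5:
            log.warning("person name has %d components, keeping first 5: %r",
                        len(tokens), pn)
            tokens = tokens[:5]
        for i, tok in enumerate(tokens):
            parts[i] = tok
    return dict(zip(("family", "given", "middle", "prefix", "suffix"), parts))


def parse_dicom_date(value) -> date | None:
    """Parse a DICOM DA value (YYYYMMDD) or ISO date; unparseable -> None."""
    if value in (None, ""):
        return None
    s = str(value).strip()
    for fmt in ("%Y%m%d", "%Y-%m-%d"):
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    log.debug("unparseable date value %r -> missing", value)
    return None


def classify_image_type(modality, image_type_tokens, sop_class_uid=None,
                        manufacturer=None, rules=None) -> str:
    """Map manufacturer metadata to one of the image categories.

    ``image_type_tokens`` is the DICOM ImageType multi-value (list or
    backslash/semicolon-joined string). Unmapped combinations -> OTHER.
    """
    if rules is None:
        rules = DEFAULT_IMAGE_TYPE_RULES
    if isinstance(image_type_tokens, str):
        tokens = [t for t in image_type_tokens.replace("\\", ";").split(";") if t]
    else:
        tokens = list(image_type_tokens or [])
    tokens = {str(t).upper() for t in tokens}
    modality = (modality or "").upper()
    manufacturer = (manufacturer or "").upper()
    for rule in rules:
        if "modality" in rule and rule["modality"] != modality:
            continue
        if "sop_class_uid" in rule and rule["sop_class_uid"] != sop_class_uid:
            continue
        if "manufacturer" in rule and rule["manufacturer"].upper() not in manufacturer:
            continue
        if "tokens_any" in rule and not tokens.intersection(
                t.upper() for t in rule["tokens_any"]):
            continue
        return rule["image_type"]
    return "OTHER"


def extract_records(tags: TagMap, location_id: str) -> dict:
    """Extract one flat per-instance metadata row from a TagMap.

    Missing tags yield empty fields, never a failure — except a missing
    SOPInstanceUID, which makes the instance unusable for deduplication and
    measurement linkage and rejects the record.
    """
    sop_uid = tags.get_value("0008,0018")
    if not sop_uid:
        raise RecordRejectedError("missing SOPInstanceUID; record rejected")

    itt = tags.get_value("0008,0008", [])
    if isinstance(itt, str):
        itt = [itt]
    row = {
        "location_id": str(location_id),
        "patient_name": str(tags.get_value("0010,0010", "") or ""),
        "patient_birthdate": str(tags.get_value("0010,0030", "") or ""),
        "patient_sex": str(tags.get_value("0010,0040", "") or ""),
        "patient_mrn": str(tags.get_value("0010,0020", "") or ""),
        "sop_instance_uid": str(sop_uid),
        "sop_class_uid": str(tags.get_value("0008,0016", "") or ""),
        "study_uid": str(tags.get_value("0020,000D", "") or ""),
        "series_uid": str(tags.get_value("0020,000E", "") or ""),
        "modality": str(tags.get_value("0008,0060", "") or ""),
        "image_type_tokens": ";".join(str(t) for t in itt),
        "manufacturer": str(tags.get_value("0008,0070", "") or ""),
        "acquisition_date": str(
            tags.get_value("0008,0022")
            or tags.get_value("0008,0023")
            or tags.get_value("0008,0021")
            or tags.get_value("0008,0020")
            or ""),
        "referenced_sop_uid": str(tags.get_value("0008,1155", "") or ""),
    }
    return row


def patient_key_for(location_id, name_raw, birthdate, mrn) -> str:
    """Deterministic opaque key for one imaging-side patient identity."""
    blob = "|".join(str(x) if x is not None else ""
                    for x in (location_id, name_raw, birthdate, mrn))
    return hashlib.sha1(blob.encode("utf-8")).hexdigest()[:16]


def _mode_first(series: pd.Series) -> str:
    vals = [v for v in series if v not in (None, "")]
    if not vals:
        return ""
    counts = pd.Series(vals).value_counts()
    top = counts[counts == counts.iloc[0]].index
    if len(counts) > 1:
        log.debug("conflicting values %s; keeping modal %r",
                  dict(counts), sorted(top)[0])
    return sorted(top)[0]


def consolidate_patients(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deduplicate per-instance rows into patient and image tables.

    ``records`` is an iterable of row dicts (from :func:`extract_records`)
    or a DataFrame in the ``INSTANCE_COLUMNS`` schema. Imaging patients are
    deduplicated on (location_id, patient_name, patient_birthdate,
    patient_mrn); ``last_visit_date`` is the max acquisition date over a
    patient's instances, and one calendar acquisition date = one visit.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        patients = pd.DataFrame(columns=[
            "patient_key", "location_id", "name_raw", "family", "given",
            "middle", "prefix", "suffix", "birthdate", "gender", "mrn",
            "last_visit_date", "n_visits", "n_images"])
        images = pd.DataFrame(columns=[
            "sop_instance_uid", "study_uid", "series_uid", "patient_key",
            "image_type", "manufacturer", "acquisition_date", "visit_key",
            "is_measurement", "referenced_sop_uid"])
        return patients, images

    for col in INSTANCE_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df.fillna("").astype({c: str for c in INSTANCE_COLUMNS})

    # SOPInstanceUID is the archive-wide primary key; exact re-sends dropped
    dup = df.duplicated(subset="sop_instance_uid", keep="first")
    if dup.any():
        log.warning("dropping %d duplicate SOP instances", int(dup.sum()))
        df = df[~dup]

    key_cols = ["location_id", "patient_name", "patient_birthdate", "patient_mrn"]
    df["patient_key"] = [
        patient_key_for(*vals) for vals in df[key_cols].itertuples(index=False)
    ]
    df["acq_date"] = df["acquisition_date"].map(parse_dicom_date)
    df["image_type"] = [
        classify_image_type(m, t, s, mf)
        for m, t, s, mf in zip(df["modality"], df["image_type_tokens"],
                               df["sop_class_uid"], df["manufacturer"])
    ]
    df["is_measurement"] = df["sop_class_uid"] == ENCAPSULATED_PDF_SOP_CLASS

    grouped = df.groupby("patient_key", sort=True)
    rows = []
    for pk, g in grouped:
        name_raw = g["patient_name"].iloc[0]
        parts = parse_person_name(name_raw)
        dates = [d for d in g["acq_date"] if d is not None]
        rows.append({
            "patient_key": pk,
            "location_id": g["location_id"].iloc[0],
            "name_raw": name_raw,
            **parts,
            "birthdate": g["patient_birthdate"].iloc[0],
            "gender": _mode_first(g["patient_sex"]),
            "mrn": g["patient_mrn"].iloc[0],
            "last_visit_date": max(dates).isoformat() if dates else "",
            "n_visits": len({d for d in dates}),
            "n_images": len(g),
        })
    patients = pd.DataFrame(rows)

    images = df[[
        "sop_instance_uid", "study_uid", "series_uid", "patient_key",
        "image_type", "manufacturer", "referenced_sop_uid", "is_measurement",
    ]].copy()
    images["acquisition_date"] = [
        d.isoformat() if d is not None else "" for d in df["acq_date"]]
    images["visit_key"] = images["patient_key"] + "@" + images["acquisition_date"]
    images = images[[
        "sop_instance_uid", "study_uid", "series_uid", "patient_key",
        "image_type", "manufacturer", "acquisition_date", "visit_key",
        "is_measurement", "referenced_sop_uid"]].reset_index(drop=True)
    return patients, images


def extract_archive(root, location_id, errors: list | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Walk a directory tree of DICOM files and consolidate it."""
    rows = []
    for path in sorted(Path(root).rglob("*.dcm")):
        try:
            rows.append(extract_records(load_dicom_tags(path), location_id))
        except (DicomFormatError, DicomParseError, RecordRejectedError) as exc:
            log.warning("skipping %s: %s", path, exc)
            if errors is not None:
                errors.append((str(path), str(exc)))
    return consolidate_patients(rows)


def read_metadata_table(path) -> pd.DataFrame:
    """Read a pre-extracted per-instance metadata table (CSV or Parquet)."""
    path = Path(path)
    if path.suffix.lower() in (".parquet", ".pq"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in INSTANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")
    return df.fillna("")
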