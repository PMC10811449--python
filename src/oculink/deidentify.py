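"""PHI masking and deterministic patient-ID tokenization.

Masking replaces the values of policy-listed DICOM attributes while keeping
the attributes themselves in place, so the masked object still carries the
same tag census and re-serializes as a standards-valid dataset. Patient IDs
are replaced by a keyed one-way token (HMAC-SHA256 truncated to 128 bits),
deterministic per (identifier, salt), so the one-to-one linkage survives
de-identification. Masking is intended to run after linkage.
"""

from __future__ import annotations

import hashlib
import hmac
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pydicom
import yaml
from pydicom.tag import Tag

from .extraction import TagEntry, TagMap

log = logging.getLogger(__name__)

ACTIONS = ("blank", "fixed_literal", "remove_value")

#: linkage-critical attributes that a policy may never mask
CRITICAL_TAGS = frozenset({
    "0008,0016",  # SOPClassUID
    "0008,0018",  # SOPInstanceUID
    "0008,1155",  # ReferencedSOPInstanceUID
    "0020,000D",  # StudyInstanceUID
    "0020,000E",  # SeriesInstanceUID
})

# VRs whose values can safely hold an arbitrary text literal
_TEXT_VRS = {"PN", "LO", "SH", "LT", "ST", "UT", "CS", "AE", "UC"}

_DEFAULT_POLICY_PATH = Path(__file__).parent / "data" / "phi_policy.yaml"


class PolicyError(ValueError):
    """PHI policy is malformed or masks a linkage-critical attribute."""


@dataclass
class PhiPolicy:
    """Masking action per DICOM tag; structure is always preserved."""

    actions: dict[str, str] = field(default_factory=dict)
    literal: str = "REMOVED"
    keep_structure: bool = True

    def __post_init__(self):
        for tag, action in self.actions.items():
            if action not in ACTIONS:
                raise PolicyError(f"unknown action {action!r} for tag {tag}")
            if tag.upper() in CRITICAL_TAGS:
                raise PolicyError(
                    f"policy must not mask linkage-critical tag {tag}")
        self.actions = {t.upper(): a for t, a in self.actions.items()}


def load_policy(path=None) -> PhiPolicy:
    """Load a PHI policy from YAML (the packaged default when no path)."""
    path = Path(path) if path else _DEFAULT_POLICY_PATH
    raw = yaml.safe_load(path.read_text())
    return PhiPolicy(actions=dict(raw.get("tags", {})),
                     literal=str(raw.get("literal", "REMOVED")))


def _masked_value(vr: str, action: str, literal: str):
    if action == "remove_value":
        return None
    if action == "fixed_literal":
        if vr in _TEXT_VRS:
            return literal
        log.warning("fixed_literal incompatible with VR %s; blanking", vr)
    return ""


def mask_phi_tags(tags: TagMap, policy: PhiPolicy) -> TagMap:
    """Mask policy tags in a TagMap; keyword, VR and tag set are preserved."""
    out = TagMap()
    for key, entry in tags.entries.items():
        action = policy.actions.get(key)
        if action is None:
            out.entries[key] = TagEntry(entry.keyword, entry.vr, entry.value,
                                        entry.depth)
        else:
            out.entries[key] = TagEntry(
                entry.keyword, entry.vr,
                _masked_value(entry.vr, action, policy.literal), entry.depth)
    return out


def _mask_dataset_inplace(ds: pydicom.Dataset, policy: PhiPolicy,
                          audit: dict[str, int]):
    for elem in ds:
        if elem.VR == "SQ":
            for item in elem.value:
                _mask_dataset_inplace(item, policy, audit)
            continue
        key = f"{elem.tag.group:04X},{elem.tag.element:04X}"
        action = policy.actions.get(key)
        if action is not None:
            elem.value = _masked_value(elem.VR, action, policy.literal)
            audit[key] = audit.get(key, 0) + 1


def mask_dataset(ds: pydicom.Dataset, policy: PhiPolicy
                 ) -> tuple[pydicom.Dataset, dict[str, int]]:
    """Mask a pydicom dataset (all nesting depths); returns (ds, audit)."""
    audit: dict[str, int] = {}
    _mask_dataset_inplace(ds, policy, audit)
    return ds, audit


def tokenize_patient_id(patient_id: str, salt: str) -> str:
    """Deterministic 32-hex-char anonymous token for a patient identifier."""
    if not patient_id:
        raise ValueError("patient_id must be non-empty")
    if not salt:
        raise ValueError("empty salt refused: tokens would be reversible "
                         "by dictionary attack")
    digest = hmac.new(salt.encode("utf-8"), str(patient_id).encode("utf-8"),
                      hashlib.sha256).hexdigest()
    return digest[:32]


def deidentify_file(src, dst, policy: PhiPolicy, salt: str) -> dict[str, int]:
    """Mask one DICOM file and tokenize its PatientID; returns the audit map."""
    ds = pydicom.dcmread(src)
    ds, audit = mask_dataset(ds, policy)
    pid = str(getattr(ds, "PatientID", "") or "")
    if pid:
        ds.PatientID = tokenize_patient_id(pid, salt)
        audit["0010,0020"] = audit.get("0010,0020", 0) + 1
    Path(dst).parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(dst, enforce_file_format=True)
    return audit


def tokenize_tables(patients, images, salt: str):
    """Replace patient keys in the linked tables with anonymous tokens."""
    mapping = {pk: tokenize_patient_id(pk, salt)
               for pk in patients["patient_key"]}
    p = patients.copy()
    p["patient_key"] = p["patient_key"].map(mapping)
    for col in ("name_raw", "family", "given", "middle", "prefix", "suffix",
                "birthdate", "mrn", "name_norm", "mrn_norm", "birthdate_norm"):
        if col in p.columns:
            p[col] = ""
    i = images.copy()
    i["patient_key"] = i["patient_key"].map(mapping)
    i["visit_key"] = i["patient_key"] + "@" + i["acquisition_date"].astype(str)
    return p, i, mapping
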