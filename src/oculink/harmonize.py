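"""Identifier harmonization and failed-linkage QC exclusions.

Both sides of the linkage (imaging-archive patients and registry roster
patients) are normalized to one canonical identity form so that the exact
match rules in :mod:`oculink.linkage` compare like with like. The QC step
flags imaging patients whose metadata makes a trustworthy link impossible:
names containing digits (Roman-numeral generational suffixes exempt) or
special characters, implausible birthdates, and device "test" patients.
A patient matching several criteria carries exactly one flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date

import pandas as pd

from .extraction import parse_dicom_date, parse_person_name

FLAG_NAME = "NAME_NUMERIC_OR_SPECIAL"
FLAG_DOB = "ABNORMAL_DOB"
FLAG_TEST = "TEST_NAME"
#: flag priority = report row order; a patient is counted under the first hit
FLAG_ORDER = (FLAG_NAME, FLAG_DOB, FLAG_TEST)

DOB_FLOOR = date(1900, 1, 1)

_ROMAN_RE = re.compile(r"^M{0,3}(CM|CD|D?C{0,3})(XC|XL|L?X{0,3})(IX|IV|V?I{0,3})$")
_GENDER_MAP = {
    "M": "M", "MALE": "M", "1": "M",
    "F": "F", "FEMALE": "F", "2": "F",
    "O": "O", "OTHER": "O",
}
_NAME_ALLOWED = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ -'")


@dataclass(frozen=True)
class NormalizedIdentity:
    name_norm: str
    birthdate: date | None
    gender: str  # "M", "F", "O" or "" (missing)
    mrn_norm: str
    location_id: str


def normalize_name(name_raw: str = "", *, family: str = "", given: str = "",
                   middle: str = "") -> str:
    """Canonical name form: FAMILY GIVEN MIDDLE, upper-case, single-spaced.

    Periods and commas are dropped; digits and any other character survive so
    the QC rules can still see them. Idempotent.
    """
    if family or given or middle:
        text = " ".join(p for p in (family, given, middle) if p)
    elif "^" in (name_raw or ""):
        parts = parse_person_name(name_raw)
        text = " ".join(p for p in (parts["family"], parts["given"],
                                    parts["middle"]) if p)
    else:
        text = name_raw or ""
    text = text.replace(".", " ").replace(",", " ").upper()
    return " ".join(text.split())


def normalize_mrn(mrn) -> str:
    """Strip whitespace and leading zeros ("000123" and "123" agree)."""
    s = str(mrn or "").strip()
    if not s:
        return ""
    stripped = s.lstrip("0")
    if not stripped and s:
        return "0"
    return stripped


def normalize_gender(value) -> str:
    return _GENDER_MAP.get(str(value or "").strip().upper(), "")


def normalize_identity(*, name_raw="", family="", given="", middle="",
                       birthdate=None, gender="", mrn="",
                       location_id="") -> NormalizedIdentity:
    """Build the canonical comparable identity from raw fields.

    Missingness propagates: absent fields come out empty/None, never raise.
    Normalizing an already-normalized identity is a no-op.
    """
    bd = birthdate if isinstance(birthdate, date) else parse_dicom_date(birthdate)
    return NormalizedIdentity(
        name_norm=normalize_name(name_raw, family=family, given=given,
                                 middle=middle),
        birthdate=bd,
        gender=normalize_gender(gender),
        mrn_norm=normalize_mrn(mrn),
        location_id=str(location_id or ""),
    )


def normalize_patients(df: pd.DataFrame) -> pd.DataFrame:
    """Add name_norm / mrn_norm / gender_norm / birthdate_norm columns."""
    out = df.copy()
    if out.empty:
        for col in ("name_norm", "mrn_norm", "gender_norm", "birthdate_norm"):
            out[col] = pd.Series(dtype=object)
        return out
    has_parts = {"family", "given", "middle"}.issubset(out.columns)
    if has_parts:
        out["name_norm"] = [
            normalize_name(nr, family=f, given=g, middle=m)
            for nr, f, g, m in zip(out.get("name_raw", ""), out["family"],
                                   out["given"], out["middle"])]
    else:
        out["name_norm"] = [normalize_name(nr) for nr in out["name_raw"]]
    out["mrn_norm"] = [normalize_mrn(m) for m in out["mrn"]]
    out["gender_norm"] = [normalize_gender(g) for g in out["gender"]]
    out["birthdate_norm"] = [
        d.isoformat() if (d := parse_dicom_date(b)) is not None else ""
        for b in out["birthdate"]]
    return out


def is_roman_numeral(token: str) -> bool:
    """True iff ``token`` is a canonical upper-case Roman numeral (1-3999)."""
    return bool(token) and _ROMAN_RE.fullmatch(token) is not None


def _name_abnormal(name_norm: str) -> bool:
    for tok in name_norm.split():
        if any(ch.isdigit() for ch in tok) and not is_roman_numeral(tok):
            return True
    return any(ch not in _NAME_ALLOWED and not ch.isdigit() for ch in name_norm)


def flag_exclusion(identity: NormalizedIdentity, cutoff_date: date,
                   test_word_boundary: bool = False) -> str | None:
    """Return the single QC flag for one normalized identity, or None.

    Checks in priority order: digits/special characters in the name (tokens
    that are wholly Roman numerals are exempt), birthdate before 1900-01-01
    or after the archive cutoff date, and the word "test" in the name
    (substring by default; ``test_word_boundary`` restricts to whole tokens).
    """
    if _name_abnormal(identity.name_norm):
        return FLAG_NAME
    if identity.birthdate is not None and (
            identity.birthdate < DOB_FLOOR or identity.birthdate > cutoff_date):
        return FLAG_DOB
    if test_word_boundary:
        if re.search(r"\bTEST\b", identity.name_norm):
            return FLAG_TEST
    elif "TEST" in identity.name_norm:
        return FLAG_TEST
    return None


def apply_exclusions(patients: pd.DataFrame, cutoff_date: date | None = None,
                     test_word_boundary: bool = False) -> pd.DataFrame:
    """Flag a normalized patient table; adds an ``exclusion`` column.

    ``cutoff_date`` defaults to the archive's latest last-visit date.
    """
    out = patients.copy()
    if out.empty:
        out["exclusion"] = pd.Series(dtype=object)
        return out
    if cutoff_date is None:
        dates = [parse_dicom_date(d) for d in out.get("last_visit_date", [])]
        dates = [d for d in dates if d is not None]
        cutoff_date = max(dates) if dates else date.today()
    out["exclusion"] = [
        flag_exclusion(
            NormalizedIdentity(nm, parse_dicom_date(bd), "", "", ""),
            cutoff_date, test_word_boundary) or ""
        for nm, bd in zip(out["name_norm"], out["birthdate_norm"])]
    return out


def qc_report(patients: pd.DataFrame, images: pd.DataFrame) -> pd.DataFrame:
    """Per-flag patient and image counts (rows mutually exclusive)."""
    rows = []
    for flag in FLAG_ORDER:
        flagged = patients.loc[patients["exclusion"] == flag, "patient_key"]
        n_img = int(images["patient_key"].isin(set(flagged)).sum()) if len(images) else 0
        rows.append({"flag": flag, "n_patients": int(len(flagged)),
                     "n_images": n_img})
    return pd.DataFrame(rows)
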