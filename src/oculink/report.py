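"""Linkage-quality reporting: cohort diagram, stratified rates, diagnosis cohorts.

Rates are percentages on the 0-100 scale with half-up rounding; headline
(initial and cleaned) rates are reported at one decimal, stratum rates at
two. "Cleaned" rates remove QC-flagged patients (and their images) from the
denominators only: flagged records are unlinkable by construction, so
exclusion re-expresses the rate over the eligible pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .extraction import parse_dicom_date
from .harmonize import FLAG_ORDER
from .linkage import LinkResult


def compute_rate(linked: int, total: int, decimals: int = 2) -> float:
    """100 * linked / total, rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("rate undefined for total <= 0")
    if not 0 <= linked <= total:
        raise ValueError("linked count must lie in [0, total]")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(linked) * 100 / Decimal(total))
                 .quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LinkageReport:
    """Cohort-diagram counts plus initial and cleaned linkage rates."""

    total_patients: int
    linked_patients: int
    total_images: int
    linked_images: int
    excluded_patients_by_flag: dict[str, int] = field(default_factory=dict)
    excluded_images_by_flag: dict[str, int] = field(default_factory=dict)
    initial_patient_rate_pct: float = 0.0
    initial_image_rate_pct: float = 0.0
    cleaned_patient_rate_pct: float = 0.0
    cleaned_image_rate_pct: float = 0.0

    @property
    def cleaned_patient_denominator(self) -> int:
        return self.total_patients - sum(self.excluded_patients_by_flag.values())

    @property
    def cleaned_image_denominator(self) -> int:
        return self.total_images - sum(self.excluded_images_by_flag.values())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cleaned_patient_denominator"] = self.cleaned_patient_denominator
        d["cleaned_image_denominator"] = self.cleaned_image_denominator
        return d


def build_cohort_diagram(*, total_patients: int, linked_patients: int,
                         total_images: int, linked_images: int,
                         excluded_patients_by_flag: dict[str, int] | None = None,
                         excluded_images_by_flag: dict[str, int] | None = None,
                         headline_decimals: int = 1) -> LinkageReport:
    """Assemble the cohort diagram from counts.

    Initial rates use the full denominators; cleaned rates deduct the
    per-flag exclusion counts (mutually exclusive by construction) from the
    denominators while the linked numerators are unchanged.
    """
    epf = dict(excluded_patients_by_flag or {})
    eif = dict(excluded_images_by_flag or {})
    rep = LinkageReport(
        total_patients=int(total_patients), linked_patients=int(linked_patients),
        total_images=int(total_images), linked_images=int(linked_images),
        excluded_patients_by_flag=epf, excluded_images_by_flag=eif)
    rep.initial_patient_rate_pct = compute_rate(
        rep.linked_patients, rep.total_patients, headline_decimals)
    rep.initial_image_rate_pct = compute_rate(
        rep.linked_images, rep.total_images, headline_decimals)
    rep.cleaned_patient_rate_pct = compute_rate(
        rep.linked_patients, rep.cleaned_patient_denominator, headline_decimals)
    rep.cleaned_image_rate_pct = compute_rate(
        rep.linked_images, rep.cleaned_image_denominator, headline_decimals)
    return rep


def cohort_diagram_from_tables(patients: pd.DataFrame, images: pd.DataFrame,
                               result: LinkResult) -> LinkageReport:
    """Cohort diagram computed from the pipeline tables themselves."""
    imgs = images[~images["is_measurement"]] if "is_measurement" in images \
        else images
    linked_pk = set(result.links)
    flagged = patients[patients.get("exclusion", "") != ""]
    epf, eif = {}, {}
    for flag in FLAG_ORDER:
        pks = set(flagged.loc[flagged["exclusion"] == flag, "patient_key"])
        epf[flag] = len(pks)
        eif[flag] = int(imgs["patient_key"].isin(pks).sum())
    return build_cohort_diagram(
        total_patients=len(patients),
        linked_patients=int(patients["patient_key"].isin(linked_pk).sum()),
        total_images=len(imgs),
        linked_images=int(imgs["patient_key"].isin(linked_pk).sum()),
        excluded_patients_by_flag=epf, excluded_images_by_flag=eif)


def _year_window_label(cutoff: date, k: int) -> str:
    end_year = cutoff.year - k
    return f"{end_year}-{end_year + 1}"


def _window_index(d: date, cutoff: date) -> int:
    """Index of the 12-month window (anchored at cutoff) containing ``d``."""
    k = 0
    while d <= _shift_years(cutoff, -(k + 1)):
        k += 1
    return k


def _shift_years(d: date, dy: int) -> date:
    try:
        return d.replace(year=d.year + dy)
    except ValueError:  # Feb 29
        return d.replace(year=d.year + dy, day=28)


def stratify_report(patients: pd.DataFrame, images: pd.DataFrame,
                    result: LinkResult, by: str,
                    cutoff_date: date | None = None) -> pd.DataFrame:
    """Linkage rate per stratum.

    ``by="last_visit_year"`` groups images by their patient's last imaging
    visit into consecutive 12-month windows ending at the archive cutoff
    date, labeled "YYYY-YYYY+1" (latest first). ``by="image_type"`` counts
    unique patients per image category (a patient contributes to every
    category they have images of, OTHER included).
    """
    linked_pk = set(result.links)
    imgs = images[~images["is_measurement"]] if "is_measurement" in images \
        else images
    rows = []
    if by == "last_visit_year":
        lv = {pk: parse_dicom_date(d) for pk, d in
              zip(patients["patient_key"], patients["last_visit_date"])}
        dates = [d for d in lv.values() if d is not None]
        if cutoff_date is None:
            if not dates:
                return pd.DataFrame(columns=["stratum_label", "total_count",
                                             "linked_count", "rate_pct"])
            cutoff_date = max(dates)
        counts: dict[int, tuple[int, int]] = {}
        grp = imgs.groupby("patient_key").size()
        for pk, n in grp.items():
            d = lv.get(pk)
            if d is None:
                continue
            k = _window_index(d, cutoff_date)
            tot, lnk = counts.get(k, (0, 0))
            counts[k] = (tot + n, lnk + (n if pk in linked_pk else 0))
        for k in sorted(counts):
            tot, lnk = counts[k]
            rows.append({"stratum_label": _year_window_label(cutoff_date, k),
                         "total_count": tot, "linked_count": lnk,
                         "rate_pct": compute_rate(lnk, tot, 2)})
    elif by == "image_type":
        for itype, g in imgs.groupby("image_type"):
            pks = set(g["patient_key"])
            lnk = len(pks & linked_pk)
            rows.append({"stratum_label": itype, "total_count": len(pks),
                         "linked_count": lnk,
                         "rate_pct": compute_rate(lnk, len(pks), 2)})
        rows.sort(key=lambda r: r["stratum_label"])
    else:
        raise ValueError(f"unknown stratification: {by!r}")
    return pd.DataFrame(rows, columns=["stratum_label", "total_count",
                                       "linked_count", "rate_pct"])


def load_icd_map(path=None) -> dict[str, list[str]]:
    p = Path(path) if path else Path(__file__).parent / "data" / "icd_map.yaml"
    raw = yaml.safe_load(p.read_text())
    return {str(k): [str(c) for c in v or []] for k, v in raw.items()}


def diagnosis_cohorts(result: LinkResult, registry: pd.DataFrame,
                      images: pd.DataFrame,
                      icd_map: dict[str, list[str]]) -> pd.DataFrame:
    """Per-diagnosis cohort counts over linked patients.

    A linked patient belongs to a diagnosis cohort when any of their registry
    ICD codes starts with one of the cohort's code prefixes; all of the
    patient's imaging visits and images are then counted for that cohort, and
    a patient with several diagnoses is counted in every matching cohort.
    Follow-up is years between first and last imaging visit (mean, SD).
    """
    log = logging.getLogger(__name__)
    pk_by_rid = {rid: pk for pk, (rid, _) in result.links.items()}
    codes_by_rid = {rid: [c for c in str(v or "").split(";") if c]
                    for rid, v in zip(registry["registry_id"],
                                      registry["icd_codes"])}
    imgs = images[~images["is_measurement"]] if "is_measurement" in images \
        else images
    per_pk = {}
    for pk, g in imgs.groupby("patient_key"):
        ds = [d for d in (parse_dicom_date(x) for x in g["acquisition_date"])
              if d is not None]
        per_pk[pk] = {
            "n_images": len(g),
            "n_visits": len(set(ds)),
            "followup_years": ((max(ds) - min(ds)).days / 365.25) if ds else 0.0,
        }
    rows = []
    for label, prefixes in icd_map.items():
        if not prefixes:
            log.warning("empty ICD set for diagnosis %r", label)
            rows.append({"diagnosis_label": label, "unique_patients": 0,
                         "unique_visits": 0, "unique_images": 0,
                         "followup_years_mean": 0.0, "followup_years_sd": 0.0})
            continue
        member_pks = [pk_by_rid[rid] for rid, codes in codes_by_rid.items()
                      if rid in pk_by_rid
                      and any(c.startswith(p) for c in codes for p in prefixes)]
        stats = [per_pk.get(pk, {"n_images": 0, "n_visits": 0,
                                 "followup_years": 0.0}) for pk in member_pks]
        fu = np.array([s["followup_years"] for s in stats], dtype=float)
        rows.append({
            "diagnosis_label": label,
            "unique_patients": len(member_pks),
            "unique_visits": int(sum(s["n_visits"] for s in stats)),
            "unique_images": int(sum(s["n_images"] for s in stats)),
            "followup_years_mean": float(fu.mean()) if fu.size else 0.0,
            "followup_years_sd": float(fu.std(ddof=1)) if fu.size > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def report_markdown(rep: LinkageReport, year_strata: pd.DataFrame | None = None,
                    type_strata: pd.DataFrame | None = None) -> str:
    """Human-readable summary of a linkage run."""
    lines = [
        "# Linkage report", "",
        f"- patients: {rep.linked_patients} / {rep.total_patients} linked "
        f"({rep.initial_patient_rate_pct}%)",
        f"- images: {rep.linked_images} / {rep.total_images} linked "
        f"({rep.initial_image_rate_pct}%)",
        f"- cleaned patient rate: {rep.cleaned_patient_rate_pct}% "
        f"(denominator {rep.cleaned_patient_denominator})",
        f"- cleaned image rate: {rep.cleaned_image_rate_pct}% "
        f"(denominator {rep.cleaned_image_denominator})",
        "",
        "## Exclusions (mutually exclusive)",
    ]
    for flag, n in rep.excluded_patients_by_flag.items():
        lines.append(f"- {flag}: {n} patients, "
                     f"{rep.excluded_images_by_flag.get(flag, 0)} images")
    for title, df in (("Rate by last-visit window", year_strata),
                      ("Rate by image type", type_strata)):
        if df is not None and len(df):
            lines += ["", f"## {title}", "",
                      df.to_string(index=False)]
    return "\n".join(lines) + "\n"
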