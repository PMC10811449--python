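"""End-to-end orchestration: extract → harmonize → flag → link → de-identify → report.

One :func:`run_pipeline` call executes the stages in order (de-identification
strictly after linkage), writes all tables under the output directory, and
returns a manifest of input hashes, configuration, and stage counts. The
manifest contains no timestamps and no salt, so re-running the same inputs
and configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deidentify import load_policy, tokenize_tables
from .extraction import (consolidate_patients, extract_archive,
                         parse_dicom_date, read_metadata_table)
from .harmonize import apply_exclusions, normalize_patients, qc_report
from .linkage import (build_candidate_edges, link_images, link_measurements,
                      resolve_matching)
from .report import (cohort_diagram_from_tables, diagnosis_cohorts,
                     load_icd_map, report_markdown, stratify_report)

log = logging.getLogger(__name__)


class ConfigValidationError(ValueError):
    """Run configuration references missing inputs or is inconsistent."""


@dataclass
class RunConfig:
    registry_table: str | Path = ""
    metadata_table: str | Path | None = None
    dicom_dir: str | Path | None = None
    location_id: str = "LOC01"  # used only when reading a DICOM directory
    out_dir: str | Path = "oculink_run"
    cutoff_date: str | None = None  # default: archive max last-visit date
    matching_mode: str = "max_cardinality"
    include_flagged: bool = True
    test_word_boundary: bool = False
    phi_policy_path: str | Path | None = None
    icd_map_path: str | Path | None = None
    salt: str = ""  # never written to logs or outputs
    seed: int = 0
    log_level: str = "INFO"

    def validate(self):
        if not self.registry_table or not Path(self.registry_table).exists():
            raise ConfigValidationError(
                f"registry table not found: {self.registry_table!r}")
        if (self.metadata_table is None) == (self.dicom_dir is None):
            raise ConfigValidationError(
                "exactly one of metadata_table / dicom_dir is required")
        for p in (self.metadata_table, self.dicom_dir, self.phi_policy_path,
                  self.icd_map_path):
            if p is not None and not Path(p).exists():
                raise ConfigValidationError(f"input path not found: {p}")
        if self.matching_mode not in ("max_cardinality", "greedy",
                                      "strict_ambiguity_drop"):
            raise ConfigValidationError(
                f"unknown matching mode {self.matching_mode!r}")


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_registry(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".parquet", ".pq"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.fillna("")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"version": __version__, "stages": {},
                      "config": {k: str(v) for k, v in vars(config).items()
                                 if k != "salt"}}

    # --- extract & consolidate -------------------------------------------
    registry = _read_registry(config.registry_table)
    manifest["inputs"] = {"registry_table": _sha256(config.registry_table)}
    if config.metadata_table is not None:
        metadata = read_metadata_table(config.metadata_table)
        manifest["inputs"]["metadata_table"] = _sha256(config.metadata_table)
        patients, images = consolidate_patients(metadata)
    else:
        patients, images = extract_archive(config.dicom_dir, config.location_id)
    manifest["stages"]["extract"] = {
        "patients": len(patients),
        "images": int((~images["is_measurement"]).sum()),
        "measurements": int(images["is_measurement"].sum()),
        "visits": int(images.loc[~images["is_measurement"], "visit_key"]
                      .nunique()),
    }

    # --- harmonize & QC ---------------------------------------------------
    patients = normalize_patients(patients)
    registry_n = normalize_patients(registry)
    cutoff = parse_dicom_date(config.cutoff_date) if config.cutoff_date else None
    patients = apply_exclusions(patients, cutoff,
                                test_word_boundary=config.test_word_boundary)
    qc = qc_report(patients, images[~images["is_measurement"]])
    manifest["stages"]["qc"] = {
        row["flag"]: {"patients": int(row["n_patients"]),
                      "images": int(row["n_images"])}
        for row in qc.to_dict("records")}

    # --- link --------------------------------------------------------------
    edges = build_candidate_edges(patients, registry_n,
                                  include_flagged=config.include_flagged)
    result = resolve_matching(edges, mode=config.matching_mode,
                              all_patient_keys=patients["patient_key"],
                              all_registry_ids=registry_n["registry_id"])
    linked_images = link_images(result, images[~images["is_measurement"]])
    measurements = link_measurements(images[images["is_measurement"]],
                                     linked_images)
    manifest["stages"]["link"] = {
        "candidate_edges": len(edges),
        "linked_patients": len(result.links),
        "unlinked_patients": len(result.unlinked_patient_keys),
        "linked_images": int(linked_images["linked"].sum()),
        "linked_measurements": int(measurements["linked"].sum())
        if len(measurements) else 0,
        "dangling_measurements": int(measurements["dangling"].sum())
        if len(measurements) else 0,
    }

    # --- de-identify (strictly after linkage) ------------------------------
    if config.salt:
        patients_tok, images_tok, _ = tokenize_tables(
            patients, pd.concat([linked_images,
                                 measurements], ignore_index=True),
            config.salt)
        patients_tok.to_csv(out / "patients_deidentified.csv", index=False)
        images_tok.to_csv(out / "images_deidentified.csv", index=False)
        manifest["stages"]["deidentify"] = {
            "tokenized_patients": len(patients_tok)}
        load_policy(config.phi_policy_path)  # validate policy up front
    else:
        manifest["stages"]["deidentify"] = {"tokenized_patients": 0}

    # --- report -------------------------------------------------------------
    rep = cohort_diagram_from_tables(patients, linked_images, result)
    year_strata = stratify_report(patients, linked_images, result,
                                  by="last_visit_year", cutoff_date=cutoff)
    type_strata = stratify_report(patients, linked_images, result,
                                  by="image_type")
    icd_map = load_icd_map(config.icd_map_path)
    diag = diagnosis_cohorts(result, registry_n, linked_images, icd_map)
    manifest["stages"]["report"] = rep.to_dict()

    patients.to_csv(out / "patients.csv", index=False)
    linked_images.to_csv(out / "images_linked.csv", index=False)
    measurements.to_csv(out / "measurements_linked.csv", index=False)
    result.to_frame().to_csv(out / "links.csv", index=False)
    qc.to_csv(out / "qc_report.csv", index=False)
    year_strata.to_csv(out / "strata_last_visit_year.csv", index=False)
    type_strata.to_csv(out / "strata_image_type.csv", index=False)
    diag.to_csv(out / "diagnosis_cohorts.csv", index=False)
    (out / "report.md").write_text(
        report_markdown(rep, year_strata, type_strata))
    (out / "report.json").write_text(
        json.dumps(rep.to_dict(), indent=2, sort_keys=True) + "\n")

    blob = json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    manifest["manifest_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
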