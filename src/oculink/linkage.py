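"""Deterministic patient-level record linkage with graph-based resolution.

Imaging patients are linked to registry patients by four exact-agreement
identifier combinations, all anchored on practice location:

* R1 — location, name, birthdate, MRN
* R2 — location, name, birthdate, gender
* R3 — location, name, MRN
* R4 — location, birthdate, MRN

A candidate edge exists when at least one rule is satisfied; a field that is
missing on either side fails the rule (missing values never wildcard-match).
Candidate generation blocks on location plus one shared identifier key, which
is provably equivalent to all-pairs evaluation because every rule requires
location plus at least one of name/birthdate/MRN. The candidate graph is then
resolved to a one-to-one mapping by maximum-cardinality matching, breaking
ties by total rule weight and then lexicographically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

#: identifier fields per rule; location membership is required by all rules
RULES: dict[str, tuple[str, ...]] = {
    "R1": ("name", "birthdate", "mrn"),
    "R2": ("name", "birthdate", "gender"),
    "R3": ("name", "mrn"),
    "R4": ("birthdate", "mrn"),
}

_FIELD_COLS = {"name": "name_norm", "birthdate": "birthdate_norm",
               "gender": "gender_norm", "mrn": "mrn_norm"}

# components above this size skip the lexicographic refinement (result is
# still optimal and deterministic via canonical node ordering)
_LEX_REFINE_LIMIT = 200


@dataclass
class LinkResult:
    """One-to-one patient mapping with rule provenance."""

    links: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    unlinked_patient_keys: set[str] = field(default_factory=set)
    unlinked_registry_ids: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"patient_key": pk, "registry_id": rid,
                 "rules": ";".join(rules), "weight": len(rules)}
                for pk, (rid, rules) in sorted(self.links.items())]
        return pd.DataFrame(rows, columns=["patient_key", "registry_id",
                                           "rules", "weight"])


def rule_satisfied(img, reg, rule_id: str) -> bool:
    """Exact-agreement test for one rule on two normalized identities.

    ``img``/``reg`` expose name_norm, birthdate, gender, mrn_norm and
    location_id / location_ids. Every field named by the rule must be
    non-missing on both sides and equal; the imaging location must belong
    to the registry patient's location set.
    """
    reg_locs = getattr(reg, "location_ids", None)
    if reg_locs is None:
        reg_locs = {reg.location_id}
    if img.location_id not in reg_locs:
        return False
    for fld in RULES[rule_id]:
        a, b = getattr(img, _ident_attr(fld)), getattr(reg, _ident_attr(fld))
        if a in (None, "") or b in (None, "") or a != b:
            return False
    return True


def _ident_attr(fld: str) -> str:
    return {"name": "name_norm", "birthdate": "birthdate",
            "gender": "gender", "mrn": "mrn_norm"}[fld]


def explode_registry_locations(reg: pd.DataFrame) -> pd.DataFrame:
    """One row per (registry patient, practice location) affiliation."""
    out = reg.copy()
    out["location_id"] = [
        str(v).split(";") if not isinstance(v, (list, tuple, set)) else list(v)
        for v in out["location_ids"]]
    return out.explode("location_id").reset_index(drop=True)


def _evaluate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Evaluate all four rules on a merged (imaging, registry) pair frame."""
    if pairs.empty:
        return pd.DataFrame(columns=["patient_key", "registry_id", "rules",
                                     "weight"])
    ok = {}
    for fld, col in _FIELD_COLS.items():
        a, b = pairs[col + "_img"], pairs[col + "_reg"]
        ok[fld] = (a != "") & (b != "") & (a == b)
    sat = {rid: np.logical_and.reduce([ok[f].to_numpy() for f in flds])
           for rid, flds in RULES.items()}
    any_rule = np.logical_or.reduce(list(sat.values()))
    kept = pairs.loc[any_rule, ["patient_key", "registry_id"]].copy()
    rule_matrix = np.column_stack([sat[r][any_rule] for r in RULES])
    kept["rules"] = [";".join(r for r, hit in zip(RULES, row) if hit)
                     for row in rule_matrix]
    kept["weight"] = rule_matrix.sum(axis=1).astype(int)
    kept = kept.sort_values(["patient_key", "registry_id"]).reset_index(drop=True)
    return kept


def _prep_sides(img: pd.DataFrame, reg: pd.DataFrame):
    icols = ["patient_key", "location_id"] + list(_FIELD_COLS.values())
    left = img[icols].copy()
    reg_x = explode_registry_locations(reg)
    rcols = ["registry_id", "location_id"] + list(_FIELD_COLS.values())
    right = reg_x[rcols].copy()
    for df in (left, right):
        for col in _FIELD_COLS.values():
            df[col] = df[col].fillna("").astype(str)
    return left, right


def build_candidate_edges(img_patients: pd.DataFrame,
                          reg_patients: pd.DataFrame,
                          include_flagged: bool = True,
                          blocking: bool = True) -> pd.DataFrame:
    """Candidate edges (patient_key, registry_id, rules, weight).

    With ``blocking`` (default), pairs are generated only within a shared
    location block that also agrees on at least one of name/birthdate/MRN;
    this is equivalent to all-pairs evaluation (``blocking=False``) because
    every rule demands location plus one of those keys. Output ordering is
    canonical and independent of input row order.
    """
    if img_patients.empty or reg_patients.empty:
        return pd.DataFrame(columns=["patient_key", "registry_id", "rules",
                                     "weight"])
    img = img_patients
    if not include_flagged and "exclusion" in img.columns:
        img = img[img["exclusion"] == ""]
    left, right = _prep_sides(img, reg_patients)

    if blocking:
        pair_frames = []
        for key in ("name_norm", "birthdate_norm", "mrn_norm"):
            li = left[left[key] != ""]
            ri = right[right[key] != ""]
            merged = li.merge(ri, on=["location_id", key],
                              suffixes=("_img", "_reg"))
            pair_frames.append(merged[["patient_key", "registry_id"]])
        pairs = (pd.concat(pair_frames, ignore_index=True)
                 .drop_duplicates() if pair_frames else pd.DataFrame())
    else:
        pairs = (left.assign(_k=1)
                 .merge(right.assign(_k=1), on="_k", suffixes=("_img", "_reg")))
        pairs = pairs[pairs["location_id_img"] == pairs["location_id_reg"]]
        pairs = pairs[["patient_key", "registry_id"]].drop_duplicates()
    if pairs.empty:
        return pd.DataFrame(columns=["patient_key", "registry_id", "rules",
                                     "weight"])
    merged = (pairs.merge(left.drop(columns="location_id")
                          .drop_duplicates("patient_key"),
                          on="patient_key")
              .merge(right.drop(columns="location_id")
                     .drop_duplicates("registry_id"),
                     on="registry_id", suffixes=("_img", "_reg")))
    # location membership already holds for every generated pair; re-derive
    # it explicitly so rule provenance is auditable from identities alone
    return _evaluate_pairs(merged)


def _component_optimum(pnodes, rnodes, wdict, forced=()):
    """(cardinality, weight) of the best matching with ``forced`` pairs fixed."""
    used_p = {p for p, _ in forced}
    used_r = {r for _, r in forced}
    ps = [p for p in pnodes if p not in used_p]
    rs = [r for r in rnodes if r not in used_r]
    base_card = len(forced)
    base_w = sum(wdict[e] for e in forced)
    if not ps or not rs:
        return base_card, base_w
    big = sum(wdict.values()) + 1
    cost = np.zeros((len(ps), len(rs)))
    for i, p in enumerate(ps):
        for j, r in enumerate(rs):
            w = wdict.get((p, r))
            if w is not None:
                cost[i, j] = -(big + w)
    rows, cols = linear_sum_assignment(cost)
    card, wt = base_card, base_w
    for i, j in zip(rows, cols):
        w = wdict.get((ps[i], rs[j]))
        if w is not None:
            card += 1
            wt += w
    return card, wt


def _resolve_component(pnodes, rnodes, wdict, strict):
    """Resolve one connected component; returns (pairs, ambiguous)."""
    pnodes, rnodes = sorted(pnodes), sorted(rnodes)
    best = _component_optimum(pnodes, rnodes, wdict)
    if len(pnodes) + len(rnodes) > _LEX_REFINE_LIMIT:
        # large component: accept the assignment solution directly
        log.debug("component with %d nodes: skipping lexicographic refinement",
                  len(pnodes) + len(rnodes))
        big = sum(wdict.values()) + 1
        cost = np.zeros((len(pnodes), len(rnodes)))
        ridx = {r: j for j, r in enumerate(rnodes)}
        for (p, r), w in wdict.items():
            cost[pnodes.index(p), ridx[r]] = -(big + w)
        rows, cols = linear_sum_assignment(cost)
        pairs = [(pnodes[i], rnodes[j]) for i, j in zip(rows, cols)
                 if (pnodes[i], rnodes[j]) in wdict]
        return pairs, False

    forced = []
    ambiguous = False
    for p in pnodes:
        cands = sorted(r for (q, r) in wdict
                       if q == p and all(r != fr for _, fr in forced))
        hit = None
        n_opt = 0
        for r in cands:
            trial = forced + [(p, r)]
            if _component_optimum(pnodes, rnodes, wdict, trial) == best:
                n_opt += 1
                if hit is None:
                    hit = r
                if not strict:
                    break
        if hit is not None:
            if strict:
                # also optimal with p unmatched? then the component is ambiguous
                others = [q for q in pnodes
                          if q != p and all(q != fp for fp, _ in forced)]
                alt = _component_optimum(others, rnodes, wdict, forced)
                if n_opt > 1 or alt == best:
                    ambiguous = True
            forced.append((p, hit))
    return forced, ambiguous


def resolve_matching(edges: pd.DataFrame, mode: str = "max_cardinality",
                     all_patient_keys: Iterable[str] | None = None,
                     all_registry_ids: Iterable[str] | None = None
                     ) -> LinkResult:
    """Resolve candidate edges to a one-to-one patient mapping.

    ``mode``:

    * ``max_cardinality`` (default) — maximum-cardinality matching; among
      those, maximum total rule weight; deterministic lexicographic
      tie-break on (patient_key, registry_id).
    * ``greedy`` — scan edges by (weight desc, patient_key, registry_id)
      and keep any pair whose endpoints are both free.
    * ``strict_ambiguity_drop`` — as the default, but connected components
      admitting more than one optimal matching contribute no links.
    """
    if mode not in ("max_cardinality", "greedy", "strict_ambiguity_drop"):
        raise ValueError(f"unknown matching mode: {mode}")
    links: dict[str, tuple[str, tuple[str, ...]]] = {}
    rules_by_pair = {(e.patient_key, e.registry_id): tuple(e.rules.split(";"))
                     for e in edges.itertuples()}
    wdict_all = {(e.patient_key, e.registry_id): int(e.weight)
                 for e in edges.itertuples()}

    if mode == "greedy":
        order = sorted(wdict_all, key=lambda pr: (-wdict_all[pr], pr))
        used_p, used_r = set(), set()
        for p, r in order:
            if p not in used_p and r not in used_r:
                links[p] = (r, rules_by_pair[(p, r)])
                used_p.add(p)
                used_r.add(r)
    else:
        strict = mode == "strict_ambiguity_drop"
        g = nx.Graph()
        for p, r in wdict_all:
            g.add_edge(("P", p), ("R", r))
        for comp in nx.connected_components(g):
            ps = sorted(n for s, n in comp if s == "P")
            rs = sorted(n for s, n in comp if s == "R")
            wdict = {(p, r): w for (p, r), w in wdict_all.items()
                     if p in set(ps) and r in set(rs)}
            pairs, ambiguous = _resolve_component(ps, rs, wdict, strict)
            if strict and ambiguous:
                log.info("dropping ambiguous component with %d+%d nodes",
                         len(ps), len(rs))
                continue
            for p, r in pairs:
                links[p] = (r, rules_by_pair[(p, r)])

    matched_r = {rid for rid, _ in links.values()}
    pk_all = set(all_patient_keys) if all_patient_keys is not None else \
        {p for p, _ in wdict_all}
    rid_all = set(all_registry_ids) if all_registry_ids is not None else \
        {r for _, r in wdict_all}
    return LinkResult(
        links=links,
        unlinked_patient_keys=pk_all - set(links),
        unlinked_registry_ids=rid_all - matched_r,
    )


def link_images(result: LinkResult, images: pd.DataFrame) -> pd.DataFrame:
    """Propagate patient-level links to every image of each linked patient."""
    out = images.copy()
    known = set(result.links) | result.unlinked_patient_keys
    if known:
        unknown = ~out["patient_key"].isin(known)
        if unknown.any():
            log.warning("excluding %d images with unknown patient keys",
                        int(unknown.sum()))
            out = out[~unknown]
    out["linked"] = out["patient_key"].isin(result.links)
    rid_map = {pk: rid for pk, (rid, _) in result.links.items()}
    out["registry_id"] = out["patient_key"].map(rid_map).fillna("")
    return out.reset_index(drop=True)


def link_measurements(measurements: pd.DataFrame,
                      linked_images: pd.DataFrame) -> pd.DataFrame:
    """Link key-measurement documents to linked OCT scans by referenced UID.

    A measurement is linked iff its referenced SOP instance UID identifies a
    linked OCT image; it then inherits that image's registry id. References
    to unknown UIDs are reported as dangling.
    """
    imgs = linked_images[~linked_images["is_measurement"]]
    oct_linked = imgs[(imgs["image_type"] == "OCT") & imgs["linked"]]
    rid_by_uid = dict(zip(oct_linked["sop_instance_uid"],
                          oct_linked["registry_id"]))
    all_uids = set(imgs["sop_instance_uid"])
    out = measurements.copy()
    refs = out["referenced_sop_uid"].fillna("")
    out["linked"] = [r in rid_by_uid for r in refs]
    out["registry_id"] = [rid_by_uid.get(r, "") for r in refs]
    out["dangling"] = [r not in all_uids for r in refs]
    return out.reset_index(drop=True)
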