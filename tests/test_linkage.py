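"""Linkage rules, blocking soundness, and matching optimality."""

import itertools
from datetime import date

import numpy as np
import pandas as pd
import pytest

import oculink as ol
from oculink.linkage import RULES, resolve_matching

from conftest import identity_from_row


def _identity(name="DOE JOHN", bd=date(1950, 1, 1), gender="M", mrn="123",
              loc="L1", locs=None):
    ident = ol.NormalizedIdentity(name, bd, gender, mrn, loc)
    if locs is not None:
        return _RegIdent(ident, locs)
    return ident


class _RegIdent:
    """Registry-side identity with a location set."""

    def __init__(self, base, locs):
        self.name_norm = base.name_norm
        self.birthdate = base.birthdate
        self.gender = base.gender
        self.mrn_norm = base.mrn_norm
        self.location_ids = set(locs)


def test_rule_satisfied_full_agreement():
    a, b = _identity(), _identity(locs={"L1", "L2"})
    for rule in RULES:
        assert ol.rule_satisfied(a, b, rule)


def test_rule_fails_on_missing_field():
    """A missing field never wildcard-matches."""
    a = _identity(mrn="")
    b = _identity(mrn="", locs={"L1"})
    assert not ol.rule_satisfied(a, b, "R3")
    assert not ol.rule_satisfied(a, b, "R1")
    assert ol.rule_satisfied(a, b, "R2")  # name+dob+gender intact


def test_rule_fails_on_gender_mismatch():
    a = _identity(gender="M")
    b = _identity(gender="F", locs={"L1"})
    assert not ol.rule_satisfied(a, b, "R2")
    assert ol.rule_satisfied(a, b, "R1")


def test_location_required_by_every_rule():
    a = _identity(loc="L9")
    b = _identity(locs={"L1"})
    assert not any(ol.rule_satisfied(a, b, r) for r in RULES)


def _brute_force_edges(patients, registry):
    """Independent all-pairs oracle built on rule_satisfied scalars."""
    rows = []
    reg_idents = []
    for _, r in registry.iterrows():
        base = identity_from_row(r)
        reg_idents.append((r["registry_id"],
                           _RegIdent(base, str(r["location_ids"]).split(";"))))
    for _, p in patients.iterrows():
        pi = identity_from_row(p)
        for rid, ri in reg_idents:
            rules = [rule for rule in RULES if ol.rule_satisfied(pi, ri, rule)]
            if rules:
                rows.append({"patient_key": p["patient_key"],
                             "registry_id": rid,
                             "rules": ";".join(rules), "weight": len(rules)})
    return (pd.DataFrame(rows, columns=["patient_key", "registry_id",
                                        "rules", "weight"])
            .sort_values(["patient_key", "registry_id"])
            .reset_index(drop=True))


def test_blocking_equals_all_pairs_oracle(messy_run):
    """Blocked candidate generation = brute-force all-pairs evaluation."""
    patients = messy_run["patients"].head(200)
    registry = messy_run["registry"]
    blocked = ol.build_candidate_edges(patients, registry, blocking=True)
    unblocked = ol.build_candidate_edges(patients, registry, blocking=False)
    oracle = _brute_force_edges(patients, registry)
    pd.testing.assert_frame_equal(blocked, unblocked)
    pd.testing.assert_frame_equal(blocked, oracle)


def test_edges_independent_of_input_order(messy_run):
    patients, registry = messy_run["patients"], messy_run["registry"]
    e1 = ol.build_candidate_edges(patients, registry)
    e2 = ol.build_candidate_edges(patients.sample(frac=1, random_state=3),
                                  registry.sample(frac=1, random_state=4))
    pd.testing.assert_frame_equal(e1, e2)


def test_edge_provenance_recomputable(messy_run):
    """satisfied_rules on every edge re-derives from the two identities."""
    edges = messy_run["edges"]
    patients = messy_run["patients"].set_index("patient_key")
    registry = messy_run["registry"].set_index("registry_id")
    for e in edges.head(300).itertuples():
        p = patients.loc[e.patient_key]
        r = registry.loc[e.registry_id]
        pi = identity_from_row(p)
        ri = _RegIdent(identity_from_row(r),
                       str(r["location_ids"]).split(";"))
        expect = [rule for rule in RULES if ol.rule_satisfied(pi, ri, rule)]
        assert ";".join(expect) == e.rules


def _edges_frame(pairs):
    return pd.DataFrame(
        [{"patient_key": p, "registry_id": r,
          "rules": ";".join(f"R{i+1}" for i in range(w)), "weight": w}
         for (p, r), w in pairs.items()])


def _exhaustive_best(pairs):
    """Enumerate all matchings; return max (cardinality, total weight)."""
    ps = sorted({p for p, _ in pairs})

    def rec(i, used):
        if i == len(ps):
            return (0, 0)
        best = rec(i + 1, used)
        p = ps[i]
        for (q, r), w in pairs.items():
            if q == p and r not in used:
                c, wt = rec(i + 1, used | {r})
                best = max(best, (c + 1, wt + w))
        return best

    return rec(0, frozenset())


def test_weight_two_edge_preferred():
    """Of two imaging patients contesting one registry patient, the pair
    satisfying more rules wins; matching stays maximum-cardinality."""
    pairs = {("p1", "r1"): 2, ("p2", "r1"): 1}
    res = resolve_matching(_edges_frame(pairs))
    assert res.links["p1"][0] == "r1"
    assert "p2" in res.unlinked_patient_keys
    # with a second registry patient available, both get matched
    pairs[("p2", "r2")] = 1
    res = resolve_matching(_edges_frame(pairs))
    assert len(res.links) == 2


def test_disjoint_perfect_pairs_identity():
    pairs = {(f"p{i}", f"r{i}"): 1 for i in range(6)}
    res = resolve_matching(_edges_frame(pairs))
    assert res.links == {f"p{i}": (f"r{i}", ("R1",)) for i in range(6)}
    assert not res.unlinked_patient_keys


def test_matching_equals_exhaustive_oracle():
    """On random small bipartite graphs the matcher attains the enumerated
    optimum in cardinality and, among those, total weight."""
    rng = np.random.default_rng(42)
    for trial in range(200):
        n_p, n_r = rng.integers(1, 7, size=2)
        pairs = {}
        for i in range(n_p):
            for j in range(n_r):
                if rng.random() < 0.35:
                    pairs[(f"p{i}", f"r{j}")] = int(rng.integers(1, 5))
        if not pairs:
            continue
        res = resolve_matching(_edges_frame(pairs))
        card = len(res.links)
        weight = sum(pairs[(p, rid)] for p, (rid, _) in res.links.items())
        assert (card, weight) == _exhaustive_best(pairs), pairs


def test_matching_one_to_one(messy_run):
    res = messy_run["result"]
    rids = [rid for rid, _ in res.links.values()]
    assert len(rids) == len(set(rids))


def test_matching_deterministic_under_permutation(messy_run):
    edges = messy_run["edges"]
    shuffled = edges.sample(frac=1, random_state=99)
    r1 = resolve_matching(edges)
    r2 = resolve_matching(shuffled)
    assert r1.links == r2.links


def test_monotone_in_registry_growth():
    """Adding a registry patient never decreases matched cardinality."""
    rng = np.random.default_rng(5)
    pairs = {(f"p{i}", f"r{j}"): 1
             for i in range(5) for j in range(5) if rng.random() < 0.4}
    pairs[("p0", "r0")] = 1
    base = resolve_matching(_edges_frame(pairs))
    grown = dict(pairs)
    grown[("p4", "r9")] = 1  # brand-new registry node
    res = resolve_matching(_edges_frame(grown))
    assert len(res.links) >= len(base.links)


def test_greedy_and_strict_modes():
    pairs = {("p1", "r1"): 1, ("p2", "r1"): 1}  # symmetric ambiguity
    strict = resolve_matching(_edges_frame(pairs), mode="strict_ambiguity_drop")
    assert not strict.links  # ambiguous component dropped entirely
    greedy = resolve_matching(_edges_frame(pairs), mode="greedy")
    assert greedy.links == {"p1": ("r1", ("R1",))}
    unambig = {("p1", "r1"): 2, ("p2", "r1"): 1, ("p2", "r2"): 1}
    strict2 = resolve_matching(_edges_frame(unambig), mode="strict_ambiguity_drop")
    assert len(strict2.links) == 2


def test_link_images_propagation(messy_run):
    images = messy_run["images"]
    res = messy_run["result"]
    imgs = images[~images["is_measurement"]]
    linked = ol.link_images(res, imgs)
    per_patient = imgs.groupby("patient_key").size()
    expect = sum(n for pk, n in per_patient.items() if pk in res.links)
    assert linked["linked"].sum() == expect
    # unlinked patients contribute zero linked images
    assert not linked.loc[~linked["patient_key"].isin(res.links), "linked"].any()


def test_link_measurements_by_referenced_uid(messy_run):
    images, res = messy_run["images"], messy_run["result"]
    imgs = images[~images["is_measurement"]]
    linked = ol.link_images(res, imgs)
    meas = images[images["is_measurement"]].copy()
    out = ol.link_measurements(meas, linked)
    oct_linked = set(linked.loc[(linked["image_type"] == "OCT")
                                & linked["linked"], "sop_instance_uid"])
    assert (out["linked"] == out["referenced_sop_uid"].isin(oct_linked)).all()
    assert not out["dangling"].any()
    # dangling reference is counted, not linked
    meas2 = meas.head(1).copy()
    meas2["referenced_sop_uid"] = "9.9.9.9.9"
    out2 = ol.link_measurements(meas2, linked)
    assert bool(out2["dangling"].iloc[0]) and not bool(out2["linked"].iloc[0])
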