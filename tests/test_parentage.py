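"""Sibship clustering, the R1-R5 parent rules, minimality and recovery."""

from __future__ import annotations

import itertools
from datetime import date

import numpy as np
import pytest

from nestkin.breeding_habits import NestRecord, nest_records_from_frame
from nestkin.kinship_ibs import compute_normalized_ibs
from nestkin.parentage import (
    HalfSibLink,
    IntegrityError,
    SibPartition,
    assign_parents,
    census_summary,
    cluster_full_sibs,
    multiple_paternity_report,
    reconstruct,
)

# ------------------------------------------------------------- clustering


def test_cluster_recovers_two_paternal_groups_in_one_nest(two_family_dataset):
    ds = two_family_dataset
    fam = {s: ds.truth.hatchlings[s][0] for s in ds.genotypes.samples}
    res = compute_normalized_ibs(ds.genotypes, groups=fam)
    part = cluster_full_sibs(res)
    sizes = sorted(len(g) for g in part.groups)
    assert sizes == [5, 5, 11]
    # exactly one half-sib link: between the two paternal groups of family 2
    assert len(part.links) == 1
    link = part.links[0]
    fathers = {
        frozenset(ds.truth.hatchlings[s][1] for s in part.groups[g])
        for g in (link.group_a, link.group_b)
    }
    assert all(len(f) == 1 for f in fathers) and len(fathers) == 2
    assert not part.unresolved


def test_cluster_partition_matches_truth_pairwise(default_dataset, default_nests):
    ds = default_dataset
    res = compute_normalized_ibs(
        ds.genotypes,
        groups={s: v[2] for s, v in ds.truth.hatchlings.items()},
        baseline_min_group_size=5,
    )
    part = cluster_full_sibs(res)
    group_of = part.group_of()
    agree = total = 0
    samples = res.samples
    for a, b in itertools.combinations(samples, 2):
        same_truth = (
            ds.truth.hatchlings[a][0] == ds.truth.hatchlings[b][0]
            and ds.truth.hatchlings[a][1] == ds.truth.hatchlings[b][1]
        )
        total += 1
        agree += (group_of[a] == group_of[b]) == same_truth
    assert agree / total >= 0.99


def test_singleton_hatchling_forms_singleton_group():
    rng = np.random.default_rng(0)
    genos = rng.integers(0, 3, size=(5, 500)).astype(np.int8)
    res = compute_normalized_ibs(genos, av_min=0.7, min_overlap=10)
    part = cluster_full_sibs(res)
    assert all(len(g) == 1 for g in part.groups)  # mutually unrelated draws


# ------------------------------------------------- rule-by-rule assignment


def _nest(nid, d, samples, lat=32.0, lon=34.9):
    return NestRecord(nest_id=nid, date=d, lat=lat, lon=lon, samples=samples)


def _partition(groups, links):
    samples = [s for g in groups for s in g]
    return SibPartition(samples=samples, groups=[list(g) for g in groups],
                        links=links, group_mean_ibs=[0.45] * len(groups))


def test_within_nest_half_sibs_mean_multiple_paternity():
    # R3: one nest, two paternal groups -> 1 mother, 2 fathers, 2 events
    groups = [["a1", "a2"], ["b1", "b2"]]
    nests = [_nest("N1", date(2020, 6, 1), ["a1", "a2", "b1", "b2"])]
    haps = {s: "6-8-8-4" for s in "a1 a2 b1 b2".split()}
    part = _partition(groups, [HalfSibLink(0, 1, 0.25)])
    res = assign_parents(part, nests, haps)
    assert res.n_mothers == 1 and res.n_fathers == 2 and res.n_mating_events == 2
    assert res.nests_with_multiple_paternity == ["N1"]
    assert res.links[0].label == "maternal"


def test_full_sib_group_spanning_nests_merges_mother_and_father():
    # R2: recurrence with sperm storage -> one mother, one father, one event
    groups = [["a1", "a2", "b1"]]
    nests = [
        _nest("N1", date(2020, 6, 1), ["a1", "a2"]),
        _nest("N2", date(2020, 6, 15), ["b1"]),
    ]
    haps = {s: "6-8-8-4" for s in ("a1", "a2", "b1")}
    res = assign_parents(_partition(groups, []), nests, haps)
    assert res.counts() == {"n_mothers": 1, "n_fathers": 1, "n_mating_events": 1}


def test_cross_nest_same_barcode_compatible_dates_is_maternal():
    # R4: same matriline, different seasons -> one female remating (flagged)
    groups = [["a1", "a2"], ["b1", "b2"]]
    nests = [
        _nest("N1", date(2017, 6, 1), ["a1", "a2"]),
        _nest("N2", date(2020, 6, 10), ["b1", "b2"]),
    ]
    haps = {s: "6-9-6-4" for s in "a1 a2 b1 b2".split()}
    part = _partition(groups, [HalfSibLink(0, 1, 0.22)])
    res = assign_parents(part, nests, haps)
    assert res.counts() == {"n_mothers": 1, "n_fathers": 2, "n_mating_events": 2}
    assert res.links[0].label == "maternal" and res.links[0].ambiguous


def test_cross_nest_same_barcode_incompatible_dates_is_paternal():
    # same season, 60 days apart: one female cannot have laid both
    groups = [["a1", "a2"], ["b1", "b2"]]
    nests = [
        _nest("N1", date(2020, 5, 1), ["a1", "a2"]),
        _nest("N2", date(2020, 6, 30), ["b1", "b2"]),
    ]
    haps = {s: "6-9-6-4" for s in "a1 a2 b1 b2".split()}
    part = _partition(groups, [HalfSibLink(0, 1, 0.22)])
    res = assign_parents(part, nests, haps)
    assert res.counts() == {"n_mothers": 2, "n_fathers": 1, "n_mating_events": 2}
    assert res.links[0].label == "paternal"


def test_cross_nest_different_barcodes_shared_father():
    # R5: half-siblings across matrilines -> 2 mothers, 1 father, 2 events
    groups = [["a1", "a2", "a3"], ["b1", "b2", "b3"]]
    nests = [
        _nest("N1", date(2018, 6, 1), ["a1", "a2", "a3"]),
        _nest("N2", date(2021, 6, 10), ["b1", "b2", "b3"]),
    ]
    haps = {"a1": "6-8-8-4", "a2": "6-8-8-4", "a3": "6-8-8-4",
            "b1": "6-9-6-4", "b2": "6-9-6-4", "b3": "6-9-6-4"}
    part = _partition(groups, [HalfSibLink(0, 1, 0.24)])
    res = assign_parents(part, nests, haps)
    assert res.counts() == {"n_mothers": 2, "n_fathers": 1, "n_mating_events": 2}
    assert res.links[0].label == "paternal"


def test_missing_date_flags_instead_of_merging():
    groups = [["a1", "a2"], ["b1", "b2"]]
    nests = [
        _nest("N1", None, ["a1", "a2"]),
        _nest("N2", date(2020, 6, 10), ["b1", "b2"]),
    ]
    haps = {s: "6-9-6-4" for s in "a1 a2 b1 b2".split()}
    part = _partition(groups, [HalfSibLink(0, 1, 0.22)])
    res = assign_parents(part, nests, haps)
    assert res.n_mothers == 2 and res.n_fathers == 2
    assert res.links[0].label == "unresolved"


def test_weak_link_not_acted_on():
    # large SE (few markers): the merge is flagged, not applied
    groups = [["a1", "a2"], ["b1", "b2"]]
    nests = [
        _nest("N1", date(2017, 6, 1), ["a1", "a2"]),
        _nest("N2", date(2020, 6, 10), ["b1", "b2"]),
    ]
    haps = {s: "6-9-6-4" for s in "a1 a2 b1 b2".split()}
    part = _partition(groups, [HalfSibLink(0, 1, 0.22, se=0.1)])
    res = assign_parents(part, nests, haps)
    assert res.n_mothers == 2
    assert res.links[0].label == "unresolved"


def test_full_sib_group_across_matrilines_is_a_contradiction():
    groups = [["a1", "b1"]]
    nests = [
        _nest("N1", date(2020, 6, 1), ["a1"]),
        _nest("N2", date(2020, 6, 15), ["b1"]),
    ]
    haps = {"a1": "6-8-8-4", "b1": "6-9-6-4"}
    with pytest.raises(IntegrityError, match="matriline"):
        assign_parents(_partition(groups, []), nests, haps)


# ------------------------------------------------------------ minimality


def _set_partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def test_parent_counts_are_minimal_by_brute_force():
    """No assignment with fewer mothers/fathers satisfies the rule evidence."""
    groups = [["a1", "a2"], ["b1"], ["c1", "c2"], ["d1", "d2"]]
    nest_of_group = [["N1", "N2"], ["N1"], ["N3"], ["N4"]]
    nests = [
        _nest("N1", date(2013, 6, 1), ["a1", "b1"]),
        _nest("N2", date(2013, 6, 15), ["a2"]),
        _nest("N3", date(2016, 6, 10), ["c1", "c2"]),
        _nest("N4", date(2013, 7, 1), ["d1", "d2"]),
    ]
    code = {"N1": "6-8-8-4", "N2": "6-8-8-4", "N3": "6-9-6-4", "N4": "6-9-6-4"}
    haps = {}
    for g, ns in zip(groups, nest_of_group):
        for s in g:
            haps[s] = code[ns[0]]
    haps["a2"] = code["N2"]
    links = [
        HalfSibLink(0, 1, 0.25),  # within N1: multiple paternity
        HalfSibLink(1, 2, 0.22),  # across matrilines: shared father
        HalfSibLink(2, 3, 0.23),  # same matriline, different seasons
    ]
    res = assign_parents(_partition(groups, links), nests, haps)
    assert res.counts() == {"n_mothers": 2, "n_fathers": 3, "n_mating_events": 4}

    # brute force over all mother (nest) and father (group) partitions
    nest_ids = [n.nest_id for n in nests]
    linked = {frozenset((l.group_a, l.group_b)) for l in links}
    group_codes = [haps[g[0]] for g in groups]

    def valid(mpart, fpart):
        mclass = {n: i for i, cls in enumerate(mpart) for n in cls}
        fclass = {g: i for i, cls in enumerate(fpart) for g in cls}
        for cls in mpart:  # matriline coherence
            if len({code[n] for n in cls}) > 1:
                return False
        for gi, ns in enumerate(nest_of_group):  # R2: groups span one mother
            if len({mclass[n] for n in ns}) > 1:
                return False
        for gi, gj in itertools.combinations(range(len(groups)), 2):
            same_m = mclass[nest_of_group[gi][0]] == mclass[nest_of_group[gj][0]]
            same_f = fclass[gi] == fclass[gj]
            if same_m and same_f:
                return False  # distinct groups cannot share both parents
            if frozenset((gi, gj)) in linked:
                if not (same_m or same_f):
                    return False  # a half-sib link needs one shared parent
            elif not (set(nest_of_group[gi]) & set(nest_of_group[gj])):
                if same_m or same_f:
                    return False  # unlinked groups share no parent
        return True

    best_m = best_f = 10**9
    for mpart in _set_partitions(nest_ids):
        for fpart in _set_partitions(range(len(groups))):
            if valid(mpart, fpart):
                best_m = min(best_m, len(mpart))
                best_f = min(best_f, len(fpart))
    assert res.n_mothers == best_m
    assert res.n_fathers == best_f


# -------------------------------------------------------------- recovery


def test_exact_recovery_on_default_scenario(default_dataset, default_nests):
    ds = default_dataset
    recon, res, part = reconstruct(ds.genotypes, default_nests, ds.haplotypes)
    assert recon.counts() == {
        "n_mothers": ds.truth.n_mothers,
        "n_fathers": ds.truth.n_fathers,
        "n_mating_events": ds.truth.n_mating_events,
    }
    assert recon.nests_with_multiple_paternity == ds.truth.multiple_paternity_nests


def test_multiple_paternity_report_matches_truth(default_dataset, default_nests):
    ds = default_dataset
    recon, _, _ = reconstruct(ds.genotypes, default_nests, ds.haplotypes)
    table, summary = multiple_paternity_report(recon, default_nests, min_hatchlings=5)
    truth_mp = set(ds.truth.multiple_paternity_nests)
    assert set(table[table["multiple_paternity"]]["nest_id"]) == truth_mp
    assert summary["n_eligible_nests"] == 18
    assert summary["n_multiple_paternity_eligible"] == 6
    assert summary["fraction_multiple_paternity_eligible"] == pytest.approx(1 / 3)


def test_multiple_paternity_report_empty_when_threshold_exceeds_all(
    default_dataset, default_nests
):
    ds = default_dataset
    recon, _, _ = reconstruct(ds.genotypes, default_nests, ds.haplotypes)
    _, summary = multiple_paternity_report(recon, default_nests, min_hatchlings=100)
    assert summary["n_eligible_nests"] == 0


def test_no_wrong_merging_with_sparse_markers():
    """At 200 SNPs the method over-flags but never merges wrong parents."""
    from nestkin.synthetic_data import SimulationConfig, simulate_dataset

    ds = simulate_dataset(SimulationConfig(n_snps=200, seed=1))
    nests = nest_records_from_frame(ds.nests_frame())
    recon, _, _ = reconstruct(ds.genotypes, nests, ds.haplotypes)
    samples = list(recon.sample_parents)
    for a, b in itertools.combinations(samples, 2):
        ra, rb = recon.sample_parents[a], recon.sample_parents[b]
        ta = ds.truth.hatchlings[a]
        tb = ds.truth.hatchlings[b]
        if ra[0] == rb[0]:
            assert ta[0] == tb[0], f"wrong mother merge: {a} {b}"
        if ra[1] == rb[1]:
            assert ta[1] == tb[1], f"wrong father merge: {a} {b}"


# ---------------------------------------------------------------- census


def test_census_summary_arithmetic():
    s = census_summary(35, 59, extra_haplotype_count=16)
    assert s.minimum_females == 51
    assert s.ratio == "1:1.68"  # 59/35 = 1.6857..., truncated not rounded
    assert census_summary(35, 59).minimum_females == 35
    assert census_summary(10, 17).ratio == "1:1.70"
    with pytest.raises(ZeroDivisionError):
        census_summary(0, 5)
    with pytest.raises(ValueError):
        census_summary(5, 5, extra_haplotype_count=-1)
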