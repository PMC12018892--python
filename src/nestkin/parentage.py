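"""Hatchling-only reconstruction of mothers, fathers and mating events.

Neither parent is sampled: everything is inferred from (i) normalized-IBS
kinship bands between hatchlings, (ii) nest membership and dates, and
(iii) matrilineal mtSTR barcodes.  Full-sib groups are found as connected
components of the full-sib graph; half-sib links between groups are then
interpreted with a fixed rule order:

R1  all hatchlings in one nest share the mother (one female per nest);
R2  a full-sib group spanning nests implies the same mother and father for
    those nests (the female nested again);
R3  a half-sib link within a nest implies one mother, two fathers
    (multiple paternity);
R4  a half-sib link across nests with identical barcodes and compatible
    dates is read as the same mother remating (flagged ambiguous: a shared
    father would also explain it);
R5  a half-sib link across nests with different barcodes can only be
    paternal: a shared father across matrilines.

Mothers and fathers are enumerated minimally consistent with R1-R5; fathers
are synthetic labels (M01, ...) since males are never observed directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from itertools import combinations
from math import floor
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .breeding_habits import NestRecord
from .kinship_ibs import KinshipBands, NormalizedIbsResult, compute_normalized_ibs

logger = logging.getLogger(__name__)

__all__ = [
    "IntegrityError",
    "HalfSibLink",
    "SibPartition",
    "ReconstructionResult",
    "cluster_full_sibs",
    "assign_parents",
    "reconstruct",
    "multiple_paternity_report",
    "census_summary",
]


class IntegrityError(RuntimeError):
    """Observed kinship contradicts nest/matriline metadata."""


@dataclass
class HalfSibLink:
    """A cross-group mean normalized IBS falling in the half-sib band."""

    group_a: int
    group_b: int
    mean_ibs: float
    se: float = 0.0  # conservative standard error of mean_ibs
    label: str = "unassigned"  # maternal | paternal | unassigned | unresolved
    ambiguous: bool = False
    note: str = ""


@dataclass
class SibPartition:
    """Partition of hatchlings into full-sib groups plus half-sib links."""

    samples: list[str]
    groups: list[list[str]]
    links: list[HalfSibLink]
    unresolved: list[int] = field(default_factory=list)
    group_mean_ibs: list[float] = field(default_factory=list)

    def group_of(self) -> dict[str, int]:
        return {s: gi for gi, g in enumerate(self.groups) for s in g}


def _split_component(
    sub: np.ndarray, members: list[int], fs_floor: float
) -> list[list[int]]:
    """Recursively split an inconsistent component by average linkage.

    A component is consistent when every within-pair value is at least
    ``fs_floor`` (the full-sib threshold minus the ambiguity margin, so one
    borderline pair does not shatter an otherwise solid clique).
    """
    block = sub[np.ix_(members, members)]
    off = block[~np.eye(len(members), dtype=bool)]
    if len(members) <= 2 or off.size == 0 or off.min() >= fs_floor:
        return [members]
    d = 1.0 - block
    np.fill_diagonal(d, 0.0)
    labels = fcluster(average(squareform(d, checks=False)), 2, criterion="maxclust")
    parts = [
        [m for m, lab in zip(members, labels) if lab == k]
        for k in np.unique(labels)
    ]
    if len(parts) == 1:  # linkage refused to split; fall back to singletons
        return [[m] for m in members]
    out: list[list[int]] = []
    for part in parts:
        out.extend(_split_component(sub, part, fs_floor))
    return out


def cluster_full_sibs(
    result: NormalizedIbsResult,
    bands: KinshipBands | None = None,
    evidence_z: float = 4.0,
) -> SibPartition:
    """Full-sib groups from the normalized-IBS matrix.

    Pairs at or above the full-sib threshold are edges; connected components
    are candidate groups.  Components containing a pair clearly below the
    threshold are split by average linkage until consistent; if the split
    halves still look like full siblings across the cut (cross mean at or
    above the threshold) the groups are flagged unresolved rather than
    silently assigned.  Half-sib links join groups whose cross-group mean
    falls in the half-sib band.

    Evidence scaling: a pair value is only trusted as a full-sib edge when it
    also exceeds the half-sib threshold by ``evidence_z`` standard errors,
    where the SE is bounded from the pair's marker overlap (per-site score
    variance <= 0.25 rescaled by the normalization).  With thousands of SNPs
    the bound is far below the band gap and the thresholds are unchanged; on
    marker-poor data it makes sparse evidence degrade into flags rather than
    false merges.  Each half-sib link carries the analogous SE so parent
    assignment can apply the same rule before merging across nests.
    """
    bands = bands or KinshipBands()
    norm = result.normalized
    n = len(result.samples)
    scale = 1.0 - result.av_min
    with np.errstate(divide="ignore"):
        pair_se = np.sqrt(0.25 / np.maximum(result.n_overlap, 1)) / scale
    adj = (np.nan_to_num(norm, nan=-np.inf) >= bands.full_sib_min) & (
        np.nan_to_num(norm, nan=-np.inf) - evidence_z * pair_se >= bands.half_sib_min
    )
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj)
    fs_floor = bands.full_sib_min - bands.ambiguity_margin

    groups_idx: list[list[int]] = []
    unresolved: list[int] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        parts = _split_component(norm, members, fs_floor)
        if len(parts) > 1:
            # audit: did we cut through something that still looks full-sib?
            base = len(groups_idx)
            for (ia, a), (ib, b) in combinations(enumerate(parts), 2):
                cross = float(np.nanmean(norm[np.ix_(a, b)]))
                if cross >= bands.full_sib_min:
                    unresolved.extend((base + ia, base + ib))
                    logger.warning(
                        "inconsistent full-sib component split but halves still "
                        "cross-match at %.3f; flagged unresolved", cross,
                    )
        groups_idx.extend(parts)
    order = sorted(range(len(groups_idx)), key=lambda i: groups_idx[i][0])
    remap = {old: new for new, old in enumerate(order)}
    groups_idx = [groups_idx[i] for i in order]
    unresolved = sorted({remap[u] for u in unresolved})

    links: list[HalfSibLink] = []
    for (ia, a), (ib, b) in combinations(enumerate(groups_idx), 2):
        cross = float(np.nanmean(norm[np.ix_(a, b)]))
        if bands.half_sib_min <= cross < bands.full_sib_min:
            # correlated pairs: SE shrinks with the smaller group, not n_pairs
            typical = float(np.median(pair_se[np.ix_(a, b)]))
            se = typical / np.sqrt(min(len(a), len(b)))
            links.append(HalfSibLink(group_a=ia, group_b=ib, mean_ibs=cross,
                                     se=se, ambiguous=bands.is_ambiguous(cross)))
    means = []
    for members in groups_idx:
        if len(members) > 1:
            block = norm[np.ix_(members, members)]
            means.append(float((block.sum() - np.trace(block)) /
                               (len(members) * (len(members) - 1))))
        else:
            means.append(float("nan"))
    return SibPartition(
        samples=list(result.samples),
        groups=[[result.samples[i] for i in g_] for g_ in groups_idx],
        links=links,
        unresolved=unresolved,
        group_mean_ibs=means,
    )


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label wins
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo

    def classes(self) -> dict:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return {k: sorted(v) for k, v in out.items()}


@dataclass
class ReconstructionResult:
    """Inferred mothers, fathers, mating events and per-nest paternity."""

    mothers: dict[str, dict]  # label -> {barcode, nests, groups}
    fathers: dict[str, list[int]]  # label -> group indices
    mating_events: list[tuple[str, str]]
    nests_with_multiple_paternity: list[str]
    sample_parents: dict[str, tuple[str, str]]
    links: list[HalfSibLink]
    partition: SibPartition | None = None

    @property
    def n_mothers(self) -> int:
        return len(self.mothers)

    @property
    def n_fathers(self) -> int:
        return len(self.fathers)

    @property
    def n_mating_events(self) -> int:
        return len(self.mating_events)

    def counts(self) -> dict[str, int]:
        return {
            "n_mothers": self.n_mothers,
            "n_fathers": self.n_fathers,
            "n_mating_events": self.n_mating_events,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "mothers": self.mothers,
            "fathers": self.fathers,
            "mating_events": [list(e) for e in self.mating_events],
            "nests_with_multiple_paternity": self.nests_with_multiple_paternity,
            "sample_parents": {s: list(v) for s, v in self.sample_parents.items()},
            "counts": self.counts(),
            "half_sib_links": [
                {"group_a": l.group_a, "group_b": l.group_b,
                 "mean_ibs": l.mean_ibs, "label": l.label,
                 "ambiguous": l.ambiguous, "note": l.note}
                for l in self.links
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _dates_compatible(
    dates_a: list[date | None], dates_b: list[date | None],
    internesting_max_days: int,
) -> bool | None:
    """Can one female plausibly have laid both nest sets?

    Different seasons: always plausible (remigration).  Same season: only if
    some cross pair of clutch dates is within the internesting window.
    Returns None when any date is missing (flag, do not guess).
    """
    if any(d is None for d in dates_a) or any(d is None for d in dates_b):
        return None
    for da in dates_a:
        for db in dates_b:
            if da.year != db.year:
                return True
            if abs((da - db).days) <= internesting_max_days:
                return True
    return False


def assign_parents(
    partition: SibPartition,
    nests: Sequence[NestRecord],
    haplotypes: Mapping[str, str],
    internesting_max_days: int = 30,
    bands: KinshipBands | None = None,
    evidence_z: float = 4.0,
) -> ReconstructionResult:
    """Apply rules R1-R5 to a sib partition (see module docstring).

    Cross-nest merges (R4/R5) additionally require the half-sib link to be
    confidently above the distant-kin floor (``mean - evidence_z * se``,
    with the SE computed at clustering time); links without that support are
    recorded as unresolved rather than acted on, so marker-poor datasets
    over-flag instead of wrongly merging parents.

    Raises :class:`IntegrityError` on contradictions, e.g. a full-sib group
    spanning nests with different mtDNA barcodes (full siblings must share
    the matriline).
    """
    bands = bands or KinshipBands()
    nest_by_id = {n.nest_id: n for n in nests}
    sample_nest: dict[str, str] = {}
    for n in nests:
        for s in n.samples:
            sample_nest[s] = n.nest_id
    missing_nest = [s for s in partition.samples if s not in sample_nest]
    if missing_nest:
        raise IntegrityError(f"samples without a nest record: {missing_nest[:5]}")

    # per-group nest set and barcode (R1/R2 substrate)
    group_nests: list[list[str]] = []
    group_code: list[str | None] = []
    unhaplotyped: list[str] = []
    for gi, members in enumerate(partition.groups):
        nset = sorted({sample_nest[s] for s in members})
        codes = set()
        for s in members:
            c = haplotypes.get(s)
            if c is None:
                unhaplotyped.append(s)
            else:
                codes.add(c)
        if len(codes) > 1:
            raise IntegrityError(
                f"full-sib group {sorted(members)} carries conflicting mtDNA "
                f"barcodes {sorted(codes)}: full siblings must share the matriline"
            )
        group_nests.append(nset)
        group_code.append(codes.pop() if codes else None)
    if unhaplotyped:
        logger.warning("%d samples lack an mtDNA barcode", len(unhaplotyped))

    # R1 + R2: mother identity is per nest; groups spanning nests merge them
    mother_dsu = _DSU(nest_by_id)
    for nset in group_nests:
        for other in nset[1:]:
            mother_dsu.union(nset[0], other)

    def nest_code(nid: str) -> set[str]:
        codes = set()
        for gi, nset in enumerate(group_nests):
            if nid in nset and group_code[gi] is not None:
                codes.add(group_code[gi])
        return codes

    father_dsu = _DSU(range(len(partition.groups)))

    # classify half-sib links (R3/R4/R5)
    for link in partition.links:
        na, nb = group_nests[link.group_a], group_nests[link.group_b]
        ca, cb = group_code[link.group_a], group_code[link.group_b]
        if set(na) & set(nb):
            link.label = "maternal"  # R3: within-nest multiple paternity
            continue
        if link.mean_ibs - evidence_z * link.se < bands.distant_min:
            link.label = "unresolved"
            link.note = "insufficient marker evidence for a cross-nest merge"
            continue
        if ca is not None and cb is not None and ca != cb:
            link.label = "paternal"  # R5: shared father across matrilines
            father_dsu.union(link.group_a, link.group_b)
            continue
        if ca is None or cb is None:
            link.label = "unresolved"
            link.note = "missing barcode: maternal vs paternal undecidable"
            continue
        dates_a = [nest_by_id[x].date for x in na]
        dates_b = [nest_by_id[x].date for x in nb]
        compat = _dates_compatible(dates_a, dates_b, internesting_max_days)
        if compat is None:
            link.label = "unresolved"
            link.note = "missing nest date: not merged"
        elif compat:
            link.label = "maternal"  # R4: same female remating
            link.ambiguous = True
            link.note = "same-barcode cross-nest half-sibs: paternal reading also possible"
            mother_dsu.union(na[0], nb[0])
        else:
            link.label = "paternal"
            link.ambiguous = True
            link.note = "same barcode but dates incompatible with one female"
            father_dsu.union(link.group_a, link.group_b)

    # mother classes; verify barcode coherence after merging
    mother_classes = mother_dsu.classes()
    for root, nids in mother_classes.items():
        codes = set().union(*(nest_code(x) for x in nids))
        if len(codes) > 1:
            raise IntegrityError(
                f"nests {nids} merged into one mother but carry barcodes {sorted(codes)}"
            )

    def nest_sort_key(nid: str):
        d = nest_by_id[nid].date
        return (d is None, d or date.min, nid)

    ordered_mothers = sorted(
        mother_classes.values(), key=lambda nids: min(nest_sort_key(x) for x in nids)
    )
    mother_label_of_nest: dict[str, str] = {}
    mothers: dict[str, dict] = {}
    for i, nids in enumerate(ordered_mothers, start=1):
        label = f"F{i:02d}"
        codes = set().union(*(nest_code(x) for x in nids))
        mothers[label] = {
            "barcode": codes.pop() if codes else None,
            "nests": sorted(nids, key=nest_sort_key),
            "groups": [],
        }
        for nid in nids:
            mother_label_of_nest[nid] = label

    # father classes, ordered deterministically by their first nest
    father_classes = father_dsu.classes()
    ordered_fathers = sorted(
        father_classes.values(),
        key=lambda gis: min(nest_sort_key(x) for gi in gis for x in group_nests[gi]),
    )
    fathers: dict[str, list[int]] = {}
    father_label_of_group: dict[int, str] = {}
    for j, gis in enumerate(ordered_fathers, start=1):
        label = f"M{j:02d}"
        fathers[label] = sorted(gis)
        for gi in gis:
            father_label_of_group[gi] = label

    events: set[tuple[str, str]] = set()
    sample_parents: dict[str, tuple[str, str]] = {}
    for gi, members in enumerate(partition.groups):
        m_label = mother_label_of_nest[group_nests[gi][0]]
        f_label = father_label_of_group[gi]
        mothers[m_label]["groups"].append(gi)
        events.add((m_label, f_label))
        for s in members:
            sample_parents[s] = (m_label, f_label)

    mp_nests = sorted(
        nid for nid in nest_by_id
        if len({father_label_of_group[gi]
                for gi, nset in enumerate(group_nests) if nid in nset}) > 1
    )
    return ReconstructionResult(
        mothers=mothers,
        fathers=fathers,
        mating_events=sorted(events),
        nests_with_multiple_paternity=mp_nests,
        sample_parents=sample_parents,
        links=list(partition.links),
        partition=partition,
    )


def reconstruct(
    genotypes,
    nests: Sequence[NestRecord],
    haplotypes: Mapping[str, str],
    bands: KinshipBands | None = None,
    av_min: float | None = None,
    min_overlap: int = 100,
    baseline_min_group_size: int = 5,
    internesting_max_days: int = 30,
    evidence_z: float = 4.0,
) -> tuple[ReconstructionResult, NormalizedIbsResult, SibPartition]:
    """Full pipeline: normalized IBS (nest-anchored baseline) -> sib
    partition -> parent assignment.

    The av_min baseline is taken between the two most distinct nests having
    at least ``baseline_min_group_size`` sampled hatchlings (a minimum of
    two pairs of well-sampled nests keeps the min-of-means baseline from
    being set by single-pair noise); it falls back to all nests if fewer
    than two nests qualify, and may be frozen explicitly via ``av_min``.
    """
    sample_group: dict[str, str] = {}
    for n in nests:
        for s in n.samples:
            sample_group[s] = n.nest_id
    try:
        result = compute_normalized_ibs(
            genotypes, groups=sample_group, av_min=av_min,
            min_overlap=min_overlap, baseline_min_group_size=baseline_min_group_size,
        )
    except Exception:
        if av_min is not None or baseline_min_group_size <= 1:
            raise
        result = compute_normalized_ibs(
            genotypes, groups=sample_group, min_overlap=min_overlap,
            baseline_min_group_size=1,
        )
    partition = cluster_full_sibs(result, bands=bands, evidence_z=evidence_z)
    recon = assign_parents(
        partition, nests, haplotypes, internesting_max_days=internesting_max_days,
        bands=bands, evidence_z=evidence_z,
    )
    return recon, result, partition


def multiple_paternity_report(
    result: ReconstructionResult,
    nests: Sequence[NestRecord],
    min_hatchlings: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Per-nest paternity table plus multiple-paternity summary fractions.

    The restricted summary counts only nests with strictly more than
    ``min_hatchlings`` sampled hatchlings, where polyandry is actually
    detectable.
    """
    father_of_sample = {s: f for s, (_, f) in result.sample_parents.items()}
    rows = []
    for n in nests:
        sires = sorted({father_of_sample[s] for s in n.samples if s in father_of_sample})
        rows.append({
            "nest_id": n.nest_id,
            "n_sampled": len(n.samples),
            "n_fathers": len(sires),
            "fathers": ",".join(sires),
            "multiple_paternity": len(sires) > 1,
        })
    table = pd.DataFrame(rows).sort_values("nest_id").reset_index(drop=True)
    eligible = table[table["n_sampled"] > min_hatchlings]
    summary = {
        "n_nests": int(len(table)),
        "n_multiple_paternity": int(table["multiple_paternity"].sum()),
        "fraction_multiple_paternity": (
            float(table["multiple_paternity"].mean()) if len(table) else float("nan")
        ),
        "min_hatchlings": min_hatchlings,
        "n_eligible_nests": int(len(eligible)),
        "n_multiple_paternity_eligible": int(eligible["multiple_paternity"].sum()),
        "fraction_multiple_paternity_eligible": (
            float(eligible["multiple_paternity"].mean()) if len(eligible) else float("nan")
        ),
    }
    return table, summary


@dataclass(frozen=True)
class CensusSummary:
    minimum_females: int
    n_fathers: int
    ratio: str


def census_summary(
    n_mothers: int | ReconstructionResult,
    n_fathers: int | None = None,
    extra_haplotype_count: int = 0,
) -> CensusSummary:
    """Minimum census of nesting females and the female:male ratio.

    Haplotypes recorded in nests but absent from the genotyped sample each
    imply at least one more female, so the minimum female count is
    ``n_mothers + extra_haplotype_count``.  The ratio is formatted
    ``1:x.xx`` with x truncated (not rounded) to two decimals.
    """
    if isinstance(n_mothers, ReconstructionResult):
        result = n_mothers
        n_mothers = result.n_mothers
        n_fathers = result.n_fathers if n_fathers is None else n_fathers
    if n_fathers is None:
        raise ValueError("n_fathers required")
    if extra_haplotype_count < 0:
        raise ValueError("extra_haplotype_count must be >= 0")
    if n_mothers == 0:
        raise ZeroDivisionError("ratio undefined: no mothers")
    truncated = floor(100.0 * n_fathers / n_mothers) / 100.0
    return CensusSummary(
        minimum_females=n_mothers + extra_haplotype_count,
        n_fathers=n_fathers,
        ratio=f"1:{truncated:.2f}",
    )
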