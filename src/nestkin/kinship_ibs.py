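"""Pairwise identity-by-state (IBS) kinship and its normalized form.

Per site, two genotypes score 1 when identical, 0.5 when they share one
allele, and 0 when they are opposite homozygotes; a pair's raw IBS is the
mean score over the sites called in both samples.  Raw IBS never reaches 0
for members of one gene pool, so it is rescaled against an empirical
baseline::

    normalized_IBS = (IBS - av_min) / (1 - av_min)

where ``av_min`` is the average raw IBS over all cross pairs of the two most
distinct groups (families or nests) in the dataset.  Identical samples map to
1, the baseline cross-group mean maps to 0 exactly, and values below the
baseline stay negative (they are never clipped).

The module also provides the analytic expectations used as test oracles.
With Cotterman coefficients ``(k0, k1, k2)`` - the probabilities that a pair
shares 0/1/2 alleles identical by descent - and per-site allele frequency
``p`` (``q = 1 - p``), the per-site conditional IBS expectations are::

    E[IBS | 2 IBD] = 1
    E[IBS | 1 IBD] = 1 - pq
    E[IBS | 0 IBD] = 0.5 * (1 + (1 - 2pq)^2)

so the expected normalized IBS (baseline = unrelated expectation) is
``k2 + k1 * n1`` with ``n1 = sum_s pq(1-2pq) / sum_s 2pq(1-pq)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InsufficientOverlapError",
    "BaselineError",
    "DegenerateBaselineError",
    "NormalizedIbsResult",
    "RelationshipModel",
    "MODELS",
    "KinshipBands",
    "PermutationCI",
    "ibs_pair",
    "ibs_matrix",
    "baseline_av_min",
    "normalize",
    "compute_normalized_ibs",
    "ibs_expectation_closed_form",
    "ibs_expectation_by_enumeration",
    "ibd1_site_weight",
    "expected_normalized_ibs",
    "classify_kinship",
    "permutation_ci",
]


class InsufficientOverlapError(ValueError):
    """A pair shares fewer non-missing sites than ``min_overlap``."""


class BaselineError(ValueError):
    """No valid group pair available to anchor the av_min baseline."""


class DegenerateBaselineError(ValueError):
    """av_min >= 1: normalization denominator vanishes."""


def _as_genotype_array(data) -> np.ndarray:
    if isinstance(data, GenotypeMatrix):
        return data.genotypes
    return np.asarray(data)


def ibs_pair(g1: np.ndarray, g2: np.ndarray, min_overlap: int = 100) -> float:
    """Raw IBS between two genotype vectors over their shared called sites.

    Scores per site: same genotype -> 1 (het vs het included); one shared
    allele (het vs either homozygote) -> 0.5; opposite homozygotes -> 0.
    Equivalently ``1 - |g1 - g2| / 2`` on dosage codes.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    shared = (g1 != MISSING) & (g2 != MISSING)
    n = int(shared.sum())
    if n < min_overlap:
        raise InsufficientOverlapError(
            f"pair shares only {n} called sites (< min_overlap={min_overlap})"
        )
    diff = np.abs(g1[shared].astype(np.float64) - g2[shared].astype(np.float64))
    return float(1.0 - diff.mean() / 2.0)


def ibs_matrix(
    genotypes, min_overlap: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs raw IBS with pairwise-complete missing-data handling.

    Returns ``(raw, n_overlap)``: a symmetric matrix with unit diagonal and
    the per-pair count of jointly called sites.  Pairs with overlap below
    ``min_overlap`` are masked to NaN with a warning.
    """
    G = _as_genotype_array(genotypes)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    called = (G != MISSING)
    X0 = (called & (G == 0)).astype(np.float64)
    X1 = (called & (G == 1)).astype(np.float64)
    X2 = (called & (G == 2)).astype(np.float64)
    M = called.astype(np.float64)
    n_overlap = M @ M.T
    same = X0 @ X0.T + X1 @ X1.T + X2 @ X2.T
    opposite = X0 @ X2.T + X2 @ X0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (same + 0.5 * (n_overlap - same - opposite)) / n_overlap
    low = n_overlap < min_overlap
    np.fill_diagonal(low, False)
    if low.any():
        n_masked = int(low.sum() // 2)
        warnings.warn(
            f"{n_masked} sample pair(s) share fewer than {min_overlap} sites; "
            "entries masked to NaN",
            stacklevel=2,
        )
        raw[low] = np.nan
    np.fill_diagonal(raw, 1.0)
    return raw, n_overlap.astype(np.int64)


def _group_indices(
    samples: Sequence[str] | None, groups
) -> dict[str, np.ndarray]:
    """Normalize a group spec (aligned sequence or sample->label map)."""
    if isinstance(groups, Mapping):
        if samples is None:
            raise ValueError("sample ids required when groups is a mapping")
        labels = [groups.get(s) for s in samples]
    else:
        labels = list(groups)
    out: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab is None:
            continue
        out.setdefault(str(lab), []).append(i)
    return {k: np.asarray(v, dtype=np.intp) for k, v in out.items()}


def baseline_av_min(
    raw: np.ndarray,
    groups,
    samples: Sequence[str] | None = None,
    min_group_size: int = 1,
) -> tuple[float, tuple[str, str]]:
    """The av_min baseline: smallest cross-group mean raw IBS.

    For every unordered pair of groups with at least ``min_group_size``
    members, the mean raw IBS over all cross pairs is computed; the minimum
    is the baseline and the winning group pair is returned.  Ties are broken
    by lexicographic group-label order (and logged).
    """
    idx = _group_indices(samples, groups)
    eligible = {k: v for k, v in idx.items() if len(v) >= min_group_size}
    if len(eligible) < 2:
        raise BaselineError(
            f"need >= 2 groups with >= {min_group_size} members to set av_min; "
            "supply av_min explicitly for single-group datasets"
        )
    best: tuple[float, tuple[str, str]] | None = None
    tie = False
    for a, b in combinations(sorted(eligible), 2):
        m = float(np.nanmean(raw[np.ix_(eligible[a], eligible[b])]))
        if best is None or m < best[0]:
            best = (m, (a, b))
            tie = False
        elif m == best[0]:
            tie = True
    assert best is not None
    if tie:
        logger.info(
            "baseline_av_min: tie at %.6f broken lexicographically -> %s", best[0], best[1]
        )
    logger.debug("baseline_av_min: %.6f from groups %s", best[0], best[1])
    return best


def normalize(raw: np.ndarray, av_min: float) -> np.ndarray:
    """Elementwise ``(raw - av_min) / (1 - av_min)``; negatives preserved."""
    if av_min >= 1.0:
        raise DegenerateBaselineError(f"av_min={av_min} >= 1: cannot normalize")
    return (np.asarray(raw, dtype=np.float64) - av_min) / (1.0 - av_min)


@dataclass
class NormalizedIbsResult:
    """Raw IBS, its baseline, and the normalized matrix for one dataset.

    The baseline is dataset-relative: the same pair of samples can get
    slightly different normalized values in a different dataset context.
    """

    samples: list[str]
    raw: np.ndarray
    av_min: float
    normalized: np.ndarray
    baseline_groups: tuple[str, str] | None
    n_overlap: np.ndarray

    def pair(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.normalized[i, j])


def compute_normalized_ibs(
    genotypes,
    groups=None,
    samples: Sequence[str] | None = None,
    av_min: float | None = None,
    min_overlap: int = 100,
    baseline_min_group_size: int = 1,
) -> NormalizedIbsResult:
    """IBS matrix + baseline + normalization in one call.

    ``av_min`` may be supplied explicitly to freeze comparisons across
    datasets; otherwise it is recomputed from ``groups``.
    """
    if isinstance(genotypes, GenotypeMatrix) and samples is None:
        samples = list(genotypes.samples)
    raw, n_overlap = ibs_matrix(genotypes, min_overlap=min_overlap)
    if samples is None:
        samples = [f"s{i}" for i in range(raw.shape[0])]
    baseline_groups = None
    if av_min is None:
        if groups is None:
            raise BaselineError("either groups or an explicit av_min is required")
        av_min, baseline_groups = baseline_av_min(
            raw, groups, samples=samples, min_group_size=baseline_min_group_size
        )
    return NormalizedIbsResult(
        samples=list(samples),
        raw=raw,
        av_min=float(av_min),
        normalized=normalize(raw, av_min),
        baseline_groups=baseline_groups,
        n_overlap=n_overlap,
    )


# ---------------------------------------------------------------------------
# analytic expectations (test oracles)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationshipModel:
    """A kinship band as Cotterman IBD-state probabilities (k0, k1, k2)."""

    name: str
    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-12:
            raise ValueError("k0 + k1 + k2 must equal 1")


MODELS: dict[str, RelationshipModel] = {
    "full_sib": RelationshipModel("full_sib", 0.25, 0.5, 0.25),
    "half_sib": RelationshipModel("half_sib", 0.5, 0.5, 0.0),
    "parent_offspring": RelationshipModel("parent_offspring", 0.0, 1.0, 0.0),
    "unrelated": RelationshipModel("unrelated", 1.0, 0.0, 0.0),
}


def _hwe(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def ibs_expectation_by_enumeration(p: float, n_ibd: int) -> float:
    """E[per-site IBS | IBD state] by exhaustive 9-genotype-pair enumeration.

    Joint genotype-pair probabilities are built from Hardy-Weinberg draws and
    Mendelian transmission of the shared allele(s); the per-site score matrix
    is ``1 - |g1 - g2| / 2``.  This is the independent oracle for the closed
    forms in :func:`ibs_expectation_closed_form`.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    hwe = _hwe(p)
    joint = np.zeros((3, 3))
    if n_ibd == 0:
        joint = np.outer(hwe, hwe)
    elif n_ibd == 2:
        np.fill_diagonal(joint, hwe)
    elif n_ibd == 1:
        # one shared allele a, one free allele per sample
        allele_p = {0: 1.0 - p, 1: p}
        for a, pa in allele_p.items():
            for b1, pb1 in allele_p.items():
                for b2, pb2 in allele_p.items():
                    joint[a + b1, a + b2] += pa * pb1 * pb2
    else:
        raise ValueError("IBD state must be 0, 1 or 2")
    g = np.arange(3)
    score = 1.0 - np.abs(g[:, None] - g[None, :]) / 2.0
    return float((joint * score).sum())


def ibs_expectation_closed_form(p: float, n_ibd: int) -> float:
    """Closed-form E[per-site IBS | IBD state] (see module docstring)."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    pq = p * (1.0 - p)
    if n_ibd == 2:
        return 1.0
    if n_ibd == 1:
        return 1.0 - pq
    if n_ibd == 0:
        return 0.5 * (1.0 + (1.0 - 2.0 * pq) ** 2)
    raise ValueError("IBD state must be 0, 1 or 2")


def ibd1_site_weight(freqs: np.ndarray) -> float:
    """The multi-site weight n1 = sum pq(1-2pq) / sum 2pq(1-pq).

    This is the expected normalized IBS of a parent-offspring pair (k1 = 1):
    the site-averaged excess of the 1-IBD expectation over the unrelated
    expectation, rescaled by the unrelated-to-identical span.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.ndim == 0:
        freqs = freqs[None]
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele frequencies must be in (0, 1)")
    pq = freqs * (1.0 - freqs)
    return float((pq * (1.0 - 2.0 * pq)).sum() / (2.0 * pq * (1.0 - pq)).sum())


def expected_normalized_ibs(model: RelationshipModel, freqs) -> float:
    """Expected normalized IBS for a relationship over a site panel.

    ``k2 + k1 * n1(freqs)``, with the baseline taken as the unrelated
    expectation.  Unrelated pairs map to 0 for any frequency spectrum.
    """
    if model.k1 == 0.0 and model.k2 == 0.0:
        np.asarray(freqs)  # still validate shape lazily
        return 0.0
    return model.k2 + model.k1 * ibd1_site_weight(np.asarray(freqs, dtype=np.float64))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinshipBands:
    """Normalized-IBS intervals used to label pairs.

    Defaults sit at midpoints between empirical band means (full-sib ~0.50,
    half-sib ~0.28, distant kin ~0.1-0.24, unrelated ~0.00); there is no
    universal threshold, so all cut points are configurable.  Values within
    ``ambiguity_margin`` of a boundary should be treated as ambiguous.
    """

    full_sib_min: float = 0.38
    half_sib_min: float = 0.15
    distant_min: float = 0.05
    ambiguity_margin: float = 0.03

    def __post_init__(self) -> None:
        if not self.distant_min < self.half_sib_min < self.full_sib_min:
            raise ValueError("band thresholds must be strictly increasing")

    def classify(self, value: float) -> str:
        if value >= self.full_sib_min:
            return "full-sibling"
        if value >= self.half_sib_min:
            return "half-sibling"
        if value >= self.distant_min:
            return "distant"
        return "unrelated"

    def is_ambiguous(self, value: float) -> bool:
        return any(
            abs(value - t) < self.ambiguity_margin
            for t in (self.full_sib_min, self.half_sib_min, self.distant_min)
        )


def classify_kinship(value: float, bands: KinshipBands | None = None) -> str:
    """Label a normalized-IBS value with its kinship band."""
    return (bands or KinshipBands()).classify(float(value))


# ---------------------------------------------------------------------------
# permutation confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class PermutationCI:
    """Permutation null for a within-group mean of pairwise values."""

    observed_within_group_mean: float
    n_perm: int
    ci_low: float
    ci_high: float
    significant: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def _pooled_within_mean(matrix: np.ndarray, group_slices, perm: np.ndarray) -> float:
    total = 0.0
    pairs = 0
    for sl in group_slices:
        idx = perm[sl]
        block = matrix[np.ix_(idx, idx)]
        k = len(idx)
        total += (block.sum() - np.trace(block)) / 2.0
        pairs += k * (k - 1) // 2
    return total / pairs


def permutation_ci(
    normalized: np.ndarray,
    groups,
    samples: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationCI:
    """Permutation 95% CI for the pooled within-group mean.

    Pairwise values are not independent, so significance is assessed by
    permuting sample labels while preserving group sizes: each permutation
    reassigns individuals to groups of the original sizes and records the
    pooled within-group mean; the CI is the empirical 2.5/97.5 percentile
    band of those permuted means, and the observed mean is flagged
    significant when it falls outside.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100: percentile estimates will be unstable",
            stacklevel=2,
        )
    idx = _group_indices(samples, groups)
    sizes = {k: len(v) for k, v in idx.items()}
    small = [k for k, n in sizes.items() if n < 2]
    if small or len(idx) < 1:
        raise ValueError(f"groups need >= 2 members for within-group means: {small}")
    participating = np.concatenate([idx[k] for k in sorted(idx)])
    sub = np.asarray(normalized, dtype=np.float64)[np.ix_(participating, participating)]
    n = len(participating)
    group_slices = []
    off = 0
    for k in sorted(idx):
        group_slices.append(slice(off, off + sizes[k]))
        off += sizes[k]
    observed = _pooled_within_mean(sub, group_slices, np.arange(n))
    rng = np.random.default_rng(seed)
    means = np.empty(n_perm)
    for t in range(n_perm):
        means[t] = _pooled_within_mean(sub, group_slices, rng.permutation(n))
    lo, hi = np.percentile(means, [2.5, 97.5])
    return PermutationCI(
        observed_within_group_mean=float(observed),
        n_perm=n_perm,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(observed < lo or observed > hi),
        seed=seed,
    )
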