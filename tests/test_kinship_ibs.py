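"""IBS scoring, normalization, analytic oracles, bands and permutation CIs."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestkin.genotype_io import MISSING
from nestkin.kinship_ibs import (
    MODELS,
    BaselineError,
    DegenerateBaselineError,
    InsufficientOverlapError,
    KinshipBands,
    baseline_av_min,
    classify_kinship,
    compute_normalized_ibs,
    expected_normalized_ibs,
    ibd1_site_weight,
    ibs_expectation_by_enumeration,
    ibs_expectation_closed_form,
    ibs_matrix,
    ibs_pair,
    normalize,
    permutation_ci,
)

# ---------------------------------------------------------------- raw IBS


def test_ibs_pair_direct_arithmetic():
    g1 = np.array([0, 0, 1, 0])
    g2 = np.array([0, 1, 1, 2])
    # scores: same=1, one-shared=0.5, het/het=1, opposite homs=0
    assert ibs_pair(g1, g2, min_overlap=1) == pytest.approx(0.625)


def test_ibs_pair_boundaries():
    same = np.array([0, 1, 2, 1])
    assert ibs_pair(same, same, min_overlap=1) == pytest.approx(1.0)
    assert ibs_pair(np.zeros(4, int), np.full(4, 2), min_overlap=1) == pytest.approx(0.0)


def test_ibs_pair_requires_overlap():
    g1 = np.array([0, MISSING, 1])
    g2 = np.array([MISSING, 1, 1])
    with pytest.raises(InsufficientOverlapError):
        ibs_pair(g1, g2, min_overlap=2)


@given(st.integers(min_value=0, max_value=2**32 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_ibs_pair_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    g1 = rng.integers(0, 3, size=50)
    g2 = rng.integers(0, 3, size=50)
    v = ibs_pair(g1, g2, min_overlap=1)
    assert v == ibs_pair(g2, g1, min_overlap=1)
    assert 0.0 <= v <= 1.0


def test_ibs_matrix_equals_looped_pairs(rng):
    genos = rng.integers(0, 3, size=(8, 120)).astype(np.int8)
    genos[rng.random(genos.shape) < 0.1] = MISSING
    raw, overlap = ibs_matrix(genos, min_overlap=10)
    for i, j in itertools.combinations(range(8), 2):
        assert raw[i, j] == pytest.approx(
            ibs_pair(genos[i], genos[j], min_overlap=10), abs=1e-12
        )
        assert raw[i, j] == raw[j, i]
    assert np.allclose(np.diag(raw), 1.0)


def test_ibs_matrix_sample_permutation_consistency(rng):
    genos = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
    raw, _ = ibs_matrix(genos, min_overlap=1)
    perm = rng.permutation(6)
    raw_p, _ = ibs_matrix(genos[perm], min_overlap=1)
    np.testing.assert_allclose(raw_p, raw[np.ix_(perm, perm)])


def test_ibs_matrix_masks_low_overlap_pairs():
    genos = np.array([[0, 1, MISSING, MISSING],
                      [MISSING, MISSING, 1, 0],
                      [0, 1, 1, 0]], dtype=np.int8)
    with pytest.warns(UserWarning, match="fewer than"):
        raw, _ = ibs_matrix(genos, min_overlap=1)
    assert np.isnan(raw[0, 1]) and np.isnan(raw[1, 0])
    assert raw[0, 0] == 1.0


# ------------------------------------------------------------- baseline


def test_baseline_two_groups_forced():
    raw = np.array([[1.0, 0.9, 0.7], [0.9, 1.0, 0.8], [0.7, 0.8, 1.0]])
    av_min, pair = baseline_av_min(raw, ["A", "A", "B"])
    assert pair == ("A", "B")
    assert av_min == pytest.approx((0.7 + 0.8) / 2)


def test_baseline_picks_minimum_cross_mean():
    # plant cross means: A-B 0.85, A-C 0.80, B-C 0.90
    raw = np.ones((3, 3))
    raw[0, 1] = raw[1, 0] = 0.85
    raw[0, 2] = raw[2, 0] = 0.80
    raw[1, 2] = raw[2, 1] = 0.90
    av_min, pair = baseline_av_min(raw, ["A", "B", "C"])
    assert pair == ("A", "C") and av_min == pytest.approx(0.80)


def test_baseline_single_group_errors():
    with pytest.raises(BaselineError):
        baseline_av_min(np.ones((3, 3)), ["A", "A", "A"])


@pytest.mark.parametrize(
    "raw,av_min,expected",
    [(0.8, 0.8, 0.0), (1.0, 0.8, 1.0), (0.9, 0.8, 0.5)],
)
def test_normalize_formula(raw, av_min, expected):
    assert normalize(np.array([raw]), av_min)[0] == pytest.approx(expected)


def test_normalize_preserves_negatives_and_rejects_degenerate():
    assert normalize(np.array([0.5]), 0.6)[0] < 0  # not clipped
    with pytest.raises(DegenerateBaselineError):
        normalize(np.array([0.5]), 1.0)


def test_normalization_identities_on_simulated_families(two_family_dataset):
    ds = two_family_dataset
    fam = {s: ds.truth.hatchlings[s][0] for s in ds.genotypes.samples}
    res = compute_normalized_ibs(ds.genotypes, groups=fam)
    assert np.allclose(np.diag(res.normalized), 1.0)
    idx_a = [i for i, s in enumerate(res.samples) if fam[s] == "F01"]
    idx_b = [i for i, s in enumerate(res.samples) if fam[s] == "F02"]
    cross = res.normalized[np.ix_(idx_a, idx_b)]
    assert abs(np.nanmean(cross)) < 1e-12
    # affine relation between raw and normalized
    np.testing.assert_allclose(
        res.normalized * (1 - res.av_min) + res.av_min, res.raw, atol=1e-12
    )


# ----------------------------------------------------- analytic oracles


@pytest.mark.parametrize("p", np.arange(0.05, 0.501, 0.05))
@pytest.mark.parametrize("state", [0, 1, 2])
def test_enumeration_matches_closed_form(p, state):
    assert ibs_expectation_by_enumeration(p, state) == pytest.approx(
        ibs_expectation_closed_form(p, state), abs=1e-12
    )


def test_expected_normalized_ibs_values():
    assert expected_normalized_ibs(MODELS["unrelated"], [0.1, 0.3]) == 0.0
    # single site at p = 0.5: parent-offspring expectation is exactly 1/3
    assert expected_normalized_ibs(MODELS["parent_offspring"], [0.5]) == pytest.approx(
        1.0 / 3.0, abs=1e-12
    )
    assert expected_normalized_ibs(MODELS["full_sib"], [0.5]) == pytest.approx(
        0.25 + 0.5 / 3.0, abs=1e-12
    )


def test_ibd1_weight_matches_enumeration_average():
    freqs = np.array([0.1, 0.25, 0.4])
    e1 = np.array([ibs_expectation_by_enumeration(p, 1) for p in freqs])
    e0 = np.array([ibs_expectation_by_enumeration(p, 0) for p in freqs])
    expected = (e1 - e0).sum() / (1.0 - e0).sum()
    assert ibd1_site_weight(freqs) == pytest.approx(expected, abs=1e-12)


def test_frequency_domain_errors():
    with pytest.raises(ValueError):
        ibs_expectation_by_enumeration(0.0, 1)
    with pytest.raises(ValueError):
        ibd1_site_weight(np.array([0.2, 1.0]))


# -------------------------------------------------------- classification


@pytest.mark.parametrize(
    "value,label",
    [(0.50, "full-sibling"), (0.28, "half-sibling"), (0.11, "distant"),
     (0.00, "unrelated"), (-0.02, "unrelated")],
)
def test_classify_kinship_default_bands(value, label):
    assert classify_kinship(value) == label


def test_bands_are_configurable_and_flag_ambiguity():
    bands = KinshipBands(full_sib_min=0.4, half_sib_min=0.2, distant_min=0.1)
    assert bands.classify(0.39) == "half-sibling"
    assert bands.is_ambiguous(0.39)
    assert not bands.is_ambiguous(0.30)
    with pytest.raises(ValueError):
        KinshipBands(full_sib_min=0.1, half_sib_min=0.2, distant_min=0.3)


def test_classification_accuracy_on_simulated_triads(two_family_dataset):
    """Full-sib / half-sib / unrelated pairs classify correctly >= 99%."""
    ds = two_family_dataset
    fam = {s: ds.truth.hatchlings[s][0] for s in ds.genotypes.samples}
    dad = {s: ds.truth.hatchlings[s][1] for s in ds.genotypes.samples}
    res = compute_normalized_ibs(ds.genotypes, groups=fam)
    n_ok = n_all = 0
    for i, j in itertools.combinations(range(len(res.samples)), 2):
        a, b = res.samples[i], res.samples[j]
        if fam[a] != fam[b]:
            truth = "unrelated"
        elif dad[a] == dad[b]:
            truth = "full-sibling"
        else:
            truth = "half-sibling"
        n_all += 1
        n_ok += classify_kinship(res.normalized[i, j]) == truth
    assert n_ok / n_all >= 0.99


# ------------------------------------------------------ permutation CI


def test_permutation_ci_degenerate_constant_matrix():
    m = np.full((6, 6), 0.3)
    np.fill_diagonal(m, 1.0)
    ci = permutation_ci(m, ["a", "a", "a", "b", "b", "b"], n_perm=200, seed=0)
    assert ci.ci_low == ci.ci_high == pytest.approx(0.3)
    assert ci.observed_within_group_mean == pytest.approx(0.3)
    assert not ci.significant


def test_permutation_ci_detects_true_family_structure(two_family_dataset):
    ds = two_family_dataset
    fam = {s: ds.truth.hatchlings[s][0] for s in ds.genotypes.samples}
    res = compute_normalized_ibs(ds.genotypes, groups=fam)
    ci = permutation_ci(res.normalized, fam, samples=res.samples,
                        n_perm=1000, seed=42)
    assert ci.observed_within_group_mean > ci.ci_high
    assert ci.significant


def test_permutation_ci_reproducible_and_warns_when_unstable(rng):
    m = rng.random((8, 8))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    groups = ["a"] * 4 + ["b"] * 4
    with pytest.warns(UserWarning, match="unstable"):
        ci1 = permutation_ci(m, groups, n_perm=50, seed=5)
    with pytest.warns(UserWarning):
        ci2 = permutation_ci(m, groups, n_perm=50, seed=5)
    assert (ci1.ci_low, ci1.ci_high) == (ci2.ci_low, ci2.ci_high)
    with pytest.raises(ValueError):
        permutation_ci(m, ["a"] * 7 + ["b"], n_perm=200)
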