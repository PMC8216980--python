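import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import braycurtis as scipy_braycurtis, squareform

from limnotte import (
    DomainError,
    ValidationError,
    ahc,
    box_stats,
    bray_curtis,
    bray_curtis_matrix,
    correspondence_analysis,
    fisher_lsd,
    one_way_anova,
)


# --- one-way ANOVA -----------------------------------------------------------

def test_anova_toy_hand_decomposition():
    """{1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, df (1,4) → F = 13.5."""
    res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
    assert res.f == pytest.approx(13.5, rel=1e-12)
    assert (res.df_between, res.df_within) == (1, 4)


def test_anova_identical_groups_f_zero():
    res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
    assert res.f == 0.0
    assert res.p == 1.0


def test_anova_study_design_degrees_of_freedom():
    """Group sizes 5/7/8/10 give the survey's df = (3, 26)."""
    rng = np.random.default_rng(0)
    groups = {c: rng.normal(size=n) for c, n in zip("abcd", (5, 7, 8, 10))}
    res = one_way_anova(groups)
    assert (res.df_between, res.df_within) == (3, 26)


def test_anova_zero_within_variance_unequal_means():
    res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
    assert res.f == np.inf
    assert res.p == 0.0


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(42)
    groups = {k: rng.normal(k_i, 1.0, size=6 + k_i) for k_i, k in enumerate("abc")}
    ours = one_way_anova(groups)
    ref = sstats.f_oneway(*groups.values())
    assert ours.f == pytest.approx(ref.statistic, rel=1e-10)
    assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
def test_anova_invariant_to_affine_rescaling(shift, scale):
    groups = {"a": [1.0, 2.0, 4.0], "b": [3.0, 5.0, 6.0], "c": [0.5, 2.5, 9.0]}
    base = one_way_anova(groups)
    moved = {k: [scale * x + shift for x in v] for k, v in groups.items()}
    res = one_way_anova(moved)
    assert res.f == pytest.approx(base.f, rel=1e-6)


def test_anova_validates_groups():
    with pytest.raises(ValidationError):
        one_way_anova({"a": [1.0]})
    with pytest.raises(ValidationError):
        one_way_anova({"a": [1.0], "b": [2.0]})  # total n must exceed k


# --- Fisher LSD and the compact letter display -------------------------------

def test_lsd_identical_groups_share_a_letter():
    res = fisher_lsd({"a": [1, 2, 3], "b": [1, 2, 3]}, protected=False)
    assert res.letters == {"a": "a", "b": "a"}


def test_lsd_far_separated_group_gets_own_letter():
    groups = {
        "g1": [10.0, 10.1, 10.2, 9.9],
        "g2": [10.05, 10.15, 9.95, 10.1],
        "g3": [50.0, 50.1, 49.9, 50.2],
    }
    res = fisher_lsd(groups, alpha=0.05)
    assert res.performed
    assert res.letters["g3"] != res.letters["g1"]
    assert res.letters["g1"] == res.letters["g2"]
    # alphabet is assigned from the highest mean downward
    assert res.letters["g3"] == "a"
    assert res.letters["g1"] == res.letters["g2"] == "b"


def test_lsd_letters_invariant_to_relabeling():
    groups = {
        "x": [1.0, 1.2, 0.9], "y": [1.1, 1.05, 0.95], "z": [9.0, 9.1, 8.9],
    }
    res1 = fisher_lsd(groups, protected=False)
    renamed = {"p": groups["x"], "q": groups["y"], "r": groups["z"]}
    res2 = fisher_lsd(renamed, protected=False)
    assert [res1.letters[k] for k in ("x", "y", "z")] == \
        [res2.letters[k] for k in ("p", "q", "r")]


def test_lsd_letters_match_pairwise_significance():
    """Two groups share a letter iff their pairwise test is non-significant."""
    rng = np.random.default_rng(3)
    groups = {
        "a": rng.normal(0, 1, 8), "b": rng.normal(0.5, 1, 8),
        "c": rng.normal(3, 1, 8), "d": rng.normal(3.2, 1, 8),
    }
    res = fisher_lsd(groups, alpha=0.05, protected=False)
    for pair, p in res.pairwise_p.items():
        g1, g2 = sorted(pair)
        shared = set(res.letters[g1]) & set(res.letters[g2])
        assert bool(shared) == (not p < 0.05)


def test_protected_lsd_stops_on_nonsignificant_anova():
    rng = np.random.default_rng(5)
    groups = {k: rng.normal(0, 1, 6) for k in "abc"}
    res = fisher_lsd(groups, alpha=0.01)
    if not res.anova.p < 0.01:
        assert not res.performed
        assert set(res.letters.values()) == {"a"}


def test_lsd_permits_singleton_group():
    res = fisher_lsd({"a": [1.0, 2.0, 3.0], "b": [10.0]}, protected=False)
    assert "b" in res.letters


# --- box statistics ----------------------------------------------------------

def test_box_stats_median_of_four():
    b = box_stats([1, 2, 3, 4])
    assert b.median == 2.5


def test_box_stats_single_value():
    b = box_stats([7.0])
    assert (b.q1, b.median, b.q3, b.mean, b.minimum, b.maximum) == (7.0,) * 6
    assert b.outliers == ()


def test_box_stats_outlier_by_iqr_rule():
    b = box_stats([1, 2, 3, 4, 100])
    assert 100.0 in b.outliers
    assert b.maximum == 100.0  # whiskers stay at min/max


def test_box_stats_type7_quartiles():
    v = [2.0, 4.0, 6.0, 8.0, 10.0]
    b = box_stats(v)
    assert b.q1 == pytest.approx(np.quantile(v, 0.25))
    assert b.q3 == pytest.approx(np.quantile(v, 0.75))


# --- Bray–Curtis -------------------------------------------------------------

def test_bray_curtis_identical_and_disjoint():
    assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
    assert bray_curtis([1, 0], [0, 1]) == 1.0
    assert bray_curtis([5, 0], [0, 5]) == 1.0  # scale of disjoint supports


def test_bray_curtis_direct_formula():
    assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2, rel=1e-12)


def test_bray_curtis_matches_scipy():
    rng = np.random.default_rng(11)
    x, y = rng.random(12), rng.random(12)
    assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y), rel=1e-12)


def test_bray_curtis_semimetric_properties():
    rng = np.random.default_rng(12)
    x, y = rng.random(6), rng.random(6)
    assert bray_curtis(x, y) == pytest.approx(bray_curtis(y, x), rel=1e-12)
    assert 0 <= bray_curtis(x, y) <= 1
    with pytest.raises(DomainError):
        bray_curtis([0, 0], [0, 0])


# --- agglomerative clustering ------------------------------------------------

def test_ahc_two_points():
    d = np.array([[0.0, 0.4], [0.4, 0.0]])
    merges = ahc(d)
    assert len(merges) == 1
    assert merges[0].height == pytest.approx(0.4)
    assert {merges[0].left, merges[0].right} == {0, 1}


def test_ahc_tie_broken_by_lowest_index_pair():
    d = np.full((3, 3), 0.5)
    np.fill_diagonal(d, 0.0)
    merges = ahc(d)
    assert (merges[0].left, merges[0].right) == (0, 1)


def test_ahc_recovers_ultrametric():
    """On an ultrametric input, merge heights reproduce the tree exactly."""
    d = np.array([
        [0.0, 0.2, 0.8, 0.8],
        [0.2, 0.0, 0.8, 0.8],
        [0.8, 0.8, 0.0, 0.4],
        [0.8, 0.8, 0.4, 0.0],
    ])
    heights = [m.height for m in ahc(d, linkage="average")]
    assert heights == pytest.approx([0.2, 0.4, 0.8])


def test_ahc_heights_nondecreasing_average_linkage():
    rng = np.random.default_rng(21)
    pts = rng.random((8, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    heights = [m.height for m in ahc(d, linkage="average")]
    assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


def test_ahc_matches_scipy_average_linkage():
    rng = np.random.default_rng(22)
    pts = rng.random((7, 4))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    ours = ahc(d, linkage="average")
    ref = scipy_hierarchy.linkage(squareform(d, checks=False), method="average")
    assert [m.height for m in ours] == pytest.approx(list(ref[:, 2]), rel=1e-10)


# --- correspondence analysis -------------------------------------------------

def _brute_force_inertia_fractions(table):
    """Independent oracle: eigendecompose SᵀS of the chi-square
    standardized matrix directly."""
    p = table / table.sum()
    r, c = p.sum(1), p.sum(0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    eig = np.linalg.eigvalsh(s.T @ s)[::-1]
    eig = eig[eig > 1e-12]
    return eig / (s ** 2).sum()


def test_ca_rank_one_table_zero_inertia():
    table = np.outer([1.0, 2.0, 3.0], [4.0, 5.0])
    res = correspondence_analysis(table)
    assert res.total_inertia == 0.0
    assert res.inertia_fractions.size == 0


def test_ca_2x2_single_dimension():
    res = correspondence_analysis(np.array([[10.0, 2.0], [3.0, 9.0]]))
    assert res.inertia_fractions.size == 1
    assert res.inertia_fractions[0] == pytest.approx(1.0, abs=1e-12)


def test_ca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(31)
    for _ in range(5):
        table = rng.integers(1, 40, size=(6, 8)).astype(float)
        res = correspondence_analysis(table)
        oracle = _brute_force_inertia_fractions(table)
        assert np.allclose(res.inertia_fractions, oracle, atol=1e-8)


def test_ca_inertia_fractions_sum_to_one():
    rng = np.random.default_rng(32)
    table = rng.integers(1, 30, size=(5, 9)).astype(float)
    res = correspondence_analysis(table)
    assert res.inertia_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(res.inertia_fractions) <= 1e-12)  # non-increasing


def test_cca_constrained_explains_no_more_than_total():
    rng = np.random.default_rng(33)
    table = rng.integers(1, 30, size=(8, 6)).astype(float)
    z = np.array([[1, 0]] * 4 + [[0, 1]] * 4, dtype=float)
    res = correspondence_analysis(table, constraints=z)
    assert res.constrained
    assert res.inertia_fractions.sum() <= 1.0 + 1e-9
    # a two-level constraint spans one non-trivial dimension
    assert res.inertia_fractions.size <= 2


def test_cca_rank_deficient_constraints_error():
    table = np.ones((4, 3)) + np.eye(4, 3)
    z = np.array([[1.0, 2.0]] * 4)
    with pytest.raises(DomainError):
        correspondence_analysis(table, constraints=z)


def test_ca_rejects_bad_tables():
    with pytest.raises(DomainError):
        correspondence_analysis(np.array([[1.0, -1.0], [1.0, 1.0]]))
    with pytest.raises(DomainError):
        correspondence_analysis(np.array([[0.0, 0.0], [1.0, 1.0]]))
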