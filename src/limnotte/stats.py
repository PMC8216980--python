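"""The survey's statistical layer, implemented from first principles.

Covers one-way ANOVA with the classical sum-of-squares decomposition,
Fisher's (protected) LSD with a compact letter display, box-plot
descriptive statistics, Bray–Curtis dissimilarity with naive
agglomerative clustering, and (canonical) correspondence analysis via
singular value decomposition of the chi-square-standardized matrix.
Only the F and t distributions are delegated to scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import DomainError, ValidationError

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 1 for a in arrs.values()):
        raise ValidationError("every group needs at least one value")
    if sum(a.size for a in arrs.values()) <= len(arrs):
        raise ValidationError("total n must exceed the number of groups")
    return arrs


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Degenerate cases: all values identical gives F = 0 (p = 1); zero
    within-group variance with unequal means gives F = inf, p = 0.
    """
    arrs = _check_groups(groups)
    allv = np.concatenate(list(arrs.values()))
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_b = len(arrs) - 1
    df_w = allv.size - len(arrs)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = 0.0 if ms_b == 0 else math.inf
    else:
        f = ms_b / ms_w
    p = 1.0 if f == 0 else (0.0 if math.isinf(f) else float(_sstats.f.sf(f, df_b, df_w)))
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w, p=p, ms_within=float(ms_w))


# ---------------------------------------------------------------------------
# Fisher LSD with compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LsdResult:
    pairwise_p: dict  # frozenset({g1, g2}) -> p
    letters: dict  # group -> letter string
    performed: bool  # False when protection stopped the pairwise stage
    anova: AnovaResult


def _compact_letters(order: Sequence[str], nonsig: set) -> dict:
    """Compact letter display from the non-significance graph.

    Groups sharing a letter are exactly the members of a maximal clique
    of the graph whose vertices are groups and whose edges join pairs
    that do not differ significantly.  ``order`` (descending mean) fixes
    the alphabet assignment.
    """
    idx = {g: i for i, g in enumerate(order)}
    adj = {g: set() for g in order}
    for a, b in nonsig:
        adj[a].add(b)
        adj[b].add(a)

    cliques: list = []

    def expand(clique: set, candidates: set) -> None:  # Bron–Kerbosch, no pivot
        if not candidates:
            if not any(clique < c for c in cliques):
                cliques.append(set(clique))
            return
        for v in sorted(candidates, key=idx.get):
            expand(clique | {v}, candidates & adj[v])
            candidates = candidates - {v}

    expand(set(), set(order))
    # keep maximal cliques only, ordered by their best (earliest) member
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    maximal.sort(key=lambda c: min(idx[g] for g in c))
    letters = {g: "" for g in order}
    for letter, clique in zip(_ALPHABET, maximal):
        for g in clique:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in order}


def fisher_lsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    protected: bool = True,
) -> LsdResult:
    """All-pairs LSD t tests on the pooled within-group mean square.

    With ``protected=True`` (default) the pairwise stage only runs when
    the omnibus ANOVA is significant at ``alpha``; otherwise every group
    shares the letter "a".  Groups of size one are permitted (their
    variance is pooled from the others).
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    arrs = _check_groups(groups)
    anova = one_way_anova(groups)
    order = sorted(arrs, key=lambda g: -float(np.mean(arrs[g])))
    if protected and not anova.p < alpha:
        return LsdResult(
            pairwise_p={},
            letters={g: "a" for g in order},
            performed=False,
            anova=anova,
        )
    pairwise = {}
    nonsig = set()
    for g1, g2 in itertools.combinations(order, 2):
        a, b = arrs[g1], arrs[g2]
        se = math.sqrt(anova.ms_within * (1 / a.size + 1 / b.size))
        if se == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            t = (a.mean() - b.mean()) / se
            p = 2 * float(_sstats.t.sf(abs(t), anova.df_within))
        pairwise[frozenset((g1, g2))] = p
        if not p < alpha:
            nonsig.add(frozenset((g1, g2)))
    letters = _compact_letters(order, {tuple(s) for s in nonsig})
    return LsdResult(pairwise_p=pairwise, letters=letters, performed=True, anova=anova)


# ---------------------------------------------------------------------------
# Box-plot descriptive statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxStats:
    q1: float
    median: float
    q3: float
    mean: float
    minimum: float
    maximum: float
    outliers: tuple


def box_stats(values: Sequence[float]) -> BoxStats:
    """Quartiles (linear interpolation), mean, min/max whiskers, and
    1.5·IQR outliers."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise DomainError("box_stats needs at least one value")
    q1, med, q3 = (float(q) for q in np.quantile(v, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(x) for x in v[(v < lo) | (v > hi)])
    return BoxStats(
        q1=q1,
        median=med,
        q3=q3,
        mean=float(v.mean()),
        minimum=float(v.min()),
        maximum=float(v.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# Bray–Curtis dissimilarity and agglomerative clustering
# ---------------------------------------------------------------------------

def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) on abundance vectors."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise DomainError("vectors differ in length")
    if (a < 0).any() or (b < 0).any():
        raise DomainError("abundances must be non-negative")
    denom = float((a + b).sum())
    if denom == 0:
        raise DomainError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(table: np.ndarray) -> np.ndarray:
    """Pairwise Bray–Curtis matrix for rows of an abundance table."""
    t = np.asarray(table, dtype=float)
    n = t.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(t[i], t[j])
    return d


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    new_id: int
    size: int


def ahc(dissimilarity: np.ndarray, linkage: str = "average") -> list:
    """Agglomerative hierarchical clustering (average/complete/single).

    Returns the n−1 merges as :class:`Merge` records; original sites are
    0..n−1, merged clusters continue the numbering (scipy convention).
    Ties are broken by the lexicographically smallest (i, j) pair of
    cluster ids.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DomainError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T):
        raise DomainError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise DomainError("dissimilarity must have a zero diagonal")
    n = d.shape[0]
    active = {i: [i] for i in range(n)}  # cluster id -> member sites
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[i] + active[j]
        merges.append(Merge(left=i, right=j, height=h, new_id=next_id, size=len(members)))
        del active[i], active[j]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k, mem in active.items():
            sub = d[np.ix_(members, mem)]
            if linkage == "average":
                v = float(sub.mean())
            elif linkage == "complete":
                v = float(sub.max())
            else:
                v = float(sub.min())
            dist[(min(k, next_id), max(k, next_id))] = v
        active[next_id] = members
        next_id += 1
    return merges


# ---------------------------------------------------------------------------
# Correspondence analysis (CA) and its constrained form (CCA)
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    site_scores: np.ndarray  # sites × dimensions
    variable_scores: np.ndarray  # variables × dimensions
    eigenvalues: np.ndarray
    inertia_fractions: np.ndarray
    total_inertia: float
    constrained: bool = False


def _standardized_residuals(table: np.ndarray) -> tuple:
    p = table / table.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return s, r, c


def correspondence_analysis(
    table: np.ndarray, constraints: Optional[np.ndarray] = None
) -> OrdinationResult:
    """CA of a non-negative sites × variables table; CCA when site
    covariates are supplied.

    CA decomposes the chi-square-standardized residual matrix
    S = D_r^{-1/2}(P − r cᵀ)D_c^{-1/2} by SVD; eigenvalues are squared
    singular values and total inertia is ‖S‖². In the constrained mode
    the rows of S are first projected onto the span of the
    row-mass-weighted covariates, and inertia fractions stay relative to
    the total (unconstrained) inertia.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise DomainError("table must be 2-D")
    if (x < 0).any():
        raise DomainError("table must be non-negative")
    if (x.sum(axis=1) == 0).any() or (x.sum(axis=0) == 0).any():
        raise DomainError("table has an all-zero row or column")
    s, r, c = _standardized_residuals(x)
    total_inertia = float((s ** 2).sum())
    if total_inertia < 1e-20:  # independence table: zero inertia
        total_inertia = 0.0
    constrained = constraints is not None
    if constrained:
        z = np.asarray(constraints, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != x.shape[0]:
            raise DomainError("constraints must have one row per site")
        w = np.sqrt(r)[:, None] * z
        if np.linalg.matrix_rank(w) < w.shape[1]:
            raise DomainError("constraints are rank-deficient")
        q, _ = np.linalg.qr(w)
        s = q @ (q.T @ s)
    u, sing, vt = np.linalg.svd(s, full_matrices=False)
    keep = sing > max(1e-12, 1e-12 * (sing[0] if sing.size else 0.0))
    u, sing, vt = u[:, keep], sing[keep], vt[keep]
    eig = sing ** 2
    fractions = eig / total_inertia if total_inertia > 0 else np.zeros(0)
    if total_inertia == 0:
        u = np.zeros((x.shape[0], 0))
        vt = np.zeros((0, x.shape[1]))
        sing = np.zeros(0)
        eig = np.zeros(0)
    site_scores = (u * sing) / np.sqrt(r)[:, None] if sing.size else np.zeros((x.shape[0], 0))
    var_scores = (vt.T * sing) / np.sqrt(c)[:, None] if sing.size else np.zeros((x.shape[1], 0))
    return OrdinationResult(
        site_scores=site_scores,
        variable_scores=var_scores,
        eigenvalues=eig,
        inertia_fractions=fractions,
        total_inertia=total_inertia,
        constrained=constrained,
    )
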