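"""Distance-based multivariate community analysis.

Bray-Curtis dissimilarity, principal coordinates analysis (Gower
double-centering + eigendecomposition), PERMANOVA (global and
pairwise), PERMDISP (homogeneity of multivariate dispersions) and
covariance-style taxon contribution arrows, all implemented directly on
the distance matrix. Permutation p-values use the add-one rule
p = (1 + #{perm >= obs}) / (1 + n_perm), so p can never be zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import AbundanceMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermutationTestResult",
    "bray_curtis",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "taxa_contributions",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray
    flagged_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be >= 0")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA coordinates, eigenvalues and axis shares."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


@dataclass(frozen=True)
class PermutationTestResult:
    statistic_name: str
    statistic: float
    p_value: float
    permutations: int
    groups: tuple[str, ...]
    seed: int | None = None
    r2: float = math.nan
    df_between: int = 0
    df_within: int = 0


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d_jk = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik). An all-zero row is
    at distance 1 from any non-zero row by convention (flagged) and at
    distance 0 from another all-zero row.
    """
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    x = np.asarray(data, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    zero_rows = x.sum(axis=1) == 0
    ids = tuple(str(i) for i in data.index)
    flagged = tuple(np.asarray(ids)[zero_rows])
    return DistanceMatrix(ids, d, flagged_samples=flagged)


def pcoa(dm: DistanceMatrix, eps: float = 1e-12) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J with J the centering matrix; coordinates are the
    eigenvectors of B scaled by the square roots of their (positive)
    eigenvalues. Negative eigenvalues (non-Euclidean distances) are
    reported; their axes are omitted. No Cailliez/Lingoes correction is
    applied.
    """
    n = dm.n
    if n < 3:
        raise ValueError("pcoa needs at least 3 samples")
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = eps * max(1.0, abs(eigval[0]))
    positive = eigval > tol
    negative = eigval[eigval < -tol]
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    share = eigval[positive] / pos_sum if pos_sum > 0 else np.zeros(positive.sum())
    axes = [f"PCoA{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=eigval,
        proportion_explained=share,
        negative_eigenvalues=negative,
    )


def _group_indicators(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    uniq, inverse = np.unique(labels, return_inverse=True)
    g = np.zeros((labels.size, uniq.size))
    g[np.arange(labels.size), inverse] = 1.0
    return g, inverse, list(uniq)


def _pseudo_f(d2: np.ndarray, inverse: np.ndarray, n_groups: int) -> tuple[float, float]:
    """PERMANOVA pseudo-F and R^2 from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = inverse == g
        ng = members.sum()
        ss_within += d2[np.ix_(members, members)].sum() / (2.0 * ng)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0:
        return math.inf, 1.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, ss_between / ss_total


def _check_groups(labels: np.ndarray) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"group of size 1: {small[0]!r}")


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    SS_total = (1/N) sum_{j<k} d^2_jk; SS_within sums (1/n_g) of
    within-group squared distances; pseudo-F = (SS_between/(a-1)) /
    (SS_within/(N-a)). Significance by random label permutations with
    the add-one rule. Degenerate zero within-group spread yields
    F = +inf and the smallest attainable p.
    """
    labels = _as_labels(dm, groups)
    _check_groups(labels)
    uniq, inverse = np.unique(labels, return_inverse=True)
    d2 = dm.values ** 2
    f_obs, r2 = _pseudo_f(d2, inverse, uniq.size)
    if math.isinf(f_obs):
        # zero within-group spread: no permutation can exceed it
        p = 1.0 / (1 + n_perm)
        return PermutationTestResult(
            statistic_name="pseudo-F", statistic=f_obs, p_value=p,
            permutations=n_perm, groups=tuple(str(u) for u in uniq), seed=seed,
            r2=r2, df_between=uniq.size - 1, df_within=dm.n - uniq.size,
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(inverse)
        f_perm, _ = _pseudo_f(d2, perm, uniq.size)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(
        statistic_name="pseudo-F", statistic=f_obs, p_value=p,
        permutations=n_perm, groups=tuple(str(u) for u in uniq), seed=seed,
        r2=r2, df_between=uniq.size - 1, df_within=dm.n - uniq.size,
    )


def _as_labels(dm: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return groups.loc[list(dm.ids)].to_numpy()
    labels = np.asarray(groups)
    if labels.size != dm.n:
        raise ValueError("group labels do not match distance matrix")
    return labels


def pairwise_permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """One PERMANOVA per unordered group pair on the sub-matrix.

    Uncorrected p-values by default, with a Benjamini-Hochberg column
    always emitted for transparency.
    """
    labels = _as_labels(dm, groups)
    _check_groups(labels)
    uniq = sorted(np.unique(labels))
    rows = []
    rng = np.random.default_rng(seed)
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i + 1:]:
            mask = np.isin(labels, [g1, g2])
            ids = [s for s, keep in zip(dm.ids, mask) if keep]
            sub = dm.subset(ids)
            res = permanova(sub, labels[mask], n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31)))
            rows.append({"group_1": g1, "group_2": g2, "pseudo_F": res.statistic,
                         "p": res.p_value, "r2": res.r2, "n": sub.n,
                         "permutations": n_perm})
    out = pd.DataFrame(rows)
    out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def _centroid_distances(dm: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Squared distances subtract the negative-axis contribution (imaginary
    coordinates of non-Euclidean distance matrices) and are clamped at
    zero before the square root.
    """
    n = dm.n
    d2 = dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    tol = 1e-12 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    neg = eigval < -tol
    coords_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])
    uniq, inverse = np.unique(labels, return_inverse=True)
    z2 = np.zeros(n)
    for g in range(uniq.size):
        members = inverse == g
        cp = coords_pos[members].mean(axis=0) if coords_pos.size else 0.0
        cn = coords_neg[members].mean(axis=0) if coords_neg.size else 0.0
        dp = ((coords_pos[members] - cp) ** 2).sum(axis=1) if coords_pos.size else 0.0
        dn = ((coords_neg[members] - cn) ** 2).sum(axis=1) if coords_neg.size else 0.0
        z2[members] = np.maximum(dp - dn, 0.0)
    return np.sqrt(z2)


def _anova_f(values: np.ndarray, inverse: np.ndarray, n_groups: int) -> float:
    n = values.size
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(n_groups):
        sub = values[inverse == g]
        ss_b += sub.size * (sub.mean() - grand) ** 2
        ss_w += ((sub - sub.mean()) ** 2).sum()
    if ss_w <= 0:
        return math.inf
    return (ss_b / (n_groups - 1)) / (ss_w / (n - n_groups))


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 999,
             seed: int | None = None) -> PermutationTestResult:
    """Permutation test of homogeneity of multivariate dispersions.

    Per-sample distances to the group centroid are computed once in
    PCoA space; the one-way ANOVA F on those distances is assessed by
    permuting group labels.
    """
    labels = _as_labels(dm, groups)
    _check_groups(labels)
    uniq, inverse = np.unique(labels, return_inverse=True)
    z = _centroid_distances(dm, labels)
    f_obs = _anova_f(z, inverse, uniq.size)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(inverse)
        if _anova_f(z, perm, uniq.size) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(
        statistic_name="PERMDISP-F", statistic=f_obs, p_value=p,
        permutations=n_perm, groups=tuple(str(u) for u in uniq), seed=seed,
        df_between=uniq.size - 1, df_within=dm.n - uniq.size,
    )


def taxa_contributions(matrix, ordination: OrdinationResult, top_k: int = 10) -> pd.DataFrame:
    """Covariance-style biplot arrows for the taxa driving dissimilarity.

    Each taxon's arrow is the covariance of its abundance with the
    scores on the first two axes, scaled so the largest arrow has unit
    magnitude. Constant taxa get zero arrows. Returns the ``top_k`` by
    magnitude.
    """
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    coords = ordination.coordinates
    if not set(data.index) == set(coords.index):
        raise ValueError("matrix and ordination must share samples")
    data = data.loc[coords.index]
    axes = coords.iloc[:, :2].to_numpy()
    centered_axes = axes - axes.mean(axis=0)
    x = data.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    n = x.shape[0]
    cov = centered.T @ centered_axes / (n - 1)
    magnitude = np.sqrt((cov ** 2).sum(axis=1))
    scale = magnitude.max()
    if scale > 0:
        cov = cov / scale
        magnitude = magnitude / scale
    arrows = pd.DataFrame({
        "taxon": data.columns,
        "axis1": cov[:, 0],
        "axis2": cov[:, 1] if cov.shape[1] > 1 else 0.0,
        "magnitude": magnitude,
    })
    arrows = arrows.sort_values(["magnitude", "taxon"], ascending=[False, True])
    return arrows.head(top_k).reset_index(drop=True)
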