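"""Cross-method statistics: reproducibility, overlap and normalization fits.

Implements the statistics used to compare metabarcoding (MB) against
Utermohl microscopy (UM): replicate coefficients of variation,
Mann-Whitney U (exact tail for small tie-free samples, tie- and
continuity-corrected normal approximation otherwise), presence/absence
cross-tabulation, rare-taxon rules, top-genera union, volume-saturation
summaries, and the log-log regression / Spearman grid across read
normalizations and microscopy currencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AsvTable
from .normalize import (
    AbundanceMatrix,
    NormalizationUnavailableError,
    aggregate_to_rank,
    dna_normalize,
    microscopy_matrix,
    relative_abundance,
    spike_normalize,
)
from .taxonomy import UNASSIGNED

__all__ = [
    "ComparisonResult",
    "replicate_cv",
    "mann_whitney_u",
    "presence_overlap",
    "rare_taxa",
    "top_genera_union",
    "volume_saturation",
    "fit_loglog",
    "spearman_rho",
    "pooled_spearman",
    "normalization_grid",
    "MB_MEASURES",
    "UM_MEASURES",
]

logger = logging.getLogger(__name__)

MB_MEASURES = ("reads", "spike", "dna", "relative")
UM_MEASURES = ("cells_per_liter", "carbon_ugC_per_liter", "biovolume_um3_per_liter")


@dataclass(frozen=True)
class ComparisonResult:
    """One regression/correlation cell of the normalization grid."""

    mb_measure: str = ""
    um_measure: str = ""
    rank: str = ""
    basin: str = "all"
    n: int = 0
    n_excluded: int = 0
    slope: float = math.nan
    intercept: float = math.nan
    r2: float = math.nan
    adj_r2: float = math.nan
    spearman: float = math.nan
    fitted: bool = False


def replicate_cv(replicates: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Per-class CV (sample SD / mean) of community proportions.

    ``replicates`` is replicates x classes. Classes with zero mean have
    undefined CV and are excluded (returned in the second element).
    """
    if len(replicates) < 2:
        raise ValueError("replicate_cv needs at least 2 replicates")
    mean = replicates.mean(axis=0)
    sd = replicates.std(axis=0, ddof=1)
    excluded = list(mean.index[mean == 0])
    cv = (sd / mean)[mean > 0]
    return cv, excluded


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _u_tail_counts(nx: int, ny: int) -> np.ndarray:
    """Number of rank arrangements with each U value, U = 0..nx*ny.

    Classic recurrence N(m, n, u) = N(m, n-1, u) + N(m-1, n, u-n) on the
    Gaussian binomial coefficients; exact for tie-free samples.
    """
    # table[m][u] for current n as we iterate n upward
    max_u = nx * ny
    prev = [np.zeros(max_u + 1) for _ in range(nx + 1)]
    for m in range(nx + 1):
        prev[m][0] = 1.0  # n = 0: only U = 0
    for n in range(1, ny + 1):
        cur = [np.zeros(max_u + 1) for _ in range(nx + 1)]
        cur[0][0] = 1.0
        for m in range(1, nx + 1):
            cur[m] = prev[m].copy()  # N(m, n-1, u)
            shifted = np.zeros(max_u + 1)
            shifted[n:] = cur[m - 1][: max_u + 1 - n]  # N(m-1, n, u-n)
            cur[m] += shifted
        prev = cur
    return prev[nx]


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U and two-sided p for two independent samples.

    U counts pairs with x_i > y_j, ties contributing 1/2. ``mode``:
    "exact" enumerates the tie-free null distribution (error on ties),
    "approx" uses the normal approximation with tie and continuity
    corrections, "auto" picks exact when n_x + n_y <= 12 and no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    u = float(greater) + 0.5 * float(ties)
    nx, ny = x.size, y.size
    has_ties = len(np.unique(np.concatenate([x, y]))) < nx + ny

    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and not has_ties and nx + ny <= 12)
    if use_exact:
        if has_ties:
            raise ValueError("exact mode requires tie-free samples")
        counts = _u_tail_counts(nx, ny)
        total = counts.sum()
        k = int(round(u))
        cdf = counts[: k + 1].sum() / total
        sf = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return u, float(p)

    # normal approximation with tie correction and continuity correction
    n = nx + ny
    combined = np.concatenate([x, y])
    _, t = np.unique(combined, return_counts=True)
    tie_term = ((t ** 3 - t).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    mu = nx * ny / 2.0
    if sigma2 <= 0:
        return u, 1.0
    diff = u - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2) if diff != 0 else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u, float(p)


# ---------------------------------------------------------------------------
# Presence / rarity / top genera

def presence_overlap(presence_a: pd.DataFrame, presence_b: pd.DataFrame,
                     grouping: pd.Series) -> tuple[pd.DataFrame, dict]:
    """Cross-tabulate presence of genera between methods per basin.

    Both inputs are boolean samples x genera with identical indexing;
    ``grouping`` maps sample -> basin. Returns per genus x basin counts
    of both / a_only / b_only / neither, plus overall totals and the
    share of union observations detected by both methods.
    """
    if not presence_a.index.equals(presence_b.index) or not presence_a.columns.equals(presence_b.columns):
        raise ValueError("presence matrices must share samples and genera")
    grouping = grouping.loc[presence_a.index]
    rows = []
    for basin, samples in grouping.groupby(grouping).groups.items():
        a = presence_a.loc[samples]
        b = presence_b.loc[samples]
        both = (a & b).sum(axis=0)
        a_only = (a & ~b).sum(axis=0)
        b_only = (~a & b).sum(axis=0)
        neither = (~a & ~b).sum(axis=0)
        for genus in presence_a.columns:
            rows.append({
                "genus": genus, "basin": basin,
                "both": int(both[genus]), "a_only": int(a_only[genus]),
                "b_only": int(b_only[genus]), "neither": int(neither[genus]),
                "n_samples": len(samples),
            })
    table = pd.DataFrame(rows)
    tot_both = int(table["both"].sum())
    tot_a = int(table["a_only"].sum())
    tot_b = int(table["b_only"].sum())
    union = tot_both + tot_a + tot_b
    totals = {
        "both": tot_both, "a_only": tot_a, "b_only": tot_b,
        "neither": int(table["neither"].sum()),
        "n_union_observations": union,
        "overlap_share": tot_both / union if union else math.nan,
    }
    return table, totals


@dataclass(frozen=True)
class RareTaxa:
    """Taxa below a relative-abundance threshold."""

    rare_everywhere: tuple[str, ...]
    rare_cumulative: tuple[str, ...]
    never_observed: tuple[str, ...]
    threshold: float


def rare_taxa(matrix, threshold: float = 1e-4) -> RareTaxa:
    """Taxa with relative abundance below ``threshold`` in every sample.

    Also returns the cumulative variant (abundance summed over samples
    below the threshold) and flags taxa never observed at all.
    """
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    if isinstance(matrix, AbundanceMatrix) and matrix.currency != "relative":
        raise ValueError("rare_taxa expects a relative matrix")
    maxima = data.max(axis=0)
    rare = maxima[maxima < threshold].index
    cumulative = data.sum(axis=0)
    rare_cum = cumulative[cumulative < threshold].index
    never = maxima[maxima == 0].index
    return RareTaxa(tuple(rare), tuple(rare_cum), tuple(never), threshold)


@dataclass(frozen=True)
class TopGeneraUnion:
    top_a: tuple[str, ...]
    top_b: tuple[str, ...]
    union: tuple[str, ...]
    membership: pd.DataFrame


def top_genera_union(matrix_a, matrix_b, k: int = 15) -> TopGeneraUnion:
    """Union of each method's top-k genera by mean relative abundance.

    Ranking uses the mean across samples, ties broken lexicographically
    for determinism; ``unassigned`` never ranks.
    """
    def top(matrix) -> tuple[str, ...]:
        data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
        means = data.mean(axis=0).drop(labels=[UNASSIGNED], errors="ignore")
        if len(means) < k:
            logger.warning("only %d genera available for top-%d ranking", len(means), k)
        order = sorted(means.index, key=lambda g: (-means[g], g))
        return tuple(order[:k])

    top_a, top_b = top(matrix_a), top(matrix_b)
    union = sorted(set(top_a) | set(top_b))
    membership = pd.DataFrame({
        "genus": union,
        "in_a": [g in top_a for g in union],
        "in_b": [g in top_b for g in union],
    })
    return TopGeneraUnion(top_a, top_b, tuple(union), membership)


# ---------------------------------------------------------------------------
# Volume saturation

def volume_saturation(volumes: pd.Series, totals: pd.DataFrame,
                      richness_col: str = "phyto_richness") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries per filtered-volume group and pairwise richness tests.

    ``volumes`` maps sample -> volume group; ``totals`` holds per-sample
    total reads, phytoplankton reads and phytoplankton ASV richness.
    Groups with fewer than two samples are excluded with a warning.
    Pairwise Mann-Whitney U is run on the richness column.
    """
    volumes = volumes.loc[totals.index]
    sizes = volumes.value_counts()
    small = sizes[sizes < 2].index
    if len(small):
        logger.warning("volume groups excluded (<2 samples): %s", list(small))
    keep = ~volumes.isin(small)
    volumes, totals = volumes[keep], totals.loc[keep]
    groups = sorted(volumes.unique())
    if len(groups) < 2:
        raise ValueError("volume_saturation needs at least 2 volume groups")
    rows = []
    for g in groups:
        sub = totals[volumes == g]
        for col in totals.columns:
            q1, med, q3 = np.percentile(sub[col], [25, 50, 75])
            rows.append({"volume": g, "quantity": col, "n": len(sub),
                         "q1": q1, "median": med, "q3": q3})
    summary = pd.DataFrame(rows)
    pair_rows = []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            u, p = mann_whitney_u(totals.loc[volumes == g1, richness_col],
                                  totals.loc[volumes == g2, richness_col])
            pair_rows.append({"volume_1": g1, "volume_2": g2, "U": u, "p": p})
    return summary, pd.DataFrame(pair_rows)


# ---------------------------------------------------------------------------
# Regression / correlation

def fit_loglog(x, y, zero_policy: str = "drop", **labels) -> ComparisonResult:
    """OLS on log10-transformed pairs.

    ``zero_policy`` "drop" excludes pairs where either value is zero
    (counted in ``n_excluded``); "pseudocount" replaces zeros with half
    the smallest positive value of the same vector. Fewer than three
    usable pairs yields an unfitted result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("log-log fit needs non-negative inputs")
    if zero_policy == "drop":
        mask = (x > 0) & (y > 0)
        n_excluded = int((~mask).sum())
        x, y = x[mask], y[mask]
    elif zero_policy == "pseudocount":
        n_excluded = 0
        for v in (x, y):
            if (v == 0).any():
                pos = v[v > 0]
                if pos.size == 0:
                    return ComparisonResult(n=0, n_excluded=v.size, **labels)
                v[v == 0] = 0.5 * pos.min()
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    n = x.size
    if n < 3:
        return ComparisonResult(n=n, n_excluded=n_excluded, **labels)
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return ComparisonResult(n=n, n_excluded=n_excluded, **labels)
    res = stats.linregress(lx, ly)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    rho = spearman_rho(lx, ly)
    return ComparisonResult(n=n, n_excluded=n_excluded, slope=res.slope,
                            intercept=res.intercept, r2=r2, adj_r2=adj,
                            spearman=rho, fitted=True, **labels)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (midranks for ties); NaN if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("spearman_rho needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pooled_spearman(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Spearman over all shared sample x taxon cells of two matrices."""
    taxa = sorted(set(a.columns) & set(b.columns))
    samples = sorted(set(a.index) & set(b.index))
    av = a.loc[samples, taxa].to_numpy().ravel()
    bv = b.loc[samples, taxa].to_numpy().ravel()
    return spearman_rho(av, bv)


def _mb_matrices(asv: AsvTable, metadata: pd.DataFrame) -> dict[str, AbundanceMatrix]:
    matrices = {
        "reads": AbundanceMatrix(asv.nonspike_counts().astype(float), "reads"),
        "relative": relative_abundance(asv),
    }
    try:
        matrices["spike"] = spike_normalize(asv, metadata)
    except NormalizationUnavailableError as exc:
        logger.warning("spike normalization disabled: %s", exc)
    try:
        matrices["dna"] = dna_normalize(asv, metadata)
    except NormalizationUnavailableError as exc:
        logger.warning("DNA normalization disabled: %s", exc)
    return matrices


def normalization_grid(asv: AsvTable, microscopy: pd.DataFrame,
                       metadata: pd.DataFrame, taxonomy: pd.DataFrame,
                       ranks: tuple[str, ...] = ("class", "genus"),
                       zero_policy: str = "drop") -> pd.DataFrame:
    """Full factorial comparison of MB normalizations vs UM currencies.

    MB measures {reads, spike, dna, relative} x UM measures {cells,
    carbon, biovolume} x rank {class, genus} x grouping {all, per
    basin}, each cell a log-log OLS fit plus Spearman on the pooled
    class-by-sample (or genus-by-sample) observations shared between the
    two datasets. ``taxonomy`` and ``microscopy`` are expected
    harmonized (name maps, diatom lumping, Centrales rule applied).
    """
    mb_raw = _mb_matrices(asv, metadata)
    basins = []
    if "basin" in metadata.columns:
        basins = sorted(metadata.loc[asv.sample_ids, "basin"].dropna().unique())
    rows = []
    for rank in ranks:
        mb_at_rank = {m: aggregate_to_rank(mat, taxonomy, rank) for m, mat in mb_raw.items()}
        um_at_rank = {u: microscopy_matrix(microscopy, u, rank) for u in UM_MEASURES}
        for mb_name in MB_MEASURES:
            if mb_name not in mb_at_rank:
                continue
            mb = mb_at_rank[mb_name].data.drop(columns=[UNASSIGNED], errors="ignore")
            for um_name, um_mat in um_at_rank.items():
                um = um_mat.data.drop(columns=[UNASSIGNED], errors="ignore")
                taxa = sorted(set(mb.columns) & set(um.columns))
                samples = sorted(set(mb.index) & set(um.index))
                if not taxa or not samples:
                    continue
                groupings = [("all", samples)]
                for basin in basins:
                    in_basin = [s for s in samples if metadata.loc[s, "basin"] == basin]
                    groupings.append((basin, in_basin))
                for basin, group_samples in groupings:
                    if len(group_samples) == 0:
                        continue
                    xv = mb.loc[group_samples, taxa].to_numpy().ravel()
                    yv = um.loc[group_samples, taxa].to_numpy().ravel()
                    res = fit_loglog(xv, yv, zero_policy=zero_policy,
                                     mb_measure=mb_name, um_measure=um_name,
                                     rank=rank, basin=basin)
                    rows.append(res.__dict__)
    return pd.DataFrame(rows)
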