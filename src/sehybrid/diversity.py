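"""Alpha/beta diversity and permutational statistics.

Shannon, Simpson and Chao1 alpha-diversity indices; Bray-Curtis
beta-diversity; one-factor PERMANOVA (Adonis) with per-variable effect
sizes (R-squared); Spearman correlation and the Wilcoxon rank-sum test.

PERMANOVA follows the classical sums-of-squares decomposition on a
distance matrix:

    SS_total   = sum_{i<j} d_ij^2 / N
    SS_within  = sum_g sum_{i<j in g} d_ij^2 / n_g
    SS_between = SS_total - SS_within
    pseudo-F   = (SS_between / (a-1)) / (SS_within / (N-a))
    R^2        = SS_between / SS_total

with the p-value from random relabelings, p = (1 + #{F_perm >= F_obs})
/ (1 + n_permutations), or from exhaustive enumeration of all distinct
group-size-preserving label assignments (``permutations="exhaustive"``).
The significance threshold used throughout the package is alpha = 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from skbio import DistanceMatrix

from .data import AbundanceTable

logger = logging.getLogger(__name__)

ALPHA = 0.01  # package-wide significance threshold


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(p: np.ndarray, base: float | None = None) -> float:
    """Shannon index, -sum p_i log p_i over p_i > 0.  Natural log by
    default; pass ``base=2`` for bits."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def simpson(p: np.ndarray) -> float:
    """Gini-Simpson index, 1 - sum p_i^2 (probability two random reads
    belong to different genera)."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - (p ** 2).sum())


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness estimate from integer counts.

    S_obs + F1^2 / (2 F2); when no doubletons exist, the classic fallback
    S_obs + F1 (F1 - 1) / 2 is used.
    """
    c = np.asarray(counts)
    if not np.allclose(c, np.round(c)):
        raise ValueError("chao1 requires integer counts")
    c = np.round(c).astype(int)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 ** 2 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / 2


def alpha_diversity(table: AbundanceTable, counts: pd.DataFrame | None = None,
                    base: float | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Shannon and Simpson are computed from relative abundances; Chao1
    needs integer counts and is only filled in when a `counts` table
    (same sample ids) is supplied.
    """
    res = pd.DataFrame(index=table.data.index)
    res["shannon"] = [shannon(row, base=base) for row in table.values]
    res["simpson"] = [simpson(row) for row in table.values]
    if counts is not None:
        cdf = counts.loc[table.sample_ids]
        res["chao1"] = [chao1(row) for row in cdf.values]
    return res


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix, d = sum|x-y| / sum(x+y) in [0,1].

    Stands in for phylogeny-weighted community distances; any precomputed
    :class:`skbio.DistanceMatrix` can be used downstream instead.
    """
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square TSV distance matrix (ids in first row and column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix(df.values, ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    variable: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"PERMANOVA[{self.variable}] R2={self.r_squared:.4f} "
                f"F={self.pseudo_f:.3f} p={self.p_value:.4g} "
                f"({self.n_permutations} permutations)")


def _ss_decomposition(sq: np.ndarray, codes: np.ndarray, n_groups: int
                      ) -> tuple[float, float, float]:
    """(SS_total, SS_within, SS_between) from squared distances `sq`."""
    n = sq.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = sq[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = sq[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def _pseudo_f(sq: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = sq.shape[0]
    ss_total, ss_within, ss_between = _ss_decomposition(sq, codes, n_groups)
    if ss_within == 0:
        return np.inf if ss_between > 0 else np.nan
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(dist: DistanceMatrix, grouping,
              n_permutations: int | str = 999,
              seed: int | None = None,
              variable: str = "grouping") -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Parameters
    ----------
    grouping
        Categorical labels aligned with ``dist.ids`` (sequence, or a
        Series indexed by sample id).
    n_permutations
        Number of random relabelings (>= 99), or ``"exhaustive"`` to
        enumerate every distinct group-size-preserving assignment
        (feasible for small N; p then equals #{F >= F_obs} / #assignments,
        the identity assignment included).
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.loc[list(dist.ids)]
    labels = np.asarray(grouping)
    if len(labels) != len(dist.ids):
        raise ValueError("grouping length does not match distance matrix")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sq = np.asarray(dist.data, dtype=float) ** 2
    n = sq.shape[0]
    ss_total, ss_within, ss_between = _ss_decomposition(sq, codes, a)
    f_obs = _pseudo_f(sq, codes, a)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    if n_permutations == "exhaustive":
        f_all = [_pseudo_f(sq, np.asarray(perm), a)
                 for perm in _distinct_assignments(codes)]
        f_all = np.asarray(f_all)
        p = float(np.mean(f_all >= f_obs - 1e-12))
        n_perm = len(f_all)
    else:
        n_perm = int(n_permutations)
        if n_perm < 99:
            raise ValueError("n_permutations must be >= 99 (or 'exhaustive')")
        rng = np.random.default_rng(seed)
        perm_codes = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
        f_perm = _pseudo_f_batch(sq, perm_codes, a, ss_total)
        hits = int(np.sum(f_perm >= f_obs - 1e-12))
        p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(variable=variable, r_squared=float(r2),
                           pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_perm)


def _pseudo_f_batch(sq: np.ndarray, perm_codes: np.ndarray, n_groups: int,
                    ss_total: float) -> np.ndarray:
    """Pseudo-F for a batch of label assignments (rows of `perm_codes`),
    vectorized over permutations.  Group sizes are permutation-invariant."""
    n = sq.shape[0]
    ss_within = np.zeros(perm_codes.shape[0])
    for g in range(n_groups):
        z = (perm_codes == g).astype(float)
        n_g = z[0].sum()
        if n_g < 2:
            continue
        # z sq z^T counts each within-group pair twice; diagonal of sq is 0
        ss_within += np.einsum("pi,ij,pj->p", z, sq, z) / (2.0 * n_g)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    f[ss_within == 0] = np.inf
    return f


def _distinct_assignments(codes: np.ndarray):
    """All distinct orderings of the label multiset (deduplicated)."""
    seen = set()
    for perm in iter_permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield perm


def effect_size_scan(dist: DistanceMatrix, meta: pd.DataFrame,
                     variables: list[str], n_permutations: int = 999,
                     seed: int | None = None) -> list[PermanovaResult]:
    """Single-factor PERMANOVA per host variable, ranked by effect size.

    Results are sorted by R-squared descending (ties broken by variable
    name); variables with a single observed level are skipped with a
    warning.  Continuous variables must be pre-binned (see the encoding
    module's age/BMI bins).
    """
    results = []
    for i, var in enumerate(variables):
        if var not in meta.columns:
            raise KeyError(f"variable {var!r} not in metadata")
        vals = meta.loc[list(dist.ids), var]
        if vals.nunique() < 2:
            logger.warning("effect_size_scan: variable %r has a single level; "
                           "skipped", var)
            continue
        sub_seed = None if seed is None else seed + i
        results.append(permanova(dist, vals, n_permutations=n_permutations,
                                 seed=sub_seed, variable=var))
    results.sort(key=lambda r: (-r.r_squared, r.variable))
    return results


def scan_to_frame(results: list[PermanovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variable": r.variable, "r_squared": r.r_squared,
          "pseudo_f": r.pseudo_f, "p_value": r.p_value,
          "n_permutations": r.n_permutations} for r in results])


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    valid: bool = True


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation, two-sided p.  Constant input gives an
    undefined rho, returned as a flagged (``valid=False``) result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs paired inputs of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=float("nan"), p_value=float("nan"),
                                 valid=False)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p))


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value; exact for
    small tie-free samples, normal approximation otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
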