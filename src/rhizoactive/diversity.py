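"""Beta diversity: Bray-Curtis, PCoA, PERMANOVA, PERMDISP, resampled richness.

Distance matrices are held in :class:`skbio.stats.distance.DistanceMatrix`
(symmetry and zero diagonal validated on construction).  PERMANOVA here is
the multi-term, sequential (Type I) sum-of-squares partition of a
Gower-centered distance matrix with free row permutation — the behaviour of
the classical ``adonis``-style test — so interaction models over the
factorial design (crop, planted, drought, day) can be fitted directly.
PERMDISP embeds samples by PCoA (positive axes), measures each sample's
distance to its group's spatial center (geometric median by default), and
permutes group labels around a one-way ANOVA F on those distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .core_io import CountTable
from .activity import rarefy

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "DispersionResult",
    "bray_curtis",
    "pcoa",
    "PCoAResult",
    "permanova",
    "pairwise_permanova",
    "permdisp",
    "resampled_richness",
]


# ---------------------------------------------------------------------------
# Dissimilarity
# ---------------------------------------------------------------------------

def bray_curtis(table, warn: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    ``d[i,j] = 1 - 2 * sum_t min(x_it, x_jt) / sum_t (x_it + x_jt)``.
    Accepts a :class:`CountTable` or a samples x taxa DataFrame of
    non-negative values (counts or relative abundances).  A pair of all-zero
    samples is defined as distance 0, with a warning.
    """
    df = table.data if isinstance(table, CountTable) else pd.DataFrame(table)
    x = df.to_numpy().astype(float)
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (x < 0).any():
        raise ValueError("negative values are not allowed")
    zero_rows = x.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if zero_rows.any():
        if warn is not None:
            warn.append(
                f"samples with zero total: {list(df.index[zero_rows])}; "
                "pairwise distances involving two all-zero samples set to 0"
            )
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(i) for i in df.index])


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCoAResult:
    sample_ids: list[str]
    coordinates: pd.DataFrame       # samples x positive axes, scaled by sqrt(lambda)
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_eigenvalue_mass: float   # sum |negative eigenvalues|


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates on the
    positive axes scaled by sqrt(eigenvalue).  Negative eigenvalues (from
    non-Euclidean dissimilarities such as Bray-Curtis) are reported but
    their axes are excluded; percent variance is taken over positive
    eigenvalues.
    """
    g = _gower_center(dm.data.astype(float))
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    ids = list(dm.ids)
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PC{i + 1}" for i in range(int(pos.sum()))]
    )
    return PCoAResult(
        sample_ids=ids,
        coordinates=frame,
        eigenvalues=vals,
        proportion_explained=(vals[pos] / vals[pos].sum()) if pos.any() else np.array([]),
        negative_eigenvalue_mass=float(-vals[vals < -tol].sum()),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    term: str
    df: int
    sum_of_squares: float
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def _term_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Full-rank-free one-hot block for a main effect or ':' interaction."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        if part not in metadata.columns:
            raise KeyError(f"metadata has no factor {part!r}")
        dummies = pd.get_dummies(metadata[part].astype(str), drop_first=False)
        blocks.append(dummies.to_numpy(dtype=float))
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(out.shape[0], -1)
    return out


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _sequential_projectors(
    blocks: list[np.ndarray], n: int
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, int]:
    """Per-term projector increments H_k - H_{k-1}, term dfs, residual projector.

    The projectors depend only on the design, so they are computed once and
    reused across permutations of the Gower matrix.
    """
    x = np.ones((n, 1))
    h_prev = _hat(x)
    rank_prev = 1
    proj, dfs = [], []
    for block in blocks:
        x = np.hstack([x, block])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        df_term = rank - rank_prev
        if df_term == 0:
            raise ValueError("model term adds no rank: aliased with preceding terms")
        proj.append(h - h_prev)
        dfs.append(df_term)
        h_prev, rank_prev = h, rank
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    resid = np.eye(n) - h_prev
    return proj, np.asarray(dfs), resid, df_res


def _sequential_ss(g, proj, resid) -> tuple[np.ndarray, float]:
    # trace(P @ G) == sum(P * G) for symmetric P, G
    return np.array([float(np.sum(p * g)) for p in proj]), float(np.sum(resid * g))


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
    permutations: str = "random",
) -> list[PermanovaResult]:
    """adonis-style PERMANOVA with sequential (Type I) sums of squares.

    ``terms`` are metadata column names, with ``"a:b"`` denoting an
    interaction; order matters (sequential partition).  p-values use the
    (b+1)/(B+1) estimator under free row permutation, or exact enumeration
    of all n! row orders when ``permutations="exact"`` (small n only).
    """
    meta = metadata.loc[list(dm.ids)]
    n = len(dm.ids)
    blocks = [_term_columns(meta, t) for t in terms]
    g = _gower_center(dm.data.astype(float))
    proj, dfs, resid, df_res = _sequential_projectors(blocks, n)
    ss, ss_res = _sequential_ss(g, proj, resid)
    ss_total = float(np.trace(g))
    f_obs = (ss / dfs) / (ss_res / df_res)

    if permutations == "exact":
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9")
        perms = list(itertools.permutations(range(n)))
        hits = np.zeros(len(terms))
        for perm in perms:
            idx = np.array(perm)
            gp = g[np.ix_(idx, idx)]
            ssp, ssrp = _sequential_ss(gp, proj, resid)
            fp = (ssp / dfs) / (ssrp / df_res)
            hits += fp >= f_obs - 1e-12
        p = hits / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        hits = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            gp = g[np.ix_(idx, idx)]
            ssp, ssrp = _sequential_ss(gp, proj, resid)
            fp = (ssp / dfs) / (ssrp / df_res)
            hits += fp >= f_obs - 1e-12
        p = (hits + 1.0) / (n_perm + 1.0)
        n_used = n_perm

    results = [
        PermanovaResult(
            term=t, df=int(dfs[i]), sum_of_squares=float(ss[i]),
            pseudo_F=float(f_obs[i]), R2=float(ss[i] / ss_total),
            p_value=float(p[i]), n_permutations=n_used,
        )
        for i, t in enumerate(terms)
    ]
    results.append(PermanovaResult(
        term="Residual", df=int(df_res), sum_of_squares=float(ss_res),
        pseudo_F=math.nan, R2=float(ss_res / ss_total), p_value=math.nan,
        n_permutations=n_used,
    ))
    return results


def pairwise_permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    n_perm: int = 999,
    seed: int = 0,
    warn: list[str] | None = None,
) -> pd.DataFrame:
    """One-factor PERMANOVA on every level pair, with BH-adjusted q-values."""
    from .stats_dynamics import bh_fdr

    meta = metadata.loc[list(dm.ids)]
    levels = sorted(meta[factor].dropna().astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(levels, 2):
        mask = meta[factor].astype(str).isin([a, b])
        ids = list(meta.index[mask])
        sub_meta = meta.loc[ids]
        if (sub_meta[factor] == a).sum() < 2 or (sub_meta[factor] == b).sum() < 2:
            if warn is not None:
                warn.append(f"pair ({a}, {b}) skipped: a level has < 2 samples")
            continue
        sub = dm.filter(ids)
        res = permanova(sub, sub_meta, [factor], n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31 - 1)))
        rows.append({
            "level_1": a, "level_2": b, "df": res[0].df,
            "pseudo_F": res[0].pseudo_F, "R2": res[0].R2, "p_value": res[0].p_value,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionResult:
    group_means: pd.Series
    F: float
    p_value: float
    distances: pd.Series
    n_permutations: int


def _spatial_median(points: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Geometric median by Weiszfeld iteration (with coincident-point guard)."""
    y = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - y, axis=1)
        if np.any(d < 1e-12):
            return points[np.argmin(d)]
        w = 1.0 / d
        y_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _dispersion_f(coords: np.ndarray, codes: np.ndarray, k: int, center: str):
    dists = np.empty(coords.shape[0])
    means = np.empty(k)
    for gi in range(k):
        pts = coords[codes == gi]
        ctr = _spatial_median(pts) if center == "median" else pts.mean(axis=0)
        dg = np.linalg.norm(pts - ctr, axis=1)
        dists[codes == gi] = dg
        means[gi] = dg.mean()
    n = coords.shape[0]
    grand = dists.mean()
    counts = np.bincount(codes, minlength=k)
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((dists - means[codes]) ** 2).sum())
    if ss_within == 0:
        f = math.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, dists, means


def permdisp(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    center: str = "median",
) -> DispersionResult:
    """Homogeneity-of-dispersion test (PERMDISP) on a distance matrix.

    Samples are embedded by PCoA (positive axes only; the discarded negative
    eigenvalue mass is available from :func:`pcoa`), each sample's distance
    to its group's spatial center is computed, and group labels are permuted
    around the one-way ANOVA F of those distances (centers recomputed per
    permutation).
    """
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")
    groups = groups.loc[list(dm.ids)].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    counts = groups.value_counts()
    singletons = counts.index[counts < 2]
    if len(singletons):
        raise ValueError(f"groups of size 1 have undefined dispersion: {list(singletons)}")
    codes = groups.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    coords = pcoa(dm).coordinates.to_numpy()
    k = len(levels)
    f_obs, dists, means = _dispersion_f(coords, codes, k, center)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _, _ = _dispersion_f(coords, rng.permutation(codes), k, center)
        if f_p >= f_obs - 1e-12:
            hits += 1
    return DispersionResult(
        group_means=pd.Series(means, index=levels, name="mean_distance_to_center"),
        F=float(f_obs),
        p_value=(hits + 1.0) / (n_perm + 1.0),
        distances=pd.Series(dists, index=list(dm.ids), name="distance_to_center"),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# Richness
# ---------------------------------------------------------------------------

def resampled_richness(
    table: CountTable, depth: int, n_resamples: int = 100, seed: int = 0
) -> pd.Series:
    """Mean observed-taxon count over repeated rarefactions to ``depth``."""
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    if depth > sums.min():
        raise ValueError(
            f"depth {depth} exceeds the smallest sample total {sums.min()}"
        )
    acc = np.zeros(table.n_samples)
    for _ in range(n_resamples):
        sub = rarefy(table, depth, seed=int(rng.integers(2 ** 31 - 1)))
        acc += (sub.data.loc[table.sample_ids].to_numpy() > 0).sum(axis=1)
    return pd.Series(acc / n_resamples, index=table.sample_ids, name="richness")
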