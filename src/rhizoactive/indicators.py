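"""Indicator-taxon analysis via the group-equalized phi coefficient.

The abundance-based phi coefficient is the Pearson correlation between a
taxon's abundance vector and the 0/1 membership vector of a target group
set.  The "r.g." (group-equalized) correction reweights samples so every
group contributes equal total weight — ``w_i = N / (K * n_g(i))`` — which
removes the dependence of phi on unequal group sizes.  Significance is
assessed by permuting sample-to-group assignments (one-sided, large phi),
with Benjamini-Hochberg FDR control across taxa.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountTable

__all__ = ["IndicatorResult", "phi_rg", "indicator_analysis", "venn_partition"]


@dataclass(frozen=True)
class IndicatorResult:
    taxon_id: str
    best_set: tuple[str, ...]
    phi: float
    p_value: float
    q_value: float


def _group_weights(groups: np.ndarray) -> np.ndarray:
    """Sample weights giving every group equal total weight (sum = N)."""
    levels, counts = np.unique(groups, return_counts=True)
    k = len(levels)
    n = len(groups)
    size = dict(zip(levels, counts))
    return np.array([n / (k * size[g]) for g in groups])


def _weighted_phi(x: np.ndarray, member: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    mm = (w * member).sum() / wsum
    cov = (w * (x - mx) * (member - mm)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vm = (w * (member - mm) ** 2).sum()
    if vx <= 0 or vm <= 0:
        return np.nan
    return cov / np.sqrt(vx * vm)


def phi_rg(x, membership, groups) -> float:
    """Group-size-corrected phi between an abundance vector and a target set.

    ``membership`` is the 0/1 indicator of the target group set per sample;
    ``groups`` assigns every sample to exactly one group (used for the
    equalizing weights).  With equal group sizes this reduces to the plain
    point-biserial correlation.  Constant ``x`` has no defined association
    and returns NaN.
    """
    x = np.asarray(x, dtype=float)
    membership = np.asarray(membership, dtype=float)
    groups = np.asarray(groups)
    if not (len(x) == len(membership) == len(groups)):
        raise ValueError("x, membership and groups must have equal length")
    return _weighted_phi(x, membership, _group_weights(groups))


def _target_sets(levels: list[str], include_unions: bool):
    targets = [(lv,) for lv in levels]
    if include_unions:
        for r in range(2, len(levels)):
            targets.extend(itertools.combinations(levels, r))
    return targets


def indicator_analysis(
    table,
    groups: pd.Series,
    include_unions: bool = False,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[IndicatorResult]:
    """Best target set, phi, permutation p and BH q for every taxon.

    For each taxon, phi_rg is evaluated against every candidate target set
    (singleton groups; proper unions if ``include_unions``, never the
    all-groups set) and the maximizing set is assigned.  The permutation
    null shuffles sample-to-group assignment and tracks the maximum phi over
    target sets, giving a one-sided (b+1)/(B+1) p-value; q-values are BH
    across taxa.  Taxa with constant abundance are reported with NaN phi.
    """
    from .stats_dynamics import bh_fdr

    df = table.data if isinstance(table, CountTable) else pd.DataFrame(table)
    groups = groups.loc[df.index].astype(str)
    g = groups.to_numpy()
    levels, counts = np.unique(g, return_counts=True)
    if (counts == 0).any() or len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    targets = _target_sets(list(levels), include_unions)
    w = _group_weights(g)
    member = np.stack([np.isin(g, t).astype(float) for t in targets])  # T x N

    x = df.to_numpy(dtype=float).T  # taxa x samples
    rng = np.random.default_rng(seed)

    wsum = w.sum()

    def best_phi(xmat: np.ndarray, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # weighted correlation of every taxon row with every target row
        mx = (xmat * w).sum(axis=1, keepdims=True) / wsum
        xc = xmat - mx
        vx = ((xc ** 2) * w).sum(axis=1)
        mm = (members * w).sum(axis=1, keepdims=True) / wsum
        mc = members - mm
        vm = ((mc ** 2) * w).sum(axis=1)
        cov = (xc * w) @ mc.T                     # taxa x targets
        with np.errstate(invalid="ignore", divide="ignore"):
            phis = cov / np.sqrt(np.outer(vx, vm))
        best = np.nanargmax(np.where(np.isnan(phis), -np.inf, phis), axis=1)
        return phis[np.arange(xmat.shape[0]), best], best

    constant = x.std(axis=1) == 0
    phi_obs, best_idx = best_phi(x, member)
    phi_obs[constant] = np.nan

    hits = np.zeros(x.shape[0])
    for _ in range(n_perm):
        # shuffling the abundance columns (samples) against the fixed design
        # keeps the equalizing weights aligned with their groups
        perm = rng.permutation(len(g))
        phi_p, _ = best_phi(x[:, perm], member)
        hits += np.where(np.isnan(phi_p), False, phi_p >= phi_obs - 1e-12)
    p = (hits + 1.0) / (n_perm + 1.0)
    p[constant] = np.nan

    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = bh_fdr(p[valid])

    return [
        IndicatorResult(
            taxon_id=str(taxon),
            best_set=targets[best_idx[i]] if not constant[i] else (),
            phi=float(phi_obs[i]) if not constant[i] else np.nan,
            p_value=float(p[i]) if not constant[i] else np.nan,
            q_value=float(q[i]) if not constant[i] else np.nan,
        )
        for i, taxon in enumerate(df.columns)
    ]


def indicators_frame(results: list[IndicatorResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_id": [r.taxon_id for r in results],
            "best_set": ["+".join(r.best_set) for r in results],
            "phi": [r.phi for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    ).set_index("taxon_id")


def venn_partition(named_sets: dict[str, set]) -> dict[tuple[str, ...], set]:
    """Exact membership of every intersection region of 2-4 named sets.

    A region is keyed by the tuple of set names its members belong to (and
    no others); empty regions are included with empty member sets.  Region
    sizes sum to the size of the union.
    """
    if not 2 <= len(named_sets) <= 4:
        raise ValueError("venn_partition supports 2-4 sets")
    names = list(named_sets)
    regions: dict[tuple[str, ...], set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(set(), *(named_sets[n] for n in names if n not in combo))
            regions[combo] = inside - outside
    return regions
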