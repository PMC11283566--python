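"""Metabolite feature-table chemometrics: filters, scaling, PCA, PLS-DA/VIP.

The processing order is fixed and mirrors common practice for untargeted
LC-MS feature tables: presence filter (maximum intensity across biological
samples >= 500 counts), interquartile-range filter, log transform with
half-minimum zero replacement, pareto scaling (mean-center, divide by the
square root of the standard deviation), then PCA for overview and PLS-DA
for supervised discrimination.  Feature influence is scored by the VIP
(variable importance in projection) statistic

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

where p is the number of features, w_a the a-th PLS weight vector and
SSY_a the Y-variance explained by component a; sum_j VIP_j^2 = p by
construction.  The top-VIP heatmap matrix is 0-1 scaled per feature (by
maximum) and ordered by Ward clustering on squared Euclidean distances
(the Ward.D flavour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "PlsdaModel",
    "presence_filter",
    "iqr_filter",
    "normalize",
    "pca_scores",
    "plsda_vip",
    "top_vip_heatmap",
]


def presence_filter(fm: pd.DataFrame, min_max_abundance: float = 500.0,
                    warn: list[str] | None = None) -> pd.DataFrame:
    """Keep features whose maximum intensity across samples >= threshold."""
    keep = fm.max(axis=0) >= min_max_abundance
    if warn is not None and not keep.any():
        warn.append("presence filter removed every feature")
    return fm.loc[:, keep]


def iqr_filter(fm: pd.DataFrame, drop_quantile: float = 0.25) -> pd.DataFrame:
    """Drop features whose IQR falls below the drop_quantile of all IQRs."""
    if not 0.0 <= drop_quantile < 1.0:
        raise ValueError("drop_quantile must be in [0, 1)")
    if drop_quantile == 0.0 or fm.shape[1] == 0:
        return fm
    iqr = fm.quantile(0.75) - fm.quantile(0.25)
    cut = iqr.quantile(drop_quantile)
    return fm.loc[:, iqr > cut]


def normalize(
    fm: pd.DataFrame,
    log_base: float = 10.0,
    zero_policy: str = "half_min",
    scaling: str = "pareto",
    warn: list[str] | None = None,
) -> pd.DataFrame:
    """Zero replacement, log transform, then column scaling.

    zero_policy "half_min" replaces each feature's zeros with half its
    smallest positive intensity.  Features that are entirely zero are
    dropped (with a warning).  scaling: "pareto" ((x - mean)/sqrt(sd)),
    "unit" ((x - mean)/sd), or "none" (log only).
    """
    if (fm.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    if scaling not in ("pareto", "unit", "none"):
        raise ValueError("scaling must be 'pareto', 'unit' or 'none'")
    x = fm.to_numpy(dtype=float).copy()
    all_zero = (x <= 0).all(axis=0)
    if all_zero.any():
        if warn is not None:
            warn.append(
                f"dropping all-zero features: {list(fm.columns[all_zero])}"
            )
        fm = fm.loc[:, ~all_zero]
        x = x[:, ~all_zero]
    if zero_policy == "half_min":
        for j in range(x.shape[1]):
            col = x[:, j]
            if (col <= 0).any():
                col[col <= 0] = col[col > 0].min() / 2.0
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    logged = np.log(x) / np.log(log_base)
    if scaling == "none":
        out = logged
    else:
        mu = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        denom = np.sqrt(sd) if scaling == "pareto" else sd
        out = (logged - mu) / denom
    return pd.DataFrame(out, index=fm.index, columns=fm.columns)


def pca_scores(matrix: pd.DataFrame, n_components: int = 2):
    """Centered PCA scores and explained-variance fractions (via SVD)."""
    from sklearn.decomposition import PCA

    n, p = matrix.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components {n_components} exceeds min(n, p) = {min(n, p)}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy(dtype=float))
    frame = pd.DataFrame(
        scores, index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, model.explained_variance_ratio_


@dataclass(frozen=True)
class PlsdaModel:
    n_components: int
    weights: np.ndarray        # p x A
    scores: pd.DataFrame       # n x A
    loadings: np.ndarray       # p x A
    ssy: np.ndarray            # explained-Y sum of squares per component
    vip: pd.Series             # per-feature VIP
    classes: list[str]


def plsda_vip(
    matrix: pd.DataFrame, class_labels: pd.Series, n_components: int = 2
) -> PlsdaModel:
    """PLS-DA (NIPALS, one-hot class response) with per-feature VIP scores."""
    from sklearn.cross_decomposition import PLSRegression

    labels = class_labels.loc[matrix.index].astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least two samples")
    y = pd.get_dummies(labels)[classes].to_numpy(dtype=float)
    x = matrix.to_numpy(dtype=float)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x, y)

    w = pls.x_weights_                   # p x A
    t = pls.x_scores_                    # n x A
    q = pls.y_loadings_                  # classes x A
    # Y sum of squares explained per component: ||t_a||^2 * ||q_a||^2
    ssy = (t ** 2).sum(axis=0) * (q ** 2).sum(axis=0)
    p = x.shape[1]
    wnorm2 = (w ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * ((w ** 2 / wnorm2) @ ssy) / ssy.sum())
    return PlsdaModel(
        n_components=n_components,
        weights=w,
        scores=pd.DataFrame(t, index=matrix.index,
                            columns=[f"comp{i + 1}" for i in range(n_components)]),
        loadings=pls.x_loadings_,
        ssy=ssy,
        vip=pd.Series(vip, index=matrix.columns, name="VIP"),
        classes=classes,
    )


def top_vip_heatmap(
    model: PlsdaModel,
    matrix: pd.DataFrame,
    n_top: int = 50,
    log_base: float = 10.0,
    warn: list[str] | None = None,
) -> pd.DataFrame:
    """0-1 scaled matrix of the top-VIP features, Ward-ordered on both axes.

    Features are log-transformed (half-minimum zero replacement) and scaled
    per feature by division by the feature's maximum, so each selected
    feature attains 1 somewhere; intensities are assumed count-like (>= 1
    where detected) so logged values are non-negative.  Rows and columns
    are reordered by agglomerative clustering with squared-Euclidean Ward
    linkage, and the returned frame's axes carry the leaf orders.
    """
    if n_top > len(model.vip):
        if warn is not None:
            warn.append(
                f"n_top {n_top} exceeds feature count {len(model.vip)}; clipped"
            )
        n_top = len(model.vip)
    top = model.vip.sort_values(ascending=False).index[:n_top]
    sub = matrix[top]
    logged = normalize(sub, log_base=log_base, scaling="none", warn=warn)
    logged = logged.clip(lower=0.0)  # guard sub-unit intensities
    mx = logged.max(axis=0).replace(0, 1.0)
    scaled = logged / mx

    def ward_order(x: np.ndarray) -> np.ndarray:
        if x.shape[0] < 3:
            return np.arange(x.shape[0])
        return leaves_list(linkage(pdist(x, metric="euclidean") ** 2, method="ward"))

    row_order = ward_order(scaled.to_numpy())
    col_order = ward_order(scaled.to_numpy().T)
    return scaled.iloc[row_order, col_order]
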