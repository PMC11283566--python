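"""Temporal baseline-similarity regressions and univariate test utilities.

Community recovery/divergence over a drought gradient is summarized by each
sample's mean Bray-Curtis *similarity* (1 - dissimilarity) to a baseline
set (typically the pre-drought day-0 samples), regressed on sampling day:
the slope is the rate of change, the intercept its magnitude.  The module
also wraps the univariate screens used alongside: Shapiro-Wilk normality
check (W > 0.9 convention), sum-contrast type-III ANOVA, Kruskal-Wallis,
ordinary least-squares fits, and Benjamini-Hochberg FDR.  DNA-yield trend
models are ``linear_fit`` applied to metadata dna_concentration vs day —
no dedicated code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "LinearFit",
    "similarity_to_baseline",
    "linear_fit",
    "kruskal_wallis",
    "anova_type3",
    "shapiro_w",
    "bh_fdr",
]


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    R2: float
    p_slope: float
    n: int


def similarity_to_baseline(
    dm: DistanceMatrix,
    days: pd.Series,
    baseline: pd.Index | list[str],
    agg: str = "mean",
) -> pd.DataFrame:
    """Per-sample similarity to a baseline sample set, paired with its day.

    similarity(s) aggregates ``1 - d(s, b)`` over baseline samples b
    (mean by default; "median" and "max" supported).  Baseline samples are
    excluded from the output.
    """
    baseline = [str(b) for b in baseline]
    ids = list(dm.ids)
    missing = set(baseline) - set(ids)
    if missing:
        raise ValueError(f"baseline samples not in distance matrix: {sorted(missing)}")
    if not baseline:
        raise ValueError("baseline set is empty")
    agg_fn = {"mean": np.mean, "median": np.median, "max": np.max}[agg]
    rows = []
    base_idx = [ids.index(b) for b in baseline]
    for i, sid in enumerate(ids):
        if sid in set(baseline):
            continue
        sims = 1.0 - dm.data[i, base_idx]
        rows.append((sid, float(days.loc[sid]), float(agg_fn(sims))))
    return pd.DataFrame(rows, columns=["sample_id", "day", "similarity"]).set_index("sample_id")


def linear_fit(x, y) -> LinearFit:
    """OLS line fit; slope p-value from the two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is undefined")
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        R2=float(res.rvalue ** 2), p_slope=float(res.pvalue), n=len(x),
    )


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H (tie-corrected) with chi-square p.

    All-tied input returns (H=0, p=1) rather than an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == lv] for lv in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def anova_type3(
    response,
    factors: pd.DataFrame,
    interactions: list[str] | None = None,
) -> pd.DataFrame:
    """Type III ANOVA with sum-to-zero contrasts.

    ``factors`` columns are treated as categorical; ``interactions`` use
    ``"a:b"`` syntax.  Returns a tidy frame (term, df, sum_sq, F, p).
    Rank-deficient designs raise, naming the aliased term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = factors.copy()
    data.columns = [str(c) for c in data.columns]
    data["_y"] = np.asarray(response, dtype=float)
    terms = [f"C({c}, Sum)" for c in factors.columns]
    for inter in interactions or []:
        parts = inter.split(":")
        terms.append(":".join(f"C({p}, Sum)" for p in parts))
    formula = "_y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(
            "design matrix is rank deficient (aliased terms); "
            f"formula was {formula!r}"
        )
    fit = model.fit()
    tab = sm.stats.anova_lm(fit, typ=3)
    tab = tab.drop(index=[i for i in ("Intercept",) if i in tab.index])
    out = tab.rename(columns={"sum_sq": "sum_sq", "F": "F", "PR(>F)": "p_value"})
    out.index = [i.replace("C(", "").replace(", Sum)", "") for i in out.index]
    out.index.name = "term"
    return out[["df", "sum_sq", "F", "p_value"]]


def shapiro_w(values, cutoff: float = 0.9) -> tuple[float, bool]:
    """Shapiro-Wilk W with the W > cutoff normality convention."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if len(values) > 5000:
        raise ValueError("Shapiro-Wilk is unreliable beyond n = 5000")
    w, _ = sps.shapiro(values)
    return float(w), bool(w > cutoff)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
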