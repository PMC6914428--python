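"""Partial-correlation age associations with multiple-comparison control."""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import AssociationResult, ConfigurationError, FormatError

__all__ = [
    "partial_pearson",
    "adjust_pvalues",
    "associate_age",
    "stratify_by_age",
    "DEFAULT_FAMILIES",
    "AGE_STRATA",
]

#: metric family -> correction method, mirroring the reported analyses
DEFAULT_FAMILIES = {
    "segregation": "bonferroni",
    "inter_integration": "bonferroni",
    "intra_integration": "fdr_bh",
}

#: (label, closed lower bound, closed upper bound) as printed; non-integer
#: ages split at the midpoints so every age maps to exactly one stratum.
AGE_STRATA = (("19-40", 19.0, 40.0), ("41-60", 41.0, 60.0), ("61-80", 61.0, 80.0))


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on an intercept plus the covariate
    columns by least squares; the Pearson correlation of the residuals is
    tested two-sided with t = r * sqrt(df / (1 - r^2)), df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise FormatError("x and y lengths differ")
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        c = np.empty((n, 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise FormatError("covariate rows do not match x")
    k = c.shape[1]
    if n <= k + 3:
        raise ConfigurationError(f"need n > k + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ beta
    rx, ry = resid[:, 0], resid[:, 1]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance: partial correlation undefined")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p, n


def adjust_pvalues(
    p: Sequence[float], method: str, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-comparison adjustment; returns (adjusted p, significance).

    ``bonferroni``: min(1, m * p).  ``fdr_bh``: Benjamini-Hochberg step-up
    with monotonicity enforced.  Significance is ``adjusted <= alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise FormatError("p must be a vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bonferroni":
        adj = np.minimum(1.0, m * p)
    elif method == "fdr_bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(1.0, ranked)
    elif method == "none":
        adj = p.copy()
    else:
        raise ConfigurationError(f"unknown correction method {method!r}")
    return adj, adj <= alpha


def associate_age(
    metrics_stack: pd.DataFrame,
    covariates: pd.DataFrame,
    families: dict[str, str] | None = None,
    alpha: float = 0.05,
    covariate_columns: tuple[str, ...] = ("sex", "mean_fd"),
) -> list[AssociationResult]:
    """Partial correlation of each (metric, network, hemisphere) with age.

    ``metrics_stack`` holds one row per subject per (network, hemisphere)
    with a ``subject_id`` column and one column per metric family;
    ``covariates`` holds subject_id, age and the adjustment columns.
    Correction is applied within each metric family, family size = number
    of (network, hemisphere) tests with defined values.
    """
    families = families or DEFAULT_FAMILIES
    cov = covariates.set_index("subject_id")
    for col in ("age",) + covariate_columns:
        if col not in cov.columns:
            raise FormatError(f"covariates missing column {col!r}")
        if cov[col].isna().any():
            raise FormatError(f"missing values in covariate {col!r}")
    results: list[AssociationResult] = []
    for metric, method in families.items():
        if metric not in metrics_stack.columns:
            continue
        tests = []
        for (network, hemi), grp in metrics_stack.groupby(
            ["network", "hemisphere"], sort=True
        ):
            merged = grp.set_index("subject_id")[[metric]].join(cov, how="inner")
            merged = merged.dropna(subset=[metric])
            if len(merged) == 0:
                continue
            const = [
                c for c in covariate_columns if merged[c].nunique() <= 1
            ]
            if const:
                warnings.warn(
                    f"constant covariates {const} dropped for "
                    f"{metric}/{network}/{hemi}"
                )
            cols = [c for c in covariate_columns if c not in const]
            r, p, n = partial_pearson(
                merged["age"].to_numpy(),
                merged[metric].to_numpy(),
                merged[cols].to_numpy() if cols else None,
            )
            tests.append((str(network), str(hemi), n, r, p, tuple(cols)))
        if not tests:
            continue
        adj, sig = adjust_pvalues([t[4] for t in tests], method, alpha)
        for (network, hemi, n, r, p, cols), pa, s in zip(tests, adj, sig):
            results.append(
                AssociationResult(
                    metric=metric,
                    network=network,
                    hemisphere=hemi,
                    n=n,
                    r=r,
                    p=p,
                    p_adjusted=float(pa),
                    correction=method,
                    significant=bool(s),
                    covariates=cols,
                )
            )
    return results


def stratify_by_age(ages: Sequence[float]) -> tuple[np.ndarray, list[str]]:
    """Assign each age to one of the three printed strata.

    Boundaries are inclusive as printed ([19,40], [41,60], [61,80]);
    non-integer ages split at the midpoints 40.5 and 60.5.  Ages outside
    [19, 80] get stratum -1 with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    out = np.full(len(ages), -1, dtype=int)
    edges = (40.5, 60.5)
    lo, hi = AGE_STRATA[0][1], AGE_STRATA[-1][2]
    in_range = (ages >= lo) & (ages <= hi)
    if (~in_range).any():
        warnings.warn(
            f"{int((~in_range).sum())} ages outside [{lo:g}, {hi:g}] excluded"
        )
    out[in_range & (ages < edges[0])] = 0
    out[in_range & (ages >= edges[0]) & (ages < edges[1])] = 1
    out[in_range & (ages >= edges[1])] = 2
    labels = [s[0] for s in AGE_STRATA]
    return out, labels
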