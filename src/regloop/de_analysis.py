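"""Two-condition differential expression with batch covariate and BH-FDR.

Genes are filtered on presence (an intensity floor replacing array
present/absent calls), fitted per gene by ordinary least squares of log2
intensity on condition plus batch indicators, and selected by converting a
Benjamini-Hochberg FDR level into a p-value cutoff — the step that turns an
FDR of 5% into a concrete per-gene p threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_core import ValidationError
from .overlap_stats import gene_overlap_hypergeom

__all__ = [
    "DEResult",
    "presence_filter",
    "fit_de",
    "bh_cutoff",
    "select_de",
    "de_bound_enrichment",
]


@dataclass
class DEResult:
    """Per-gene effects, p-values and the applied FDR selection.

    ``table`` has one row per gene with columns effect (log2 fold change,
    induced minus control), p, degenerate, selected.  ``selected`` holds
    exactly when ``p <= p_cutoff``.
    """

    table: pd.DataFrame
    q: float
    p_cutoff: float
    n_selected: int


def presence_filter(
    expr: pd.DataFrame, min_samples: int, intensity_floor: float | None = None
) -> pd.DataFrame:
    """Keep genes whose intensity reaches the floor in enough samples.

    ``intensity_floor=None`` uses the matrix-wide 25th percentile, the
    package's stand-in for array present/absent calls.
    """
    if min_samples > expr.shape[1]:
        raise ValidationError("min_samples exceeds the number of samples")
    if intensity_floor is None:
        intensity_floor = float(np.quantile(expr.to_numpy(), 0.25))
    present = (expr.to_numpy() >= intensity_floor).sum(axis=1)
    return expr.loc[present >= min_samples]


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Intercept + induced indicator + batch dummies. Returns (X, condition col)."""
    if not {"condition", "batch"} <= set(design.columns):
        raise ValidationError("design requires 'condition' and 'batch' columns")
    cond = (design["condition"] == "induced").to_numpy(dtype=float)
    if cond.sum() < 2 or (1 - cond).sum() < 2:
        raise ValidationError("need >=2 samples per condition")
    batches = pd.get_dummies(design["batch"], drop_first=True).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(design)), cond, batches])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return X, 1


def fit_de(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene OLS of log2 intensity on condition + batch.

    Returns a frame indexed by gene with columns effect, se, t, p,
    degenerate.  The effect is the condition coefficient; p is the two-sided
    t-test on it with the residual degrees of freedom.  Genes with zero
    residual variance and a nonzero effect get the machine-minimum positive
    p and a degenerate flag.
    """
    if list(expr.columns) != list(design.index):
        design = design.loc[expr.columns]
    X, c = _design_matrix(design)
    Y = expr.to_numpy().T  # samples x genes
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValidationError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # k x genes
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    effect = beta[c]
    var_c = XtX_inv[c, c] * sigma2
    # zero residual variance up to accumulated rounding in the projection
    scale = (Y**2).mean(axis=0)
    degenerate = sigma2 <= 1e-18 * (scale + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_c)
        t = effect / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    tiny = np.nextafter(0.0, 1.0)
    eff_zero = np.abs(effect) <= 1e-9 * np.sqrt(scale + 1.0)
    p = np.where(degenerate & ~eff_zero, tiny, p)
    p = np.where(degenerate & eff_zero, 1.0, p)
    p = np.clip(p, tiny, 1.0)
    return pd.DataFrame(
        {"effect": effect, "se": se, "t": t, "p": p, "degenerate": degenerate},
        index=expr.index,
    )


def bh_cutoff(pvals: np.ndarray | list[float], q: float) -> tuple[float, int]:
    """Benjamini-Hochberg step-up: FDR level -> p-value cutoff.

    ``k = max{i : p_(i) <= (i/m) q}`` over the sorted p-values; the cutoff is
    ``p_(k)`` and ``k`` genes are selected.  Returns ``(0.0, 0)`` when no
    index qualifies.
    """
    if not (0.0 < q < 1.0):
        raise ValidationError("q must lie in (0,1)")
    p = np.sort(np.asarray(pvals, dtype=float))
    m = len(p)
    if m == 0:
        return 0.0, 0
    thresh = q * np.arange(1, m + 1) / m
    ok = np.flatnonzero(p <= thresh)
    if len(ok) == 0:
        return 0.0, 0
    k = ok[-1] + 1
    return float(p[k - 1]), int(k)


def select_de(expr: pd.DataFrame, design: pd.DataFrame, q: float = 0.05) -> DEResult:
    """Fit, derive the BH p cutoff at FDR ``q``, and flag selected genes."""
    table = fit_de(expr, design)
    p_cutoff, n_selected = bh_cutoff(table["p"].to_numpy(), q)
    table = table.assign(selected=(table["p"] <= p_cutoff) if n_selected else False)
    return DEResult(table=table, q=q, p_cutoff=p_cutoff, n_selected=n_selected)


def de_bound_enrichment(
    de_genes: set[str], bound_genes: set[str], universe: set[str]
) -> tuple[int, float]:
    """Hypergeometric enrichment of factor-bound genes among DE genes.

    Joins the expression arm to the ChIP arm of the pipeline; delegates to
    :func:`gene_overlap_hypergeom`.
    """
    return gene_overlap_hypergeom(de_genes, bound_genes, universe)
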