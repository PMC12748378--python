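"""Single-cell QC, normalization, quartile stratification, and rank-sum DE.

Cells are carried as an :class:`anndata.AnnData` (cells x genes, raw counts
in ``X``) with the per-cell metadata columns ``sample``, ``cell_type``,
``n_genes_detected`` and ``pct_mito`` (a proportion in [0, 1]).

The stratification convention: within each sample, epithelial cells are
z-scored on the log-normalized anchor-gene expression; cells at or above
the 75th percentile of the scaled value are labeled ``high``, at or below
the 25th percentile ``low``, and everything else (including all
non-epithelial cells) ``excluded``.  Percentiles use linear interpolation
(numpy's default, the "type 7" convention).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateCellError, GroupingError, InputError

logger = logging.getLogger(__name__)

SAMPLE_KEY = "sample"
CELL_TYPE_KEY = "cell_type"
N_GENES_KEY = "n_genes_detected"
PCT_MITO_KEY = "pct_mito"
EPITHELIAL_LABEL = "epithelial"


@dataclass
class GroupAssignment:
    """Per-cell high/low/excluded labels with per-sample quartile cuts."""

    labels: pd.Series                      # index = cell barcodes
    thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def high_cells(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low_cells(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]


def _dense_column(adata: AnnData, gene: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise InputError(f"gene {gene!r} not present in matrix")
    col = adata[:, gene].X
    if sp.issparse(col):
        col = col.toarray()
    return np.asarray(col, dtype=float).ravel()


def qc_filter(
    adata: AnnData,
    min_genes: int = 50,
    max_genes: int = 9000,
    max_pct_mito: float = 0.15,
) -> AnnData:
    """Drop low-quality cells.

    Retains cells with ``min_genes <= n_genes_detected <= max_genes`` and
    mitochondrial fraction at most ``max_pct_mito`` (strictly greater is
    removed).  Removal counts are logged per criterion.  Idempotent.
    """
    for key in (N_GENES_KEY, PCT_MITO_KEY):
        if key not in adata.obs.columns:
            raise InputError(f"obs is missing required QC column {key!r}")
    ngenes = adata.obs[N_GENES_KEY].to_numpy()
    mito = adata.obs[PCT_MITO_KEY].to_numpy(dtype=float)
    low = ngenes < min_genes
    high = ngenes > max_genes
    mt = mito > max_pct_mito
    keep = ~(low | high | mt)
    logger.info(
        "qc_filter: removed %d cells (<%d genes), %d (>%d genes), "
        "%d (mito > %.0f%%); kept %d/%d",
        int(low.sum()), min_genes, int(high.sum()), max_genes,
        int(mt.sum()), 100 * max_pct_mito, int(keep.sum()), adata.n_obs,
    )
    return adata[keep].copy()


def normalize_log(adata: AnnData, scale_factor: float = 1e4) -> AnnData:
    """Library-size normalization followed by log1p.

    Each cell's counts are divided by the cell total, multiplied by
    ``scale_factor``, then transformed with log(1 + x).  A cell with zero
    total counts cannot be normalized and raises
    :class:`DegenerateCellError` naming the cell.
    """
    X = adata.X
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        totals = np.asarray(X).sum(axis=1)
    if adata.n_obs and totals.min() <= 0:
        bad = adata.obs_names[np.flatnonzero(totals <= 0)[0]]
        raise DegenerateCellError(f"cell {bad!r} has zero total counts")
    out = adata.copy()
    if sp.issparse(X):
        X = X.tocsr().astype(float)
        scale = sp.diags(scale_factor / totals)
        X = scale @ X
        X.data = np.log1p(X.data)
        out.X = X
    else:
        out.X = np.log1p(np.asarray(X, dtype=float) / totals[:, None] * scale_factor)
    return out


def quartile_labels(
    scaled: np.ndarray,
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> tuple[np.ndarray, float, float]:
    """Label values as high/low/excluded at closed quartile bounds.

    ``high`` iff value >= the ``q_high`` percentile, ``low`` iff value <=
    the ``q_low`` percentile (linear-interpolation percentiles).  If the two
    percentiles coincide the distribution is degenerate and every value is
    excluded.
    """
    lo = float(np.quantile(scaled, q_low))
    hi = float(np.quantile(scaled, q_high))
    labels = np.full(scaled.shape, "excluded", dtype=object)
    if hi == lo:
        return labels, lo, hi
    labels[scaled >= hi] = "high"
    labels[scaled <= lo] = "low"
    return labels, lo, hi


def assign_groups(
    adata: AnnData,
    anchor_gene: str = "CCNE1",
    epithelial_label: str = EPITHELIAL_LABEL,
    sample_key: str = SAMPLE_KEY,
    cell_type_key: str = CELL_TYPE_KEY,
    q_low: float = 0.25,
    q_high: float = 0.75,
    scale: str = "zscore",
    per_sample: bool = True,
    min_cells: int = 4,
) -> GroupAssignment:
    """Quartile-stratify epithelial cells by scaled anchor-gene expression.

    ``adata.X`` is expected to hold log-normalized values (see
    :func:`normalize_log`).  ``scale="zscore"`` (default) z-scores the
    anchor expression within each sample's epithelial cells before taking
    quartiles; ``scale="none"`` uses the log-normalized value directly.
    Samples with fewer than ``min_cells`` epithelial cells, or a constant
    anchor distribution, are skipped with a warning (all their cells
    excluded).  Non-epithelial cells are always excluded.
    """
    if scale not in ("zscore", "none"):
        raise InputError(f"unknown scale mode {scale!r}")
    expr = _dense_column(adata, anchor_gene)
    labels = pd.Series("excluded", index=adata.obs_names, dtype=object)
    thresholds: dict[str, tuple[float, float]] = {}

    epi = adata.obs[cell_type_key].to_numpy() == epithelial_label
    if per_sample:
        groups = adata.obs.groupby(sample_key, observed=True).indices.items()
    else:
        groups = [("__all__", np.arange(adata.n_obs))]

    for sample, idx in groups:
        idx = np.asarray(idx)
        eidx = idx[epi[idx]]
        if len(eidx) < min_cells:
            logger.warning(
                "sample %r skipped: %d epithelial cells (< %d)",
                sample, len(eidx), min_cells,
            )
            continue
        vals = expr[eidx]
        if scale == "zscore":
            sd = vals.std(ddof=0)
            if sd == 0:
                logger.warning(
                    "sample %r skipped: constant %s expression",
                    sample, anchor_gene,
                )
                continue
            vals = (vals - vals.mean()) / sd
        lab, lo, hi = quartile_labels(vals, q_low=q_low, q_high=q_high)
        if hi == lo:
            logger.warning(
                "sample %r skipped: degenerate quartiles (q%d == q%d)",
                sample, int(100 * q_low), int(100 * q_high),
            )
            continue
        thresholds[str(sample)] = (lo, hi)
        labels.iloc[eidx] = lab
    return GroupAssignment(labels=labels, thresholds=thresholds)


# --- rank-sum machinery -----------------------------------------------------

_EXACT_MAX = 10  # exact enumeration when both group sizes are at or below this


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by enumeration over all group assignments.

    Handles ties through average ranks; the null is the permutation
    distribution of the rank sum of the first sample.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for comb in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def _rank_sum_normal_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: tie-corrected normal approximation with
    continuity correction."""
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = ranks[:nx].sum()
    mean = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = max(0.0, (abs(w - mean) - 0.5) / math.sqrt(var))
    return float(2 * stats.norm.sf(z))


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of the permutation null when both groups have at most
    ten observations; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InputError("rank-sum test requires two nonempty samples")
    if len(x) <= _EXACT_MAX and len(y) <= _EXACT_MAX:
        return _rank_sum_exact_p(x, y)
    return _rank_sum_normal_p(x, y)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    adata: AnnData,
    assignment: GroupAssignment,
    lfc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_cells_detected: int = 3,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Rank-sum differential expression between high and low cells.

    For each gene detected (nonzero) in at least ``min_cells_detected``
    cells across the pooled high+low groups: ``avg_log2FC`` is the log2
    ratio of pseudocounted group means of the *normalized* (linear-scale)
    expression — ``adata.X`` is expected log-normalized, so values are
    passed through expm1 before averaging, the usual marker-test
    convention — the p-value is the two-sided rank-sum test on the
    log-normalized values, and q-values are BH-adjusted across tested
    genes.  ``passes`` is true iff |avg_log2FC| exceeds ``lfc_threshold``
    and q < ``alpha``.
    """
    hi = assignment.high_cells
    lo = assignment.low_cells
    if len(hi) == 0 or len(lo) == 0:
        raise GroupingError(
            f"both groups must be nonempty (high={len(hi)}, low={len(lo)})"
        )
    Xh = adata[hi].X
    Xl = adata[lo].X
    if sp.issparse(Xh):
        Xh = Xh.toarray()
    if sp.issparse(Xl):
        Xl = Xl.toarray()
    Xh = np.asarray(Xh, dtype=float)
    Xl = np.asarray(Xl, dtype=float)

    detected = ((Xh > 0).sum(axis=0) + (Xl > 0).sum(axis=0)) >= min_cells_detected
    n_skipped = int((~detected).sum())
    if n_skipped:
        logger.info(
            "differential_expression: %d genes below detection threshold "
            "(%d cells) not tested", n_skipped, min_cells_detected,
        )

    genes, lfcs, pvals = [], [], []
    for j in np.flatnonzero(detected):
        mh = np.expm1(Xh[:, j]).mean()
        ml = np.expm1(Xl[:, j]).mean()
        lfcs.append(math.log2((mh + pseudocount) / (ml + pseudocount)))
        pvals.append(rank_sum_p(Xh[:, j], Xl[:, j]))
        genes.append(adata.var_names[j])

    qvals = bh_adjust(pvals) if pvals else np.array([])
    out = pd.DataFrame(
        {
            "gene": genes,
            "avg_log2FC": lfcs,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
    out["passes"] = (out["avg_log2FC"].abs() > lfc_threshold) & (
        out["qvalue"] < alpha
    )
    return out.sort_values(["qvalue", "pvalue", "gene"]).reset_index(drop=True)
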