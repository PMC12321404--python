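"""Composite signature scoring and four-way AR/NE single-cell classification.

A cell's composite score for a gene set is the mean log-normalized
expression of the signature genes minus the mean of control genes matched
on average expression: genes are ranked by their dataset-wide mean
expression and cut into bins, and for each signature gene a pool of
control genes is drawn from its bin. Cells with either composite score
above 0.1 are called positive for the corresponding axis, yielding the
same four AR/NE classes used for tissue-level subtyping.

Gene sets for the AR and NE axes are configuration: the defaults shipped
here (`PLACEHOLDER_AR_GENES`, `PLACEHOLDER_NE_GENES`) are small synthetic
placeholder lists intended for tests and examples only; real analyses
must supply established signature gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SCORE_THRESHOLD = 0.1
DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100

# synthetic placeholder gene symbols for tests/examples, not biological sets
PLACEHOLDER_AR_GENES = tuple(f"ARSIG{i}" for i in range(1, 11))
PLACEHOLDER_NE_GENES = tuple(f"NESIG{i}" for i in range(1, 11))

CLASS_LABELS = ("AR+/NE-", "AR-/NE+", "AR+/NE+", "AR-/NE-")


def _as_frame(matrix) -> pd.DataFrame:
    """Accept a cells x genes DataFrame or an AnnData-like object."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    elif hasattr(matrix, "to_df"):
        df = matrix.to_df()
    else:
        raise TypeError("expected a pandas DataFrame or AnnData-like object")
    if df.columns.duplicated().any():
        raise ValueError("duplicate gene identifiers in matrix")
    return df


def qc_filter(
    counts: pd.DataFrame,
    min_genes: int = 200,
    max_mito_fraction: float = 0.80,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """Drop low-quality cells from a raw count matrix (cells x genes).

    Retains cells with at least ``min_genes`` detected genes (count > 0)
    and a mitochondrial UMI fraction at or below ``max_mito_fraction``.
    """
    df = _as_frame(counts)
    if df.shape[1] == 0:
        raise ValueError("count matrix has no gene identifiers")
    values = df.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    detected = (values > 0).sum(axis=1)
    mito_cols = [c for c in df.columns if str(c).startswith(mito_prefix)]
    total = values.sum(axis=1)
    mito = df[mito_cols].to_numpy().sum(axis=1) if mito_cols else np.zeros(len(df))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / total, 0.0)
    keep = (detected >= min_genes) & (mito_frac <= max_mito_fraction)
    return df.loc[keep]


def lognormalize(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Total-count normalization to ``target_sum`` per cell, then log1p."""
    df = _as_frame(counts)
    total = df.to_numpy().sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return pd.DataFrame(
        np.log1p(df.to_numpy() / total * target_sum),
        index=df.index,
        columns=df.columns,
    )


def module_score(
    matrix: pd.DataFrame,
    gene_set,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.Series:
    """Binned-control composite score per cell.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins; for each signature gene, ``n_ctrl``
    control genes are sampled (with replacement if the bin is smaller)
    from the gene's bin. The score is the mean signature expression minus
    the mean control expression, per cell. Deterministic given ``seed``.
    """
    df = _as_frame(matrix)
    genes = [g for g in gene_set if g in df.columns]
    missing = [g for g in gene_set if g not in df.columns]
    if not genes:
        raise ValueError("no signature gene found in the expression matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix and dropped: "
            f"{missing[:5]}", stacklevel=2,
        )

    mean_expr = df.mean(axis=0)
    # equal-frequency bins over average expression; ties broken by rank
    order = mean_expr.rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)
    bin_members = {b: mean_expr.index[bins == b].to_numpy() for b in range(n_bins)}

    rng = np.random.default_rng(seed)
    control_genes: list[str] = []
    for g in genes:
        pool = bin_members[int(bins[g])]
        pool = pool[pool != g]
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        control_genes.extend(rng.choice(pool, size=take, replace=False))
    if not control_genes:
        raise ValueError("no control genes available; matrix too small")

    sig_mean = df[genes].to_numpy().mean(axis=1)
    ctrl_mean = df[control_genes].to_numpy().mean(axis=1)
    return pd.Series(sig_mean - ctrl_mean, index=df.index, name="module_score")


@dataclass(frozen=True)
class CellClassification:
    scores: pd.DataFrame       # columns ar_score, ne_score, label
    fractions: dict[str, float]


def classify_cells(
    ar_score: pd.Series,
    ne_score: pd.Series,
    threshold: float = SCORE_THRESHOLD,
) -> CellClassification:
    """Four-way AR/NE class per cell from composite scores.

    Positive on an axis iff the score strictly exceeds ``threshold``
    (default 0.1); a score exactly at the threshold is negative.
    """
    ar = np.asarray(ar_score, dtype=float)
    ne = np.asarray(ne_score, dtype=float)
    if ar.shape != ne.shape:
        raise ValueError("score vectors differ in length")
    if np.any(~np.isfinite(ar)) or np.any(~np.isfinite(ne)):
        raise ValueError("scores must be finite")
    ar_pos = ar > threshold
    ne_pos = ne > threshold
    labels = np.where(
        ar_pos,
        np.where(ne_pos, "AR+/NE+", "AR+/NE-"),
        np.where(ne_pos, "AR-/NE+", "AR-/NE-"),
    )
    index = ar_score.index if isinstance(ar_score, pd.Series) else pd.RangeIndex(len(ar))
    scores = pd.DataFrame(
        {"ar_score": ar, "ne_score": ne, "label": labels}, index=index
    )
    n = len(labels)
    fractions = {lab: float(np.sum(labels == lab)) / n for lab in CLASS_LABELS}
    return CellClassification(scores=scores, fractions=fractions)


def score_and_classify(
    matrix: pd.DataFrame,
    ar_genes,
    ne_genes,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    threshold: float = SCORE_THRESHOLD,
    seed: int = 0,
) -> CellClassification:
    """Convenience: score both axes and classify every cell."""
    ar = module_score(matrix, ar_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    ne = module_score(matrix, ne_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    return classify_cells(ar, ne, threshold=threshold)
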