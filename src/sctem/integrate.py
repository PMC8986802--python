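"""Linking per-cell methylation to gene and TE expression.

Counts (features x cells) are RPM-normalised and log-transformed,
filtered on minimum expression, and each feature is correlated with the
per-cell methylation estimate by Pearson's r, with two-sided p-values
from the t transform and Benjamini-Hochberg FDR control across all
tested features.  TE features carry ``family:class`` labels in their
ids and can be aggregated to family level (sum of element counts) for
family-scale analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError

#: named feature-filter presets: (min_reads, min_cells)
FILTER_PRESETS = {
    "standard": (2, 10),   # correlation analysis inclusion rule
    "de": (5, 3),          # differential-expression-style filter
    "background": (10, 2), # expressed-gene background list rule
}


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    r: float
    p: float
    fdr: float
    n_cells: int


def normalize_expression(matrix: pd.DataFrame, log_base: float = 2.0,
                         pseudocount: float = 1.0) -> pd.DataFrame:
    """Reads-per-million normalisation followed by log transform.

    value = log_base(pseudocount + count * 1e6 / library_size), with
    library_size the column sum of raw counts.  Cells with zero library
    size are excluded with a warning.
    """
    lib = matrix.sum(axis=0)
    zero = lib[lib <= 0].index
    if len(zero):
        warnings.warn(f"excluding {len(zero)} cell(s) with zero library size")
        matrix = matrix.drop(columns=zero)
        lib = lib.drop(zero)
    rpm = matrix * (1e6 / lib)
    return np.log(pseudocount + rpm) / np.log(log_base)


def filter_features(matrix: pd.DataFrame, min_reads: int = 2,
                    min_cells: int = 10) -> pd.DataFrame:
    """Keep features with >= min_reads counts in >= min_cells cells."""
    if min_reads < 0 or min_cells < 0:
        raise InvalidParameterError("thresholds must be >= 0")
    keep = (matrix >= min_reads).sum(axis=1) >= min_cells
    return matrix.loc[keep]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation via centred sums (the estimator under test)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p from t = r*sqrt((n-2)/(1-r^2)) on n-2 df."""
    if n < 3 or not np.isfinite(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=np.float64)
    out = np.full(p.size, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def correlate_methylation_expression(
    meth: pd.Series,
    expr: pd.DataFrame,
) -> list[CorrelationResult]:
    """Per-feature Pearson correlation of expression with methylation.

    ``meth`` is indexed by cell id (methylation percent, QC-passing
    cells only); ``expr`` is a normalised features x cells frame.  Only
    shared cells are used.  Constant features (or constant methylation)
    are skipped — an undefined correlation is not zero — and reported
    via a warning; BH-FDR is computed over all tested features.
    """
    shared = [c for c in expr.columns if c in meth.index]
    if len(shared) < 3:
        raise InsufficientDataError("need >= 3 shared cells")
    mv = meth.loc[shared].to_numpy(dtype=np.float64)
    if np.allclose(mv, mv[0]):
        raise InsufficientDataError("methylation is constant across cells")
    sub = expr[shared]
    n = len(shared)
    feats, rs, ps = [], [], []
    skipped = []
    for feature, row in sub.iterrows():
        y = row.to_numpy(dtype=np.float64)
        if np.allclose(y, y[0]):
            skipped.append(feature)
            continue
        r = pearson_r(mv, y)
        feats.append(feature)
        rs.append(r)
        ps.append(pearson_pvalue(r, n))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} constant feature(s)")
    fdrs = bh_fdr(ps)
    return [
        CorrelationResult(f, r, p, q, n)
        for f, r, p, q in zip(feats, rs, ps, fdrs)
    ]


def results_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(x.feature, x.r, x.p, x.fdr, x.n_cells) for x in results],
        columns=["feature", "r", "p", "fdr", "n"],
    )


def parse_te_family(feature_id: str) -> str | None:
    """family:class label from a TE feature id, or None for genes."""
    if "|" in feature_id:
        return feature_id.rsplit("|", 1)[1]
    return None


def aggregate_te_families(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum TE element counts to family level; genes pass through.

    TE rows are identified by the ``element|family:class`` id
    convention; TE rows without a parsable family label fall into
    ``unknown`` with a warning.
    """
    families = []
    n_unlabeled = 0
    for f in matrix.index:
        fam = parse_te_family(f)
        if fam is None:
            if f.startswith("te"):
                fam = "unknown"
                n_unlabeled += 1
            else:
                fam = f  # genes keep their own id
        families.append(fam)
    if n_unlabeled:
        warnings.warn(f"{n_unlabeled} TE feature(s) without family label")
    out = matrix.groupby(pd.Index(families, name="feature"), sort=False).sum()
    return out


def export_ranked_genes(
    results: Sequence[CorrelationResult],
    raw_counts: pd.DataFrame,
    fdr_threshold: float = 0.05,
    significant_path: str | None = None,
    background_path: str | None = None,
) -> tuple[list[str], list[str]]:
    """Significant and background gene lists for enrichment tools.

    The significant list contains gene features at fdr < threshold,
    ranked by |r| descending; the background list applies the expressed
    -gene rule (>= 10 reads in >= 2 cells) to the raw counts.  TE
    features (``|family:class`` ids) are excluded from both.
    """
    if not results:
        raise InvalidParameterError("no correlation results to export")
    genes = [x for x in results if parse_te_family(x.feature) is None]
    sig = sorted(
        (x for x in genes if np.isfinite(x.fdr) and x.fdr < fdr_threshold),
        key=lambda x: -abs(x.r),
    )
    sig_ids = [x.feature for x in sig]
    mr, mc = FILTER_PRESETS["background"]
    bg = filter_features(raw_counts, mr, mc)
    bg_ids = [f for f in bg.index if parse_te_family(f) is None]
    if significant_path is not None:
        with open(significant_path, "w") as fh:
            fh.writelines(f"{g}\n" for g in sig_ids)
    if background_path is not None:
        with open(background_path, "w") as fh:
            fh.writelines(f"{g}\n" for g in bg_ids)
    return sig_ids, bg_ids
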