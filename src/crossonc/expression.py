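"""Expression normalization and the copy-number/expression correlation filter.

Counts are depth-normalized with the median-of-ratios size factors familiar
from bulk RNA-seq differential-expression tooling, then log2(x+1)
transformed. Candidate driver genes are kept only when their expression
rank-correlates with their copy number across samples (Spearman rho strictly
above a threshold, 0.2 by default) — amplified passengers whose expression
does not track dosage are filtered out here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossmap import CandidateGene

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.2


@dataclass(frozen=True)
class CorrelationFilterParams:
    """Settings for the correlation filter.

    ``mode="positive"`` requires rho > threshold (amplification candidates
    should gain expression with dosage); ``mode="absolute"`` requires
    |rho| > threshold. Both comparisons are strict.
    """

    rho_threshold: float = DEFAULT_RHO_THRESHOLD
    mode: str = "positive"
    cn_source: str = "calls"  # or "gene_logratio"; informational

    def __post_init__(self) -> None:
        if not 0 <= self.rho_threshold < 1:
            raise ValueError("rho_threshold must be in [0, 1)")
        if self.mode not in ("positive", "absolute"):
            raise ValueError("mode must be 'positive' or 'absolute'")


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the log2-normalized matrix.

    The per-gene reference is the geometric mean across samples, computed
    over genes with no zero count; each sample's size factor is the median of
    its counts divided by the reference; the normalized layer is
    log2(count / size_factor + 1). Returns (size_factors, normalized).
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has all-positive counts; median-of-ratios needs at least one "
            "(filter to expressed genes or add a different normalization)"
        )
    ref = np.exp(np.log(x[all_positive]).mean(axis=1))
    factors = np.median(x[all_positive] / ref[:, None], axis=0)
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    normalized = pd.DataFrame(
        np.log2(x / factors[None, :] + 1.0), index=counts.index, columns=counts.columns
    )
    return size_factors, normalized


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs with a missing value in either vector are dropped first. Returns
    NaN (degenerate) when fewer than 3 complete pairs remain or either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return float("nan")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def filter_by_correlation(
    candidates: list[CandidateGene],
    gene_cn: pd.DataFrame,
    expression: pd.DataFrame,
    params: CorrelationFilterParams = CorrelationFilterParams(),
    expression_species: str = "a",
) -> list[CandidateGene]:
    """Fill in rho and pass/fail status for each candidate, in place.

    Copy number and expression rows are matched on the gene id of the
    species carrying the expression data (``expression_species``: "a" or
    "b"); samples are intersected between the two matrices. A candidate with
    no usable data (gene absent, < 3 shared samples, or degenerate rho) is
    flagged ``correlation_fail`` with rho NaN rather than silently dropped.
    Returns the same list for chaining.
    """
    if expression_species not in ("a", "b"):
        raise ValueError("expression_species must be 'a' or 'b'")
    shared = gene_cn.columns.intersection(expression.columns)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared samples between copy number and expression; need >= 3"
        )
    for cand in candidates:
        gene = cand.gene_a if expression_species == "a" else cand.gene_b
        if gene not in gene_cn.index or gene not in expression.index:
            logger.warning("candidate %s: no copy-number/expression row; flagged fail", gene)
            cand.rho = float("nan")
            cand.status = "correlation_fail"
            continue
        rho = spearman(
            gene_cn.loc[gene, shared].to_numpy(),
            expression.loc[gene, shared].to_numpy(),
        )
        cand.rho = rho
        if np.isnan(rho):
            logger.warning("candidate %s: degenerate correlation; flagged fail", gene)
            cand.status = "correlation_fail"
        else:
            value = rho if params.mode == "positive" else abs(rho)
            cand.status = "correlation_pass" if value > params.rho_threshold else "correlation_fail"
    return candidates
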