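"""Per-sample copy-number statistics.

Everything here operates on per-bin log2 ratios over a shared
:class:`~crossonc.genome.BinGrid`: segmentation into piecewise-constant runs,
mapping segmented bins to gene-level values (with windowed imputation for
genes whose bins are all missing), discretization into the five-level call
vocabulary, and the genomic-instability score (fraction of the binned genome
beyond +/-0.5 in the segmented data).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid

logger = logging.getLogger(__name__)

#: Default call thresholds on segmented log2 ratios, ordered
#: homdel < loss < gain < amp.
DEFAULT_CALL_THRESHOLDS = (-1.0, -0.3, 0.3, 1.0)

DEFAULT_INSTABILITY_THRESHOLD = 0.5
DEFAULT_IMPUTE_WINDOW = 11
DEFAULT_MIN_NON_MISSING = 5


@dataclass
class CopyNumberProfile:
    """One sample's per-bin log2 ratios on a shared grid.

    ``raw`` and ``segmented`` are float vectors of grid length with NaN for
    missing bins; ``segmented`` is piecewise constant within chromosomes.
    ``calls`` holds optional discrete calls in {-2,-1,0,1,2} (NaN missing).
    """

    sample_id: str
    raw: np.ndarray
    segmented: np.ndarray | None = None
    calls: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.segmented is not None:
            self.segmented = np.asarray(self.segmented, dtype=float)
            if self.segmented.shape != self.raw.shape:
                raise ValueError("segmented length differs from raw length")


@dataclass(frozen=True)
class InstabilityScore:
    sample_id: str
    score: float
    threshold: float = DEFAULT_INSTABILITY_THRESHOLD
    n_bins_used: int = 0


def _best_split(values: np.ndarray) -> tuple[int, float]:
    """Best binary split of ``values``: (index, SSE reduction).

    Split at i places values[:i] | values[i:]. Uses the closed form
    reduction = S_l^2/n_l + S_r^2/n_r - S^2/n, which needs only cumsums.
    """
    n = len(values)
    cs = np.cumsum(values)
    total = cs[-1]
    left_n = np.arange(1, n, dtype=float)
    right_n = n - left_n
    left_s = cs[:-1]
    right_s = total - left_s
    reduction = left_s**2 / left_n + right_s**2 / right_n - total**2 / n
    k = int(np.argmax(reduction))
    return k + 1, float(reduction[k])


def _segment_values(values: np.ndarray, threshold: float, out: np.ndarray) -> None:
    """Recursive binary segmentation of ``values``; writes means into ``out``."""
    n = len(values)
    if n <= 1:
        out[:] = values
        return
    split, reduction = _best_split(values)
    if reduction > threshold:
        _segment_values(values[:split], threshold, out[:split])
        _segment_values(values[split:], threshold, out[split:])
    else:
        out[:] = values.mean()


def estimate_noise_variance(raw: np.ndarray) -> float:
    """Noise variance from the median absolute successive difference.

    For i.i.d. Gaussian noise of sd s, successive differences are
    N(0, 2 s^2), so median|diff| = s * sqrt(2) * Phi^-1(0.75) and
    s = median|diff| / 0.9539. Robust to the (sparse) true breakpoints.
    """
    v = raw[~np.isnan(raw)]
    if len(v) < 2:
        return 0.0
    d = np.abs(np.diff(v))
    return float((np.median(d) / 0.9539) ** 2)


def segment_profile(
    raw: np.ndarray,
    grid: BinGrid,
    penalty: float | None = None,
) -> np.ndarray:
    """Segment per-bin log2 ratios into piecewise-constant runs per chromosome.

    Recursive binary splitting minimizing the residual sum of squares; a
    split is accepted only if it reduces the SSE by more than
    ``penalty * log(n)`` where n is the chromosome's non-missing bin count.
    ``penalty`` defaults to twice the estimated noise variance
    (:func:`estimate_noise_variance`). Missing bins are skipped and stay
    missing; segment values are means of member bins.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) != grid.n_bins:
        raise ValueError("profile length does not match grid")
    if penalty is None:
        penalty = 2.0 * estimate_noise_variance(raw)
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    segmented = np.full_like(raw, np.nan)
    for chrom, sl in grid.chrom_slices.items():
        chunk = raw[sl]
        present = ~np.isnan(chunk)
        n = int(present.sum())
        if n == 0:
            warnings.warn(f"chromosome {chrom!r} is all-missing; left missing")
            continue
        values = chunk[present]
        out = np.empty(n)
        _segment_values(values, penalty * math.log(max(n, 2)), out)
        seg_chunk = np.full_like(chunk, np.nan)
        seg_chunk[present] = out
        segmented[sl] = seg_chunk
    return segmented


def call_bins(
    segmented: np.ndarray,
    thresholds: tuple[float, float, float, float] = DEFAULT_CALL_THRESHOLDS,
) -> np.ndarray:
    """Discretize segmented log2 ratios into calls {-2,-1,0,1,2}.

    With thresholds (homdel, loss, gain, amp): <= homdel -> -2,
    <= loss -> -1, >= amp -> +2, >= gain -> +1, else 0. Missing stays NaN.
    """
    homdel, loss, gain, amp = thresholds
    if not (homdel < loss < gain < amp):
        raise ValueError(f"thresholds must be ordered homdel < loss < gain < amp, got {thresholds}")
    x = np.asarray(segmented, dtype=float)
    calls = np.zeros_like(x)
    calls[x <= loss] = -1
    calls[x <= homdel] = -2
    calls[x >= gain] = 1
    calls[x >= amp] = 2
    calls[np.isnan(x)] = np.nan
    return calls


def instability_score(
    profile: CopyNumberProfile,
    threshold: float = DEFAULT_INSTABILITY_THRESHOLD,
) -> InstabilityScore:
    """Fraction of non-missing bins whose segmented value exceeds +/-threshold.

    Comparisons are strict, so a bin exactly at the threshold does not count.
    Raises if the profile has no segmented values at all.
    """
    if profile.segmented is None:
        raise ValueError(f"sample {profile.sample_id}: no segmented values")
    seg = profile.segmented
    present = ~np.isnan(seg)
    n = int(present.sum())
    if n == 0:
        raise ValueError(f"sample {profile.sample_id}: all bins missing, score undefined")
    altered = int(((seg > threshold) | (seg < -threshold)).sum())
    return InstabilityScore(profile.sample_id, altered / n, threshold, n)


def cohort_instability(
    profiles: list[CopyNumberProfile],
    threshold: float = DEFAULT_INSTABILITY_THRESHOLD,
) -> pd.DataFrame:
    rows = [instability_score(p, threshold) for p in profiles]
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in rows], "score": [r.score for r in rows]}
    )


def gene_copy_number(
    profiles: list[CopyNumberProfile],
    grid: BinGrid,
    genes: pd.DataFrame,
    window: int = DEFAULT_IMPUTE_WINDOW,
    min_non_missing: int = DEFAULT_MIN_NON_MISSING,
) -> pd.DataFrame:
    """Gene-level log2 ratios from segmented bins, genes x samples.

    A gene's value is the overlap-length-weighted mean of its non-missing
    segmented bins. If every overlapping bin is missing, the value is imputed
    as the plain mean of non-missing segmented bins in a ``window``-bin window
    centered on the bin holding the gene midpoint (clipped at chromosome
    ends); the gene stays missing if the window holds fewer than
    ``min_non_missing`` values. Genes on chromosomes absent from the grid are
    missing and logged.

    ``genes`` needs columns gene_id, chrom, start, end (0-based half-open).
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd bin count")
    gene_ids = genes["gene_id"].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_id values must be unique")
    half = window // 2
    out = np.full((len(genes), len(profiles)), np.nan)
    seg_matrix = np.vstack([
        p.segmented if p.segmented is not None else np.full(grid.n_bins, np.nan)
        for p in profiles
    ])
    for gi, gene in enumerate(genes.itertuples(index=False)):
        if gene.chrom not in grid.chrom_slices:
            logger.warning("gene %s on unknown chromosome %s; recorded missing", gene.gene_id, gene.chrom)
            continue
        idx = grid.overlapping_bins(gene.chrom, gene.start, gene.end)
        if len(idx) == 0:
            continue
        ov = np.minimum(grid.ends[idx], gene.end) - np.maximum(grid.starts[idx], gene.start)
        ov = ov.astype(float)
        sl = grid.chrom_slices[gene.chrom]
        mid_bin = grid.bin_index(gene.chrom, (gene.start + gene.end) // 2)
        lo = max(sl.start, mid_bin - half)
        hi = min(sl.stop, mid_bin + half + 1)
        for si in range(len(profiles)):
            vals = seg_matrix[si, idx]
            ok = ~np.isnan(vals)
            if ok.any():
                out[gi, si] = np.average(vals[ok], weights=ov[ok])
            else:
                win = seg_matrix[si, lo:hi]
                win = win[~np.isnan(win)]
                if len(win) >= min_non_missing:
                    out[gi, si] = win.mean()
    return pd.DataFrame(out, index=gene_ids, columns=[p.sample_id for p in profiles])
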