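"""Bin grid, segmentation, gene-level copy number, calls, instability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossonc.cn import (
    CopyNumberProfile,
    call_bins,
    gene_copy_number,
    instability_score,
    segment_profile,
)
from crossonc.genome import GenomeSpec, make_bins

from conftest import random_segmented_profile


class TestMakeBins:
    def test_exact_division(self):
        grid = make_bins(GenomeSpec("t", (("chr1", 100_000),), 50_000))
        assert len(grid) == 2
        assert grid.starts.tolist() == [0, 50_000]
        assert grid.ends.tolist() == [50_000, 100_000]

    def test_remainder_bin(self):
        grid = make_bins(GenomeSpec("t", (("chr1", 120_000),), 50_000))
        assert len(grid) == 3
        assert (grid.starts[-1], grid.ends[-1]) == (100_000, 120_000)

    def test_bin_count_matches_ceil_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_chrom = rng.integers(1, 5)
            chroms = tuple(
                (f"chr{i}", int(rng.integers(1, 500_001))) for i in range(n_chrom)
            )
            b = int(rng.integers(1, 100_001))
            grid = make_bins(GenomeSpec("t", chroms, b))
            expected = sum(-(-L // b) for _, L in chroms)
            assert len(grid) == expected
            # terminal bin of each chromosome ends at chromosome length
            for name, L in chroms:
                sl = grid.chrom_slices[name]
                assert grid.ends[sl.stop - 1] == L

    def test_rejects_bad_genome(self):
        with pytest.raises(ValueError):
            GenomeSpec("t", (("chr1", 0),), 50_000)
        with pytest.raises(ValueError):
            GenomeSpec("t", (("chr1", 10), ("chr1", 20)), 5)


class TestSegmentProfile:
    def test_constant_vector_single_segment(self, tiny_grid):
        raw = np.full(tiny_grid.n_bins, 0.7)
        seg = segment_profile(raw, tiny_grid, penalty=0.1)
        assert np.allclose(seg, 0.7)

    def test_noise_free_step_exact_breakpoint(self):
        grid = make_bins(GenomeSpec("t", (("chr1", 1_000_000),), 10_000))
        raw = np.zeros(100)
        raw[50:] = 1.0
        seg = segment_profile(raw, grid, penalty=0.01)
        assert np.allclose(seg[:50], 0.0)
        assert np.allclose(seg[50:], 1.0)

    def test_noisy_step_breakpoint_within_two_bins(self):
        """Step of 1.5 in noise sd 0.2: breakpoint within +/-2 bins >=95/100."""
        grid = make_bins(GenomeSpec("t", (("chr1", 1_000_000),), 10_000))
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            raw = np.zeros(100)
            raw[50:] = 1.5
            raw += rng.normal(0, 0.2, 100)
            seg = segment_profile(raw, grid)
            bps = np.nonzero(np.diff(seg) != 0)[0] + 1
            if len(bps) and min(abs(bps - 50)) <= 2:
                hits += 1
        assert hits >= 95

    def test_sse_never_increases_and_idempotent(self, tiny_grid):
        rng = np.random.default_rng(3)
        raw = random_segmented_profile(rng, tiny_grid, missing_frac=0.0)
        seg = segment_profile(raw, tiny_grid)
        for sl in tiny_grid.chrom_slices.values():
            chunk, s = raw[sl], seg[sl]
            assert np.sum((chunk - s) ** 2) <= np.sum((chunk - chunk.mean()) ** 2) + 1e-12
        # noise-free piecewise-constant input is reproduced exactly
        again = segment_profile(seg, tiny_grid, penalty=0.0)
        assert np.allclose(again, seg)

    def test_all_missing_chromosome_warns(self, tiny_grid):
        raw = np.zeros(tiny_grid.n_bins)
        raw[tiny_grid.chrom_slices["chr2"]] = np.nan
        with pytest.warns(UserWarning, match="chr2"):
            seg = segment_profile(raw, tiny_grid, penalty=0.1)
        assert np.isnan(seg[tiny_grid.chrom_slices["chr2"]]).all()


class TestCallBins:
    def test_threshold_examples(self):
        calls = call_bins(np.array([0.0, 1.2, -0.5, 0.3, -1.0, np.nan]))
        assert calls[0] == 0
        assert calls[1] == 2
        assert calls[2] == -1
        assert calls[3] == 1  # boundary is inclusive for gain
        assert calls[4] == -2
        assert np.isnan(calls[5])

    def test_matches_bruteforce_chain(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 500)
        x[rng.random(500) < 0.1] = np.nan
        calls = call_bins(x)
        for v, c in zip(x, calls):
            if np.isnan(v):
                assert np.isnan(c)
            elif v <= -1.0:
                assert c == -2
            elif v <= -0.3:
                assert c == -1
            elif v >= 1.0:
                assert c == 2
            elif v >= 0.3:
                assert c == 1
            else:
                assert c == 0

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_bins(np.zeros(3), thresholds=(-0.3, -1.0, 0.3, 1.0))


class TestInstabilityScore:
    def _profile(self, seg):
        seg = np.asarray(seg, dtype=float)
        return CopyNumberProfile("s", np.full_like(seg, np.nan), segmented=seg)

    def test_flat_profile_zero(self):
        assert instability_score(self._profile(np.zeros(10))).score == 0.0

    def test_hand_computed_fraction(self):
        assert instability_score(self._profile([0.6, -0.7, 0.0, 0.4])).score == 0.5

    def test_boundary_strict(self):
        assert instability_score(self._profile([0.5])).score == 0.0
        assert instability_score(self._profile([-0.5, 0.5, 0.51])).score == pytest.approx(1 / 3)

    def test_missing_excluded_from_denominator(self):
        r = instability_score(self._profile([0.6, np.nan, np.nan, 0.0]))
        assert r.score == 0.5
        assert r.n_bins_used == 2

    def test_all_missing_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            instability_score(self._profile([np.nan, np.nan]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_invariant_under_permutation_and_sign_flip(self, values, rnd):
        seg = np.array(values)
        base = instability_score(self._profile(seg)).score
        perm = seg.copy()
        rnd.shuffle(perm)
        assert instability_score(self._profile(perm)).score == base
        assert instability_score(self._profile(-seg)).score == base


def _oracle_gene_cn(seg, grid, gene, window, min_nm):
    """Independent per-gene recount: weighted mean, then window imputation."""
    if gene["chrom"] not in grid.chrom_slices:
        return np.nan
    sl = grid.chrom_slices[gene["chrom"]]
    num = den = 0.0
    any_overlap = False
    for i in range(sl.start, sl.stop):
        ov = min(grid.ends[i], gene["end"]) - max(grid.starts[i], gene["start"])
        if ov > 0:
            any_overlap = True
            if not np.isnan(seg[i]):
                num += seg[i] * ov
                den += ov
    if den > 0:
        return num / den
    if not any_overlap:
        return np.nan
    mid = (gene["start"] + gene["end"]) // 2
    mid_bin = None
    for i in range(sl.start, sl.stop):
        if grid.starts[i] <= mid < grid.ends[i]:
            mid_bin = i
    if mid_bin is None:
        mid_bin = sl.stop - 1
    lo, hi = max(sl.start, mid_bin - window // 2), min(sl.stop, mid_bin + window // 2 + 1)
    vals = [seg[i] for i in range(lo, hi) if not np.isnan(seg[i])]
    if len(vals) >= min_nm:
        return float(np.mean(vals))
    return np.nan


class TestGeneCopyNumber:
    def test_gene_inside_one_bin(self, tiny_grid):
        seg = np.full(tiny_grid.n_bins, np.nan)
        seg[2] = 0.8
        p = CopyNumberProfile("s", np.full(tiny_grid.n_bins, np.nan), segmented=seg)
        genes = pd.DataFrame([{"gene_id": "g", "chrom": "chr1", "start": 21_000, "end": 24_000}])
        table = gene_copy_number([p], tiny_grid, genes)
        assert table.loc["g", "s"] == pytest.approx(0.8)

    def test_equal_overlap_weighted_mean(self, tiny_grid):
        seg = np.zeros(tiny_grid.n_bins)
        seg[2], seg[3] = 0.2, 0.4
        p = CopyNumberProfile("s", np.full(tiny_grid.n_bins, np.nan), segmented=seg)
        genes = pd.DataFrame([{"gene_id": "g", "chrom": "chr1", "start": 25_000, "end": 35_000}])
        table = gene_copy_number([p], tiny_grid, genes)
        assert table.loc["g", "s"] == pytest.approx(0.3)

    def test_window_below_minimum_stays_missing(self):
        """All gene bins missing and only 4 non-missing window values -> NaN."""
        grid = make_bins(GenomeSpec("t", (("chr1", 200_000),), 10_000))  # 20 bins
        seg = np.full(20, np.nan)
        seg[[7, 8, 12, 13]] = 0.5  # 4 values inside the 11-bin window around bin 10
        p = CopyNumberProfile("s", np.full(20, np.nan), segmented=seg)
        genes = pd.DataFrame([{"gene_id": "g", "chrom": "chr1", "start": 100_000, "end": 110_000}])
        table = gene_copy_number([p], grid, genes, window=11, min_non_missing=5)
        assert np.isnan(table.loc["g", "s"])
        # a fifth value within the window flips it to imputed
        seg[6] = 0.5
        table = gene_copy_number([p], grid, genes, window=11, min_non_missing=5)
        assert table.loc["g", "s"] == pytest.approx(0.5)

    def test_unknown_chromosome_missing(self, tiny_grid):
        p = CopyNumberProfile("s", np.zeros(tiny_grid.n_bins), segmented=np.zeros(tiny_grid.n_bins))
        genes = pd.DataFrame([{"gene_id": "g", "chrom": "chrX", "start": 0, "end": 10}])
        assert np.isnan(gene_copy_number([p], tiny_grid, genes).loc["g", "s"])

    def test_matches_oracle_on_random_grids(self, tiny_genome):
        rng = np.random.default_rng(11)
        grid = make_bins(tiny_genome)
        for _ in range(25):
            seg = random_segmented_profile(rng, grid, missing_frac=0.4)
            p = CopyNumberProfile("s", np.full(grid.n_bins, np.nan), segmented=seg)
            genes = []
            for k in range(5):
                chrom = "chr1" if rng.random() < 0.5 else "chr2"
                start = int(rng.integers(0, 95_000))
                end = start + int(rng.integers(1_000, 40_000))
                genes.append({"gene_id": f"g{k}", "chrom": chrom, "start": start, "end": min(end, 100_000)})
            genes = pd.DataFrame(genes)
            table = gene_copy_number([p], grid, genes, window=11, min_non_missing=5)
            for _, gene in genes.iterrows():
                expected = _oracle_gene_cn(seg, grid, gene, 11, 5)
                got = table.loc[gene["gene_id"], "s"]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)
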