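import numpy as np
import pandas as pd
import pytest

from crossonc.genome import GenomeSpec, make_bins


@pytest.fixture
def tiny_genome():
    """Two chromosomes, 10 bins of 10 kb each."""
    return GenomeSpec("test", (("chr1", 100_000), ("chr2", 100_000)), bin_size=10_000)


@pytest.fixture
def tiny_grid(tiny_genome):
    return make_bins(tiny_genome)


def random_segmented_profile(rng, grid, missing_frac=0.1, n_segments=3):
    """Piecewise-constant vector with random NaN holes, for oracle tests."""
    seg = np.empty(grid.n_bins)
    for sl in grid.chrom_slices.values():
        L = sl.stop - sl.start
        cuts = np.sort(rng.choice(np.arange(1, L), size=min(n_segments - 1, L - 1), replace=False))
        bounds = [0, *cuts.tolist(), L]
        vals = rng.normal(0, 1, size=len(bounds) - 1)
        for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            seg[sl.start + a:sl.start + b] = vals[k]
    holes = rng.random(grid.n_bins) < missing_frac
    seg[holes] = np.nan
    return seg


@pytest.fixture
def mutland_toy():
    """12-sample, 3-dataset landscape fixture with hand-known composition.

    BRCA1-deficient set (hand enumeration): s01, s02 (homdel), s03 (nonsense),
    s04 (frameshift del), s05 (missense C15), s07 (missense BIC-important).
    Excluded: s06 (missense C0), s08 (missense unannotated), s10 (BRCA1 amp,
    not a deletion), s11 (BRCA1 silent), s09/s12 (no BRCA1 event).
    One duplicated event across datasets: s01 TP53 missense in ds1 and ds2.
    """
    mut_rows = [
        # sample, gene, classification, protein_change, dataset
        ("s03", "BRCA1", "Nonsense_Mutation", "p.Q356*", "ds1"),
        ("s04", "BRCA1", "Frame_Shift_Del", "p.E23fs", "ds1"),
        ("s05", "BRCA1", "Missense_Mutation", "p.C61G", "ds2"),
        ("s06", "BRCA1", "Missense_Mutation", "p.M1652I", "ds2"),
        ("s07", "BRCA1", "Missense_Mutation", "p.R1699W", "ds2"),
        ("s08", "BRCA1", "Missense_Mutation", "p.V1234L", "ds3"),
        ("s11", "BRCA1", "Silent", "p.S694S", "ds3"),
        ("s01", "TP53", "Missense_mutation", "p.R175H", "ds1"),  # lowercase variant
        ("s01", "TP53", "Missense_Mutation", "p.R175H", "ds2"),  # duplicate event
        ("s02", "TP53", "Nonsense_Mutation", "p.R196*", "ds2"),
        ("s03", "TP53", "Frame_Shift_Ins", "p.P27fs", "ds3"),
        ("s09", "TP53", "Missense_Mutation", "p.Y220C", "ds3"),
        ("s02", "MYC", "Intron", None, "ds1"),  # decoy class, never counted
    ]
    tables = []
    for ds in ("ds1", "ds2", "ds3"):
        rows = [r for r in mut_rows if r[4] == ds]
        tables.append(
            pd.DataFrame(
                {
                    "Tumor_Sample_Barcode": [r[0] for r in rows],
                    "Hugo_Symbol": [r[1] for r in rows],
                    "Variant_Classification": [r[2] for r in rows],
                    "HGVSp_Short": [r[3] for r in rows],
                    "source_dataset": ds,
                }
            )
        )
    cna = pd.DataFrame(
        [
            ("s01", "BRCA1", -2, "ds1"),
            ("s02", "BRCA1", -2, "ds1"),
            ("s10", "BRCA1", 2, "ds2"),
            ("s09", "BRCA1", -1, "ds2"),  # shallow loss, filtered out
            ("s01", "MYC", 2, "ds1"),
            ("s03", "MYC", 2, "ds1"),
            ("s04", "MYC", 2, "ds2"),
            ("s05", "MYC", 2, "ds2"),
            ("s01", "MCL1", 2, "ds3"),
            ("s03", "MCL1", 2, "ds3"),
            ("s07", "MCL1", 2, "ds3"),
            ("s12", "MCL1", 1, "ds3"),  # gain, filtered out
        ],
        columns=["sample_id", "gene", "call", "source_dataset"],
    )
    pathogenicity = pd.DataFrame(
        [
            ("BRCA1", "p.C61G", False, "C15"),
            ("BRCA1", "p.M1652I", False, "C0"),
            ("BRCA1", "p.R1699W", True, "unknown"),
        ],
        columns=["gene", "protein_change", "bic_clinically_important", "agvgd_class"],
    )
    receptors = pd.DataFrame(
        {
            "sample_id": [f"s{i:02d}" for i in range(1, 13)],
            "er": ["negative", "negative", "negative", "positive", "negative", "negative",
                   "positive", "negative", "negative", "positive", "negative", "negative"],
            "pr": ["negative", "missing", "negative", "negative", "negative", "positive",
                   "negative", "negative", "negative", "positive", "negative", "negative"],
            "her2": ["negative", "negative", "negative", "negative", "negative", "negative",
                     "positive", "missing", "negative", "negative", "positive", "negative"],
        }
    )
    return tables, cna, receptors, pathogenicity
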