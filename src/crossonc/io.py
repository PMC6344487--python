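"""Readers and writers for the plain-text formats the pipeline exchanges.

Internal coordinates are 0-based half-open everywhere; SEG files use the
conventional 1-based inclusive dialect and are converted on the way in/out.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cn import CopyNumberProfile
from .genome import BinGrid

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_bins", "seg_mean"]


def write_seg(profiles: list[CopyNumberProfile], grid: BinGrid, path: str | Path) -> None:
    """Write segmented profiles as SEG-style TSV (1-based inclusive)."""
    rows = []
    for p in profiles:
        if p.segmented is None:
            raise ValueError(f"sample {p.sample_id}: no segmented values to write")
        for chrom, sl in grid.chrom_slices.items():
            seg = p.segmented[sl]
            # runs of equal (or equally-missing) consecutive values
            i = 0
            L = sl.stop - sl.start
            while i < L:
                j = i + 1
                while j < L and (
                    (np.isnan(seg[j]) and np.isnan(seg[i]))
                    or (not np.isnan(seg[j]) and not np.isnan(seg[i]) and seg[j] == seg[i])
                ):
                    j += 1
                if not np.isnan(seg[i]):
                    rows.append(
                        {
                            "sample": p.sample_id,
                            "chrom": chrom,
                            "start": int(grid.starts[sl.start + i]) + 1,
                            "end": int(grid.ends[sl.start + j - 1]),
                            "n_bins": j - i,
                            "seg_mean": float(seg[i]),
                        }
                    )
                i = j
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path, grid: BinGrid) -> list[CopyNumberProfile]:
    """Read a SEG-style TSV onto a bin grid; bins outside segments are missing.

    Each bin takes the seg_mean of the segment covering its midpoint.
    Profiles read this way carry segmented values only (raw is all-missing).
    """
    table = pd.read_csv(path, sep="\t")
    profiles = []
    mids = (grid.starts + grid.ends) / 2.0
    for sample, group in table.groupby("sample", sort=True):
        seg = np.full(grid.n_bins, np.nan)
        for row in group.itertuples(index=False):
            if row.chrom not in grid.chrom_slices:
                continue
            sl = grid.chrom_slices[row.chrom]
            start0, end0 = int(row.start) - 1, int(row.end)  # to 0-based half-open
            m = mids[sl]
            mask = (m >= start0) & (m < end0)
            seg[sl][mask] = float(row.seg_mean)
        profiles.append(
            CopyNumberProfile(str(sample), np.full(grid.n_bins, np.nan), segmented=seg)
        )
    return profiles


def write_bin_matrix(profiles: list[CopyNumberProfile], grid: BinGrid, path: str | Path, layer: str = "raw") -> None:
    """Binned matrix TSV: chrom/start/end (0-based half-open) + one column per sample."""
    data = {
        "chrom": grid.chroms,
        "start": grid.starts,
        "end": grid.ends,
    }
    for p in profiles:
        vec = p.raw if layer == "raw" else p.segmented
        data[p.sample_id] = vec
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_bin_matrix(path: str | Path, grid: BinGrid, layer: str = "raw") -> list[CopyNumberProfile]:
    table = pd.read_csv(path, sep="\t")
    if len(table) != grid.n_bins:
        raise ValueError(f"matrix has {len(table)} rows, grid has {grid.n_bins} bins")
    sample_cols = [c for c in table.columns if c not in ("chrom", "start", "end")]
    out = []
    for s in sample_cols:
        vec = table[s].to_numpy(dtype=float)
        if layer == "raw":
            out.append(CopyNumberProfile(s, vec))
        else:
            out.append(CopyNumberProfile(s, np.full(grid.n_bins, np.nan), segmented=vec))
    return out


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """BED4/BED6 gene annotation -> DataFrame(gene_id, chrom, start, end, strand)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] < 4:
        raise ValueError("gene BED needs at least 4 columns (chrom, start, end, name)")
    out = pd.DataFrame(
        {
            "gene_id": table[3],
            "chrom": table[0],
            "start": table[1].astype(int),
            "end": table[2].astype(int),
            "strand": table[5] if table.shape[1] >= 6 else "+",
        }
    )
    if out["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in BED")
    return out


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            0: genes["chrom"], 1: genes["start"], 2: genes["end"],
            3: genes["gene_id"], 4: 0, 5: genes.get("strand", "+"),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    needed = {"gene_a", "gene_b", "homology_type"}
    if not needed <= set(table.columns):
        raise ValueError(f"ortholog table needs columns {sorted(needed)}")
    return table


def write_truth_json(truth, path: str | Path) -> None:
    """Structured JSON sidecar with the simulation ground truth."""
    cfg = truth.config
    payload = {
        "config": {
            "species_label": cfg.genome.species_label,
            "chromosomes": list(map(list, cfg.genome.chromosomes)),
            "bin_size": cfg.genome.bin_size,
            "n_samples": cfg.n_samples,
            "passenger_rate": cfg.passenger_rate,
            "bin_noise_sd": cfg.bin_noise_sd,
            "expression_beta": cfg.expression_beta,
            "nb_dispersion": cfg.nb_dispersion,
            "seed": cfg.seed,
            "drivers": [
                {
                    "gene_id": d.gene_id, "chrom": d.chrom, "start": d.start, "end": d.end,
                    "direction": d.direction, "amplitude": d.amplitude, "penetrance": d.penetrance,
                }
                for d in cfg.drivers
            ],
        },
        "sample_ids": truth.sample_ids,
        "carriers": {g: sorted(s) for g, s in truth.carriers.items()},
        "events": truth.events,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
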