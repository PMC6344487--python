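"""Ortholog mapping and cross-species intersection of recurrent genes.

A gene becomes a cross-species candidate when it sits in a recurrent region
in species A, its ortholog sits in a recurrent region in species B, and both
regions have the same direction (amp with amp, del with del).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .recurrence import RecurrentRegion

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")


@dataclass
class CandidateGene:
    """An ortholog pair surviving cross-species intersection.

    ``rho`` and the correlation verdict are filled in later by the
    expression filter; until then status is ``intersected``.
    """

    gene_a: str
    gene_b: str
    region_a: RecurrentRegion
    region_b: RecurrentRegion
    direction: str
    rho: float | None = None
    status: str = "intersected"

    def __post_init__(self) -> None:
        if self.region_a.direction != self.region_b.direction:
            raise ValueError(
                f"candidate ({self.gene_a}, {self.gene_b}): region directions disagree"
            )


def map_orthologs(
    genes_a: list[str],
    table: pd.DataFrame,
    policy: str = "one2one",
) -> dict[str, set[str]]:
    """Map species-A genes to their species-B orthologs.

    ``table`` needs columns gene_a, gene_b, homology_type. The default
    policy keeps one2one pairs only; ``policy="all"`` also retains one2many /
    many2many partners (all of them). Conflicting one2one rows (one gene_a
    claiming two distinct one2one partners) are rejected with row numbers.
    """
    if policy not in ("one2one", "all"):
        raise ValueError("policy must be 'one2one' or 'all'")
    bad = ~table["homology_type"].isin(HOMOLOGY_TYPES)
    if bad.any():
        raise ValueError(
            f"unknown homology_type values at rows {table.index[bad].tolist()}"
        )
    one2one = table[table["homology_type"] == "one2one"]
    conflicts = one2one.groupby("gene_a")["gene_b"].nunique()
    if (conflicts > 1).any():
        rows = one2one[one2one["gene_a"].isin(conflicts[conflicts > 1].index)]
        raise ValueError(
            f"conflicting one2one rows for {sorted(set(rows['gene_a']))} "
            f"at table rows {rows.index.tolist()}"
        )
    keep = table if policy == "all" else one2one
    wanted = set(genes_a)
    mapping: dict[str, set[str]] = {}
    for row in keep.itertuples(index=False):
        if row.gene_a in wanted:
            mapping.setdefault(row.gene_a, set()).add(row.gene_b)
    return mapping


def intersect_candidates(
    regions_a: list[RecurrentRegion],
    regions_b: list[RecurrentRegion],
    mapping: dict[str, set[str]],
) -> list[CandidateGene]:
    """Cross-species candidates: same-direction recurrent in both species.

    Each (gene_a, gene_b) pair is emitted once per matching region pair,
    ordered by species-A region, then gene. Regions must carry their
    ``genes_overlapping`` annotation.
    """
    gene_b_regions: dict[str, list[RecurrentRegion]] = {}
    for rb in regions_b:
        for g in rb.genes_overlapping:
            gene_b_regions.setdefault(g, []).append(rb)

    candidates: list[CandidateGene] = []
    seen: set[tuple[str, str, int, int]] = set()
    for ra in regions_a:
        for ga in ra.genes_overlapping:
            for gb in sorted(mapping.get(ga, ())):
                for rb in gene_b_regions.get(gb, ()):
                    if rb.direction != ra.direction:
                        continue
                    key = (ga, gb, id(ra), id(rb))
                    if key in seen:
                        continue
                    seen.add(key)
                    candidates.append(
                        CandidateGene(
                            gene_a=ga, gene_b=gb,
                            region_a=ra, region_b=rb,
                            direction=ra.direction,
                        )
                    )
    return candidates


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": c.gene_a, "gene_b": c.gene_b, "direction": c.direction,
                "region_a": f"{c.region_a.chrom}:{c.region_a.start}-{c.region_a.end}",
                "region_b": f"{c.region_b.chrom}:{c.region_b.start}-{c.region_b.end}",
                "rho": c.rho, "status": c.status,
            }
            for c in candidates
        ],
        columns=["gene_a", "gene_b", "direction", "region_a", "region_b", "rho", "status"],
    )
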