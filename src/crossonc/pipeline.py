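"""End-to-end orchestration of the cross-species driver discovery workflow.

``run_crossonc`` chains the stages for each species — segmentation (skipped
for externally segmented input), instability scoring, recurrent-region
calling — then intersects recurrent genes through the ortholog map and
applies the expression-correlation filter. ``run_mutland`` chains the
mutation-landscape meta-analysis. Both write their tables plus a manifest
recording the config, seeds, per-stage record counts, timings, and output
checksums, so a rerun with the same config is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cn import (
    CopyNumberProfile,
    cohort_instability,
    gene_copy_number,
    segment_profile,
)
from .crossmap import candidates_to_frame, intersect_candidates, map_orthologs
from .expression import CorrelationFilterParams, filter_by_correlation, median_of_ratios
from .genome import BinGrid, make_bins
from .mutland import (
    alteration_summary,
    annotate_tn,
    dedup_events,
    filter_cna_extreme,
    filter_deleterious,
    harmonize_mutations,
    select_brca1_deficient,
)
from .recurrence import RecurrenceParams, call_recurrent_regions, regions_to_frame

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31.

    Derived by hashing (global_seed, stage name), so any stage can be rerun
    in isolation with the same stream it had inside the full pipeline.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SpeciesInputs:
    """Everything the per-species arm needs, already in memory."""

    label: str
    profiles: list[CopyNumberProfile]
    grid: BinGrid
    genes: pd.DataFrame
    recurrence: RecurrenceParams = field(default_factory=RecurrenceParams)
    segmented_externally: bool = True


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int, seconds: float) -> None:
        self.stages.append(
            {"stage": stage, "records_in": n_in, "records_out": n_out,
             "wall_clock_s": round(seconds, 3)}
        )

    def checksum(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version, "config": self.config,
            "stages": self.stages, "outputs": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2))


def _prepare_species(inputs: SpeciesInputs, seed: int, manifest: RunManifest):
    """Segment if needed, score instability, call recurrent regions (amp+del)."""
    t0 = time.perf_counter()
    if not inputs.segmented_externally:
        for p in inputs.profiles:
            p.segmented = segment_profile(p.raw, inputs.grid)
    manifest.record(f"{inputs.label}:segment", len(inputs.profiles), len(inputs.profiles),
                    time.perf_counter() - t0)

    t0 = time.perf_counter()
    instab = cohort_instability(inputs.profiles)
    manifest.record(f"{inputs.label}:instability", len(inputs.profiles), len(instab),
                    time.perf_counter() - t0)

    regions = []
    for direction in ("amp", "del"):
        t0 = time.perf_counter()
        params = RecurrenceParams(
            focal_threshold=inputs.recurrence.focal_threshold,
            min_probes=inputs.recurrence.min_probes,
            fdr=inputs.recurrence.fdr,
            n_permutations=inputs.recurrence.n_permutations,
            direction=direction,
            seed=stage_seed(seed, f"{inputs.label}:recur:{direction}"),
        )
        called = call_recurrent_regions(inputs.profiles, inputs.grid, params, inputs.genes)
        manifest.record(f"{inputs.label}:recur_{direction}", len(inputs.profiles), len(called),
                        time.perf_counter() - t0)
        regions.extend(called)
    return instab, regions


def run_crossonc(
    species_a: SpeciesInputs,
    species_b: SpeciesInputs,
    orthologs: pd.DataFrame,
    expression_counts: pd.DataFrame,
    correlation: CorrelationFilterParams = CorrelationFilterParams(),
    ortholog_policy: str = "one2one",
    expression_species: str = "a",
    cn_for_correlation: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, RunManifest]:
    """Run the full cross-species candidate-discovery workflow.

    ``expression_counts`` is a genes x samples raw-count matrix for the
    species named by ``expression_species``; ``cn_for_correlation``
    optionally supplies the gene-level copy-number matrix for the same
    species (computed from the profiles via
    :func:`~crossonc.cn.gene_copy_number` when omitted). Returns the final
    candidate table and the manifest; with ``out_dir`` set, all intermediate
    tables are written beneath it.
    """
    manifest = RunManifest(config={
        "seed": seed,
        "species_a": species_a.label,
        "species_b": species_b.label,
        "correlation": {"rho_threshold": correlation.rho_threshold, "mode": correlation.mode},
        "ortholog_policy": ortholog_policy,
    })

    instab_a, regions_a = _prepare_species(species_a, seed, manifest)
    instab_b, regions_b = _prepare_species(species_b, seed, manifest)

    t0 = time.perf_counter()
    genes_a = sorted({g for r in regions_a for g in r.genes_overlapping})
    mapping = map_orthologs(genes_a, orthologs, policy=ortholog_policy)
    candidates = intersect_candidates(regions_a, regions_b, mapping)
    manifest.record("crossmap", len(genes_a), len(candidates), time.perf_counter() - t0)

    t0 = time.perf_counter()
    _, normalized = median_of_ratios(expression_counts)
    expr_inputs = species_a if expression_species == "a" else species_b
    if cn_for_correlation is None:
        cn_for_correlation = gene_copy_number(expr_inputs.profiles, expr_inputs.grid, expr_inputs.genes)
    filter_by_correlation(candidates, cn_for_correlation, normalized, correlation,
                          expression_species=expression_species)
    manifest.record("correlation_filter", len(candidates),
                    sum(c.status == "correlation_pass" for c in candidates),
                    time.perf_counter() - t0)

    table = candidates_to_frame(candidates)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            f"instability_{species_a.label}.tsv": instab_a,
            f"instability_{species_b.label}.tsv": instab_b,
            f"regions_{species_a.label}.tsv": regions_to_frame(regions_a),
            f"regions_{species_b.label}.tsv": regions_to_frame(regions_b),
            "candidates.tsv": table,
        }
        for name, frame in files.items():
            path = out / name
            frame.to_csv(path, sep="\t", index=False)
            manifest.checksum(path)
        manifest.write(out / "manifest.json")
    return table, manifest


def run_mutland(
    mutation_tables: list[pd.DataFrame],
    cna: pd.DataFrame,
    receptors: pd.DataFrame,
    panel: list[str],
    pathogenicity: pd.DataFrame | None = None,
    source_priority: list[str] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, pd.DataFrame], RunManifest]:
    """Run the mutation-landscape meta-analysis on harmonized inputs.

    Stages: harmonize + dedup -> deleterious / extreme-CNA filters -> BRCA1
    deficiency selection -> TN annotation -> per-gene frequency and
    co-occurrence summaries over the BRCA1-deficient set. With an empty
    BRCA1-deficient set, zero-row summaries are emitted with a warning.
    """
    manifest = RunManifest(config={"panel": panel, "source_priority": source_priority})

    t0 = time.perf_counter()
    merged = dedup_events(harmonize_mutations(mutation_tables), source_priority)
    cna = dedup_events(cna, source_priority)
    manifest.record("harmonize", sum(map(len, mutation_tables)), len(merged),
                    time.perf_counter() - t0)

    t0 = time.perf_counter()
    deleterious = filter_deleterious(merged)
    extreme = filter_cna_extreme(cna)
    manifest.record("filter_deleterious", len(merged), len(deleterious), time.perf_counter() - t0)
    manifest.record("filter_cna_extreme", len(cna), len(extreme), 0.0)

    t0 = time.perf_counter()
    brca1 = select_brca1_deficient(deleterious, extreme, pathogenicity)
    manifest.record("select_brca1", len(deleterious) + len(extreme), len(brca1),
                    time.perf_counter() - t0)

    tn = annotate_tn(receptors)
    manifest.record("annotate_tn", len(receptors), len(tn), 0.0)

    if brca1:
        freq, cooc, oncoprint = alteration_summary(deleterious, extreme, brca1, panel)
    else:
        logger.warning("BRCA1-deficient sample set is empty; emitting zero-row summaries")
        freq = pd.DataFrame(columns=["n_mut", "n_cna", "n_altered",
                                     "freq_mut", "freq_cna", "freq_altered"])
        cooc = pd.DataFrame(columns=["gene_1", "gene_2", "n_both", "n_gene_1", "n_gene_2",
                                     "frac_1_given_2", "frac_2_given_1"])
        oncoprint = pd.DataFrame()
    manifest.record("summaries", len(brca1), len(freq), 0.0)

    tables = {
        "mutations_deleterious": deleterious,
        "cna_extreme": extreme,
        "brca1_deficient": pd.DataFrame({"sample_id": sorted(brca1)}),
        "tn_status": tn.reset_index(),
        "frequencies": freq.reset_index(),
        "cooccurrence": cooc,
        "oncoprint": oncoprint.reset_index(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            manifest.checksum(path)
        manifest.write(out / "manifest.json")
    return tables, manifest
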