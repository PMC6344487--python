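"""Multi-dataset mutation-landscape meta-analysis.

Harmonizes MAF-like mutation tables and cBioPortal-style discrete CNA calls
from several source datasets, applies the deleterious-class and extreme-CNA
filters, selects BRCA1-deficient samples (homozygous deletion, truncating
mutation, or pathogenic missense per BIC / Align-GVGD), annotates
triple-negative receptor status, and computes per-gene alteration frequencies
and pairwise co-occurrence over a gene panel.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Variant classes counted as deleterious in the landscape (canonical form).
DELETERIOUS_CLASSES = frozenset(
    {"missense_mutation", "nonsense_mutation", "frame_shift_del", "frame_shift_ins"}
)

#: Classes counted as truncating for BRCA1-deficiency selection.
TRUNCATING_CLASSES = frozenset({"nonsense_mutation", "frame_shift_del", "frame_shift_ins"})

#: Align-GVGD missense classes treated as pathogenic.
PATHOGENIC_AGVGD = frozenset({"C15", "C25", "C65"})

MUTATION_COLUMNS = ["sample_id", "gene", "variant_classification", "protein_change", "source_dataset"]
CNA_COLUMNS = ["sample_id", "gene", "call", "source_dataset"]


def normalize_classification(value: str) -> str:
    """Canonical lower_snake form of a variant classification string.

    Source datasets disagree on case and punctuation ("Nonsense_mutation",
    "Nonsense_Mutation", "nonsense mutation"); all collapse to one token.
    """
    return re.sub(r"[\s\-]+", "_", str(value).strip()).lower()


def harmonize_mutations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate MAF-like tables into the internal mutation schema.

    Accepts either MAF column names (Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification, HGVSp_Short) or the internal ones. Unknown
    classification strings are kept and logged, not dropped.
    """
    renames = {
        "Tumor_Sample_Barcode": "sample_id",
        "Hugo_Symbol": "gene",
        "Variant_Classification": "variant_classification",
        "HGVSp_Short": "protein_change",
    }
    frames = []
    for t in tables:
        t = t.rename(columns=renames).copy()
        for col in MUTATION_COLUMNS:
            if col not in t.columns:
                t[col] = pd.NA if col != "source_dataset" else "unknown"
        t["variant_classification"] = t["variant_classification"].map(normalize_classification)
        frames.append(t[MUTATION_COLUMNS])
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=MUTATION_COLUMNS)
    unknown = set(merged["variant_classification"]) - DELETERIOUS_CLASSES - {
        "silent", "intron", "splice_site", "in_frame_del", "in_frame_ins", "3'utr", "5'utr",
    }
    if unknown:
        logger.info("unrecognized variant classes kept as-is: %s", sorted(unknown))
    return merged


def dedup_events(table: pd.DataFrame, source_priority: list[str] | None = None) -> pd.DataFrame:
    """Drop duplicate (sample, gene, event) rows across source datasets.

    When the same event is reported by several datasets, the row from the
    highest-priority source wins (priority list order; unlisted sources rank
    last in input order).
    """
    event_cols = [c for c in ("variant_classification", "call") if c in table.columns]
    key = ["sample_id", "gene"] + event_cols
    if source_priority:
        rank = {s: i for i, s in enumerate(source_priority)}
        order = table["source_dataset"].map(lambda s: rank.get(s, len(rank)))
        table = table.iloc[np.argsort(order.to_numpy(), kind="stable")]
    return table.drop_duplicates(subset=key, keep="first").reset_index(drop=True)


def filter_deleterious(mutations: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the four deleterious classes (missense, nonsense,
    frameshift del/ins), case- and punctuation-normalized."""
    cls = mutations["variant_classification"].map(normalize_classification)
    return mutations[cls.isin(DELETERIOUS_CLASSES)].reset_index(drop=True)


def filter_cna_extreme(cna: pd.DataFrame) -> pd.DataFrame:
    """Keep high-level amplifications (+2) and homozygous deletions (-2) only."""
    if not cna["call"].isin([-2, -1, 0, 1, 2]).all():
        raise ValueError("CNA calls must be in {-2,-1,0,1,2}")
    return cna[cna["call"].isin([-2, 2])].reset_index(drop=True)


def select_brca1_deficient(
    mutations: pd.DataFrame,
    cna: pd.DataFrame,
    pathogenicity: pd.DataFrame | None = None,
    gene: str = "BRCA1",
) -> set[str]:
    """Samples with a BRCA1 homozygous deletion or an inactivating mutation.

    A sample qualifies if (a) its BRCA1 CNA call is -2, (b) it carries a
    truncating BRCA1 mutation (nonsense or frameshift), or (c) it carries a
    BRCA1 missense mutation annotated pathogenic — clinically important in
    BIC, or Align-GVGD class C15/C25/C65. Missense variants without any
    pathogenicity annotation are excluded and logged, never guessed.

    ``pathogenicity`` columns: gene, protein_change, bic_clinically_important
    (bool), agvgd_class (C0..C65 or "unknown").
    """
    selected: set[str] = set(cna.loc[(cna["gene"] == gene) & (cna["call"] == -2), "sample_id"])

    muts = mutations[mutations["gene"] == gene].copy()
    muts["cls"] = muts["variant_classification"].map(normalize_classification)
    selected |= set(muts.loc[muts["cls"].isin(TRUNCATING_CLASSES), "sample_id"])

    missense = muts[muts["cls"] == "missense_mutation"]
    if len(missense):
        if pathogenicity is None:
            logger.warning(
                "%d %s missense mutations but no pathogenicity table; all excluded",
                len(missense), gene,
            )
        else:
            path = pathogenicity[pathogenicity["gene"] == gene].set_index("protein_change")
            for row in missense.itertuples(index=False):
                pc = row.protein_change
                if pc not in path.index:
                    logger.info(
                        "sample %s: %s missense %s lacks pathogenicity annotation; excluded",
                        row.sample_id, gene, pc,
                    )
                    continue
                ann = path.loc[pc]
                if bool(ann["bic_clinically_important"]) or str(ann["agvgd_class"]) in PATHOGENIC_AGVGD:
                    selected.add(row.sample_id)
    return selected


def annotate_tn(receptors: pd.DataFrame) -> pd.Series:
    """Triple-negative status per sample: TN, non-TN, or undetermined.

    TN requires ER, PR and HER2 all negative; any missing receptor makes the
    sample undetermined (IHC inconclusive), anything else is non-TN.
    ``receptors`` columns: sample_id, er, pr, her2 with values in
    {positive, negative, missing}.
    """
    def status(row: pd.Series) -> str:
        vals = [row["er"], row["pr"], row["her2"]]
        if all(v == "negative" for v in vals):
            return "TN"
        if any(v == "missing" or pd.isna(v) for v in vals):
            return "undetermined"
        return "non-TN"

    out = receptors.apply(status, axis=1)
    out.index = receptors["sample_id"]
    out.name = "tn_status"
    return out


def alteration_summary(
    mutations: pd.DataFrame,
    cna: pd.DataFrame,
    samples: set[str] | list[str],
    panel: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene alteration frequencies and pairwise co-occurrence.

    Over the given sample set and gene panel, returns:

    * ``freq`` — per gene, the fraction of samples with >= 1 qualifying
      mutation, >= 1 qualifying CNA, and either (combined), plus raw counts;
    * ``cooc`` — long table of gene pairs with overlap counts and the two
      conditional fractions P(g1 altered | g2 altered) and vice versa;
    * ``oncoprint`` — genes x samples matrix with values in
      {"", "mut", "cna", "mut;cna"}.

    Genes absent from both tables get frequency 0 and are logged.
    """
    samples = sorted(set(samples))
    if not samples:
        raise ValueError("sample set is empty")
    n = len(samples)
    mut_sets = {
        g: set(mutations.loc[(mutations["gene"] == g) & mutations["sample_id"].isin(samples), "sample_id"])
        for g in panel
    }
    cna_sets = {
        g: set(cna.loc[(cna["gene"] == g) & cna["sample_id"].isin(samples), "sample_id"])
        for g in panel
    }
    altered = {g: mut_sets[g] | cna_sets[g] for g in panel}
    for g in panel:
        if not altered[g]:
            logger.info("gene %s: no alterations in any table", g)

    freq = pd.DataFrame(
        {
            "gene": panel,
            "n_mut": [len(mut_sets[g]) for g in panel],
            "n_cna": [len(cna_sets[g]) for g in panel],
            "n_altered": [len(altered[g]) for g in panel],
            "freq_mut": [len(mut_sets[g]) / n for g in panel],
            "freq_cna": [len(cna_sets[g]) / n for g in panel],
            "freq_altered": [len(altered[g]) / n for g in panel],
        }
    ).set_index("gene")

    rows = []
    for i, g1 in enumerate(panel):
        for g2 in panel[i + 1:]:
            both = altered[g1] & altered[g2]
            rows.append(
                {
                    "gene_1": g1, "gene_2": g2, "n_both": len(both),
                    "n_gene_1": len(altered[g1]), "n_gene_2": len(altered[g2]),
                    "frac_1_given_2": len(both) / len(altered[g2]) if altered[g2] else float("nan"),
                    "frac_2_given_1": len(both) / len(altered[g1]) if altered[g1] else float("nan"),
                }
            )
    cooc = pd.DataFrame(
        rows,
        columns=["gene_1", "gene_2", "n_both", "n_gene_1", "n_gene_2",
                 "frac_1_given_2", "frac_2_given_1"],
    )

    cells = []
    for g in panel:
        row = []
        for s in samples:
            tags = []
            if s in mut_sets[g]:
                tags.append("mut")
            if s in cna_sets[g]:
                tags.append("cna")
            row.append(";".join(tags))
        cells.append(row)
    oncoprint = pd.DataFrame(cells, index=panel, columns=samples)
    return freq, cooc, oncoprint
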