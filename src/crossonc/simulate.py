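"""Seeded synthetic tumor cohorts.

The generator emulates shallow CNV-seq cohorts: each sample's true profile is
a baseline of 0 with random passenger segments (Poisson count, log-normal
length, signed amplitude) and planted recurrent driver events shared by a
fixed fraction of the cohort; observed bins add i.i.d. Gaussian noise on the
log2-ratio scale. Companion generators produce expression count matrices
whose means track planted copy number, and cBioPortal-style mutation / CNA /
receptor-status tables. Every draw flows from a single integer seed, and a
:class:`SimulationTruth` records exactly what was planted so recovery tests
can be exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cn import CopyNumberProfile
from .genome import BinGrid, GenomeSpec, make_bins

#: The four MAF variant classes treated as deleterious downstream, plus decoys.
DEFAULT_VARIANT_VOCABULARY = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Silent",
    "Intron",
)


def default_genome(species_label: str = "mouse") -> GenomeSpec:
    """Desk-scale default: 3 chromosomes x 50 Mb at 50 kb bins (1000 bins each)."""
    return GenomeSpec(
        species_label=species_label,
        chromosomes=(("chr1", 50_000_000), ("chr2", 50_000_000), ("chr3", 50_000_000)),
        bin_size=50_000,
    )


@dataclass(frozen=True)
class PlantedDriver:
    """A recurrent focal event planted at a fixed locus.

    ``penetrance`` is the fraction of samples carrying the event; carriers
    are assigned deterministically (round(penetrance * n) of them, chosen by
    seeded shuffle). ``amplitude`` is the log2-ratio step, positive for
    amplifications and negative for deletions.
    """

    chrom: str
    start: int
    end: int
    direction: str  # "amp" | "del"
    amplitude: float
    penetrance: float
    gene_id: str

    def __post_init__(self) -> None:
        if self.direction not in ("amp", "del"):
            raise ValueError(f"direction must be 'amp' or 'del', got {self.direction!r}")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must be in (0, 1]")
        if self.direction == "amp" and self.amplitude <= 0:
            raise ValueError("amp driver needs amplitude > 0")
        if self.direction == "del" and self.amplitude >= 0:
            raise ValueError("del driver needs amplitude < 0")
        if self.end <= self.start:
            raise ValueError("driver interval must be non-empty")


@dataclass
class SimulationConfig:
    """Everything the cohort generator needs, including the seed.

    Passenger segments: count ~ Poisson(passenger_rate) per sample, length
    ~ LogNormal(passenger_length_mu, passenger_length_sigma) in bp, absolute
    amplitude ~ Normal(passenger_amplitude_mean, passenger_amplitude_sd)
    truncated at 0, sign +/- with equal probability. Passengers may overlap
    drivers; values add.
    """

    genome: GenomeSpec = field(default_factory=default_genome)
    n_samples: int = 20
    drivers: tuple[PlantedDriver, ...] = ()
    passenger_rate: float = 5.0
    passenger_length_mu: float = 14.5  # log bp; median ~2 Mb
    passenger_length_sigma: float = 1.0
    passenger_amplitude_mean: float = 0.6
    passenger_amplitude_sd: float = 0.2
    bin_noise_sd: float = 0.2
    expression_beta: float = 1.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in (
            "passenger_rate",
            "passenger_length_sigma",
            "passenger_amplitude_sd",
            "bin_noise_sd",
            "nb_dispersion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort: the acceptance oracle.

    ``true_bins`` is the noise-free per-bin matrix (samples x bins);
    ``carriers`` maps each driver gene to the set of carrier sample ids;
    ``gene_cn`` is the true per-driver-gene copy-number matrix
    (genes x samples, length-weighted over the driver locus).
    """

    config: SimulationConfig
    sample_ids: list[str]
    true_bins: np.ndarray
    carriers: dict[str, set[str]]
    events: list[dict]
    gene_cn: pd.DataFrame

    def gene_table(self) -> pd.DataFrame:
        """Driver loci as a gene annotation table (gene_id, chrom, start, end)."""
        rows = [
            {"gene_id": d.gene_id, "chrom": d.chrom, "start": d.start, "end": d.end, "strand": "+"}
            for d in self.config.drivers
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _check_on_grid(driver: PlantedDriver, genome: GenomeSpec) -> None:
    lengths = genome.chrom_lengths
    if driver.chrom not in lengths:
        raise ValueError(f"driver {driver.gene_id}: unknown chromosome {driver.chrom!r}")
    L = lengths[driver.chrom]
    if driver.start < 0 or driver.end > L:
        raise ValueError(f"driver {driver.gene_id}: interval outside chromosome bounds")
    b = genome.bin_size
    if driver.start % b != 0 or (driver.end % b != 0 and driver.end != L):
        raise ValueError(
            f"driver {driver.gene_id}: interval [{driver.start}, {driver.end}) is off the "
            f"{b}-bp bin grid; align start/end to bin boundaries"
        )


def simulate_cohort(config: SimulationConfig) -> tuple[list[CopyNumberProfile], SimulationTruth]:
    """Generate a seeded cohort of copy-number profiles plus its ground truth.

    Observed raw bins = true segment value + N(0, bin_noise_sd); identical
    (config, seed) gives byte-identical output. Driver carrier counts are
    exact: round(penetrance * n_samples) samples per driver.
    """
    for d in config.drivers:
        _check_on_grid(d, config.genome)
    grid = make_bins(config.genome)
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"{config.genome.species_label}_s{i:03d}" for i in range(n)]
    true_bins = np.zeros((n, grid.n_bins))
    events: list[dict] = []
    lengths = config.genome.chrom_lengths
    chrom_names = [c for c, _ in config.genome.chromosomes]

    # Passengers first so the carrier shuffle is independent of driver list order.
    for si in range(n):
        k = rng.poisson(config.passenger_rate)
        for _ in range(k):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            L = lengths[chrom]
            seg_len = int(rng.lognormal(config.passenger_length_mu, config.passenger_length_sigma))
            seg_len = max(config.genome.bin_size, min(seg_len, L))
            start = int(rng.integers(0, max(L - seg_len, 0) + 1))
            amp = abs(rng.normal(config.passenger_amplitude_mean, config.passenger_amplitude_sd))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            idx = grid.overlapping_bins(chrom, start, start + seg_len)
            true_bins[si, idx] += sign * amp
            events.append(
                {"sample_id": sample_ids[si], "kind": "passenger", "chrom": chrom,
                 "start": start, "end": start + seg_len, "value": sign * amp}
            )

    carriers: dict[str, set[str]] = {}
    for d in config.drivers:
        n_carriers = int(round(d.penetrance * n))
        order = rng.permutation(n)
        chosen = order[:n_carriers]
        carriers[d.gene_id] = {sample_ids[i] for i in chosen}
        idx = grid.overlapping_bins(d.chrom, d.start, d.end)
        for si in chosen:
            true_bins[si, idx] += d.amplitude
            events.append(
                {"sample_id": sample_ids[si], "kind": "driver", "chrom": d.chrom,
                 "start": d.start, "end": d.end, "value": d.amplitude, "gene_id": d.gene_id}
            )

    noise = rng.normal(0.0, config.bin_noise_sd, size=true_bins.shape) if config.bin_noise_sd > 0 else 0.0
    raw = true_bins + noise

    profiles = [
        CopyNumberProfile(sample_ids[si], raw[si].copy(), segmented=true_bins[si].copy())
        for si in range(n)
    ]

    # True gene-level CN: length-weighted mean of true bin values over the locus.
    gene_rows = {}
    for d in config.drivers:
        idx = grid.overlapping_bins(d.chrom, d.start, d.end)
        w = (np.minimum(grid.ends[idx], d.end) - np.maximum(grid.starts[idx], d.start)).astype(float)
        gene_rows[d.gene_id] = true_bins[:, idx] @ (w / w.sum())
    gene_cn = pd.DataFrame(gene_rows, index=sample_ids).T

    truth = SimulationTruth(
        config=config,
        sample_ids=sample_ids,
        true_bins=true_bins,
        carriers=carriers,
        events=events,
        gene_cn=gene_cn,
    )
    return profiles, truth


def simulate_expression(
    truth: SimulationTruth,
    base_means: pd.Series,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    beta: float | pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial expression counts tracking true gene copy number.

    Counts for gene i in sample j are NB with mean
    ``base_means[i] * 2 ** (beta_i * cn_ij)`` and dispersion
    ``nb_dispersion`` (variance = m + dispersion * m^2); dispersion 0 falls
    back to Poisson. ``beta`` defaults to the config's ``expression_beta``
    for every gene; a per-gene Series plants dose-insensitive decoys.
    Returns a genes x samples integer DataFrame.
    """
    config = config or truth.config
    if not base_means.index.equals(truth.gene_cn.index):
        if set(base_means.index) != set(truth.gene_cn.index):
            raise ValueError("base_means gene set must match the truth gene set")
        base_means = base_means.reindex(truth.gene_cn.index)
    if (base_means <= 0).any():
        raise ValueError("base means must be positive")
    if beta is None:
        beta_vec = np.full(len(base_means), config.expression_beta)
    elif isinstance(beta, pd.Series):
        beta_vec = beta.reindex(truth.gene_cn.index).fillna(config.expression_beta).to_numpy()
    else:
        beta_vec = np.full(len(base_means), float(beta))
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    cn = truth.gene_cn.to_numpy()
    mean = base_means.to_numpy()[:, None] * 2.0 ** (beta_vec[:, None] * cn)
    alpha = config.nb_dispersion
    if alpha <= 0:
        counts = rng.poisson(mean)
    else:
        size = 1.0 / alpha
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p)
    return pd.DataFrame(counts, index=truth.gene_cn.index, columns=truth.sample_ids)


@dataclass(frozen=True)
class AlterationSpec:
    """Per-gene event probabilities for the mutation-table generator."""

    gene: str
    mutation_prob: float = 0.0
    variant_classification: str = "Missense_Mutation"
    cna_prob: float = 0.0
    cna_call: int = 2

    def __post_init__(self) -> None:
        for p in (self.mutation_prob, self.cna_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.cna_call not in (-2, -1, 0, 1, 2):
            raise ValueError("cna_call must be in {-2,-1,0,1,2}")


def simulate_mutation_tables(
    n_samples: int,
    panel: list[AlterationSpec],
    seed: int = 0,
    receptor_neg_prob: float = 0.6,
    receptor_missing_prob: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """cBioPortal-style mutation, CNA-call and receptor-status tables.

    Per sample and panel gene, an independent Bernoulli draw per event type.
    Receptor statuses (ER/PR/HER2) are drawn i.i.d. from
    {negative, positive, missing} with the given probabilities.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    mut_rows, cna_rows = [], []
    for spec in panel:
        mut_draw = rng.random(n_samples) < spec.mutation_prob
        cna_draw = rng.random(n_samples) < spec.cna_prob
        for si in range(n_samples):
            if mut_draw[si]:
                mut_rows.append(
                    {"Tumor_Sample_Barcode": sample_ids[si], "Hugo_Symbol": spec.gene,
                     "Variant_Classification": spec.variant_classification,
                     "source_dataset": "synthetic"}
                )
            if cna_draw[si]:
                cna_rows.append(
                    {"sample_id": sample_ids[si], "gene": spec.gene,
                     "call": spec.cna_call, "source_dataset": "synthetic"}
                )
    mutations = pd.DataFrame(
        mut_rows,
        columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification", "source_dataset"],
    )
    cna = pd.DataFrame(cna_rows, columns=["sample_id", "gene", "call", "source_dataset"])
    statuses = np.array(["negative", "positive", "missing"], dtype=object)
    probs = [receptor_neg_prob, 1 - receptor_neg_prob - receptor_missing_prob, receptor_missing_prob]
    rec = {
        col: statuses[rng.choice(3, size=n_samples, p=probs)]
        for col in ("er", "pr", "her2")
    }
    receptors = pd.DataFrame({"sample_id": sample_ids, **rec})
    return mutations, cna, receptors


def two_species_configs(
    seed: int = 0,
    n_samples: int = 30,
    shared_gene: tuple[str, str] = ("Mcl1", "MCL1"),
    decoy_gene: tuple[str, str] = ("Dcy1", "DCY1"),
) -> tuple[SimulationConfig, SimulationConfig, pd.DataFrame]:
    """Paired mouse/human-like configs with one shared driver, one shared
    uncorrelated decoy, and one private driver per species, plus the
    one2one ortholog table linking them.

    The shared driver and the decoy sit at the same loci in both genomes;
    private drivers are species-specific. Used by the end-to-end recovery
    tests and the demo pipeline.
    """
    def drv(chrom: str, start_bin: int, n_bins: int, gene: str, amplitude: float = 1.2) -> PlantedDriver:
        return PlantedDriver(
            chrom=chrom, start=start_bin * 50_000, end=(start_bin + n_bins) * 50_000,
            direction="amp", amplitude=amplitude, penetrance=0.8, gene_id=gene,
        )

    cfg_a = SimulationConfig(
        genome=default_genome("mouse"),
        n_samples=n_samples,
        drivers=(
            drv("chr1", 200, 4, shared_gene[0]),
            drv("chr2", 500, 4, decoy_gene[0]),
            drv("chr3", 300, 4, "PrivA"),
        ),
        passenger_rate=3.0,
        seed=seed,
    )
    cfg_b = SimulationConfig(
        genome=default_genome("human"),
        n_samples=n_samples,
        drivers=(
            drv("chr1", 600, 4, shared_gene[1]),
            drv("chr2", 100, 4, decoy_gene[1]),
            drv("chr3", 700, 4, "PRIVB"),
        ),
        passenger_rate=3.0,
        seed=seed + 1,
    )
    orthologs = pd.DataFrame(
        {
            "gene_a": [shared_gene[0], decoy_gene[0], "PrivA"],
            "gene_b": [shared_gene[1], decoy_gene[1], "PRIVB_OTHER"],
            "homology_type": ["one2one", "one2one", "one2one"],
        }
    )
    return cfg_a, cfg_b, orthologs
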