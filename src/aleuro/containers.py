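"""Core data containers shared across pipeline stages.

The pipeline moves three kinds of objects between stages: a count matrix with
its sample sheet and gene lengths (:class:`CountMatrix`), the knobs of the
synthetic study design (:class:`SimConfig`), and the ground truth emitted by
every generator (:class:`SimTruth`).  Stage-specific records (DEG tables,
protein tiers, profiles) live in their own modules as plain DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

TISSUES = ("AL", "ST")
TIMEPOINTS = (8, 15, 18, 22)


@dataclass
class SimConfig:
    """Knobs of the synthetic study design.

    The defaults encode the study conditions the pipeline is meant to
    emulate: paired AL/ST biological replicates at four developmental
    timepoints, a heavy-tailed transcriptome dominated by storage-protein
    transcripts late in development, a triplicate co-IP design with a planted
    tonoplast-true subset, and a double-membrane engulfment geometry in the
    imaging profiles.

    Parameters
    ----------
    seed
        Base seed; identical ``(seed, config)`` pairs give byte-identical
        outputs from every generator.
    n_genes, n_replicates_per_tissue
        Size of the simulated transcriptome and number of paired biological
        replicates per tissue at each timepoint (>= 2; pairing is undefined
        below that).
    de_fraction, log2fc_effect
        Fraction of genes planted as differentially expressed between AL and
        ST, and the magnitude of their log2 effect (sign drawn per gene).
    nb_dispersion
        Negative-binomial dispersion phi in Var = mu + phi * mu^2; 0 gives
        Poisson counts.
    library_size_range
        Inclusive (low, high) range of per-sample library sizes.
    abundance_meanlog, abundance_sdlog
        Log-normal parameters for relative gene abundances (heavy tail).
    block_sd
        Standard deviation of the additive replicate-block effect on the
        log mean (paired design).
    n_storage_prolamin, n_storage_other
        Number of genes planted in the prolamin and non-prolamin
        storage-protein classes.
    storage_st_boost
        Per-timepoint multiplicative boost of storage-class abundance in ST
        (compounded along the 8->22 DAP axis), mimicking the
        storage-protein-dominated late starchy endosperm.
    n_proteins, tonoplast_fraction, ip_enrichment_factor, dropout_rate
        Co-IP design: universe size, fraction of proteins planted as true
        tonoplast residents, IP/pre-immune abundance ratio for those, and
        independent Bernoulli zeroing rate per measurement.
    protein_abundance_meanlog, protein_abundance_sdlog, protein_noise_sdlog
        Log-normal baseline abundances and multiplicative measurement noise.
    go_terms, go_depth, go_genes_per_leaf, go_enriched_terms
        Size and shape of the synthetic GO universe and how many leaf terms
        to plant as enriched in the study set.
    membrane_enrichment_factor
        True per-membrane enrichment of the tagged protein in the engulfment
        domain; the observed ratio under the double-membrane geometry is
        2x this factor.
    profile_length, engulfment_span, profile_baseline
        Number of positions along a traced tonoplast, the (start, stop)
        index span labelled as engulfment, and the per-membrane baseline
        intensity.
    noise_sd
        Gaussian intensity noise, in the same arbitrary units as baseline.
    saturation_level
        Intensities at or above this level are flagged saturated
        (default 4095 = 12-bit detector ceiling).
    qpcr_genes, qpcr_ratio_log2_sd, qpcr_ct_noise_sd, qpcr_reference
        qPCR panel size, spread of true log2 AL/ST ratios, per-well Ct noise
        in cycles, and the reference gene name.
    """

    seed: int = 0
    # --- RNA-seq ---
    n_genes: int = 2000
    n_replicates_per_tissue: int = 3
    timepoints: tuple = TIMEPOINTS
    de_fraction: float = 0.1
    log2fc_effect: float = 2.0
    nb_dispersion: float = 0.1
    library_size_range: tuple = (800_000, 1_200_000)
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    block_sd: float = 0.1
    gene_length_meanlog: float = 7.3
    gene_length_sdlog: float = 0.5
    n_storage_prolamin: int = 30
    n_storage_other: int = 15
    storage_st_boost: float = 8.0
    # --- proteomics ---
    n_proteins: int = 500
    tonoplast_fraction: float = 0.2
    ip_enrichment_factor: float = 10.0
    dropout_rate: float = 0.1
    protein_abundance_meanlog: float = 4.0
    protein_abundance_sdlog: float = 1.0
    protein_noise_sdlog: float = 0.2
    # --- GO ---
    go_terms: int = 50
    go_depth: int = 4
    go_genes_per_leaf: int = 25
    go_enriched_terms: int = 2
    # --- imaging ---
    membrane_enrichment_factor: float = 2.0
    profile_length: int = 200
    engulfment_span: tuple = (80, 120)
    profile_baseline: float = 100.0
    noise_sd: float = 5.0
    saturation_level: float = 4095.0
    # --- qPCR ---
    qpcr_genes: int = 6
    qpcr_ratio_log2_sd: float = 2.0
    qpcr_ct_noise_sd: float = 0.2
    qpcr_reference: str = "Ubc9"

    def __post_init__(self) -> None:
        for name in ("de_fraction", "tonoplast_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_proteins", "go_terms", "qpcr_genes",
                     "profile_length"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_replicates_per_tissue < 2:
            raise ValueError(
                "n_replicates_per_tissue must be >= 2: the paired design "
                "is undefined with a single replicate block")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.membrane_enrichment_factor < 1:
            raise ValueError("membrane_enrichment_factor must be >= 1")
        if self.ip_enrichment_factor <= 0:
            raise ValueError("ip_enrichment_factor must be > 0")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("library_size_range must satisfy 1 <= lo <= hi")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("library_size_range", "timepoints", "engulfment_span"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth emitted by the generators; the recovery target of tests.

    ``de_genes`` maps gene id -> signed log2 effect (AL relative to ST);
    ``expression_class_map`` maps gene id -> {"prolamin",
    "non-prolamin-storage", "other"}; ``qpcr_ratios`` maps gene id -> true
    AL/ST expression ratio.
    """

    de_genes: dict = field(default_factory=dict)
    tonoplast_proteins: set = field(default_factory=set)
    enriched_terms: set = field(default_factory=set)
    membrane_enrichment_factor: float = float("nan")
    expression_class_map: dict = field(default_factory=dict)
    qpcr_ratios: dict = field(default_factory=dict)


class CountMatrix:
    """Integer gene x sample counts with gene lengths and a paired design.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, genes as rows, samples as
        columns.
    gene_lengths
        Series of positive transcript lengths (bases) indexed by gene id.
    samples
        Sample sheet indexed by sample id with columns ``tissue`` (AL/ST),
        ``timepoint`` (DAP) and ``replicate_block``; a block pairs one AL
        with one ST sample at a timepoint.
    """

    def __init__(self, counts: pd.DataFrame, gene_lengths: pd.Series,
                 samples: pd.DataFrame):
        counts = counts.copy()
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integral")
        counts = counts.astype(np.int64)
        missing = counts.index.difference(gene_lengths.index)
        if len(missing):
            raise ValueError(
                f"missing gene length for gene(s): {list(missing[:5])}")
        if (gene_lengths.loc[counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        extra = counts.columns.difference(samples.index)
        if len(extra):
            raise ValueError(f"samples missing from sheet: {list(extra[:5])}")
        for col in ("tissue", "timepoint"):
            if col not in samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        self.counts = counts
        self.gene_lengths = gene_lengths.loc[counts.index].astype(float)
        self.samples = samples.loc[counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.gene_lengths,
                           self.samples.loc[list(sample_ids)])

    def at_timepoint(self, timepoint: int) -> "CountMatrix":
        keep = self.samples.index[self.samples["timepoint"] == timepoint]
        if not len(keep):
            raise ValueError(f"no samples at timepoint {timepoint}")
        return self.subset_samples(keep)
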