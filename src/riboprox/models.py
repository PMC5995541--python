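"""Domain types shared across the pipeline.

Coordinate conventions: codon and protein positions are 1-based and
inclusive everywhere.  A gene's protein length equals its codon count
(stop codons are excluded from ``n_codons``), so transmembrane-domain
spans in protein coordinates align 1:1 with codon coordinates of the
ribosome-footprint profiles.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum

import numpy as np


class TMDSource(str, Enum):
    """Provenance of a transmembrane-domain annotation."""

    PREDICTED = "PREDICTED"
    CURATED = "CURATED"


class FilterFailure(str, Enum):
    """Eligibility filter a gene failed during client calling."""

    MAPPABILITY = "MAPPABILITY"
    EXPRESSION = "EXPRESSION"
    LOCALIZATION = "LOCALIZATION"


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence with its length in codons.

    Parameters
    ----------
    gene_id : str
        Unique identifier within a collection.
    n_codons : int
        Codon count of the CDS excluding the stop codon.
    cds_seq : str, optional
        In-frame nucleotide sequence of length ``3 * n_codons``.
    is_secretory : bool
        Membership in the secretory/TMD-containing reference set.
    excluded : bool
        Flag for genes removed from TMD analyses (mitochondrially
        encoded, dubious ORFs, pseudogenes).
    """

    gene_id: str
    n_codons: int
    cds_seq: str | None = None
    is_secretory: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError(f"{self.gene_id}: n_codons must be >= 1, got {self.n_codons}")
        if self.cds_seq is not None and len(self.cds_seq) != 3 * self.n_codons:
            raise ValueError(
                f"{self.gene_id}: cds_seq length {len(self.cds_seq)} != 3 x {self.n_codons}"
            )

    @property
    def protein_seq(self) -> str:
        """Translation of ``cds_seq`` (standard code, no stop)."""
        if self.cds_seq is None:
            raise ValueError(f"{self.gene_id}: no cds_seq to translate")
        from Bio.Seq import Seq

        return str(Seq(self.cds_seq).translate())


@dataclass
class FootprintProfile:
    """Per-codon ribosome-footprint counts for one gene in one sample.

    ``sample_total_mapped`` is the total number of mapped reads in the
    whole sample (not recomputed from per-gene tables, since a profile
    collection may cover only a gene subset); it is the normalizer for
    reads-per-million quantities.  Counts are integers for sequencing
    data but may be real-valued in the simulator's analytic
    (infinite-depth) mode, where expected rates stand in for draws.
    """

    gene_id: str
    sample_id: str
    counts: np.ndarray
    sample_total_mapped: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError(f"{self.gene_id}/{self.sample_id}: counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.gene_id}/{self.sample_id}: negative counts")
        if self.sample_total_mapped <= 0:
            raise ValueError(f"{self.sample_id}: sample_total_mapped must be positive")
        if self.sample_total_mapped < self.counts.sum() - 1e-6:
            raise ValueError(
                f"{self.gene_id}/{self.sample_id}: sample total below the gene's own counts"
            )

    @property
    def n_codons(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class SamplePair:
    """Matched pulldown/input samples for one BirA fusion and replicate."""

    bait_id: str
    replicate_id: str
    pulldown_sample: str
    input_sample: str

    def __post_init__(self) -> None:
        if self.pulldown_sample == self.input_sample:
            raise ValueError(f"{self.bait_id}/{self.replicate_id}: pulldown == input sample")


@dataclass(frozen=True, order=True)
class TMDomain:
    """A membrane-spanning segment in 1-based inclusive protein coordinates."""

    gene_id: str
    start_aa: int
    end_aa: int
    source: TMDSource = TMDSource.CURATED

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(
                f"{self.gene_id}: invalid TMD span {self.start_aa}..{self.end_aa}"
            )

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1

    def overlaps(self, other: "TMDomain") -> bool:
        """True when both spans share >= 1 residue of the same gene."""
        return (
            self.gene_id == other.gene_id
            and self.start_aa <= other.end_aa
            and other.start_aa <= self.end_aa
        )


@dataclass
class ProteomeRecord:
    """Per-protein log2 SILAC ratios for two knockdowns vs control."""

    protein_id: str
    log2_kd1_vs_control: float
    log2_kd2_vs_control: float
    log2_translation_change: float | None = None
    n_tmds: int | None = None

    def __post_init__(self) -> None:
        for v in (self.log2_kd1_vs_control, self.log2_kd2_vs_control):
            if not np.isfinite(v):
                raise ValueError(f"{self.protein_id}: non-finite log2 ratio")
        if self.n_tmds is not None and self.n_tmds < 0:
            raise ValueError(f"{self.protein_id}: negative n_tmds")


@dataclass
class ClientCall:
    """Per-gene client-calling outcome.

    ``max_ratio_by_replicate`` holds the gene's maximum positional
    ratio-of-ratios per replicate; percentile ranks are computed among
    eligible genes only.
    """

    gene_id: str
    max_ratio_by_replicate: dict = field(default_factory=dict)
    percentile_rank_by_replicate: dict = field(default_factory=dict)
    eligible: bool = False
    is_client: bool = False
    filter_failures: list = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Tunable thresholds and constants for the whole pipeline.

    Defaults implement the published analysis: a 101-codon window
    (half-width 50), 25-nt synthetic reads and a strict >80% unique
    fraction for mappability, a strict expression floor of 0.02 reads
    per codon per million, a strict pulldown/input RPKM ratio of 1 for
    localization, the top decile in every replicate for client status,
    a 10,000-subset composition bootstrap summarized at the 5th/95th
    percentiles, and an inclusive 0.5 log2 proteome threshold.
    """

    window_half_width: int = 50
    read_length_nt: int = 25
    mappability_threshold: float = 0.80
    expression_cutoff: float = 0.02
    localization_ratio_min: float = 1.0
    client_percentile: float = 90.0
    n_bootstrap: int = 10000
    ci_percentiles: tuple = (5.0, 95.0)
    proteome_log2_threshold: float = 0.5
    rank_among_all: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_half_width < 0:
            raise ValueError("window_half_width must be >= 0")
        for name in (
            "read_length_nt",
            "mappability_threshold",
            "expression_cutoff",
            "localization_ratio_min",
            "n_bootstrap",
            "proteome_log2_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = self.ci_percentiles
        if not (0 < lo < hi < 100):
            raise ValueError("ci_percentiles must be ordered and within (0, 100)")
        if not (0 < self.client_percentile < 100):
            raise ValueError("client_percentile must be in (0, 100)")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ci_percentiles" in raw:
            raw["ci_percentiles"] = tuple(raw["ci_percentiles"])
        return cls(**raw)
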