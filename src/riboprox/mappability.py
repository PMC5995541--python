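"""Unique-mappability of coding sequences under synthetic fixed-length reads.

Genes whose sequences are too similar to others in the pool produce
multi-mapping footprints; such genes are excluded from client calling.
A nucleotide start position is uniquely mappable when the read-length
substring beginning there occurs exactly once among all sense-strand
substrings of the whole CDS collection.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .models import GeneModel


@dataclass(frozen=True)
class MappabilityResult:
    gene_id: str
    fraction_unique: float
    n_positions_tested: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_unique <= 1.0):
            raise ValueError(f"{self.gene_id}: fraction_unique outside [0, 1]")
        if self.n_positions_tested < 0:
            raise ValueError(f"{self.gene_id}: negative n_positions_tested")


def _kmers(seq: str, k: int) -> Iterable[str]:
    for p in range(len(seq) - k + 1):
        yield seq[p : p + k]


def compute_mappability(
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    read_length_nt: int = 25,
) -> list[MappabilityResult]:
    """Fraction of uniquely mappable read start positions per gene.

    The uniqueness universe is the sense strand of the CDS pool itself.
    Genes shorter than the read length have no testable position and are
    unmappable by definition (``fraction_unique = 0``).
    """
    if read_length_nt < 1:
        raise ValueError("read_length_nt must be >= 1")
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    for g in gene_list:
        if g.cds_seq is None:
            raise ValueError(f"gene {g.gene_id} has no cds_seq; cannot assess mappability")

    pool: Counter = Counter()
    for g in gene_list:
        pool.update(_kmers(g.cds_seq, read_length_nt))

    results = []
    for g in gene_list:
        n_positions = max(0, len(g.cds_seq) - read_length_nt + 1)
        if n_positions == 0:
            results.append(MappabilityResult(g.gene_id, 0.0, 0))
            continue
        n_unique = sum(1 for kmer in _kmers(g.cds_seq, read_length_nt) if pool[kmer] == 1)
        results.append(MappabilityResult(g.gene_id, n_unique / n_positions, n_positions))
    return results


def filter_mappable(
    results: Iterable[MappabilityResult], threshold: float = 0.80
) -> set[str]:
    """Gene ids whose unique fraction strictly exceeds ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return {r.gene_id for r in results if r.fraction_unique > threshold}
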