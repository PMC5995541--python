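"""Transmembrane-domain annotation merging and composition statistics.

Annotations come from two sources — predictions (TMHMM-style) and
curated database entries (UniProt-style).  When a predicted span
overlaps a curated span of the same gene, the curated span wins.
Composition statistics pool all residues of all spans in a set (long
TMDs weigh more) and compare the fraction carrying each biochemical
property between a client TMD set and the full TMD universe; a
resampling of same-size random subsets from the universe provides a
null band for the ratio of fractions.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import GeneModel, TMDomain, TMDSource

PROPERTIES = ("ALIPHATIC", "AROMATIC", "CHARGED", "HYDROPHOBIC", "POLAR")


def _load_property_table() -> dict[str, frozenset]:
    """Residue -> property set, from the editable shipped table."""
    table: dict[str, frozenset] = {}
    ref = importlib.resources.files("riboprox").joinpath("data/aa_properties.tsv")
    for line in ref.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        parts = line.split("\t")
        residue = parts[0].strip()
        props = (
            frozenset(p for p in parts[1].split(",") if p)
            if len(parts) > 1 and parts[1].strip()
            else frozenset()
        )
        unknown = props - set(PROPERTIES)
        if unknown:
            raise ValueError(f"unknown properties {unknown} for residue {residue}")
        table[residue] = props
    return table


_PROPERTY_TABLE = _load_property_table()


def classify_residue(aa: str) -> frozenset:
    """All properties holding for a one-letter residue code."""
    aa = aa.upper()
    if aa not in _PROPERTY_TABLE:
        raise ValueError(f"nonstandard residue code: {aa!r}")
    return _PROPERTY_TABLE[aa]


def merge_tmd_sources(
    predicted: Iterable[TMDomain],
    curated: Iterable[TMDomain],
    genes: Mapping[str, GeneModel] | None = None,
) -> list[TMDomain]:
    """Union of both sources with curated spans taking precedence.

    A predicted span sharing >= 1 residue with any curated span of the
    same gene is dropped.  Spans from genes flagged ``excluded`` (or
    absent from ``genes`` when provided) are removed.
    """
    def keep(t: TMDomain) -> bool:
        if genes is None:
            return True
        g = genes.get(t.gene_id)
        return g is not None and not g.excluded

    curated = [t for t in curated if keep(t)]
    curated_by_gene: dict[str, list[TMDomain]] = {}
    for t in curated:
        curated_by_gene.setdefault(t.gene_id, []).append(t)
    merged = list(curated)
    for t in predicted:
        if not keep(t):
            continue
        if any(t.overlaps(c) for c in curated_by_gene.get(t.gene_id, [])):
            continue
        merged.append(t)
    return sorted(merged)


@dataclass
class TMDCountHistogram:
    """Proportion of proteins carrying each TMD count."""

    gene_set_label: str
    bins: dict


def tmd_count_histogram(
    tmds: Iterable[TMDomain],
    gene_set: Iterable[str],
    gene_set_label: str = "",
) -> TMDCountHistogram:
    """TMD-count distribution over a gene set (genes without spans bin at 0)."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("tmd_count_histogram requires a nonempty gene set")
    counts = {g: 0 for g in gene_set}
    for t in tmds:
        if t.gene_id in counts:
            counts[t.gene_id] += 1
    bins: dict[int, float] = {}
    for c in counts.values():
        bins[c] = bins.get(c, 0) + 1
    n = len(gene_set)
    return TMDCountHistogram(
        gene_set_label=gene_set_label,
        bins={k: v / n for k, v in sorted(bins.items())},
    )


@dataclass
class PropertyEnrichment:
    """Client-vs-all composition for one residue property.

    ``ratio`` is fraction-in-client-TMDs over fraction-in-all-TMDs;
    ``ci_low``/``ci_high`` bound the null resampling distribution of
    that ratio at the configured percentiles.
    """

    property: str
    fraction_clients: float
    fraction_all: float
    ratio: float
    ci_low: float
    ci_high: float


def span_residues(tmd: TMDomain, protein_seqs: Mapping[str, str]) -> str:
    """Residues of a span, sliced from the gene's protein sequence."""
    seq = protein_seqs.get(tmd.gene_id)
    if seq is None:
        raise ValueError(f"no protein sequence for gene {tmd.gene_id}")
    if tmd.end_aa > len(seq):
        raise ValueError(
            f"{tmd.gene_id}: TMD {tmd.start_aa}..{tmd.end_aa} exceeds protein length {len(seq)}"
        )
    return seq[tmd.start_aa - 1 : tmd.end_aa]


def _span_property_counts(
    tmds: Sequence[TMDomain], protein_seqs: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-span residue-property counts (n_spans x n_properties) and lengths."""
    counts = np.zeros((len(tmds), len(PROPERTIES)), dtype=float)
    lengths = np.zeros(len(tmds), dtype=float)
    for i, t in enumerate(tmds):
        residues = span_residues(t, protein_seqs)
        lengths[i] = len(residues)
        for aa in residues:
            for j, prop in enumerate(PROPERTIES):
                if prop in classify_residue(aa):
                    counts[i, j] += 1
    return counts, lengths


def property_fractions(
    tmds: Sequence[TMDomain], protein_seqs: Mapping[str, str]
) -> dict[str, float]:
    """Fraction of pooled TMD residues carrying each property."""
    counts, lengths = _span_property_counts(tmds, protein_seqs)
    total = lengths.sum()
    if total == 0:
        raise ValueError("no residues in TMD set")
    return {p: counts[:, j].sum() / total for j, p in enumerate(PROPERTIES)}


def property_enrichment(
    client_tmds: Sequence[TMDomain],
    all_tmds: Sequence[TMDomain],
    protein_seqs: Mapping[str, str],
    n_bootstrap: int = 10000,
    ci: tuple = (5.0, 95.0),
    rng: np.random.Generator | int | None = 0,
) -> list[PropertyEnrichment]:
    """Client/all composition ratios with a resampling null band.

    ``n_bootstrap`` random subsets of ``len(client_tmds)`` spans are
    drawn uniformly without replacement from ``all_tmds``; each yields
    a ratio of fractions, and ``ci`` gives the percentiles of those
    ratios reported as the band.  A fixed ``rng`` seed reproduces the
    sampled subsets exactly.
    """
    k = len(client_tmds)
    n = len(all_tmds)
    if k > n:
        raise ValueError(f"client set ({k}) larger than TMD universe ({n})")
    if k == 0:
        raise ValueError("empty client TMD set")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    all_counts, all_lengths = _span_property_counts(all_tmds, protein_seqs)
    client_counts, client_lengths = _span_property_counts(client_tmds, protein_seqs)

    frac_all = all_counts.sum(axis=0) / all_lengths.sum()
    frac_clients = client_counts.sum(axis=0) / client_lengths.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(frac_all > 0, frac_clients / frac_all, np.nan)

    boot = np.empty((n_bootstrap, len(PROPERTIES)))
    # chunked subset sampling keeps the index-matrix memory bounded
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_bootstrap:
        b = min(chunk, n_bootstrap - done)
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :k]
        sub_counts = all_counts[idx].sum(axis=1)
        sub_lengths = all_lengths[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot[done : done + b] = np.where(
                frac_all > 0,
                (sub_counts / sub_lengths[:, None]) / frac_all,
                np.nan,
            )
        done += b

    lo, hi = np.percentile(boot, ci, axis=0)
    return [
        PropertyEnrichment(
            property=p,
            fraction_clients=float(frac_clients[j]),
            fraction_all=float(frac_all[j]),
            ratio=float(ratio[j]),
            ci_low=float(lo[j]),
            ci_high=float(hi[j]),
        )
        for j, p in enumerate(PROPERTIES)
    ]


def positional_property_fractions(
    tmds: Sequence[TMDomain],
    protein_seqs: Mapping[str, str],
    n_bins: int = 7,
) -> np.ndarray:
    """Property fractions along the span, in relative-position bins.

    Each span is divided into ``n_bins`` equal relative-position bins
    (bin 0 at the span start); returns an ``n_bins x n_properties``
    matrix of residue fractions, for examining whether a property
    concentrates at span edges or is distributed throughout.
    """
    counts = np.zeros((n_bins, len(PROPERTIES)))
    totals = np.zeros(n_bins)
    for t in tmds:
        residues = span_residues(t, protein_seqs)
        L = len(residues)
        for i, aa in enumerate(residues):
            b = min(int(i * n_bins / L), n_bins - 1)
            totals[b] += 1
            for j, prop in enumerate(PROPERTIES):
                if prop in classify_residue(aa):
                    counts[b, j] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(totals[:, None] > 0, counts / totals[:, None], np.nan)
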