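"""Metagene averaging of enrichment aligned to the start of the first TMD.

Offset 0 is the first codon of the earliest transmembrane domain
(smallest start); positive offsets run downstream.  Averaging is
unweighted at the gene level — each gene counts once regardless of
expression — and raw enrichment values are averaged by default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import EnrichmentProfile
from .models import TMDomain

log = logging.getLogger(__name__)

DEFAULT_OFFSETS = range(-50, 251)


@dataclass
class MetageneCurve:
    """Mean enrichment per offset with per-offset contributing gene counts."""

    bait_id: str
    gene_set_label: str
    offsets: np.ndarray
    mean_enrichment: np.ndarray
    n_genes_contributing: np.ndarray


def align_to_first_tmd(
    profile: EnrichmentProfile,
    tmds: Iterable[TMDomain],
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> np.ndarray | None:
    """Profile values re-indexed relative to the first TMD start codon.

    Returns one value per offset (NaN where the offset falls outside
    the gene or the profile is undefined there), or None when the gene
    has no TMD (skipped with a warning).
    """
    spans = [t for t in tmds if t.gene_id == profile.gene_id]
    if not spans:
        log.warning("gene %s has no TMD; skipped in metagene", profile.gene_id)
        return None
    first_start = min(t.start_aa for t in spans)
    n = profile.values.size
    out = np.full(len(offsets), np.nan)
    for j, d in enumerate(offsets):
        codon = first_start + d  # 1-based
        if 1 <= codon <= n:
            out[j] = profile.values[codon - 1]
    return out


def mean_curve(
    aligned: Iterable[np.ndarray],
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    bait_id: str = "",
    gene_set_label: str = "",
) -> MetageneCurve:
    """Per-offset arithmetic mean over genes with a defined value."""
    rows = [a for a in aligned if a is not None]
    if not rows:
        raise ValueError("mean_curve requires a nonempty collection")
    stack = np.vstack(rows)
    n = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(stack, axis=0) / np.maximum(n, 1), np.nan)
    return MetageneCurve(
        bait_id=bait_id,
        gene_set_label=gene_set_label,
        offsets=np.asarray(list(offsets)),
        mean_enrichment=mean,
        n_genes_contributing=n,
    )


def metagene_curve(
    profiles: Iterable[EnrichmentProfile],
    tmds_by_gene: Mapping[str, list[TMDomain]],
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    bait_id: str = "",
    gene_set_label: str = "",
) -> MetageneCurve:
    """Align every profile to its first TMD and average."""
    aligned = [
        align_to_first_tmd(p, tmds_by_gene.get(p.gene_id, []), offsets)
        for p in profiles
    ]
    return mean_curve(
        [a for a in aligned if a is not None], offsets, bait_id, gene_set_label
    )


def rise_midpoint(
    curve: MetageneCurve,
    baseline_range: tuple = (-40, 0),
    plateau_range: tuple = (90, 130),
) -> float:
    """Offset where the curve first reaches halfway from baseline to plateau.

    Baseline and plateau are means of the curve over the given offset
    windows; NaN when either is undefined or the curve never crosses.
    """
    off = curve.offsets
    m = curve.mean_enrichment
    base_mask = (off >= baseline_range[0]) & (off <= baseline_range[1])
    plat_mask = (off >= plateau_range[0]) & (off <= plateau_range[1])
    if not np.any(np.isfinite(m[base_mask])) or not np.any(np.isfinite(m[plat_mask])):
        return float("nan")
    baseline = np.nanmean(m[base_mask])
    plateau = np.nanmean(m[plat_mask])
    half = (baseline + plateau) / 2.0
    after = (off > baseline_range[1]) & np.isfinite(m)
    crossing = np.flatnonzero(after & (m >= half))
    if crossing.size == 0:
        return float("nan")
    return float(off[crossing[0]])
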