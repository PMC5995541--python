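"""Sliding-window enrichment profiles and the ratio-of-ratios statistic.

For each codon position the footprint counts of a sample are summed in
a window of ``2 * half_width + 1`` codons (edge-truncated at gene
boundaries) and normalized to the sample's total mapped reads; the
enrichment at a position is the windowed pulldown rate divided by the
windowed input rate.  The per-million constant cancels in every ratio
and is omitted.  Positions whose input window holds zero reads are
undefined (NaN), never infinite — a deliberate policy: the expression
filter removes genes with empty windows from client calling, so a
pseudocount would silently change the statistic elsewhere.

The ratio-of-ratios divides a test bait's enrichment profile by a
reference ER bait's profile position by position; its per-gene maximum
ranks candidate clients.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import FootprintProfile


def window_sums(counts, half_width: int) -> np.ndarray:
    """Edge-truncated boxcar sums.

    ``out[i] = sum(counts[max(1, i-h) .. min(n, i+h)])`` in 1-based
    coordinates.  ``half_width = 0`` returns the counts themselves.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    c = np.asarray(counts, dtype=float)
    n = c.size
    cs = np.concatenate(([0.0], np.cumsum(c)))
    i = np.arange(n)
    lo = np.maximum(i - half_width, 0)
    hi = np.minimum(i + half_width, n - 1)
    return cs[hi + 1] - cs[lo]


@dataclass
class EnrichmentProfile:
    """Windowed pulldown/input enrichment along one gene.

    ``values`` has one entry per codon; NaN marks undefined positions
    (zero input-window sum).
    """

    gene_id: str
    bait_id: str
    replicate_id: str
    values: np.ndarray
    window_half_width: int


@dataclass
class RatioOfRatiosProfile:
    """Positionwise test-bait/reference-bait enrichment ratio.

    ``max_value`` is the maximum over defined positions, or NaN when no
    position is defined.
    """

    gene_id: str
    replicate_id: str
    values: np.ndarray

    @property
    def max_value(self) -> float:
        if np.all(np.isnan(self.values)):
            return math.nan
        return float(np.nanmax(self.values))


def enrichment_profile(
    pulldown: FootprintProfile,
    input_: FootprintProfile,
    half_width: int = 50,
    bait_id: str = "",
    replicate_id: str = "",
) -> EnrichmentProfile:
    """Windowed, depth-normalized pulldown/input enrichment for one gene."""
    if pulldown.gene_id != input_.gene_id:
        raise ValueError(
            f"gene mismatch: pulldown {pulldown.gene_id} vs input {input_.gene_id}"
        )
    if pulldown.n_codons != input_.n_codons:
        raise ValueError(f"{pulldown.gene_id}: profile length mismatch")
    wp = window_sums(pulldown.counts, half_width)
    wi = window_sums(input_.counts, half_width)
    values = np.full(wp.size, np.nan)
    defined = wi > 0
    values[defined] = (wp[defined] / pulldown.sample_total_mapped) / (
        wi[defined] / input_.sample_total_mapped
    )
    return EnrichmentProfile(
        gene_id=pulldown.gene_id,
        bait_id=bait_id,
        replicate_id=replicate_id,
        values=values,
        window_half_width=half_width,
    )


def ratio_of_ratios(
    bait: EnrichmentProfile, reference: EnrichmentProfile
) -> RatioOfRatiosProfile:
    """Positionwise bait/reference ratio where both are defined."""
    if bait.gene_id != reference.gene_id:
        raise ValueError(
            f"gene mismatch: {bait.gene_id} vs {reference.gene_id}"
        )
    if bait.values.size != reference.values.size:
        raise ValueError(f"{bait.gene_id}: profile length mismatch")
    if bait.window_half_width != reference.window_half_width:
        raise ValueError(f"{bait.gene_id}: window half-width mismatch")
    values = np.full(bait.values.size, np.nan)
    defined = (
        np.isfinite(bait.values)
        & np.isfinite(reference.values)
        & (reference.values > 0)
    )
    values[defined] = bait.values[defined] / reference.values[defined]
    return RatioOfRatiosProfile(
        gene_id=bait.gene_id, replicate_id=bait.replicate_id, values=values
    )
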