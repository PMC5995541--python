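"""Client calling from dual-knockdown SILAC proteome ratios.

Proteins depleted in both independent knockdowns of complex subunits
are putative clients destabilized in the complex's absence; proteins
induced in both typically reflect a stress response.  The boundary is
a plain fold-change threshold, inclusive at the boundary, applied to
the two log2 ratios.  Subunits of the depleted complex itself are
reported separately and excluded from the partition, since one
knockdown depletes the whole complex.
"""
from __future__ import annotations

import logging
from typing import Iterable

from .models import ProteomeRecord

log = logging.getLogger(__name__)


def call_regulated(
    records: Iterable[ProteomeRecord],
    log2_threshold: float = 0.5,
    exclude_ids: Iterable[str] = (),
) -> dict[str, list[ProteomeRecord]]:
    """Partition records into down_in_both / up_in_both / other.

    ``down_in_both`` requires both log2 ratios <= -threshold,
    ``up_in_both`` both >= +threshold (inclusive boundaries).  Records
    whose id is in ``exclude_ids`` are set aside under ``excluded``.
    The three main keys partition the remaining records exhaustively
    and disjointly.
    """
    if log2_threshold <= 0:
        raise ValueError("log2_threshold must be positive")
    exclude_ids = set(exclude_ids)
    out: dict[str, list[ProteomeRecord]] = {
        "down_in_both": [],
        "up_in_both": [],
        "other": [],
        "excluded": [],
    }
    for r in records:
        if r.protein_id in exclude_ids:
            out["excluded"].append(r)
        elif (
            r.log2_kd1_vs_control <= -log2_threshold
            and r.log2_kd2_vs_control <= -log2_threshold
        ):
            out["down_in_both"].append(r)
        elif (
            r.log2_kd1_vs_control >= log2_threshold
            and r.log2_kd2_vs_control >= log2_threshold
        ):
            out["up_in_both"].append(r)
        else:
            out["other"].append(r)
    return out


def flag_translationally_driven(
    records: Iterable[ProteomeRecord],
    log2_threshold: float = 0.5,
) -> tuple[set[str], int]:
    """Down-in-both proteins whose translation also drops.

    Among records down in both knockdowns, returns ids whose
    ``log2_translation_change`` <= -threshold — decreases explainable
    by reduced synthesis rather than degradation.  Records lacking a
    translation value are skipped; their count is returned.
    """
    down = call_regulated(records, log2_threshold)["down_in_both"]
    flagged: set[str] = set()
    n_skipped = 0
    for r in down:
        if r.log2_translation_change is None:
            n_skipped += 1
        elif r.log2_translation_change <= -log2_threshold:
            flagged.add(r.protein_id)
    if n_skipped:
        log.info("%d down-regulated records lack translation values", n_skipped)
    return flagged, n_skipped


def tmd_summary(down_records: Iterable[ProteomeRecord]) -> dict[str, int]:
    """Membrane-topology counts for a depleted-protein set.

    Reports how many members carry >= 1 TMD, are multipass (>= 2), or
    are soluble (0), plus the same at the 2-fold stringency (both
    |log2| >= 1).
    """
    down = list(down_records)
    for r in down:
        if r.n_tmds is None:
            raise ValueError(f"{r.protein_id}: n_tmds required for tmd_summary")
    twofold = [
        r
        for r in down
        if r.log2_kd1_vs_control <= -1.0 and r.log2_kd2_vs_control <= -1.0
    ]
    return {
        "n_total": len(down),
        "n_with_tmd": sum(1 for r in down if r.n_tmds >= 1),
        "n_multipass": sum(1 for r in down if r.n_tmds >= 2),
        "n_soluble": sum(1 for r in down if r.n_tmds == 0),
        "n_twofold_down": len(twofold),
        "n_twofold_with_tmd": sum(1 for r in twofold if r.n_tmds >= 1),
    }
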