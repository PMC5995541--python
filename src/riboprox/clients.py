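"""Eligibility filters and top-decile client calling.

Three filters restrict the gene universe before ranking:

1. mappability — >80% of coding-sequence positions uniquely mappable
   with synthetic fixed-length reads (see :mod:`riboprox.mappability`);
2. expression — strictly more than 0.02 reads per codon per million
   mapped reads in every bait's input sample, and no 101-codon window
   with zero total reads in any sample;
3. localization — pulldown/input RPKM ratio strictly above 1 in at
   least one bait sample pair (gene length cancels, so this is a
   total-normalized reads-share ratio).

Among eligible genes, a gene is a client when its maximum positional
ratio-of-ratios sits in the top decile in every biological replicate.
The decile holds ``floor(N * (100 - p) / 100)`` slots; the threshold is
the value in the last slot and boundary ties are all included, so with
no ties at most 10% of eligible genes qualify per replicate.
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np

from .enrichment import enrichment_profile, ratio_of_ratios, window_sums
from .models import (
    ClientCall,
    FilterFailure,
    FootprintProfile,
    GeneModel,
    PipelineConfig,
    SamplePair,
)

log = logging.getLogger(__name__)

ProfileMap = Mapping[tuple, FootprintProfile]  # keyed (gene_id, sample_id)


def profiles_by_key(profiles: Iterable[FootprintProfile]) -> dict:
    """Index profiles by (gene_id, sample_id)."""
    out: dict = {}
    for p in profiles:
        key = (p.gene_id, p.sample_id)
        if key in out:
            raise ValueError(f"duplicate profile for {key}")
        out[key] = p
    return out


def _gene_ids(profiles: ProfileMap) -> list[str]:
    return sorted({g for g, _ in profiles})


def filter_expression(
    profiles: ProfileMap,
    pairs: Iterable[SamplePair],
    half_width: int = 50,
    cutoff: float = 0.02,
) -> set[str]:
    """Genes passing the expression floor and the no-empty-window rule.

    A gene passes iff (a) in every bait's input sample its read density
    strictly exceeds ``cutoff`` reads per codon per million mapped
    reads, and (b) in every sample (pulldown and input) every
    edge-truncated ``2*half_width + 1``-codon window holds at least one
    read.  A gene missing a profile for any paired sample fails.
    """
    pairs = list(pairs)
    input_samples = [p.input_sample for p in pairs]
    all_samples = [s for p in pairs for s in (p.pulldown_sample, p.input_sample)]
    passing = set()
    for gene_id in _gene_ids(profiles):
        ok = True
        for sample_id in input_samples:
            prof = profiles.get((gene_id, sample_id))
            if prof is None:
                ok = False
                break
            density = (
                prof.counts.sum()
                / prof.n_codons
                / (prof.sample_total_mapped / 1e6)
            )
            if not density > cutoff:
                ok = False
                break
        if ok:
            for sample_id in all_samples:
                prof = profiles.get((gene_id, sample_id))
                if prof is None or window_sums(prof.counts, half_width).min() <= 0:
                    ok = False
                    break
        if ok:
            passing.add(gene_id)
    return passing


def filter_localization(
    profiles: ProfileMap,
    pairs: Iterable[SamplePair],
    ratio_min: float = 1.0,
) -> set[str]:
    """Genes with pulldown/input RPKM ratio strictly above ``ratio_min``
    in at least one sample pair."""
    passing = set()
    for gene_id in _gene_ids(profiles):
        for pair in pairs:
            pd_prof = profiles.get((gene_id, pair.pulldown_sample))
            in_prof = profiles.get((gene_id, pair.input_sample))
            if pd_prof is None or in_prof is None:
                continue
            sum_in = in_prof.counts.sum()
            if sum_in == 0:
                continue
            ratio = (pd_prof.counts.sum() / pd_prof.sample_total_mapped) / (
                sum_in / in_prof.sample_total_mapped
            )
            if ratio > ratio_min:
                passing.add(gene_id)
                break
    return passing


def max_ratio_of_ratios(
    profiles: ProfileMap,
    pairs: Iterable[SamplePair],
    test_bait: str,
    reference_bait: str,
    half_width: int = 50,
) -> dict[str, dict[str, float]]:
    """Per-gene, per-replicate maximum positional ratio-of-ratios.

    Replicates of the test bait are matched to replicates of the
    reference bait by replicate id.  Genes lacking any defined position
    get NaN for that replicate.
    """
    by_bait_rep = {(p.bait_id, p.replicate_id): p for p in pairs}
    replicate_ids = sorted(
        {r for b, r in by_bait_rep if b == test_bait}
        & {r for b, r in by_bait_rep if b == reference_bait}
    )
    if not replicate_ids:
        raise ValueError(
            f"no shared replicates between baits {test_bait!r} and {reference_bait!r}"
        )
    out: dict[str, dict[str, float]] = {}
    for gene_id in _gene_ids(profiles):
        per_rep: dict[str, float] = {}
        for rep in replicate_ids:
            tp = by_bait_rep[(test_bait, rep)]
            rp = by_bait_rep[(reference_bait, rep)]
            needed = [
                (gene_id, tp.pulldown_sample),
                (gene_id, tp.input_sample),
                (gene_id, rp.pulldown_sample),
                (gene_id, rp.input_sample),
            ]
            if any(k not in profiles for k in needed):
                per_rep[rep] = math.nan
                continue
            test_prof = enrichment_profile(
                profiles[needed[0]], profiles[needed[1]], half_width, test_bait, rep
            )
            ref_prof = enrichment_profile(
                profiles[needed[2]], profiles[needed[3]], half_width, reference_bait, rep
            )
            per_rep[rep] = ratio_of_ratios(test_prof, ref_prof).max_value
        out[gene_id] = per_rep
    return out


def decile_threshold(values: np.ndarray, percentile: float) -> float:
    """Ratio value delimiting the top ``100 - percentile`` percent.

    The top tail holds ``k = floor(N * (100 - percentile) / 100)``
    slots; the threshold is the k-th largest value.  When N is too
    small for a single slot no gene qualifies (+inf).
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    k = int(math.floor(n * (100.0 - percentile) / 100.0))
    if k < 1:
        return math.inf
    return float(values[n - k])


def call_clients(
    max_ratios: Mapping[str, Mapping[str, float]],
    percentile: float = 90.0,
    ranking_pool: Mapping[str, Mapping[str, float]] | None = None,
) -> list[ClientCall]:
    """Rank per-replicate maxima and flag top-decile-in-all-replicates genes.

    ``max_ratios`` maps eligible gene -> replicate -> max ratio; all
    values must be defined.  ``ranking_pool`` optionally supplies a
    wider value set (e.g. all genes rather than eligible only) from
    which thresholds are computed; membership is still restricted to
    ``max_ratios``.  Boundary ties are all included.
    """
    genes = sorted(max_ratios)
    if not genes:
        return []
    replicate_ids = sorted({r for g in genes for r in max_ratios[g]})
    if len(replicate_ids) < 2:
        raise ValueError("client calling requires >= 2 replicates")
    for g in genes:
        if set(max_ratios[g]) != set(replicate_ids):
            raise ValueError(f"gene {g} missing replicates")
        if any(not np.isfinite(max_ratios[g][r]) for r in replicate_ids):
            raise ValueError(f"gene {g} has undefined max ratio; exclude it upstream")

    pool = ranking_pool if ranking_pool is not None else max_ratios
    thresholds = {}
    for rep in replicate_ids:
        vals = np.array(
            [pool[g][rep] for g in pool if np.isfinite(pool[g].get(rep, math.nan))]
        )
        thresholds[rep] = decile_threshold(vals, percentile)

    calls = []
    for g in genes:
        ranks = {}
        for rep in replicate_ids:
            vals = np.array([max_ratios[x][rep] for x in genes])
            ranks[rep] = 100.0 * np.count_nonzero(vals <= max_ratios[g][rep]) / len(genes)
        is_client = all(
            max_ratios[g][rep] >= thresholds[rep] for rep in replicate_ids
        )
        calls.append(
            ClientCall(
                gene_id=g,
                max_ratio_by_replicate=dict(max_ratios[g]),
                percentile_rank_by_replicate=ranks,
                eligible=True,
                is_client=is_client,
            )
        )
    return calls


def identify_clients(
    genes: Mapping[str, GeneModel],
    profiles: ProfileMap,
    pairs: Iterable[SamplePair],
    test_bait: str,
    reference_bait: str,
    config: PipelineConfig | None = None,
    mappable_ids: set[str] | None = None,
) -> tuple[list[ClientCall], dict]:
    """Run filters, ranking and client calling end to end.

    ``mappable_ids`` may be precomputed; otherwise it is derived from
    the gene models' coding sequences (all genes pass when no sequence
    is available).  Returns one ClientCall per profiled gene (eligible
    or not) plus a diagnostics dict of per-filter gene counts.
    """
    config = config or PipelineConfig()
    pairs = list(pairs)
    profiled = set(_gene_ids(profiles))

    if mappable_ids is None:
        with_seq = [g for g in genes.values() if g.cds_seq is not None]
        if with_seq and len(with_seq) == len(genes):
            from .mappability import compute_mappability, filter_mappable

            mappable_ids = filter_mappable(
                compute_mappability(with_seq, config.read_length_nt),
                config.mappability_threshold,
            )
        else:
            mappable_ids = set(genes)

    expressed = filter_expression(
        profiles, pairs, config.window_half_width, config.expression_cutoff
    )
    localized = filter_localization(profiles, pairs, config.localization_ratio_min)

    all_max = max_ratio_of_ratios(
        profiles, pairs, test_bait, reference_bait, config.window_half_width
    )

    failures: dict[str, list] = {g: [] for g in profiled}
    for g in profiled:
        if g not in mappable_ids:
            failures[g].append(FilterFailure.MAPPABILITY)
        if g not in expressed or any(
            not np.isfinite(v) for v in all_max[g].values()
        ):
            # undefined maxima arise from empty windows -> expression failure
            if FilterFailure.EXPRESSION not in failures[g]:
                failures[g].append(FilterFailure.EXPRESSION)
        if g not in localized:
            failures[g].append(FilterFailure.LOCALIZATION)
    eligible = {g for g in profiled if not failures[g]}

    ranking_pool = None
    if config.rank_among_all:
        ranking_pool = {
            g: v
            for g, v in all_max.items()
            if all(np.isfinite(x) for x in v.values())
        }
    calls = call_clients(
        {g: all_max[g] for g in sorted(eligible)},
        config.client_percentile,
        ranking_pool,
    )
    called = {c.gene_id: c for c in calls}
    for g in sorted(profiled - eligible):
        called[g] = ClientCall(
            gene_id=g,
            max_ratio_by_replicate={
                r: v for r, v in all_max[g].items() if np.isfinite(v)
            },
            eligible=False,
            is_client=False,
            filter_failures=failures[g],
        )
    diagnostics = {
        "n_profiled": len(profiled),
        "n_mappable": len(mappable_ids & profiled),
        "n_expressed": len(expressed),
        "n_localized": len(localized),
        "n_eligible": len(eligible),
        "n_clients": sum(c.is_client for c in called.values()),
    }
    log.info("client calling: %s", diagnostics)
    return [called[g] for g in sorted(called)], diagnostics
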