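"""Synthetic data generator with planted, recoverable structure.

The generator emulates the statistical structure the analysis assumes:

* a transcriptome of random coding sequences (uniform over sense
  codons, so translations contain no internal stops), a subset of
  which carry transmembrane architecture — either a single TMD or a
  multipass cluster of TMDs separated by short loops;
* client genes, drawn only from multipass genes, whose pulldown
  enrichment under the test bait gains an extra multiplicative peak
  downstream of the TMD cluster;
* input footprint profiles with roughly uniform per-codon coverage
  scaled by a log-normal per-gene expression factor (so the expression
  filter has real work to do);
* a targeting-driven pulldown enrichment ramp beginning ~60 codons
  after the first TMD for every ER-localized bait, rising as a
  logistic rather than a step — the onset is approximate in nature,
  and smoothness avoids brittle tests;
* a reference bait that shares the targeting ramp but never the client
  peak, mirroring the use of a general-ER tail-anchored fusion as the
  denominator of the ratio-of-ratios;
* per-protein log2 SILAC ratios with a planted shift for clients in
  both knockdowns.

All draws flow from a single seeded :class:`numpy.random.Generator`;
identical seeds give identical outputs.  The analytic mode replaces
count draws by their expected rates and gives every sample a common
nominal total, the infinite-depth limit in which the recovered maximum
ratio-of-ratios equals the planted gain exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .models import FootprintProfile, GeneModel, ProteomeRecord, SamplePair, TMDomain, TMDSource

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

ANALYTIC_TOTAL = 1e6


@dataclass
class SimulationSpec:
    """Study conditions for the generator.

    Lengths and offsets are in codons; ``fraction_clients`` is the
    fraction of TMD genes planted as clients (clients are drawn from
    multipass genes only, so it must not exceed
    ``multipass_fraction``).  ``input_depth`` is the mean input reads
    per codon for a gene of average expression.
    """

    n_genes: int = 500
    fraction_tmd_genes: float = 0.4
    fraction_clients: float = 0.08
    gene_length_range: tuple = (350, 800)
    tmd_length: int = 21
    cluster_size_range: tuple = (2, 5)
    loop_length_range: tuple = (5, 15)
    multipass_fraction: float = 0.6
    first_tmd_start_range: tuple = (30, 80)
    targeting_ramp_start: int = 60
    ramp_amplitude: float = 4.0
    ramp_width: int = 20
    client_peak_gain: float = 4.0
    client_peak_offset: int = 20
    downstream_margin: int = 110
    input_depth: float = 20.0
    capture_efficiency: float = 0.25
    background_efficiency: float = 0.05
    expression_sigma: float = 0.5
    n_replicates: int = 2
    noise_model: str = "poisson"
    nb_dispersion: float = 10.0
    proteome_effect_log2: float = -1.0
    proteome_noise_sd: float = 0.2
    translation_driven_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_tmd_genes", "fraction_clients", "multipass_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraction_clients > self.multipass_fraction:
            raise ValueError("fraction_clients cannot exceed multipass_fraction")
        for name in ("tmd_length", "n_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.targeting_ramp_start < 0 or self.client_peak_offset < 0:
            raise ValueError("ramp/peak offsets must be >= 0")
        if self.noise_model not in ("poisson", "nb"):
            raise ValueError("noise_model must be 'poisson' or 'nb'")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in (
            "gene_length_range",
            "cluster_size_range",
            "loop_length_range",
            "first_tmd_start_range",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class Transcriptome:
    """Generated genes, TMD spans, and the planted truth table."""

    genes: dict
    tmds: list
    truth: pd.DataFrame

    @property
    def client_ids(self) -> set:
        return set(self.truth.index[self.truth["is_client"]])

    @property
    def tmd_gene_ids(self) -> set:
        return set(self.truth.index[self.truth["is_tmd"]])

    def tmds_by_gene(self) -> dict:
        out: dict = {}
        for t in self.tmds:
            out.setdefault(t.gene_id, []).append(t)
        return out


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def simulate_transcriptome(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> Transcriptome:
    """Generate gene models, TMD architectures, and truth labels.

    TMD genes receive either a single TMD or a multipass cluster of
    adjacent TMDs separated by short loops; clients are drawn only
    from multipass genes, with probability
    ``fraction_clients / multipass_fraction`` so the expected client
    count is ``n_genes * fraction_tmd_genes * fraction_clients``.
    Gene lengths leave ``downstream_margin`` codons after the client
    peak start so a full enrichment window fits; infeasible lengths
    are resampled a bounded number of times.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.gene_length_range
    genes: dict[str, GeneModel] = {}
    tmds: list[TMDomain] = []
    truth_rows = []
    client_prob = (
        spec.fraction_clients / spec.multipass_fraction
        if spec.multipass_fraction > 0
        else 0.0
    )
    for i in range(spec.n_genes):
        gene_id = f"g{i:04d}"
        is_tmd = rng.random() < spec.fraction_tmd_genes
        is_multipass = is_tmd and rng.random() < spec.multipass_fraction
        is_client = is_multipass and rng.random() < client_prob

        if not is_tmd:
            n_codons = int(rng.integers(lo, hi + 1))
            spans: list[tuple] = []
            first_start = cluster_end = None
        else:
            n_tmds = (
                int(rng.integers(spec.cluster_size_range[0], spec.cluster_size_range[1] + 1))
                if is_multipass
                else 1
            )
            first_start = int(
                rng.integers(spec.first_tmd_start_range[0], spec.first_tmd_start_range[1] + 1)
            )
            spans = []
            pos = first_start
            for j in range(n_tmds):
                spans.append((pos, pos + spec.tmd_length - 1))
                pos = spans[-1][1] + 1
                if j < n_tmds - 1:
                    pos += int(
                        rng.integers(spec.loop_length_range[0], spec.loop_length_range[1] + 1)
                    )
            cluster_end = spans[-1][1]
            required = cluster_end + spec.client_peak_offset + spec.downstream_margin
            n_codons = int(rng.integers(lo, hi + 1))
            for _ in range(50):
                if n_codons >= required:
                    break
                n_codons = int(rng.integers(lo, hi + 1))
            else:
                raise RuntimeError(
                    f"{gene_id}: cluster geometry (needs {required} codons) cannot fit "
                    f"gene_length_range {spec.gene_length_range}"
                )
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            n_codons=n_codons,
            cds_seq=_random_cds(rng, n_codons),
            is_secretory=is_tmd,
        )
        for start, end in spans:
            tmds.append(TMDomain(gene_id, start, end, TMDSource.CURATED))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "is_tmd": is_tmd,
                "is_multipass": is_multipass,
                "is_client": is_client,
                "n_tmds": len(spans),
                "first_tmd_start": np.nan if first_start is None else first_start,
                "cluster_end": np.nan if cluster_end is None else cluster_end,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return Transcriptome(genes=genes, tmds=tmds, truth=truth)


def positional_enrichment(
    spec: SimulationSpec,
    n_codons: int,
    first_tmd_start: float,
    cluster_end: float,
    client_under_bait: bool,
) -> np.ndarray:
    """Expected pulldown/input enrichment along one gene for one bait.

    1 everywhere for genes without TMDs; otherwise a logistic targeting
    ramp centred ``targeting_ramp_start`` codons after the first TMD,
    multiplied by ``client_peak_gain`` from ``cluster_end +
    client_peak_offset`` onward when the gene is a client under the
    bait in question.
    """
    pos = np.arange(1, n_codons + 1, dtype=float)
    if np.isnan(first_tmd_start):
        return np.ones(n_codons)
    t0 = first_tmd_start + spec.targeting_ramp_start
    scale = max(spec.ramp_width / 4.0, 1e-9)
    e = 1.0 + (spec.ramp_amplitude - 1.0) / (1.0 + np.exp(-(pos - t0) / scale))
    if client_under_bait:
        e = np.where(pos >= cluster_end + spec.client_peak_offset, e * spec.client_peak_gain, e)
    return e


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, spec: SimulationSpec
) -> np.ndarray:
    if spec.noise_model == "poisson":
        return rng.poisson(mean).astype(float)
    lam = rng.gamma(shape=spec.nb_dispersion, scale=mean / spec.nb_dispersion)
    return rng.poisson(lam).astype(float)


def simulate_profiles(
    spec: SimulationSpec,
    transcriptome: Transcriptome,
    rng: np.random.Generator | None = None,
    test_bait: str = "emc5",
    reference_bait: str = "ubc6_ta",
    analytic: bool = False,
) -> tuple[dict, list[SamplePair], dict]:
    """Footprint profiles and sample pairs for test and reference baits.

    Returns ``(profiles, pairs, totals)`` with profiles keyed
    ``(gene_id, sample_id)``.  In analytic mode counts are the exact
    expected rates and every sample carries a common nominal total.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    truth = transcriptome.truth
    gene_ids = sorted(transcriptome.genes)
    expr = {
        g: float(np.exp(rng.normal(0.0, spec.expression_sigma))) for g in gene_ids
    }

    pairs: list[SamplePair] = []
    raw_counts: dict[tuple, np.ndarray] = {}
    sample_ids: list[str] = []
    for r in range(1, spec.n_replicates + 1):
        rep = f"rep{r}"
        for bait in (test_bait, reference_bait):
            pd_id, in_id = f"{bait}_{rep}_pulldown", f"{bait}_{rep}_input"
            pairs.append(SamplePair(bait, rep, pd_id, in_id))
            sample_ids.extend([pd_id, in_id])
            for g in gene_ids:
                row = truth.loc[g]
                n = transcriptome.genes[g].n_codons
                input_mean = np.full(n, spec.input_depth * expr[g])
                eff = (
                    spec.capture_efficiency
                    if row["is_tmd"]
                    else spec.background_efficiency
                )
                enrich = positional_enrichment(
                    spec,
                    n,
                    row["first_tmd_start"],
                    row["cluster_end"],
                    client_under_bait=bool(row["is_client"]) and bait == test_bait,
                )
                pd_mean = input_mean * eff * enrich
                if analytic:
                    raw_counts[(g, in_id)] = input_mean
                    raw_counts[(g, pd_id)] = pd_mean
                else:
                    raw_counts[(g, in_id)] = _draw_counts(rng, input_mean, spec)
                    raw_counts[(g, pd_id)] = _draw_counts(rng, pd_mean, spec)

    totals: dict[str, float] = {}
    for s in sample_ids:
        if analytic:
            totals[s] = ANALYTIC_TOTAL
        else:
            totals[s] = float(
                sum(raw_counts[(g, s)].sum() for g in gene_ids)
            )
    profiles = {
        (g, s): FootprintProfile(
            gene_id=g, sample_id=s, counts=c, sample_total_mapped=totals[s]
        )
        for (g, s), c in raw_counts.items()
    }
    return profiles, pairs, totals


def simulate_proteome(
    spec: SimulationSpec,
    transcriptome: Transcriptome,
    rng: np.random.Generator | None = None,
) -> list[ProteomeRecord]:
    """Per-protein log2 ratios for two knockdowns, with planted clients.

    Clients shift by ``proteome_effect_log2`` in both knockdowns;
    everything else is centred noise.  A configurable fraction of
    clients is translationally driven (translation change shifted too);
    all other translation changes are noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    truth = transcriptome.truth
    sd = spec.proteome_noise_sd
    records = []
    for g in sorted(transcriptome.genes):
        row = truth.loc[g]
        loc = spec.proteome_effect_log2 if row["is_client"] else 0.0
        kd1 = float(rng.normal(loc, sd))
        kd2 = float(rng.normal(loc, sd))
        trans_driven = bool(row["is_client"]) and rng.random() < spec.translation_driven_fraction
        trans = float(rng.normal(spec.proteome_effect_log2 if trans_driven else 0.0, sd))
        records.append(
            ProteomeRecord(
                protein_id=g,
                log2_kd1_vs_control=kd1,
                log2_kd2_vs_control=kd2,
                log2_translation_change=trans,
                n_tmds=int(row["n_tmds"]),
            )
        )
    return records


@dataclass
class SimulationResult:
    """Everything one seeded run of the generator produces."""

    spec: SimulationSpec
    transcriptome: Transcriptome
    profiles: dict
    pairs: list
    totals: dict
    proteome: list
    test_bait: str = "emc5"
    reference_bait: str = "ubc6_ta"


def simulate_all(
    spec: SimulationSpec,
    test_bait: str = "emc5",
    reference_bait: str = "ubc6_ta",
    analytic: bool = False,
) -> SimulationResult:
    """Run transcriptome, profile and proteome generation off one seed."""
    rng = np.random.default_rng(spec.rng_seed)
    transcriptome = simulate_transcriptome(spec, rng)
    profiles, pairs, totals = simulate_profiles(
        spec, transcriptome, rng, test_bait, reference_bait, analytic
    )
    proteome = simulate_proteome(spec, transcriptome, rng)
    return SimulationResult(
        spec=spec,
        transcriptome=transcriptome,
        profiles=profiles,
        pairs=pairs,
        totals=totals,
        proteome=proteome,
        test_bait=test_bait,
        reference_bait=reference_bait,
    )
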