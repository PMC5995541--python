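"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are tab-separated UTF-8 with a header row; lines starting
with ``#`` are comments (output tables carry the configuration used to
produce them in such comments).  FASTA handling goes through Biopython.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    FootprintProfile,
    GeneModel,
    ProteomeRecord,
    SamplePair,
    TMDomain,
    TMDSource,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# generic table helpers
# ---------------------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read a tab-separated table, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, comments: Mapping | None = None) -> None:
    """Write ``df`` as TSV, preceded by ``# key = value`` comment lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coding sequences
# ---------------------------------------------------------------------------

def read_cds_fasta(path) -> dict[str, GeneModel]:
    """Read in-frame coding sequences into GeneModels keyed by gene id.

    ``n_codons`` is ``floor(len/3)``; records whose length is not a
    multiple of 3 are truncated to the last complete codon and logged.
    Duplicate ids are fatal.
    """
    genes: dict[str, GeneModel] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id = record.id
        if gene_id in genes:
            raise ValueError(f"duplicate gene_id in FASTA: {gene_id}")
        seq = str(record.seq).upper()
        n_codons, rem = divmod(len(seq), 3)
        if rem:
            log.warning(
                "CDS %s has length %d, not a multiple of 3; truncating to %d codons",
                gene_id, len(seq), n_codons,
            )
            seq = seq[: 3 * n_codons]
        genes[gene_id] = GeneModel(gene_id=gene_id, n_codons=n_codons, cds_seq=seq)
    return genes


def write_cds_fasta(genes: Iterable[GeneModel], path) -> None:
    records = [
        SeqRecord(Seq(g.cds_seq), id=g.gene_id, description="")
        for g in genes
        if g.cds_seq is not None
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# footprint counts
# ---------------------------------------------------------------------------

def read_sample_totals(path) -> dict[str, float]:
    """Sidecar table of per-sample total mapped reads (sample_id, total_mapped)."""
    df = read_table(path)
    return dict(zip(df["sample_id"].astype(str), df["total_mapped"].astype(float)))


def read_counts_table(
    path,
    genes: Mapping[str, GeneModel],
    totals: Mapping[str, float],
) -> list[FootprintProfile]:
    """Assemble dense per-codon count vectors from a sparse table.

    Expected columns: gene_id, sample_id, codon_position (1-based),
    count.  Positions absent from the table are zero.  Unknown genes,
    out-of-range positions and negative counts are fatal.
    """
    df = read_table(path)
    profiles: list[FootprintProfile] = []
    if df.empty:
        return profiles
    for (gene_id, sample_id), group in df.groupby(["gene_id", "sample_id"], sort=True):
        gene_id, sample_id = str(gene_id), str(sample_id)
        if gene_id not in genes:
            raise ValueError(f"counts table references unknown gene_id: {gene_id}")
        n = genes[gene_id].n_codons
        pos = group["codon_position"].to_numpy(dtype=int)
        cnt = group["count"].to_numpy(dtype=float)
        if np.any(cnt < 0):
            raise ValueError(f"negative count for {gene_id}/{sample_id}")
        if np.any((pos < 1) | (pos > n)):
            bad = pos[(pos < 1) | (pos > n)][0]
            raise ValueError(
                f"codon_position {bad} outside [1, {n}] for gene {gene_id}"
            )
        dense = np.zeros(n, dtype=float)
        np.add.at(dense, pos - 1, cnt)
        if sample_id not in totals:
            raise ValueError(f"no sample total for sample_id: {sample_id}")
        profiles.append(
            FootprintProfile(
                gene_id=gene_id,
                sample_id=sample_id,
                counts=dense,
                sample_total_mapped=float(totals[sample_id]),
            )
        )
    return profiles


def write_counts_table(profiles: Iterable[FootprintProfile], path, comments=None) -> None:
    """Write profiles sparsely (zero positions omitted)."""
    rows = []
    for p in profiles:
        (nz,) = np.nonzero(p.counts)
        for i in nz:
            c = p.counts[i]
            c = int(c) if float(c).is_integer() else float(c)
            rows.append((p.gene_id, p.sample_id, int(i) + 1, c))
    df = pd.DataFrame(rows, columns=["gene_id", "sample_id", "codon_position", "count"])
    write_table(df, path, comments)


def write_sample_totals(totals: Mapping[str, float], path, comments=None) -> None:
    df = pd.DataFrame(
        sorted(totals.items()), columns=["sample_id", "total_mapped"]
    )
    write_table(df, path, comments)


# ---------------------------------------------------------------------------
# sample pairing
# ---------------------------------------------------------------------------

def read_pairs_table(path) -> list[SamplePair]:
    df = read_table(path)
    pairs = [
        SamplePair(
            bait_id=str(r.bait_id),
            replicate_id=str(r.replicate_id),
            pulldown_sample=str(r.pulldown_sample),
            input_sample=str(r.input_sample),
        )
        for r in df.itertuples()
    ]
    keys = [(p.bait_id, p.replicate_id) for p in pairs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (bait_id, replicate_id) in pairs table")
    return pairs


def write_pairs_table(pairs: Iterable[SamplePair], path, comments=None) -> None:
    df = pd.DataFrame(
        [(p.bait_id, p.replicate_id, p.pulldown_sample, p.input_sample) for p in pairs],
        columns=["bait_id", "replicate_id", "pulldown_sample", "input_sample"],
    )
    write_table(df, path, comments)


# ---------------------------------------------------------------------------
# transmembrane domains
# ---------------------------------------------------------------------------

def read_tmd_table(path, source: TMDSource) -> list[TMDomain]:
    """Read TMD spans (gene_id, start_aa, end_aa) and attach a source label.

    Exact duplicate rows are collapsed to one span with a warning.
    """
    df = read_table(path)
    seen: set[tuple] = set()
    tmds: list[TMDomain] = []
    for r in df.itertuples():
        key = (str(r.gene_id), int(r.start_aa), int(r.end_aa))
        if key in seen:
            log.warning("duplicate TMD row %s:%d-%d collapsed", *key)
            continue
        seen.add(key)
        tmds.append(
            TMDomain(gene_id=key[0], start_aa=key[1], end_aa=key[2], source=source)
        )
    return tmds


def write_tmd_table(tmds: Iterable[TMDomain], path, comments=None) -> None:
    df = pd.DataFrame(
        [(t.gene_id, t.start_aa, t.end_aa, t.source.value) for t in tmds],
        columns=["gene_id", "start_aa", "end_aa", "source"],
    )
    write_table(df, path, comments)


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def read_proteome_table(path) -> list[ProteomeRecord]:
    """Read per-protein log2 ratios; optional columns may be empty."""
    df = read_table(path)
    records = []
    for r in df.itertuples():
        trans = getattr(r, "log2_translation_change", None)
        if trans is not None and pd.isna(trans):
            trans = None
        ntmd = getattr(r, "n_tmds", None)
        if ntmd is not None and pd.isna(ntmd):
            ntmd = None
        records.append(
            ProteomeRecord(
                protein_id=str(r.protein_id),
                log2_kd1_vs_control=float(r.log2_kd1_vs_control),
                log2_kd2_vs_control=float(r.log2_kd2_vs_control),
                log2_translation_change=None if trans is None else float(trans),
                n_tmds=None if ntmd is None else int(ntmd),
            )
        )
    return records


def write_proteome_table(records: Iterable[ProteomeRecord], path, comments=None) -> None:
    df = pd.DataFrame(
        [
            (
                r.protein_id,
                r.log2_kd1_vs_control,
                r.log2_kd2_vs_control,
                np.nan if r.log2_translation_change is None else r.log2_translation_change,
                np.nan if r.n_tmds is None else r.n_tmds,
            )
            for r in records
        ],
        columns=[
            "protein_id",
            "log2_kd1_vs_control",
            "log2_kd2_vs_control",
            "log2_translation_change",
            "n_tmds",
        ],
    )
    write_table(df, path, comments)
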