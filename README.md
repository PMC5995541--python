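# riboprox

Analysis of proximity-specific ribosome profiling to identify proteins
that a membrane-bound factor engages **cotranslationally**, with
companion analyses of transmembrane-domain (TMD) composition and of
dual-knockdown SILAC proteomics.

In proximity-specific ribosome profiling, a biotin ligase (BirA) fused
to a bait protein — here a subunit of the ER membrane protein complex
(EMC) — biotinylates tagged ribosomes translating in the bait's
vicinity. Sequencing footprints from the streptavidin-purified
ribosomes alongside the total pool gives, per gene and codon, a
pulldown and an input count profile. The package turns those profiles
into ranked candidate **client** genes, and characterizes client TMDs.

## The statistics at its core

For codon position *i* of a gene, with half-width *h* = 50 (101-codon
window) and per-sample total mapped reads *T*:

```
E(i) = [ Σ_{j=i−h..i+h} pulldown(j) / T_pd ] / [ Σ_{j=i−h..i+h} input(j) / T_in ]
```

windows truncated at gene boundaries, undefined (never infinite) where
the input window is empty. The ratio-of-ratios divides the test bait's
E(i) by that of a general-ER reference bait (a tail-anchored fusion),
cancelling generic ER targeting; each gene is scored by its maximum
over positions, per replicate.

Genes enter the ranking only if they pass three filters:

1. **mappability** — strictly more than 80% of CDS positions uniquely
   mappable with synthetic 25-nt reads (uniqueness assessed against the
   sense strand of the CDS pool);
2. **expression** — strictly more than 0.02 reads/codon per million
   mapped reads in every bait's input sample, and no 101-codon window
   with zero reads in any sample;
3. **localization** — pulldown/input RPKM ratio strictly above 1 in at
   least one bait sample pair.

A gene is called a client when its maximum ratio-of-ratios lies in the
top decile of eligible genes in **every** biological replicate
(`floor(N/10)` slots per replicate; boundary ties included).

Client TMD composition is compared against all TMDs by pooling
residues and computing, per property (aliphatic, aromatic, charged,
hydrophobic, polar), the ratio of residue fractions; 10,000 random
same-size TMD subsets drawn from the full TMD set give a 5th–95th
percentile null band. Dual-knockdown SILAC proteomes are partitioned
into proteins down/up in both knockdowns at an inclusive |log2| ≥ 0.5
threshold.

A seeded synthetic-data generator plants all of this structure
(targeting ramp ~60 codons after the first TMD, client enrichment
peaks after TMD clusters, log-normal expression, Poisson or
negative-binomial counts, shifted proteome ratios) so every stage is
testable without any download.

## Worked example

```python
import numpy as np
import riboprox as rp

spec = rp.SimulationSpec(n_genes=200, rng_seed=42)
sim = rp.simulate_all(spec)
calls, diag = rp.identify_clients(
    sim.transcriptome.genes, sim.profiles, sim.pairs,
    sim.test_bait, sim.reference_bait,
)
print(diag)
```

prints

```
{'n_profiled': 200, 'n_mappable': 200, 'n_expressed': 200,
 'n_localized': 90, 'n_eligible': 90, 'n_clients': 7}
```

— 200 simulated genes, of which the 90 ER-targeted ones pass the
localization filter, and 7 land in the top decile of both replicates.
Here all 7 are exactly the planted clients, with per-replicate maximum
ratio-of-ratios close to the planted peak gain of 4 (window averaging
over the ramp edge keeps the realized maximum slightly below it):

```
g0054 {'rep1': 3.45, 'rep2': 3.35}
g0104 {'rep1': 3.74, 'rep2': 3.63}
g0140 {'rep1': 3.5,  'rep2': 3.51}
```

Because simulated client TMDs are drawn from the same residue
distribution as all TMDs, their composition ratios sit inside the
resampled null band, e.g.

```python
seqs = {g.gene_id: g.protein_seq for g in sim.transcriptome.genes.values()}
client_tmds = [t for t in sim.transcriptome.tmds
               if t.gene_id in sim.transcriptome.client_ids]
for e in rp.property_enrichment(client_tmds, sim.transcriptome.tmds, seqs,
                                n_bootstrap=10000, rng=np.random.default_rng(42)):
    print(f"{e.property:<12} ratio={e.ratio:.3f} band=({e.ci_low:.3f}, {e.ci_high:.3f})")
```

```
ALIPHATIC    ratio=0.988 band=(0.890, 1.113)
AROMATIC     ratio=1.027 band=(0.783, 1.248)
CHARGED      ratio=1.020 band=(0.868, 1.141)
HYDROPHOBIC  ratio=1.031 band=(0.915, 1.089)
POLAR        ratio=1.091 band=(0.893, 1.110)
```

A ratio outside its band (as for a genuinely composition-biased client
set) flags the property as enriched or depleted.

## Command line

The same stages are available as subcommands over tab-separated files:

```
riboprox simulate --seed 7 --outdir data/
riboprox mappability --cds data/cds.fasta --out mapp.tsv
riboprox call-clients --cds data/cds.fasta --counts data/counts.tsv \
    --totals data/totals.tsv --pairs data/pairs.tsv --out clients.tsv
riboprox metagene ... ; riboprox composition ... ; riboprox proteome-call ...
riboprox run-all --simulate --seed 7 --outdir run/
```

All outputs carry their configuration in `#`-commented headers;
identical seeds reproduce byte-identical tables.

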