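# foramdelim

Amplicon metabarcoding inference for planktonic foraminifera: from raw
tagged 454-style reads to a reference-anchored molecular taxonomy and
ecological summaries.

## The problem

Metabarcoding surveys of marine plankton recover thousands of molecular
operational taxonomic units (MOTUs), but turning read clusters into
*named, comparable taxa* is hard: rDNA substitution rates in
foraminifera vary enormously between lineages, so no single similarity
threshold separates species everywhere. This package implements a
complete inference chain that solves the problem by *anchoring*
distance-based delimitation to curated reference sequences whose
morphospecies and genetic-type identities are known:

1. **Read preparation** — demultiplex by 8-nt sample tags, retain reads
   with the exact forward primer and no ambiguous base, trim to 300 bp
   after the primer.
2. **Chimera screening** — de-novo two-parent detection with
   UCHIME-style weighted votes on each side of the candidate breakpoint.
3. **Clustering** — SWARM-style single-linkage MOTUs at a local
   threshold of *d* = 2 differences (full edit distance).
4. **Reference screening** — global-alignment best hit against a
   PR²-style database; non-foraminiferal MOTUs discarded.
5. **Delimitation** — Kimura (1980) two-parameter distances, an ABGD
   barcode-gap sweep over 100 priors with relative gap 0.5, and
   selection of two plateau levels: the coarsest partition that never
   merges reference genetic types of one morphospecies (genetic-type
   level) and the coarsest that never merges distinct morphospecies
   (morphospecies level). Output is a 4-rank nomenclature
   `Morphogroup | Genus | Morphospecies | GeneticType`.
6. **Meta-reference reassignment** — environmental representatives join
   the curated references; *all* MOTUs (including rare ones) with >95 %
   identity and unambiguous attribution are retained and merged by
   taxon.
7. **Ecology** — taxon × sample tables, analytic (hypergeometric)
   rarefaction, occurrence profiles, and clade composition per plankton
   size fraction.

A synthetic-community generator (`foramdelim.synthdata`) emulates the
survey design — stations × {surface, deep chlorophyll maximum} × three
plankton size fractions, 350–700 bp amplicons of which only a minority
reach the reverse primer, tiered divergences producing a barcode gap,
"long-branch" clades with multiplied rates, PCR chimeras and
pyrosequencing noise — with full ground truth, so every stage is
testable without any external data.

## Key formulas

K80 distance from transition proportion *P* and transversion proportion
*Q* (pairwise deletion of gapped/ambiguous sites):

    d = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

Analytic rarefaction (expected richness in a subsample of *n* of *N*
reads with per-taxon counts *N_i*):

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

## Worked example

```python
from foramdelim import synthdata as sd
from foramdelim.pipeline import run_pipeline

tax  = sd.generate_taxonomy(n_morphogroups=3, species_per_genus=2,
                            types_per_species=2, seed=0)
refs = sd.evolve_references(tax, seed=0)
outg = sd.make_outgroup_references(seed=2)
cfg  = sd.SimulationConfig(n_stations=2, reads_per_sample=300, seed=1)
ds   = sd.simulate_reads(tax, refs, cfg, outgroups=outg)

res = run_pipeline(ds)
print(res.n_raw_reads, res.n_retained_reads, res.n_motus,
      res.n_abundant_motus, res.n_genetic_types, res.n_morphospecies)
print(res.evaluation)
```

prints

```
3600 2416 464 12 12 6
{'chimera_sensitivity': 0.9643, 'chimera_fpr': 0.0, 'ari_genetic_type': 1.0,
 'ari_morphospecies': 1.0, 'n_scored_motus': 12.0}
```

Reading: of 3,600 simulated reads, 2,416 survive demultiplexing, the
exact-primer/no-ambiguity filter and the 300 bp trim; they dereplicate
and cluster into 464 MOTUs of which 12 pass the occurrence/abundance
filter (≥3 samples, ≥10 reads). The anchored delimitation recovers
exactly the 12 generating genetic types in 6 morphospecies (adjusted
Rand index 1.0 at both ranks), and the chimera screen finds 96 % of
detectable simulated chimeras with no false positives on this seed.

The same chain is exposed on the command line:

```bash
foramdelim simulate --out sim/ --seed 0          # reads + tags + truth
foramdelim prep --reads sim/reads.fasta --tags sim/tags.tsv --out prep/
foramdelim chimera --in prep/trimmed.fasta --out chim/
foramdelim cluster --in chim/clean.fasta --out motus/
foramdelim run --seed 0                          # full chain + summary JSON
```

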